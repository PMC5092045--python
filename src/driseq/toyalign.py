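"""Exhaustive spliced alignment of short reads against a genome pair.

This is a deliberately simple, exact aligner for desk-scale simulated
data: every full-length alignment of a read (no clipping, substitutions
only) is found, both contiguous (every genomic offset, both strands)
and spliced (every offset in every annotated transcript, projected back
to genomic blocks).  Only alignments attaining the maximum score
(``read_length - mismatches``) are reported, emulating aligners
configured to keep max-score hits only; duplicates arising from
overlapping genomic and transcript-projected coordinates are merged by
``(strand, blocks)``.

A pigeonhole k-mer seed index accelerates the scan: with seeds of
length *k* and ``n = len(read) // k >= max_mismatches + 1`` disjoint
seeds, any alignment with at most ``max_mismatches`` substitutions must
match at least one seed exactly, so seeding loses nothing relative to
the literal all-offset scan.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pysam

from .simgen import GenomePair, GeneModel, Transcript, revcomp, spliced_sequence, transcript_to_genomic


@dataclass(frozen=True)
class AlignmentRecord:
    """One full-length alignment of a read to one genome.

    ``blocks`` are ordered, non-overlapping 0-based half-open genomic
    intervals (more than one block means the alignment spans introns);
    ``clipped`` is always 0 here since only full-length alignments are
    emitted.
    """

    read_id: str
    genome_id: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    mismatches: int
    clipped: int = 0

    @property
    def read_length(self) -> int:
        return sum(e - s for s, e in self.blocks) + self.clipped

    @property
    def score(self) -> int:
        return self.read_length - self.mismatches


class GenomeIndex:
    """Seed index over one genome and its annotated transcriptome."""

    def __init__(self, genome_id: str, seq: str, genes: list[GeneModel], seed_len: int = 15):
        self.genome_id = genome_id
        self.seq = seq
        self.arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        self.seed_len = seed_len
        self._gkmers: dict[str, list[int]] = defaultdict(list)
        for i in range(len(seq) - seed_len + 1):
            self._gkmers[seq[i : i + seed_len]].append(i)
        self.transcripts: list[tuple[Transcript, np.ndarray]] = []
        self._tkmers: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for gene in genes:
            for tx in gene.transcripts:
                if len(tx.exons) < 2:
                    continue  # single-exon transcripts are covered by the genomic scan
                tseq = spliced_sequence(seq, tx)
                ti = len(self.transcripts)
                self.transcripts.append((tx, np.frombuffer(tseq.encode(), dtype=np.uint8)))
                for i in range(len(tseq) - seed_len + 1):
                    self._tkmers[tseq[i : i + seed_len]].append((ti, i))

    def _candidates(self, query: str):
        k = self.seed_len
        L = len(query)
        gcand: set[int] = set()
        tcand: set[tuple[int, int]] = set()
        for j in range(L // k):
            seed = query[j * k : (j + 1) * k]
            for p in self._gkmers.get(seed, ()):
                o = p - j * k
                if 0 <= o <= len(self.seq) - L:
                    gcand.add(o)
            for ti, p in self._tkmers.get(seed, ()):
                o = p - j * k
                if 0 <= o <= len(self.transcripts[ti][1]) - L:
                    tcand.add((ti, o))
        return gcand, tcand


def enumerate_alignments(
    read_id: str,
    sequence: str,
    index: GenomeIndex,
    max_mismatches: int = 4,
) -> list[AlignmentRecord]:
    """All maximum-score full-length alignments of a read to one genome.

    Both read orientations are searched; spliced alignments are
    discovered through the annotated transcripts and projected to
    genomic blocks.  Alignments with more than ``max_mismatches``
    substitutions are not considered; among the rest only those at the
    minimum mismatch count are returned.  Returns an empty list when
    nothing aligns.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    L = len(sequence)
    if L // index.seed_len < max_mismatches + 1:
        raise ValueError(
            "read too short for the seed index: need len(read)//seed_len "
            ">= max_mismatches + 1 for the pigeonhole guarantee"
        )
    found: dict[tuple[str, tuple[tuple[int, int], ...]], int] = {}
    for strand, query in (("+", sequence), ("-", revcomp(sequence))):
        qarr = np.frombuffer(query.encode(), dtype=np.uint8)
        gcand, tcand = index._candidates(query)
        for o in gcand:
            mm = int(np.count_nonzero(index.arr[o : o + L] != qarr))
            if mm <= max_mismatches:
                key = (strand, ((o, o + L),))
                found[key] = mm
        for ti, o in tcand:
            tx, tarr = index.transcripts[ti]
            mm = int(np.count_nonzero(tarr[o : o + L] != qarr))
            if mm <= max_mismatches:
                blocks = transcript_to_genomic(tx.exons, o, o + L)
                key = (strand, blocks)
                found[key] = mm
    if not found:
        return []
    best = min(found.values())
    return [
        AlignmentRecord(read_id, index.genome_id, strand, blocks, mm)
        for (strand, blocks), mm in sorted(found.items())
        if mm == best
    ]


class PairAligner:
    """Aligner over both genomes of a :class:`GenomePair`."""

    def __init__(self, pair: GenomePair, seed_len: int = 15, max_mismatches: int = 4):
        self.max_mismatches = max_mismatches
        self.index_a = GenomeIndex("A", pair.seq_a, pair.genes_a, seed_len)
        self.index_b = GenomeIndex("B", pair.seq_b, pair.genes_b, seed_len)

    def align(self, read_id: str, sequence: str):
        return (
            enumerate_alignments(read_id, sequence, self.index_a, self.max_mismatches),
            enumerate_alignments(read_id, sequence, self.index_b, self.max_mismatches),
        )


def _cigar_tuples(blocks):
    cig = []
    prev_end = None
    for s, e in blocks:
        if prev_end is not None:
            cig.append((3, s - prev_end))  # N
        cig.append((0, e - s))  # M
        prev_end = e
    return cig


def write_sam(
    alignments: list[AlignmentRecord],
    ref_lengths: dict[str, int],
    path: str,
    read_seqs: dict[str, str] | None = None,
) -> None:
    """Write alignments as SAM 1.6 (1-based POS, M/N CIGAR, NM tag).

    ``ref_lengths`` maps reference names (``chrA``/``chrB`` for genomes
    A/B) to lengths.  Alignments referencing an undeclared genome, or
    extending past the reference end, raise ``ValueError``.  When the
    same read has several alignments, all after the first are flagged
    secondary.
    """
    names = list(ref_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": ref_lengths[n]} for n in names],
    }
    seen: set[str] = set()
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for al in alignments:
            ref = f"chr{al.genome_id}"
            if ref not in ref_lengths:
                raise ValueError(f"unknown reference for genome {al.genome_id!r}")
            if al.blocks[-1][1] > ref_lengths[ref]:
                raise ValueError(f"alignment past end of {ref}")
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = al.read_id
            seg.flag = (16 if al.strand == "-" else 0) | (
                256 if al.read_id in seen else 0
            )
            seen.add(al.read_id)
            seg.reference_id = names.index(ref)
            seg.reference_start = al.blocks[0][0]
            seg.mapping_quality = 255
            seg.cigartuples = _cigar_tuples(al.blocks)
            if read_seqs and al.read_id in read_seqs:
                s = read_seqs[al.read_id]
                seg.query_sequence = revcomp(s) if al.strand == "-" else s
            seg.set_tag("NM", al.mismatches)
            out.write(seg)


def read_sam(path: str) -> list[AlignmentRecord]:
    """Read a SAM file written by :func:`write_sam` back into records."""
    records = []
    with pysam.AlignmentFile(path, "r") as f:
        for seg in f:
            if seg.is_unmapped:
                continue
            ref = seg.reference_name
            genome_id = ref[3:] if ref.startswith("chr") else ref
            blocks = tuple((s, e) for s, e in seg.get_blocks())
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    genome_id=genome_id,
                    strand="-" if seg.is_reverse else "+",
                    blocks=blocks,
                    mismatches=int(seg.get_tag("NM")),
                )
            )
    return records
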