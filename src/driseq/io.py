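"""Reading and writing the pipeline's on-disk formats.

FASTA (60-column wrap) and FASTQ (Phred+33, fixed quality) go through
Biopython; GTF parsing goes through gffutils.  GTF coordinates are
1-based inclusive with ``gene_id``/``transcript_id`` attributes, as is
conventional.
"""

from __future__ import annotations

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simgen import GeneModel, GenomePair, SimulatedRead, Transcript

FASTQ_QUALITY = 40  # fixed per-base quality for simulated reads


def write_fasta(seq: str, name: str, path: str) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_gtf(genes: list[GeneModel], seqname: str, path: str) -> None:
    """Write gene models as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                for s, e in t.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                    )
                    fh.write(
                        f"{seqname}\tdriseq\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )


def read_gtf(path: str) -> list[GeneModel]:
    """Parse exon features back into gene models."""
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by="start"):
        gid = feat.attributes["gene_id"][0]
        tid = feat.attributes["transcript_id"][0]
        g = by_gene.setdefault(gid, {"strand": feat.strand, "tx": {}})
        g["tx"].setdefault(tid, []).append((feat.start - 1, feat.end))
    genes = []
    for gid in sorted(by_gene):
        info = by_gene[gid]
        transcripts = tuple(
            Transcript(tid, tuple(sorted(info["tx"][tid])))
            for tid in sorted(info["tx"])
        )
        genes.append(GeneModel(gid, info["strand"], transcripts))
    return genes


def write_genome_pair(pair: GenomePair, outdir) -> dict[str, str]:
    """Write both genomes and annotations; returns the paths written."""
    paths = {}
    for sp in ("A", "B"):
        fa = str(outdir / f"{sp}.fa")
        gtf = str(outdir / f"{sp}.gtf")
        write_fasta(pair.seq(sp), f"chr{sp}", fa)
        write_gtf(pair.genes(sp), f"chr{sp}", gtf)
        paths[f"fasta_{sp}"] = fa
        paths[f"gtf_{sp}"] = gtf
    return paths


def write_fastq(reads: list[SimulatedRead], path_r1: str, path_r2: str) -> None:
    """Write mates to a pair of FASTQ files with fixed quality."""

    def recs(mate):
        for r in reads:
            if r.mate != mate:
                continue
            rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
            rec.letter_annotations["phred_quality"] = [FASTQ_QUALITY] * len(r.sequence)
            yield rec

    SeqIO.write(recs(1), path_r1, "fastq")
    SeqIO.write(recs(2), path_r2, "fastq")


def read_fastq(path: str) -> list[tuple[str, str]]:
    """Read names and sequences from a FASTQ file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fastq")]
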