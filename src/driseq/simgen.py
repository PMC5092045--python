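"""Synthetic dual-genome experiments with full ground truth.

This module emulates the data structure of a transchromosomic RNA-seq
study, in which transcripts from two homologous genomes (here "A", the
host genome, and "B", the transferred chromosome) are sequenced together
and every read must later be attributed to its species of origin.

Three generators are provided:

* :func:`generate_genome_pair` — two homologous annotated genomes that
  differ only by point substitutions at a tunable per-site rate, with a
  shared exon/intron structure so that homologous coordinates coincide
  exactly (the substitution-only model keeps the orthologous-position
  oracle exact).
* :func:`simulate_reads` — spliced paired-end reads with sequencing
  errors and a complete truth record (species, gene, transcript, genomic
  blocks, error count) per mate.
* :func:`simulate_count_experiment` — negative-binomial count matrices
  for a control-vs-stimulated design in both species, with log-normal
  basal expression, normally distributed induction effects, and a
  controlled spread of between-species regulation differences (the log2
  differential regulation index, DRI) and of basal-expression
  differences (the log2 differential basal expression index, DBEI).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import CountMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A transcript as an ordered tuple of exon intervals.

    Exons are 0-based half-open genomic intervals, sorted and
    non-overlapping; the spliced length is the sum of exon lengths.
    """

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    strand: str
    transcripts: tuple[Transcript, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(s for t in self.transcripts for s, _ in t.exons),
            max(e for t in self.transcripts for _, e in t.exons),
        )

    def union_exons(self) -> list[tuple[int, int]]:
        """Merged (union) exon intervals over all transcripts."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


@dataclass
class GenomePair:
    """Two homologous annotated genomes with known per-site divergence."""

    seq_a: str
    seq_b: str
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    divergence: float
    seed: int

    def genes(self, species: str) -> list[GeneModel]:
        return self.genes_a if species == "A" else self.genes_b

    def seq(self, species: str) -> str:
        return self.seq_a if species == "A" else self.seq_b


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    mate: int
    sequence: str
    true_species: str
    true_gene: str
    true_transcript: str
    true_blocks: tuple[tuple[int, int], ...]
    true_strand: str
    n_errors: int

    @property
    def name(self) -> str:
        """Read name as written to FASTQ/SAM: ``<fragment>/<mate>``."""
        return f"{self.read_id}/{self.mate}"


def transcript_to_genomic(
    exons: tuple[tuple[int, int], ...], t_start: int, t_end: int
) -> tuple[tuple[int, int], ...]:
    """Project a forward-spliced coordinate interval onto genomic blocks.

    ``t_start``/``t_end`` index into the concatenation of the exon
    sequences in genomic order (0-based half-open).
    """
    blocks = []
    offset = 0
    for s, e in exons:
        ln = e - s
        lo, hi = max(t_start, offset), min(t_end, offset + ln)
        if lo < hi:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += ln
    return tuple(blocks)


def _random_composition(rng, total: int, parts: int, minimum: int) -> list[int]:
    extra = total - parts * minimum
    if extra < 0:
        raise ValueError("total too small for the requested composition")
    counts = rng.multinomial(extra, [1.0 / parts] * parts)
    return [minimum + int(c) for c in counts]


def generate_genome_pair(
    n_genes: int = 50,
    gene_length_range: tuple[int, int] = (600, 2000),
    intron_params: dict | None = None,
    divergence: float = 0.02,
    seed: int = 0,
    *,
    min_exon: int = 80,
    spacer_range: tuple[int, int] = (200, 500),
    second_transcript_prob: float = 0.5,
) -> GenomePair:
    """Generate a pair of homologous annotated genomes.

    Genome A is a uniform-random nucleotide sequence with ``n_genes``
    gene models laid end to end (random strand, 1–4 exons, intergenic
    spacers).  Genome B shares the coordinates and gene structure of A
    exactly and differs only by independent per-site substitutions at
    probability ``divergence``.  ``gene_length_range`` bounds the mRNA
    (summed-exon) length of the primary transcript; a second transcript
    that skips one exon is added with probability
    ``second_transcript_prob`` when the remainder stays usable.

    Raises
    ------
    ValueError
        If ``divergence`` is outside ``[0, 0.25)`` or ``n_genes < 1``.
    """
    if not (0.0 <= divergence < 0.25):
        raise ValueError(f"divergence must be in [0, 0.25), got {divergence}")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gene_length_range
    if lo < 2 * min_exon:
        raise ValueError(f"gene_length_range minimum must be >= {2 * min_exon}")
    intron_params = intron_params or {}
    n_introns_range = intron_params.get("n_introns_range", (0, 3))
    intron_length_range = intron_params.get("length_range", (60, 400))

    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    cursor = int(rng.integers(*spacer_range))
    for gi in range(n_genes):
        mrna_len = int(rng.integers(lo, hi + 1))
        n_introns = int(rng.integers(n_introns_range[0], n_introns_range[1] + 1))
        n_exons = min(n_introns + 1, mrna_len // min_exon)
        n_exons = max(n_exons, 1)
        exon_lens = _random_composition(rng, mrna_len, n_exons, min_exon)
        intron_lens = [
            int(rng.integers(*intron_length_range)) for _ in range(n_exons - 1)
        ]
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
        gene_id = f"g{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts = [Transcript(f"{gene_id}.t1", tuple(exons))]
        if len(exons) >= 2 and rng.random() < second_transcript_prob:
            drop = int(rng.integers(0, len(exons)))
            alt = tuple(e for i, e in enumerate(exons) if i != drop)
            if sum(e - s for s, e in alt) >= 300:
                transcripts.append(Transcript(f"{gene_id}.t2", alt))
        genes.append(GeneModel(gene_id, strand, tuple(transcripts)))
        cursor = pos + int(rng.integers(*spacer_range))

    genome_len = cursor
    codes = rng.integers(0, 4, size=genome_len)
    seq_a = _BASES[codes].tobytes().decode()
    mask = rng.random(genome_len) < divergence
    shift = rng.integers(1, 4, size=genome_len)
    codes_b = np.where(mask, (codes + shift) % 4, codes)
    seq_b = _BASES[codes_b].tobytes().decode()
    return GenomePair(seq_a, seq_b, genes, list(genes), divergence, seed)


def spliced_sequence(seq: str, transcript: Transcript) -> str:
    """Forward-spliced transcript sequence (exons concatenated in genomic order)."""
    return "".join(seq[s:e] for s, e in transcript.exons)


def simulate_reads(
    pair: GenomePair,
    n_fragments: int,
    read_length: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Simulate paired-end reads from both genomes with known truth.

    Each fragment is drawn from a uniformly chosen species, gene and
    transcript at a uniform start position.  The fragment length is
    fixed at twice the read length (mates abut); mate 1 carries the 5'
    end of the mRNA and mate 2 the reverse complement of the 3' end.
    Sequencing errors are independent per-base substitutions at
    ``error_rate``.

    Raises
    ------
    ValueError
        If twice the read length exceeds the shortest transcript, or
        ``error_rate`` is outside ``[0, 1]``.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must be in [0, 1]")
    frag_len = 2 * read_length
    shortest = min(t.length for g in pair.genes_a for t in g.transcripts)
    if frag_len > shortest:
        raise ValueError(
            f"read_length {read_length} too large: fragment length {frag_len} "
            f"exceeds shortest transcript length {shortest}"
        )
    rng = np.random.default_rng(seed)
    # cache forward-spliced sequences per species/transcript
    cache: dict[tuple[str, str], tuple[str, GeneModel, Transcript]] = {}
    for sp in ("A", "B"):
        seq = pair.seq(sp)
        for gene in pair.genes(sp):
            for tx in gene.transcripts:
                cache[(sp, tx.transcript_id)] = (
                    spliced_sequence(seq, tx),
                    gene,
                    tx,
                )

    reads: list[SimulatedRead] = []
    for i in range(n_fragments):
        sp = "A" if rng.integers(2) == 0 else "B"
        gene = pair.genes(sp)[int(rng.integers(len(pair.genes(sp))))]
        tx = gene.transcripts[int(rng.integers(len(gene.transcripts)))]
        fwd, _, _ = cache[(sp, tx.transcript_id)]
        L = tx.length
        start = int(rng.integers(0, L - frag_len + 1))
        mrna = revcomp(fwd) if gene.strand == "-" else fwd
        frag = mrna[start : start + frag_len]
        frag_id = f"frag{i:06d}"
        for mate in (1, 2):
            if mate == 1:
                raw = frag[:read_length]
                m_lo, m_hi = start, start + read_length
                read_strand = "+"
            else:
                raw = revcomp(frag[read_length:])
                m_lo, m_hi = start + read_length, start + frag_len
                read_strand = "-"
            if gene.strand == "-":
                # mRNA coordinate u maps to forward-spliced coordinate L-1-u
                f_lo, f_hi = L - m_hi, L - m_lo
                genome_strand = "-" if read_strand == "+" else "+"
            else:
                f_lo, f_hi = m_lo, m_hi
                genome_strand = read_strand
            blocks = transcript_to_genomic(tx.exons, f_lo, f_hi)
            if error_rate > 0:
                arr = np.frombuffer(raw.encode(), dtype=np.uint8).copy()
                err = rng.random(read_length) < error_rate
                n_err = int(err.sum())
                if n_err:
                    idx = np.flatnonzero(err)
                    cur = np.searchsorted(_BASES, arr[idx])  # ACGT are sorted
                    arr[idx] = _BASES[(cur + rng.integers(1, 4, size=n_err)) % 4]
                seq_out = arr.tobytes().decode()
            else:
                seq_out, n_err = raw, 0
            reads.append(
                SimulatedRead(
                    read_id=frag_id,
                    mate=mate,
                    sequence=seq_out,
                    true_species=sp,
                    true_gene=gene.gene_id,
                    true_transcript=tx.transcript_id,
                    true_blocks=blocks,
                    true_strand=genome_strand,
                    n_errors=n_err,
                )
            )
    return reads


def reads_truth_table(reads: list[SimulatedRead]) -> pd.DataFrame:
    """Truth labels for a read set as a tidy table (one row per mate)."""
    return pd.DataFrame(
        {
            "read": [r.name for r in reads],
            "mate": [r.mate for r in reads],
            "true_species": [r.true_species for r in reads],
            "true_gene": [r.true_gene for r in reads],
            "true_transcript": [r.true_transcript for r in reads],
            "true_strand": [r.true_strand for r in reads],
            "true_blocks": [
                ";".join(f"{s}-{e}" for s, e in r.true_blocks) for r in reads
            ],
            "n_errors": [r.n_errors for r in reads],
        }
    )


def simulate_count_experiment(
    n_genes: int,
    n_reps: int = 3,
    frac_induced: float = 0.05,
    mean_log2fc: float = 2.0,
    sd_log2fc: float = 1.0,
    sigma_dri: float = 0.68,
    nb_dispersion: float = 0.05,
    seed: int = 0,
    *,
    sigma_dbei: float = 1.39,
    basal_log_mean: float = math.log(100.0),
    basal_log_sd: float = 1.5,
    depth_log_sd: float = 0.15,
) -> tuple[pd.DataFrame, dict[str, CountMatrix]]:
    """Simulate a two-species control/stimulated count experiment.

    Species A plays the host (mouse-side) role and species B the
    human-side role.  Per gene: basal mean expression is log-normal; a
    fraction ``frac_induced`` of genes receives a normal log2
    fold-change effect in species A (non-induced genes have log2fc 0);
    the species-B effect is the species-A effect plus an independent
    N(0, ``sigma_dri``) log2-DRI term, so the true log2 DRI of the gene
    set has standard deviation ``sigma_dri``.  Basal expression in B is
    the A basal scaled by an independent N(0, ``sigma_dbei``) log2-DBEI
    term.  Counts are negative-binomial (gamma-Poisson) draws around
    depth-factor-scaled means.

    Returns the truth table and a dict of :class:`CountMatrix` keyed by
    species.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not (0.0 <= frac_induced <= 1.0):
        raise ValueError("frac_induced must be in [0, 1]")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    if sigma_dri < 0 or sigma_dbei < 0:
        raise ValueError("spread parameters must be non-negative")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    induced = rng.random(n_genes) < frac_induced
    log2fc_m = np.where(induced, rng.normal(mean_log2fc, sd_log2fc, n_genes), 0.0)
    log2_dri = rng.normal(0.0, sigma_dri, n_genes) if sigma_dri > 0 else np.zeros(n_genes)
    log2fc_h = log2fc_m + log2_dri
    log2_dbei = (
        rng.normal(0.0, sigma_dbei, n_genes) if sigma_dbei > 0 else np.zeros(n_genes)
    )
    basal_m = rng.lognormal(basal_log_mean, basal_log_sd, n_genes)
    basal_h = basal_m * np.exp2(log2_dbei)

    truth = pd.DataFrame(
        {
            "basal_mean_m": basal_m,
            "basal_mean_h": basal_h,
            "induced": induced,
            "log2fc_m": log2fc_m,
            "log2fc_h": log2fc_h,
            "true_log2_dri": log2_dri,
            "log2_dbei": log2_dbei,
            "dispersion": nb_dispersion,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    matrices = counts_from_truth(
        truth, n_reps=n_reps, seed=int(rng.integers(2**31)), depth_log_sd=depth_log_sd
    )
    return truth, matrices


def counts_from_truth(
    truth: pd.DataFrame,
    n_reps: int = 3,
    seed: int = 0,
    depth_log_sd: float = 0.15,
) -> dict[str, CountMatrix]:
    """Negative-binomial count matrices conditional on a given truth table.

    Draws a fresh control/stimulated experiment (both species) around
    the basal means, fold changes and dispersion recorded in ``truth``
    — an independent re-measurement of the same underlying regulatory
    program, as when the same sequence-encoded effects are assayed in a
    second preparation.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    n_genes = len(truth)
    disp = truth["dispersion"].to_numpy(dtype=float)
    if (disp <= 0).any():
        raise ValueError("dispersion must be positive")
    matrices: dict[str, CountMatrix] = {}
    for sp, basal_col, fc_col in (
        ("A", "basal_mean_m", "log2fc_m"),
        ("B", "basal_mean_h", "log2fc_h"),
    ):
        basal = truth[basal_col].to_numpy(dtype=float)
        log2fc = truth[fc_col].to_numpy(dtype=float)
        cols, meta = [], []
        data = np.empty((n_genes, 2 * n_reps), dtype=np.int64)
        j = 0
        for cond, mult in (("control", np.ones(n_genes)), ("stimulated", np.exp2(log2fc))):
            for rep in range(1, n_reps + 1):
                depth = rng.lognormal(0.0, depth_log_sd)
                mu = basal * mult * depth
                lam = rng.gamma(1.0 / disp, mu * disp)
                data[:, j] = rng.poisson(lam)
                cols.append(f"{sp}_{cond}_{rep}")
                meta.append({"sample": f"{sp}_{cond}_{rep}", "species": sp,
                             "condition": cond, "replicate": rep})
                j += 1
        counts = pd.DataFrame(data, index=truth.index, columns=cols)
        samples = pd.DataFrame(meta).set_index("sample")
        matrices[sp] = CountMatrix(counts=counts, samples=samples)
    return matrices


def simulate_induction_programs(
    cluster_sizes: tuple[int, ...] = (3, 1),
    n_reps: int = 3,
    n_genes: int = 2000,
    signal_sd: float = 1.0,
    noise_sd: float = 0.7,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Replicate-level log2 fold-change vectors under a shared-signal model.

    Each cluster draws one N(0, ``signal_sd``) induction program over
    genes; every preparation in the cluster and every replicate within
    a preparation observes that program plus independent
    N(0, ``noise_sd``) replicate noise.  Returns the vectors keyed by
    replicate label and a map from label to cluster index — the
    generative construction behind the replicate connection map.
    """
    rng = np.random.default_rng(seed)
    vectors: dict[str, np.ndarray] = {}
    cluster_of: dict[str, int] = {}
    for ci, n_preps in enumerate(cluster_sizes):
        program = rng.normal(0.0, signal_sd, n_genes)
        for pi in range(n_preps):
            for ri in range(1, n_reps + 1):
                label = f"c{ci}p{pi}_r{ri}"
                vectors[label] = program + rng.normal(0.0, noise_sd, n_genes)
                cluster_of[label] = ci
    return vectors, cluster_of


def make_promoter_pair(
    length: int = 600,
    divergence: float = 0.02,
    n_sites: int = 3,
    motif_text: str = "TGACTCA",
    seed: int = 0,
) -> tuple[str, str]:
    """Synthetic promoter pair with species-specific planted motif sites.

    Returns ``(promoter_1, promoter_2)`` where promoter 2 is the
    diverged homolog of promoter 1 and ``n_sites`` copies of
    ``motif_text`` are planted at evenly spaced positions in promoter 1
    only; the homologous windows in promoter 2 carry a single-base
    disruption of the site.  Synthetic stand-in for a promoter pair in
    which one species has gained activity-response elements.
    """
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    mask = rng.random(length) < divergence
    shift = rng.integers(1, 4, size=length)
    codes2 = np.where(mask, (codes + shift) % 4, codes)
    s1 = list(_BASES[codes].tobytes().decode())
    s2 = list(_BASES[codes2].tobytes().decode())
    broken = list(motif_text)
    broken[3] = "A" if motif_text[3] != "A" else "T"
    broken = "".join(broken)
    step = length // (n_sites + 1)
    for i in range(1, n_sites + 1):
        p = i * step
        s1[p : p + len(motif_text)] = motif_text
        s2[p : p + len(motif_text)] = broken
    return "".join(s1), "".join(s2)
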