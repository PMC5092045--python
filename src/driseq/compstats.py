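"""Cross-species comparative statistics over ortholog pairs.

Implements the pair-level statistics used to compare activity-dependent
gene regulation between two species: the differential regulation index
(DRI, fold-change ratio between species for an ortholog pair) and the
differential basal expression index (DBEI, basal-expression ratio);
expression-filtered 1:1 ortholog pairing; Pearson correlations with
Fisher-z confidence intervals; strongly-induced cohort and conserved
induction overlap counts; replicate connection maps (complete graphs
edge-weighted by R^2 of log2 fold-change vectors); the within-sample
("Tc1-style") versus separate-preparation DRI concordance; and a
promoter motif divergence scan based on global pairwise alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from Bio import Align

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT_IUPAC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


# ---------------------------------------------------------------------------
# ortholog pairing and the DRI/DBEI table


def pair_orthologs_and_filter(
    tables_a: dict[str, pd.DataFrame],
    tables_b: dict[str, pd.DataFrame],
    ortholog_map: pd.DataFrame,
    min_avg_expr: float = 0.5,
) -> tuple[pd.DataFrame, int]:
    """Retain 1:1 ortholog pairs expressed above threshold everywhere.

    ``ortholog_map`` has columns ``gene_a``/``gene_b``; rows whose
    ``gene_a`` or ``gene_b`` appears more than once (non-bijective) are
    dropped and counted.  A pair is retained iff the gene's mean
    expression across samples is strictly greater than
    ``min_avg_expr`` in every supplied preparation table (``tables_a``
    are preparations measuring species-A genes, ``tables_b``
    species-B genes; tables are genes x samples).

    Returns the retained pairs (columns gene_a, gene_b) and the number
    of non-bijective rows dropped.
    """
    m = ortholog_map[["gene_a", "gene_b"]].copy()
    dup = m["gene_a"].duplicated(keep=False) | m["gene_b"].duplicated(keep=False)
    n_dropped = int(dup.sum())
    m = m[~dup]

    def passes(gene: str, tables: dict[str, pd.DataFrame]) -> bool:
        for tab in tables.values():
            if gene not in tab.index:
                return False
            if not tab.loc[gene].mean() > min_avg_expr:
                return False
        return True

    keep = [
        passes(ga, tables_a) and passes(gb, tables_b)
        for ga, gb in zip(m["gene_a"], m["gene_b"])
    ]
    return m[keep].reset_index(drop=True), n_dropped


def compute_dri_table(
    pairs: pd.DataFrame,
    de_h: pd.DataFrame,
    de_m: pd.DataFrame,
    basal_h: pd.Series,
    basal_m: pd.Series,
) -> tuple[pd.DataFrame, int]:
    """Per-pair DRI and DBEI from two DE tables and basal expression.

    DRI = fold-change(human-side) / fold-change(mouse-side); DBEI =
    basal(human-side) / basal(mouse-side).  ``de_h`` is indexed by
    species-B (``gene_b``) ids and ``de_m`` by species-A (``gene_a``)
    ids, both with a ``fold_change`` column.  Pairs missing from any
    input are skipped and tallied.
    """
    rows, skipped = [], 0
    for ga, gb in zip(pairs["gene_a"], pairs["gene_b"]):
        if (
            gb not in de_h.index
            or ga not in de_m.index
            or gb not in basal_h.index
            or ga not in basal_m.index
        ):
            skipped += 1
            continue
        fc_h = float(de_h.at[gb, "fold_change"])
        fc_m = float(de_m.at[ga, "fold_change"])
        bh, bm = float(basal_h[gb]), float(basal_m[ga])
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "fc_h": fc_h,
                "fc_m": fc_m,
                "dri": fc_h / fc_m,
                "log2_dri": np.log2(fc_h) - np.log2(fc_m),
                "basal_h": bh,
                "basal_m": bm,
                "dbei": bh / bm if bm > 0 else np.nan,
                "log2_dbei": np.log2(bh) - np.log2(bm) if bh > 0 and bm > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows), skipped


@dataclass
class DistributionSummary:
    mean: float
    sd: float
    n: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def summarize_log2_distribution(values, bins: int = 50) -> DistributionSummary:
    """Mean, sample SD (n-1 denominator) and histogram of log2 values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two finite values")
    counts, edges = np.histogram(v, bins=bins)
    return DistributionSummary(
        mean=float(v.mean()), sd=float(v.std(ddof=1)), n=int(v.size),
        hist_counts=counts, hist_edges=edges,
    )


# ---------------------------------------------------------------------------
# correlation inference


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    ``tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3))``; degenerate at
    |r| = 1, where the interval collapses to the point.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = scipy.stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def pearson_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with a Fisher-z CI and a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = scipy.stats.pearsonr(x, y)
    if 1.0 - abs(r) < 1e-12:  # numerically exact linear relation
        r = float(np.copysign(1.0, r))
    lo, hi = fisher_ci(float(r), x.size, alpha)
    return CorrelationResult(float(r), lo, hi, float(p), int(x.size))


# ---------------------------------------------------------------------------
# induced cohorts and conserved-induction overlap


def induced_cohort(
    de_h: pd.DataFrame,
    de_m: pd.DataFrame,
    pairs: pd.DataFrame,
    fc_min: float = 5.0,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Pairs strongly and significantly induced in both species.

    Both orthologs must satisfy ``fold_change > fc_min`` (strict) and
    ``padj < padj_max``.
    """
    rows = []
    for ga, gb in zip(pairs["gene_a"], pairs["gene_b"]):
        if gb not in de_h.index or ga not in de_m.index:
            continue
        h, m = de_h.loc[gb], de_m.loc[ga]
        if (
            h["fold_change"] > fc_min
            and m["fold_change"] > fc_min
            and h["padj"] < padj_max
            and m["padj"] < padj_max
        ):
            rows.append({"gene_a": ga, "gene_b": gb,
                         "fc_h": h["fold_change"], "fc_m": m["fold_change"]})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "fc_h", "fc_m"])


def conserved_induction_overlap(
    reference_de: pd.DataFrame,
    comparison_des: dict[str, pd.DataFrame],
    top_n: int | None = 100,
    ref_fc_min: float = 3.5,
    cmp_fc_min: float = 1.5,
    padj_max: float = 0.05,
) -> dict:
    """Overlap of a reference induced cohort with comparison data sets.

    All tables are indexed by a shared pair id with ``fold_change`` and
    ``padj`` columns.  The reference set is the ``top_n`` genes by fold
    change among those passing ``fold_change > ref_fc_min`` and
    ``padj < padj_max`` (ties broken by id for determinism); with
    ``top_n=None`` the whole qualifying set is used.  Per comparison,
    the overlap is the number of reference members passing
    ``fold_change > cmp_fc_min`` and ``padj < padj_max`` there; the
    union overlap counts members passing in at least one comparison.
    """
    qual = reference_de[
        (reference_de["fold_change"] > ref_fc_min)
        & (reference_de["padj"] < padj_max)
    ]
    if top_n is not None:
        if len(qual) < top_n:
            raise ValueError(
                f"only {len(qual)} genes qualify for a top-{top_n} reference set"
            )
        ordered = qual.assign(_id=qual.index).sort_values(
            ["fold_change", "_id"], ascending=[False, True]
        )
        ref_ids = list(ordered.index[:top_n])
    else:
        ref_ids = sorted(qual.index)

    overlaps: dict[str, int] = {}
    passed_any: set = set()
    for name, de in comparison_des.items():
        hits = [
            g
            for g in ref_ids
            if g in de.index
            and de.at[g, "fold_change"] > cmp_fc_min
            and de.at[g, "padj"] < padj_max
        ]
        overlaps[name] = len(hits)
        passed_any.update(hits)
    return {
        "reference_ids": ref_ids,
        "reference_size": len(ref_ids),
        "overlaps": overlaps,
        "union_overlap": len(passed_any),
    }


# ---------------------------------------------------------------------------
# connection maps


def connection_map(vectors: dict[str, np.ndarray]) -> nx.Graph:
    """Complete graph over replicates, edges weighted by R^2.

    ``vectors`` maps a node label (preparation/replicate) to its log2
    fold-change vector over a common ordered gene set; the edge weight
    is the squared Pearson correlation of the two vectors.
    """
    labels = list(vectors)
    n = {len(v) for v in vectors.values()}
    if len(n) > 1:
        raise ValueError("all vectors must have the same length")
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, u in enumerate(labels):
        for v in labels[i + 1 :]:
            r = np.corrcoef(vectors[u], vectors[v])[0, 1]
            g.add_edge(u, v, weight=float(r**2))
    return g


def write_connection_map(graph: nx.Graph, graphml_path: str, edges_path: str) -> None:
    """Export a connection map as GraphML and a plain edge list."""
    nx.write_graphml(graph, graphml_path)
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tr_squared\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['weight']:.6g}\n")


# ---------------------------------------------------------------------------
# within-sample vs separate-preparation DRI concordance


def tc1_concordance(
    tc1_de_h: pd.DataFrame,
    tc1_de_m: pd.DataFrame,
    separate_dri: pd.DataFrame,
    pairs: pd.DataFrame,
    human_read_totals: pd.Series,
    min_reads: int = 100,
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Correlate within-sample DRIs with separate-preparation DRIs.

    For each ortholog pair whose human-side gene has total raw reads
    strictly greater than ``min_reads``, the within-sample DRI is
    fold-change(human ortholog)/fold-change(mouse ortholog) computed in
    the same (dual-genome) sample set; ``separate_dri`` supplies the
    pair's ``log2_dri`` from independent single-species preparations.
    Returns the per-pair table and the Pearson correlation (with CI) of
    the two log2 DRI vectors.  Fewer than 4 retained pairs is an error.
    """
    sep = separate_dri.set_index(["gene_a", "gene_b"])["log2_dri"]
    rows = []
    for ga, gb in zip(pairs["gene_a"], pairs["gene_b"]):
        if gb not in human_read_totals.index or not human_read_totals[gb] > min_reads:
            continue
        if gb not in tc1_de_h.index or ga not in tc1_de_m.index or (ga, gb) not in sep.index:
            continue
        fc_h = float(tc1_de_h.at[gb, "fold_change"])
        fc_m = float(tc1_de_m.at[ga, "fold_change"])
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "tc1_log2_dri": np.log2(fc_h) - np.log2(fc_m),
                "separate_log2_dri": float(sep[(ga, gb)]),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 4:
        raise ValueError(f"only {len(table)} pairs pass the >{min_reads}-read cut-off")
    corr = pearson_with_ci(table["tc1_log2_dri"], table["separate_log2_dri"])
    return table, corr


# ---------------------------------------------------------------------------
# promoter motif divergence


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    position: int
    strand: str
    matched_text: str
    species_specific: bool = False


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in motif")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(sequence: str, motif: str, sequence_id: str = "seq") -> list[MotifHit]:
    """All matches of an IUPAC consensus on both strands of a sequence.

    Positions are 0-based on the forward strand; for minus-strand hits
    the position is the forward-strand start of the matched window.
    """
    seq = sequence.upper()
    w = len(motif)
    pat_f = _iupac_regex(motif)
    pat_r = _iupac_regex(motif.upper().translate(_COMPLEMENT_IUPAC)[::-1])
    hits = [
        MotifHit(sequence_id, m.start(), "+", m.group(1))
        for m in pat_f.finditer(seq)
    ]
    hits += [
        MotifHit(sequence_id, m.start(), "-", m.group(1))
        for m in pat_r.finditer(seq)
    ]
    return sorted(hits, key=lambda h: (h.position, h.strand))


def _alignment_position_map(seq1: str, seq2: str, match=1, mismatch=-1, gap=-2):
    """Map seq1 positions to seq2 positions via global alignment."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq1, seq2)[0]
    pos_map = np.full(len(seq1) + 1, -1, dtype=int)
    b1, b2 = aln.aligned
    for (s1, e1), (s2, e2) in zip(b1, b2):
        pos_map[s1:e1] = np.arange(s2, e2)
    pos_map[len(seq1)] = len(seq2)
    # fill gap positions with the next mapped coordinate
    nxt = len(seq2)
    for i in range(len(seq1), -1, -1):
        if pos_map[i] == -1:
            pos_map[i] = nxt
        else:
            nxt = pos_map[i]
    return pos_map


def compare_promoter_motifs(
    seq_1: str,
    seq_2: str,
    motif: str = "TGASTCA",
    align_params: tuple[int, int, int] = (1, -1, -2),
) -> tuple[list[MotifHit], list[MotifHit]]:
    """Species-specific motif occurrences in a pair of promoters.

    The promoters are globally aligned (default scores: match +1,
    mismatch -1, gap -2) and the IUPAC consensus is scanned on both
    strands of both sequences.  A hit is species-specific iff the
    aligned window in the other promoter overlaps no hit there.
    Returns the hit lists for ``seq_1`` and ``seq_2``.
    """
    if not seq_1 or not seq_2:
        raise ValueError("promoter sequences must be non-empty")
    hits1 = scan_motif(seq_1, motif, "seq1")
    hits2 = scan_motif(seq_2, motif, "seq2")
    w = len(motif)
    m12 = _alignment_position_map(seq_1.upper(), seq_2.upper(), *align_params)
    m21 = _alignment_position_map(seq_2.upper(), seq_1.upper(), *align_params)

    def flag(hits, other_hits, pos_map):
        out = []
        other_ivs = [(h.position, h.position + w) for h in other_hits]
        for h in hits:
            lo = int(pos_map[h.position])
            hi = int(pos_map[h.position + w])
            specific = not any(s < hi and lo < e for s, e in other_ivs)
            out.append(
                MotifHit(h.sequence_id, h.position, h.strand, h.matched_text, specific)
            )
        return out

    return flag(hits1, hits2, m12), flag(hits2, hits1, m21)
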