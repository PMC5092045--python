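"""Per-gene quantification: fragment counting, FPKM, normalization, DE.

FPKM follows the species-aware convention of dual-genome experiments:
the per-million denominator for a sample is the number of fragments
unambiguously attributed to that sample's species (not the whole
library), and the per-kilobase denominator is the gene's maximum
transcript length.  Union-exon gene lengths are computed alongside for
reporting.

The differential-expression stage is a deliberately simple, pluggable
stand-in: fold change as the ratio of pseudocounted mean normalized
counts, a two-sided Welch t-test on log2(normalized + 1), and
Benjamini-Hochberg adjustment.  It provides fold changes and an
FDR-thresholded p-value — the two quantities the downstream comparative
statistics consume — without negative-binomial GLM fitting or shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd
import scipy.stats
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) with sample metadata.

    ``samples`` is indexed by sample id with columns ``species``,
    ``condition`` (control|stimulated) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if not (self.counts.to_numpy() >= 0).all():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample metadata disagree")


def gene_lengths(genes) -> pd.DataFrame:
    """Per-gene maximum transcript length and union-exon length.

    The union-exon length is the number of nucleotides in the union of
    all exons of all transcripts of the gene; the maximum transcript
    length is the largest summed-exon length over its transcripts.
    """
    rows = []
    for g in genes:
        if not g.transcripts:
            raise ValueError(f"gene {g.gene_id} has no transcripts")
        max_len = max(t.length for t in g.transcripts)
        union_len = sum(e - s for s, e in g.union_exons())
        rows.append((g.gene_id, max_len, union_len))
    return pd.DataFrame(
        rows, columns=["gene_id", "max_transcript_length", "union_exon_length"]
    ).set_index("gene_id")


def _union_exon_tree(genes) -> IntervalTree:
    tree = IntervalTree()
    for g in genes:
        for s, e in g.union_exons():
            tree[s:e] = g.gene_id
    return tree


def count_fragments(
    assignments, genes_by_species: dict[str, list]
) -> tuple[dict[str, pd.Series], dict[str, int]]:
    """Count fragments per gene from species-sorted read assignments.

    A fragment is counted for gene *g* iff both mates were assigned to
    the same species and the fragment's aligned blocks overlap union
    exons of exactly that one gene.  Fragments whose blocks touch exons
    of zero genes or of two or more genes are discarded, as are
    fragments with an unassigned mate or mates assigned to different
    species.  Each fragment is counted once.

    Parameters
    ----------
    assignments
        Iterable of ``ReadAssignment`` (one per mate; read names are
        ``<fragment>/<mate>``).
    genes_by_species
        Mapping species -> list of GeneModel.

    Returns
    -------
    (counts, discards)
        ``counts[species]`` is an integer Series over that species'
        genes; ``discards`` tallies the discard reasons.
    """
    from .sss import Verdict  # local import to avoid a cycle

    trees = {sp: _union_exon_tree(genes) for sp, genes in genes_by_species.items()}
    counts = {
        sp: pd.Series(0, index=[g.gene_id for g in genes], dtype=np.int64)
        for sp, genes in genes_by_species.items()
    }
    discards = defaultdict(int)

    by_frag: dict[str, list] = defaultdict(list)
    for a in assignments:
        frag = a.read_id.rsplit("/", 1)[0]
        by_frag[frag].append(a)

    species_verdicts = {Verdict.SPECIES_A: "A", Verdict.SPECIES_B: "B"}
    for frag, mates in by_frag.items():
        sps = [species_verdicts.get(a.verdict) for a in mates]
        if len(mates) != 2 or any(s is None for s in sps):
            discards["unassigned_mate"] += 1
            continue
        if sps[0] != sps[1]:
            discards["species_conflict"] += 1
            continue
        sp = sps[0]
        tree = trees[sp]
        genes_hit: set[str] = set()
        for a in mates:
            for s, e in a.chosen_alignment.blocks:
                genes_hit |= {iv.data for iv in tree.overlap(s, e)}
        if len(genes_hit) == 0:
            discards["no_gene"] += 1
        elif len(genes_hit) > 1:
            discards["multi_gene"] += 1
        else:
            counts[sp][genes_hit.pop()] += 1
    return counts, dict(discards)


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    species_totals: pd.Series,
) -> pd.DataFrame:
    """Fragments per kilobase of message per million assigned fragments.

    ``FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * species_totals[s])``
    where ``species_totals[s]`` is the number of fragments unambiguously
    attributed to sample *s*'s species and ``length[g]`` the maximum
    transcript length in nucleotides.
    """
    totals = species_totals.reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("species_totals must be positive for every sample")
    lens = lengths.reindex(counts.index)
    if lens.isna().any() or (lens <= 0).any():
        raise ValueError("every gene needs a positive length")
    return counts.mul(1e9).div(lens, axis=0).div(totals, axis=1)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per-gene geometric mean over samples is the reference; each sample's
    factor is the median, over genes with no zero count, of the ratio of
    its count to the reference.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has all-positive counts")
    sub = arr[positive]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def differential_expression(
    counts: pd.DataFrame,
    factors: pd.Series,
    condition: pd.Series,
) -> pd.DataFrame:
    """Per-gene fold change and Welch-test significance, BH-adjusted.

    ``condition`` maps each sample (column) to ``control`` or
    ``stimulated``; at least two replicates per condition are required.
    Fold change is ``(mean normalized stimulated + 1) / (mean normalized
    control + 1)``; the p-value is a two-sided Welch t-test on
    ``log2(normalized + 1)``.
    """
    condition = condition.reindex(counts.columns)
    ctrl_cols = condition.index[condition == "control"]
    stim_cols = condition.index[condition == "stimulated"]
    if len(ctrl_cols) < 2 or len(stim_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    norm = counts.div(factors.reindex(counts.columns), axis=1)
    mean_c = norm[ctrl_cols].mean(axis=1)
    mean_s = norm[stim_cols].mean(axis=1)
    fold_change = (mean_s + 1.0) / (mean_c + 1.0)

    log = np.log2(norm + 1.0)
    a = log[stim_cols].to_numpy()
    b = log[ctrl_cols].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    # degenerate groups: zero variance in both
    degen = se2 == 0
    p = np.where(degen, np.where(m1 == m2, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)

    out = pd.DataFrame(
        {
            "base_mean": (mean_c + mean_s) / 2.0,
            "fold_change": fold_change,
            "log2fc": np.log2(fold_change),
            "p_value": p,
        },
        index=counts.index,
    )
    out["padj"] = bh_adjust(out["p_value"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
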