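"""Config-driven orchestration: simulate -> align -> sort -> quantify -> compare.

The pipeline runs two parallel tracks from one global seed:

* a *sequence track* at read level (genome pair -> spliced reads ->
  exhaustive alignment -> species sorting -> fragment counting ->
  species-aware FPKM), which exercises the read-disambiguation
  machinery against full ground truth; and
* a *count track* at gene level (negative-binomial count experiment in
  both species -> size factors -> differential expression -> DRI/DBEI
  statistics, cohort overlaps, connection maps, within-sample DRI
  concordance, promoter motif scan), which exercises the comparative
  statistics at a realistic gene count.

Every output file is recorded in a manifest with a content hash;
identical config and seed reproduce identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from collections import namedtuple
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import compstats, io, quant, simgen, sss, toyalign

log = logging.getLogger("driseq")

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# configuration


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimGenConfig(_Strict):
    n_genes: int = Field(50, gt=0)
    gene_length_range: tuple[int, int] = (600, 2000)
    divergence: float = Field(0.02, ge=0.0, lt=0.25)
    n_fragments: int = Field(20000, ge=0)
    read_length: int = Field(75, gt=0)
    error_rate: float = Field(0.0, ge=0.0, le=1.0)


class CountSimConfig(_Strict):
    n_genes: int = Field(11302, gt=1)
    n_reps: int = Field(3, ge=2)
    frac_induced: float = Field(0.05, ge=0.0, le=1.0)
    mean_log2fc: float = 2.0
    sd_log2fc: float = Field(1.0, ge=0.0)
    sigma_dri: float = Field(0.68, ge=0.0)
    sigma_dbei: float = Field(1.39, ge=0.0)
    nb_dispersion: float = Field(0.05, gt=0.0)


class AlignConfig(_Strict):
    max_mismatches: int = Field(4, ge=0)
    seed_len: int = Field(15, gt=0)


class QuantConfig(_Strict):
    min_avg_expr: float = Field(5.0, ge=0.0)


class CompareConfig(_Strict):
    cohort_fc_min: float = 5.0
    top_n: int = Field(100, gt=0)
    ref_fc_min: float = 3.5
    cmp_fc_min: float = 1.5
    padj_max: float = Field(0.05, gt=0.0, le=1.0)
    min_reads: int = Field(100, ge=0)
    n_transferred_genes: int = Field(150, gt=0)
    motif: str = "TGASTCA"
    promoter_length: int = Field(600, gt=0)
    promoter_sites: int = Field(3, ge=0)


class PipelineConfig(_Strict):
    seed: int = 1
    verbosity: int = 1
    simgen: SimGenConfig = SimGenConfig()
    countsim: CountSimConfig = CountSimConfig()
    align: AlignConfig = AlignConfig()
    quant: QuantConfig = QuantConfig()
    compare: CompareConfig = CompareConfig()


class ConfigError(ValueError):
    """Config validation failure with all problems enumerated."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


def validate_config(path_or_dict) -> PipelineConfig:
    """Load, type-check and default-fill a YAML/JSON pipeline config."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as err:
        problems = [
            ".".join(str(x) for x in e["loc"]) + ": " + e["msg"] for e in err.errors()
        ]
        raise ConfigError(problems) from None


def stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (seed * 1000003 + stage_index) % 2**31


# ---------------------------------------------------------------------------
# stages (file-based contracts under the output directory)


def _write_tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    gdir, rdir, cdir = outdir / "genomes", outdir / "reads", outdir / "counts_sim"
    for d in (gdir, rdir, cdir):
        d.mkdir(parents=True, exist_ok=True)
    sg = cfg.simgen
    pair = simgen.generate_genome_pair(
        n_genes=sg.n_genes,
        gene_length_range=sg.gene_length_range,
        divergence=sg.divergence,
        seed=stage_seed(cfg.seed, 0),
    )
    io.write_genome_pair(pair, gdir)
    reads = simgen.simulate_reads(
        pair,
        n_fragments=sg.n_fragments,
        read_length=sg.read_length,
        error_rate=sg.error_rate,
        seed=stage_seed(cfg.seed, 1),
    )
    io.write_fastq(reads, str(rdir / "R1.fastq"), str(rdir / "R2.fastq"))
    _write_tsv(simgen.reads_truth_table(reads), rdir / "truth.tsv", index=False)

    cs = cfg.countsim
    truth, matrices = simgen.simulate_count_experiment(
        n_genes=cs.n_genes,
        n_reps=cs.n_reps,
        frac_induced=cs.frac_induced,
        mean_log2fc=cs.mean_log2fc,
        sd_log2fc=cs.sd_log2fc,
        sigma_dri=cs.sigma_dri,
        sigma_dbei=cs.sigma_dbei,
        nb_dispersion=cs.nb_dispersion,
        seed=stage_seed(cfg.seed, 2),
    )
    _write_tsv(truth, cdir / "truth.tsv")
    for sp, cm in matrices.items():
        _write_tsv(cm.counts, cdir / f"counts_{sp}.tsv")
        _write_tsv(cm.samples, cdir / f"samples_{sp}.tsv")
    log.info("simulate: %d genes, %d fragments, %d count-sim genes (%.1fs)",
             sg.n_genes, sg.n_fragments, cs.n_genes, time.time() - t0)


def _load_count_matrix(cdir: Path, sp: str) -> quant.CountMatrix:
    counts = pd.read_csv(cdir / f"counts_{sp}.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(cdir / f"samples_{sp}.tsv", sep="\t", index_col=0)
    return quant.CountMatrix(counts=counts, samples=samples)


def stage_align(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    adir = outdir / "align"
    adir.mkdir(parents=True, exist_ok=True)
    seqs = {
        sp: io.read_fasta(outdir / "genomes" / f"{sp}.fa")[f"chr{sp}"] for sp in "AB"
    }
    genes = {sp: io.read_gtf(str(outdir / "genomes" / f"{sp}.gtf")) for sp in "AB"}
    pair = simgen.GenomePair(
        seqs["A"], seqs["B"], genes["A"], genes["B"], cfg.simgen.divergence, cfg.seed
    )
    aligner = toyalign.PairAligner(
        pair, seed_len=cfg.align.seed_len, max_mismatches=cfg.align.max_mismatches
    )
    reads = io.read_fastq(str(outdir / "reads" / "R1.fastq")) + io.read_fastq(
        str(outdir / "reads" / "R2.fastq")
    )
    alns = {"A": [], "B": []}
    seq_by_name = {}
    for name, seq in reads:
        aa, ab = aligner.align(name, seq)
        alns["A"].extend(aa)
        alns["B"].extend(ab)
        seq_by_name[name] = seq
    for sp in "AB":
        toyalign.write_sam(
            alns[sp],
            {f"chr{sp}": len(seqs[sp])},
            str(adir / f"chr{sp}.sam"),
            read_seqs=seq_by_name,
        )
    log.info("align: %d reads -> %d/%d alignments (A/B) (%.1fs)",
             len(reads), len(alns["A"]), len(alns["B"]), time.time() - t0)


def stage_sort(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    sdir = outdir / "sort"
    sdir.mkdir(parents=True, exist_ok=True)
    names = [n for n, _ in io.read_fastq(str(outdir / "reads" / "R1.fastq"))]
    names += [n for n, _ in io.read_fastq(str(outdir / "reads" / "R2.fastq"))]
    grouped: dict[str, tuple[list, list]] = {n: ([], []) for n in names}
    for i, sp in enumerate("AB"):
        for al in toyalign.read_sam(str(outdir / "align" / f"chr{sp}.sam")):
            grouped[al.read_id][i].append(al)
    table, summary, assignments = sss.sort_sample(
        (n, a, b) for n, (a, b) in grouped.items()
    )
    _write_tsv(table, sdir / "verdicts.tsv", index=False)
    (sdir / "summary.json").write_text(summary.to_json())

    # evaluation against simulator truth
    truth = pd.read_csv(outdir / "reads" / "truth.tsv", sep="\t").set_index("read")
    verdict_species = {"SPECIES_A": "A", "SPECIES_B": "B"}
    n_mis = 0
    n_soundness = 0
    for a in assignments:
        spv = verdict_species.get(a.verdict.value)
        if spv is None:
            continue
        if truth.at[a.read_id, "true_species"] != spv:
            n_mis += 1
        al = a.chosen_alignment
        aln_list = grouped[a.read_id][0 if spv == "A" else 1]
        if (
            al is None
            or al.mismatches != 0
            or al.clipped != 0
            or not sss.structure_ok(al)
            or len(aln_list) != 1
        ):
            n_soundness += 1
    (sdir / "accuracy.json").write_text(
        json.dumps(
            {
                "n_assigned": summary.n_assigned,
                "n_misassigned": n_mis,
                "n_soundness_violations": n_soundness,
            },
            indent=2,
            sort_keys=True,
        )
    )
    log.info("sort: %d reads, %d assigned, %d misassigned (%.1fs)",
             summary.n_reads, summary.n_assigned, n_mis, time.time() - t0)


_MiniAssignment = namedtuple("_MiniAssignment", "read_id verdict chosen_alignment")


def _assignments_from_table(table: pd.DataFrame):
    out = []
    for row in table.itertuples(index=False):
        verdict = sss.Verdict(row.verdict)
        al = None
        if verdict in (sss.Verdict.SPECIES_A, sss.Verdict.SPECIES_B):
            blocks = tuple(
                tuple(int(x) for x in b.split("-")) for b in row.blocks.split(";")
            )
            al = toyalign.AlignmentRecord(
                row.read, row.genome, row.strand, blocks, int(row.mismatches)
            )
        out.append(_MiniAssignment(row.read, verdict, al))
    return out


def stage_quantify(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    qdir = outdir / "quant"
    qdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(
        outdir / "sort" / "verdicts.tsv", sep="\t", keep_default_na=False
    )
    assignments = _assignments_from_table(table)
    genes = {sp: io.read_gtf(str(outdir / "genomes" / f"{sp}.gtf")) for sp in "AB"}
    counts, discards = quant.count_fragments(assignments, genes)

    # species-specific denominators: fragments with both mates assigned there
    verdict_species = {"SPECIES_A": "A", "SPECIES_B": "B"}
    frag_sp: dict[str, set] = {}
    for a in assignments:
        spv = verdict_species.get(a.verdict.value)
        frag = a.read_id.rsplit("/", 1)[0]
        frag_sp.setdefault(frag, set()).add(spv)
    totals = {
        sp: sum(1 for v in frag_sp.values() if v == {sp}) for sp in "AB"
    }

    rows = []
    for sp in "AB":
        lengths = quant.gene_lengths(genes[sp])
        cdf = counts[sp].to_frame(name=f"{sp}_demo")
        if totals[sp] > 0:
            fpkm = quant.compute_fpkm(
                cdf, lengths["max_transcript_length"],
                pd.Series({f"{sp}_demo": totals[sp]}),
            )
        else:  # degenerate: no fragment attributable to this species
            fpkm = cdf * np.nan
        merged = lengths.join(cdf).join(fpkm.rename(columns={f"{sp}_demo": "fpkm"}))
        merged.insert(0, "species", sp)
        merged = merged.rename(columns={f"{sp}_demo": "count"})
        rows.append(merged)
    _write_tsv(pd.concat(rows), qdir / "expression.tsv")
    (qdir / "discards.json").write_text(
        json.dumps({"discards": discards, "species_totals": totals}, indent=2, sort_keys=True)
    )

    # count track: size factors and differential expression per species
    ddir = outdir / "de"
    ddir.mkdir(parents=True, exist_ok=True)
    factors = {}
    for sp in "AB":
        cm = _load_count_matrix(outdir / "counts_sim", sp)
        f = quant.estimate_size_factors(cm.counts)
        factors[sp] = f
        de = quant.differential_expression(cm.counts, f, cm.samples["condition"])
        _write_tsv(de, ddir / f"de_{sp}.tsv")
    _write_tsv(pd.DataFrame(factors).rename_axis("sample"), ddir / "size_factors.tsv")
    log.info("quantify: totals=%s discards=%s (%.1fs)", totals, discards, time.time() - t0)


def stage_compare(cfg: PipelineConfig, outdir: Path) -> dict:
    t0 = time.time()
    pdir = outdir / "compare"
    pdir.mkdir(parents=True, exist_ok=True)
    cc = cfg.compare
    truth = pd.read_csv(outdir / "counts_sim" / "truth.tsv", sep="\t", index_col=0)
    matrices = {sp: _load_count_matrix(outdir / "counts_sim", sp) for sp in "AB"}
    de = {
        sp: pd.read_csv(outdir / "de" / f"de_{sp}.tsv", sep="\t", index_col=0)
        for sp in "AB"
    }
    factors = pd.read_csv(outdir / "de" / "size_factors.tsv", sep="\t", index_col=0)

    norm = {
        sp: matrices[sp].counts.div(factors[sp].reindex(matrices[sp].counts.columns), axis=1)
        for sp in "AB"
    }
    ortho = pd.DataFrame({"gene_a": truth.index, "gene_b": truth.index})
    pairs, n_dropped = compstats.pair_orthologs_and_filter(
        {"prep_A": norm["A"]}, {"prep_B": norm["B"]}, ortho, cfg.quant.min_avg_expr
    )

    ctrl = {
        sp: norm[sp].loc[:, matrices[sp].samples["condition"] == "control"].mean(axis=1)
        for sp in "AB"
    }
    dri, n_skipped = compstats.compute_dri_table(
        pairs, de["B"], de["A"], ctrl["B"], ctrl["A"]
    )
    _write_tsv(dri, pdir / "dri.tsv", index=False)
    dist = compstats.summarize_log2_distribution(dri["log2_dri"])

    corr_rows = []
    c_fc = compstats.pearson_with_ci(
        np.log2(dri["fc_h"]), np.log2(dri["fc_m"])
    )
    corr_rows.append(("log2fc_h_vs_log2fc_m", c_fc))
    c_basal = compstats.pearson_with_ci(
        np.log2(dri["basal_h"] + 1e-9), np.log2(dri["basal_m"] + 1e-9)
    )
    corr_rows.append(("log2_basal_h_vs_m", c_basal))
    dd = dri.dropna(subset=["log2_dbei"])
    c_dri_dbei = compstats.pearson_with_ci(dd["log2_dri"], dd["log2_dbei"])
    corr_rows.append(("log2_dri_vs_log2_dbei", c_dri_dbei))

    cohort = compstats.induced_cohort(
        de["B"].loc[pairs["gene_b"]], de["A"].loc[pairs["gene_a"]], pairs,
        fc_min=cc.cohort_fc_min, padj_max=cc.padj_max,
    )
    ref = de["B"].loc[pairs["gene_b"]]
    top_n = min(cc.top_n, int(((ref["fold_change"] > cc.ref_fc_min) & (ref["padj"] < cc.padj_max)).sum()))
    overlap = compstats.conserved_induction_overlap(
        ref, {"mouse_side": de["A"].loc[pairs["gene_a"]]},
        top_n=top_n if top_n > 0 else None,
        ref_fc_min=cc.ref_fc_min, cmp_fc_min=cc.cmp_fc_min, padj_max=cc.padj_max,
    )
    (pdir / "overlap.json").write_text(
        json.dumps(
            {k: v for k, v in overlap.items() if k != "reference_ids"},
            indent=2, sort_keys=True,
        )
    )

    # replicate connection map from per-replicate fold changes
    vectors = {}
    for sp in "AB":
        samples = matrices[sp].samples
        gene_sel = pairs["gene_b" if sp == "B" else "gene_a"]
        for rep in sorted(samples["replicate"].unique()):
            c_col = samples.index[(samples["condition"] == "control") & (samples["replicate"] == rep)][0]
            s_col = samples.index[(samples["condition"] == "stimulated") & (samples["replicate"] == rep)][0]
            v = np.log2((norm[sp].loc[gene_sel, s_col] + 1.0) / (norm[sp].loc[gene_sel, c_col] + 1.0))
            vectors[f"{sp}_rep{rep}"] = v.to_numpy()
    graph = compstats.connection_map(vectors)
    compstats.write_connection_map(
        graph, str(pdir / "connection_map.graphml"), str(pdir / "connection_map_edges.tsv")
    )

    # within-sample (dual-genome) DRI concordance against separate preparations
    tc1_matrices = simgen.counts_from_truth(
        truth, n_reps=cfg.countsim.n_reps, seed=stage_seed(cfg.seed, 3)
    )
    tc1_de = {}
    for sp in "AB":
        cm = tc1_matrices[sp]
        f = quant.estimate_size_factors(cm.counts)
        tc1_de[sp] = quant.differential_expression(cm.counts, f, cm.samples["condition"])
    transferred = pairs.head(cc.n_transferred_genes)
    human_totals = tc1_matrices["B"].counts.sum(axis=1)
    tc1_table, tc1_corr = compstats.tc1_concordance(
        tc1_de["B"], tc1_de["A"], dri, transferred, human_totals, cc.min_reads
    )
    _write_tsv(tc1_table, pdir / "tc1_concordance.tsv", index=False)
    corr_rows.append(("tc1_vs_separate_log2_dri", tc1_corr))

    with open(pdir / "correlations.tsv", "w") as fh:
        fh.write("comparison\tr\tci_low\tci_high\tp\tn\n")
        for name, c in corr_rows:
            fh.write(f"{name}\t{c.r:.6g}\t{c.ci_low:.6g}\t{c.ci_high:.6g}\t{c.p:.6g}\t{c.n}\n")

    # promoter motif divergence demo (synthetic planted sites)
    plant = cc.motif.replace("S", "C")
    p1, p2 = simgen.make_promoter_pair(
        length=cc.promoter_length, divergence=cfg.simgen.divergence,
        n_sites=cc.promoter_sites, motif_text=plant, seed=stage_seed(cfg.seed, 4),
    )
    hits1, hits2 = compstats.compare_promoter_motifs(p1, p2, motif=cc.motif)
    motif_report = {
        "motif": cc.motif,
        "planted_sites": cc.promoter_sites,
        "seq1_hits": [h.__dict__ for h in hits1],
        "seq2_hits": [h.__dict__ for h in hits2],
        # a palindromic consensus hits both strands of one site: count windows
        "seq1_specific_sites": len({h.position for h in hits1 if h.species_specific}),
        "seq2_specific_sites": len({h.position for h in hits2 if h.species_specific}),
    }
    (pdir / "motifs.json").write_text(json.dumps(motif_report, indent=2, sort_keys=True))

    sort_summary = json.loads((outdir / "sort" / "summary.json").read_text())
    accuracy = json.loads((outdir / "sort" / "accuracy.json").read_text())
    summary = {
        "sort": sort_summary,
        "sort_accuracy": accuracy,
        "n_pairs_retained": int(len(pairs)),
        "n_nonbijective_dropped": int(n_dropped),
        "n_pairs_skipped_in_dri": int(n_skipped),
        "log2_dri_mean": dist.mean,
        "log2_dri_sd": dist.sd,
        "true_log2_dri_sd": float(truth["true_log2_dri"].std(ddof=1)),
        "correlations": {
            name: {"r": c.r, "ci_low": c.ci_low, "ci_high": c.ci_high, "p": c.p, "n": c.n}
            for name, c in corr_rows
        },
        "cohort_size": int(len(cohort)),
        "overlap": {k: v for k, v in overlap.items() if k != "reference_ids"},
        "tc1_pairs": int(len(tc1_table)),
        "motif_seq1_specific_sites": motif_report["seq1_specific_sites"],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("compare: %d pairs, DRI sd %.3f (%.1fs)", len(pairs), dist.sd, time.time() - t0)
    return summary


STAGES = [
    ("simulate", stage_simulate),
    ("align", stage_align),
    ("sort", stage_sort),
    ("quantify", stage_quantify),
    ("compare", stage_compare),
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path) -> dict:
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages in order; returns the manifest (with summary)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        log.info("stage %s ...", name)
        try:
            fn(cfg, outdir)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
    manifest = write_manifest(outdir)
    return manifest
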