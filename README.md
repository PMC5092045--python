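# driseq

Dual-genome RNA-seq read sorting and cross-species differential-regulation
statistics, with a fully ground-truthed simulator.

## The problem

When transcripts from two closely related genomes are sequenced together —
as in a transchromosomic mouse whose nuclei carry a human chromosome
alongside the mouse genome — every short read must first be attributed to
its genome of origin before expression can be quantified per species.
Because the two genomes are highly similar, naive mapping misassigns
reads; a conservative sorter instead rejects everything it cannot place
with certainty and keeps only reads with a *single, full-length,
zero-mismatch* alignment to exactly one genome.

Once reads (or whole samples from separate single-species preparations)
are quantified per species, the question becomes comparative: is a gene's
response to a stimulus — here, the activity-dependent induction program of
depolarized neurons — the same in the two species? `driseq` implements the
statistics used to answer this:

- **DRI** (differential regulation index) for an ortholog pair:
  `DRI = FC_human / FC_mouse`, where `FC` is the stimulated/control fold
  change; `log2 DRI = 0` means identical responsiveness.
- **DBEI** (differential basal expression index):
  `DBEI = basal_human / basal_mouse` on unstimulated samples.
- **Species-aware FPKM**: `FPKM = count · 10⁹ / (L_max · N_species)` with
  the maximum transcript length `L_max` and, crucially, the number of
  fragments unambiguously attributed to that species, `N_species`, as the
  per-million denominator.
- **Fisher-z correlation inference**: 95% CI of a Pearson r as
  `tanh(atanh(r) ± z₀.₉₇₅/√(n−3))`.
- Induced-cohort overlaps, replicate connection maps (complete graphs
  edge-weighted by R² of log2 fold-change vectors), within-sample vs
  separate-preparation DRI concordance, and an IUPAC motif divergence
  scan (e.g. the AP-1 consensus `TGASTCA`) over globally aligned promoter
  pairs.

Everything runs at desk scale on simulated data with complete ground
truth: a pair of homologous annotated genomes differing only by point
substitutions, spliced paired-end reads of known origin, and
negative-binomial count experiments with a controlled spread of
between-species effects.

## Worked example

Run the full pipeline (simulate → align → sort → quantify → compare)
with the default configuration — two ~100 kb genomes at 2% divergence,
50 genes, 20,000 error-free 75-bp fragment pairs, plus an 11,302-gene
count experiment with a log2-DRI spread of 0.68:

```bash
driseq run-all --outdir out --seed 1
```

`out/summary.json` from this exact command contains (abridged):

```json
{
  "sort": {
    "n_reads": 40000,
    "n_assigned": 30160,
    "counts": {"SPECIES_A": 15050, "SPECIES_B": 15110, "AMBIGUOUS": 9424,
               "REJECTED_STRUCTURE": 388, "REJECTED_MULTIMAP": 28},
    "conserved_fraction": 0.238
  },
  "sort_accuracy": {"n_misassigned": 0, "n_soundness_violations": 0},
  "n_pairs_retained": 10746,
  "true_log2_dri_sd": 0.687,
  "log2_dri_sd": 0.797,
  "correlations": {
    "log2fc_h_vs_log2fc_m": {"r": 0.461, "ci_low": 0.446, "ci_high": 0.475},
    "tc1_vs_separate_log2_dri": {"r": 0.749, "n": 134}
  },
  "motif_seq1_specific_sites": 3
}
```

Reading this: of 40,000 reads, 75% were assigned to a species with **zero
misassignments** (the conservative sorter's design goal); 24% of
perfect-match reads were lost to sequence identity between the genomes
(at the real mouse–human divergence this loss is far smaller). Across
10,746 expression-filtered ortholog pairs the estimated log2-DRI spread
is 0.797 — the generator's 0.68 inflated by counting noise — and the
cross-species fold-change correlation is r ≈ 0.46. Re-measuring the same
sequence-encoded effects in an independent "same-nucleus" experiment
reproduces the per-gene DRIs (r ≈ 0.75), and the motif scan recovers
exactly the three planted species-specific AP-1 sites in the synthetic
promoter pair.

Each stage can also be run separately (`driseq simulate|align|sort|
quantify|compare --config cfg.yaml --outdir out`); stages communicate
through plain files (FASTA/GTF/FASTQ/SAM/TSV/JSON) and every run writes
a `manifest.json` of content hashes — identical config and seed give
identical hashes.

## Layout

- `src/driseq/simgen.py` — genome-pair, read and count-experiment simulators
- `src/driseq/toyalign.py` — exhaustive spliced aligner + SAM I/O
- `src/driseq/sss.py` — species-specific sorting procedure
- `src/driseq/quant.py` — fragment counting, FPKM, size factors, DE, BH
- `src/driseq/compstats.py` — DRI/DBEI, correlations, overlaps, connection maps, motifs
- `src/driseq/pipeline.py`, `src/driseq/cli.py` — config-driven orchestration
- `docs/methods.md` — models, assumptions, parameter choices, limitations
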