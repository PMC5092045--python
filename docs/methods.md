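# Methods

## Scope and model overview

`driseq` reimplements, at desk scale and with full ground truth, the
analysis pattern of a dual-genome (transchromosomic) RNA-seq study of
activity-dependent gene regulation: species-of-origin sorting of reads
aligned against two homologous genomes, species-aware quantification,
and the comparative statistics over 1:1 ortholog pairs (differential
regulation index, basal-expression index, correlation and clustering
structure, induced-cohort overlaps, promoter motif divergence). All
inputs are simulated; every stage can therefore be checked against the
generator's truth labels.

## The synthetic data generator

**Genome pair.** Genome A is uniform-random nucleotide sequence with
gene models laid end to end: 1–4 exons (introns 60–400 bp), mRNA length
uniform in 600–2,000 nt, exons at least 80 nt, random strand,
intergenic spacers 200–500 bp; about half the multi-exon genes get a
second transcript that skips one exon. Genome B shares every coordinate
and differs only by independent per-site substitutions at probability
`divergence` (default 0.02). The substitution-only model (no indels) is
deliberate: homologous positions coincide exactly in both genomes, so
the species-of-origin of a read is well defined at every locus, the
orthologous-position oracle is exact, and the sorter's mismatch-count
comparison is meaningful. The default 2% per-site divergence is of the
order of exonic sequence divergence between closely related mammalian
genomes; it yields a substantial ambiguous fraction (a 75-mer is
identical in both genomes with probability 0.98⁷⁵ ≈ 0.22), which
deliberately stresses the sorter far harder than the real mouse–human
comparison, where conserved-read loss is a fraction of a percent.

**Reads.** Fragments choose species, gene and transcript uniformly and
a uniform start; the fragment length is fixed at twice the read length
(default 75 bp), so mates abut — fragment-length modelling adds nothing
to the claims tested here. Mate 1 carries the 5' end of the mRNA, mate
2 the reverse complement of the 3' end; sequencing errors are
independent substitutions at `error_rate`. Truth records per mate:
species, gene, transcript, genomic blocks, strand, error count.

**Count experiment.** Per gene: basal mean expression is log-normal
(median 100 counts, log-sd 1.5 — a realistic bulk dynamic range); a
fraction `frac_induced` (default 0.05) of genes receives an
N(mean_log2fc = 2, sd = 1) log2 fold-change in species A, zero
otherwise; the species-B effect adds an independent N(0, `sigma_dri`)
term, so the true log2 DRI of the gene set has standard deviation
`sigma_dri` (default 0.68, the spread this class of experiment
reports); basal expression in B is scaled by an independent
N(0, `sigma_dbei` = 1.39) log2 DBEI. Counts are gamma-Poisson
(negative binomial) with dispersion 0.05 — typical for good biological
replicates — around per-sample depth factors (log-normal, log-sd 0.15),
with `n_reps` = 3 replicates per condition as in the emulated design.
Because DRI and DBEI are drawn independently, the generator encodes *no*
relationship between differential responsiveness and differential basal
expression; recovering that null is one of the acceptance checks.

What the generator does **not** emulate: indels and structural
variation, isoform abundance differences, GC/positional bias,
quality-score structure, batch effects, and the heavy-tailed
mean–dispersion relationships of real libraries. Passing tests
therefore demonstrate correctness of the procedures under their stated
assumptions, not performance on real libraries.

## Alignment

The aligner is exhaustive by construction: every full-length,
substitution-only alignment of a read — contiguous at any genomic
offset on either strand, or spliced at any offset of any annotated
transcript, projected to genomic blocks — is found, and only alignments
attaining the maximum score (read length minus mismatches) are
reported, emulating aligners configured to keep maximal-score hits
only. Spliced candidates are discovered through the annotation, not by
de-novo junction search; this is exact for simulated reads, which are
drawn from the annotated transcripts. Duplicate placements arising from
both the genomic and the transcript route are merged by
`(strand, blocks)`.

A pigeonhole seed index (seed length 15) accelerates the scan: with
`max_mismatches` = 4 (ample for 75-bp reads at these divergences) a
75-mer contains 5 disjoint seeds, so any qualifying alignment matches
at least one seed exactly and seeding provably loses nothing. The tests
verify equality with a literal all-offset Hamming scan.

## The sorting procedure

Each read is assigned to genome A, genome B, or rejected, in this
order: reads aligning to neither genome are unaligned; reads aligning
to exactly one genome are provisionally assigned to it; for reads
aligning to both, any read with more than one (max-score) alignment to
either genome is discarded as a multimapper, otherwise fewer mismatches
wins provisionally, and on a tie a structural check — full length, no
clipping, and at least 5 bases aligned to the exons on either side of
any intron — decides: satisfied for exactly one genome, provisional to
it; for both, *ambiguous*; for neither, rejected on structure. Finally,
every provisional assignment must be a single alignment with **zero**
mismatches satisfying the structural criteria. The invariant — every
assigned read has a single, full-length, zero-mismatch, well-anchored
alignment to its species' genome — is asserted over all reads in the
acceptance suite, and with error-free reads and the exhaustive aligner
the misassignment count is exactly zero: an error-free read always
matches its true genome perfectly, so it can only be assigned there or
be ambiguous/rejected.

The `conserved_fraction` reports reads lost to complete inter-species
identity: among reads meeting the initial criterion of a perfect
full-length match (assigned reads plus perfect-tie ambiguous reads),
the ambiguous share. The denominator choice (perfect-match reads, not
all reads) is a design decision; at zero divergence the fraction is 1
by construction.

Mates are classified independently at read level; fragment-level
species agreement is enforced in quantification, where a fragment
counts only if both mates were assigned to the same species.

## Quantification

Fragments count toward a gene iff both mates are assigned to the same
species and the fragment's blocks overlap union exons of exactly one
gene (fragments touching zero or several genes are discarded and
tallied). FPKM uses the maximum transcript length per gene and a
species-specific per-million denominator: only fragments unambiguously
attributed to that species. Union-exon lengths are computed alongside
for reporting. Size factors are median-of-ratios against the
geometric-mean reference over genes with no zero count.

The differential-expression stage is an intentionally simple, pluggable
stand-in, not a reimplementation of a negative-binomial GLM package:
fold change is the ratio of pseudocounted (+1) mean normalized counts,
and the p-value a two-sided Welch t-test on log2(normalized + 1), BH
adjusted. The downstream statistics consume only fold changes and an
FDR-thresholded p-value. Two consequences are documented rather than
hidden: (i) at 3 replicates the Welch test is weakly powered, so
BH-significant cohorts are small and conserved-induction overlap
counts are limited by detection power, not by regulation divergence —
overlap rises toward truth with replicate count; (ii) the pseudocount
bounds fold changes for zero counts and shrinks them for very weakly
expressed genes, which is why DRI summaries are computed over
expression-filtered pairs.

## Comparative statistics

Ortholog pairing keeps 1:1 rows only (non-bijective map rows are
dropped and counted) and retains pairs whose mean expression strictly
exceeds the threshold in *every* supplied preparation, mirroring the
"expressed in all cell types" restriction; thresholds are strict
inequalities throughout, as printed in the conventions this package
follows (> 0.5 FPKM, > 5-fold, > 100 reads). In the count track, where
no transcript lengths exist, mean normalized counts (threshold 5)
proxy for the FPKM filter; the FPKM path itself is exercised and tested
in the read-level track.

Correlations of fold changes are computed on the log2 scale; CIs use
the Fisher z transform with the normal quantile and √(n−3), degenerate
at |r| = 1. Basal expression for the DBEI is the mean of normalized
control samples — "basal" is not otherwise defined, and unstimulated
samples are the natural reading. Connection maps weight the complete
replicate graph by squared Pearson correlation of log2 fold-change
vectors and are exported as GraphML and edge lists; layout is a
rendering concern and is delegated. Top-N reference sets for overlap
counts break fold-change ties by gene id for determinism. The
within-sample ("Tc1-style") DRI concordance retains pairs whose
human-side gene has strictly more than 100 raw reads summed over the
dual-genome samples — the aggregate reading of the cut-off — and
correlates within-sample log2 DRIs with separate-preparation log2 DRIs.

Normality of the log2 DRI distribution is reported descriptively
(mean, SD, histogram), not asserted by a test.

One estimation artifact is worth naming: *estimated* DRI and DBEI share
the control-sample counting noise (the control mean enters the fold
change's denominator and the basal estimate), which induces a small
negative correlation between them (r ≈ −0.10 at the default settings)
even though the generator draws them independently. The independence
recovery check therefore runs on the generator's truth channel; the
estimated-channel correlation is reported alongside in the pipeline
summary so the artifact is visible rather than absorbed.

## Promoter motif divergence

The motif scan matches an IUPAC consensus (default the AP-1 site
`TGASTCA`) on both strands of both promoters; the pair is globally
aligned with match +1, mismatch −1, gap −2 (a standard stringent-gap
scoring under which substitution-only homologs align without gaps), and
a hit is species-specific iff its aligned window in the other promoter
overlaps no hit there. Since the AP-1 consensus is its own reverse
complement, one physical site yields a hit on each strand; site counts
collapse hits by window position. The pipeline's demo promoter pair is
synthetic: planted consensus sites in one sequence with a single-base
disruption at the homologous positions of the other.

## Numerical and design choices

- One top-level seed; each stage draws from a derived stream
  (`(seed · 1000003 + stage) mod 2³¹`), so stages are independently
  reproducible and identical config + seed give byte-identical outputs
  (manifest hashes are compared in tests).
- SAM output is version 1.6 with 1-based POS, M/N CIGARs only, a
  mandatory NM tag and no clipping operations; round-trips are lossless.
- Verdicts refine "rejected" into labelled causes (multimap, structure,
  mismatch, ambiguous) for testability; a rolled-up rejected count is
  also reported.
- Reads aligning multiply to one genome with no alignment to the other
  are rejected at the final single-alignment check, as the assignment
  invariant requires a single alignment.
- BH adjustment delegates to `statsmodels` behind the package's
  `bh_adjust` surface and is verified against an explicit
  min-over-suffix step-up oracle for all short inputs.
- Degenerate inputs are defined, not accidental: zero-variance groups
  give p = 1 (equal means) or 0; zero assigned fragments for a species
  yield NaN FPKM rather than division by zero; empty read sets produce
  empty, valid outputs.

## Problem sizes

The shipped defaults — two ~100 kb genomes, 50 genes, 20,000 fragment
pairs, an 11,302-gene count experiment with 3 replicates — run the full
pipeline in ~10 s and the acceptance script in under a minute on one
CPU, while being large enough for the stochastic checks (binomial
calibration of divergence and error rates, SD recovery within
chi-square bounds at 10,000 genes, 99%-null bands for independence,
100-run cluster-recovery rates). These sizes are the package's chosen
demonstration scale.

## Known limitations

- The DE stand-in has neither shrinkage nor NB GLM inference; absolute
  significance counts are not comparable to dedicated DE packages,
  and cohort/overlap sizes at 3 replicates are power-limited.
- The aligner is annotation-guided; novel junctions would be found only
  as (penalized) contiguous alignments.
- Conserved-read loss at the default 2% divergence (~24% of
  perfect-match reads) is orders of magnitude above what distant
  genome pairs exhibit; it is a stress setting, not a fidelity target.
- The motif scan is consensus-based by design; probabilistic (PWM)
  scoring is out of scope.
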