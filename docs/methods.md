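# Methods

`aluedit` quantifies adenosine-to-inosine (A-to-I) RNA editing from aligned
bulk RNA-seq and runs the statistics of a case/control editing study.
Inosine pairs as guanosine during sequencing, so editing appears as A→G
mismatches against the reference genome on the edited strand — and as T→C
on the sequenced strand when the edited transcript is antisense.  All
quantities below are strand-aware in this sense.

## Editing indices

**Alu Editing Index (AEI).**  For a set of strand-annotated repeat regions,

    AEI = 100 · Σ G / Σ (A + G)

summed over all reference-adenosine positions of plus-strand regions
(and `C / (T + C)` at reference-thymidine positions of minus-strand
regions).  Numerators and denominators pool over the whole region set, so
the index adds over any partition of the regions — a property the tests
assert.  Reference bases come from the FASTA, never from a read majority
vote.  A zero denominator yields NA.

A cleaner subset restricts to repeats that are (i) fully contained in a
3'UTR, (ii) at least 250 bp long, and (iii) accompanied in the same 3'UTR
by a contained, oppositely oriented repeat — the configuration that folds
into immunostimulatory double-stranded RNA.  Containment is full
containment (partial overlaps excluded; the stricter, reproducible
choice).  The opposite partner need not itself pass the length floor; a
`strict_partner` flag enables the alternative reading.

**Per-site levels and the Coding Editing Index (CEI).**  For each site in a
known exonic-site panel, coverage is the informative read count (A+G on
plus-strand sites, T+C on minus), the edited count is the G (or C)
support, and the level is `100·edited/coverage`.  Sites need ≥ 10
supporting reads to enter per-site analyses (`included`); a REDItools-style
detection flag (≥ 1 variant read, ≥ 0.001 frequency) is informational only
and never gates the arithmetic, so levels of exactly 0 are representable.
The pooled index

    CEI = 100 · Σ edited / Σ coverage

applies no per-site floor and is algebraically the coverage-weighted mean
of per-site levels (asserted to 1e-12).

**Centralization** is the fraction of total edited counts carried by the
top-k (default 5) sites of a tissue, with deterministic coordinate
tie-breaking.

## Pileup engine

Reads are converted to per-position base counts with the filters typical of
editing quantification: 5 bases trimmed at each read end *in read
coordinates* (sequenced bases, the `-T 5-5` convention), base quality ≥ 20
(configurable; a conventional default), mapping quality ≥ 10 as a proxy for
unique alignment (the aligner's multimapper filter is not re-run), and
exclusion of duplicate/secondary/supplementary/QC-fail records.
Insertions, deletions and reference skips contribute no counts at skipped
positions; `N` bases contribute nothing.  Overlapping mates are counted
independently by default (`mate_overlap="once"` drops second-mate bases in
the approximate mate span).  The engine accepts indexed BAM or plain
coordinate-sorted SAM and is verified against an independent naive
per-read recount on randomized fixtures.

## Interferon-signature (ISG) score

Interferon-stimulated-gene activity is summarized per sample from a 38-gene
signature (packaged; ADAR included).  Per gene, `z = (log2(TPM+1) − μ_ref) /
σ_ref` with the reference statistics taken from a designated control group;
a sample's score is the **median** z over available signature genes
(mean-z is an option).  The log2(TPM+1) transform stabilizes variance.
Genes with zero reference variance are dropped and counted.  The exact
arithmetic of published ISG pipelines varies; median-of-z against a control
reference is the conventional choice and all variants are exposed as
options.  The score is invariant to per-gene affine rescaling of
expression common to all samples.

## Cohort statistics

*Test gate.*  Student's unpaired two-sided t-test (or one-way ANOVA with
Tukey HSD for ≥ 3 groups) is used only when **every** group passes
Shapiro–Wilk at p ≥ 0.05 **and** every group has n ≥ 30; otherwise the
two-sided Mann–Whitney U test (or Kruskal–Wallis with Dunn's rank
post-test, BH-adjusted).  The conjunction is the conservative reading of
the two gating conditions.  Mann–Whitney p-values are exact for
min(n) ≤ 8 without ties, otherwise normal approximation with mid-rank tie
correction.  Group summaries are mean ± SEM with n; direction labels
follow the sign of (second group mean − first group mean), so with
`pair=(control, patient)` "up" means elevated in patients.

*Multiple testing.*  Benjamini–Hochberg step-up, one family per analysis.
Dunn post-test p-values are BH-adjusted (classical Bonferroni available).

*Meaningful sites.*  Per site (included observations only, ≥ 3 per group),
a two-group comparison of levels; BH across the sites of one analysis; a
site is *meaningful* iff |patient mean − control mean| ≥ 5 percentage
points **and** adjusted p < 0.05.  The threshold arm is deliberately
independent of the p-value: a precisely measured 2-point shift is
significant but never meaningful.

*Regression.*  Covariate adjustment is OLS of the response on a group
indicator plus age and a single sex indicator, with listwise deletion
(rejected if < 80% of samples have complete covariates) and explicit
collinearity detection.  The editing–inflammation interaction model is OLS
of AEI on standardized ADAR1 expression, standardized ISG score and their
product; the product-term p-value tests whether interferon signalling
modulates the ADAR1–editing relationship.

*Correlation* is Spearman with mid-rank ties (≥ 4 pairs; constant vectors
give NA).  *ROC* AUC is the rank statistic U/(n₁n₀) — equal to
P(case > control) + ½P(tie) — with a Hanley–McNeil normal confidence
interval clipped to [0, 1].

## Tissue editing profiles

Profile cells pool counts, never ratios: the (tissue, site) value is
`100·Σedited/Σcoverage` over the tissue's samples, masked below 10 pooled
reads.  Site inclusion follows two cutoffs — available in ≥ 5 tissues and
reaching ≥ 5% editing in at least one tissue (a strict variant requires
≥ 5% in ≥ 5 tissues).  "PCA-based hierarchical clustering" is
under-determined, so the implementation fixes and exposes: mean imputation
of masked cells, per-site standardization, principal components retaining
≥ 90% of variance, Euclidean distance, average linkage, and
name-sorted/deterministic leaf order.  Trees are exported as Newick.

## Synthetic cohort generator

The generator plants every structure the pipeline measures, on a toy
genome (default 3 × 120 kb):

- A-rich repeat regions (~150–350 bp, 35% adenosine on their sense strand),
  most inside 3'UTRs with a configurable fraction arranged as oppositely
  oriented pairs, some intergenic.  Within a repeat, each strand-adjusted
  reference adenosine is emitted edited with the sample's rate ε.
- A 314-site coding panel.  Seven named sites mirror the prominent
  cardiovascular recoding sites: IGFBP7/COPA/COG3-like sites start at
  control levels 16/13/12% and gain +11 percentage points in disease;
  FLNA/NEIL1/CCNI/SRP9-like sites are highly edited (75–90%) and, together
  with IGFBP7, highly expressed (25× exon coverage), reproducing the
  centralized recoding activity of cardiovascular tissue.  Background
  sites sit at 2–35%.
- Two groups, by default 14 controls vs. 13 patients with ε 0.56% → 0.67% —
  the scale reported for ventricular cardiomyopathy cohorts.  Per-sample ε
  is Beta-distributed around the group rate (concentration 8000, giving
  SEM-scale donor spread); per-site levels get Beta jitter
  (concentration 150).
- Expression: the 38 ISG genes shift +1 log2 in disease and share a latent
  inflammation component correlated with ε (default Spearman-scale coupling
  0.5); the ADAR1 gene participates in both; an ADAR2 stand-in (ADARB1) is
  uncoupled and unshifted; four heart-failure markers (NPPA, NPPB, TNNI3,
  TNNT2) shift 0.8–2 log2 with donor noise; background genes are null.
- Reads: single-end 100 bp, uniform-start tiling of transcribed regions at
  Poisson depth (default 50×, typical exonic depth for this design),
  uniform strand-symmetric sequencing error 0.001 (an A→G error is e/3),
  constant base quality, correct coordinates/CIGAR, coordinate-sorted SAM.
  Reads are emitted pre-aligned because alignment is out of scope.
- `reads=False` skips read emission and draws measured indices directly
  from their exact sampling distributions (Poisson coverage, binomial
  mismatches) — the analytic closure used for statistical calibration.

Identical configuration + seed ⇒ byte-identical outputs.  What the
generator does **not** emulate: genomic SNPs and allele-specific
expression (a known-site panel and the index's aggregation sidestep most
SNP confounding in practice, but tests here cannot demonstrate that),
empirical error/quality profiles, splicing, paired-end fragments, and
tissue-specific editing programs in the *default* cohort — the default
emulates a single-tissue ventricular case/control study; per-tissue level
scales are a config knob exercised by the clustering tests.  Passing tests
therefore show correctness of the measurement and inference machinery
under the planted model, not robustness to alignment artefacts or genomic
variation.

## Pipeline, determinism, problem sizes

`run_pipeline` executes simulate → pileup/indices → ISG → statistics →
clustering → ROC into a run directory of TSV tables, with a JSON manifest
recording config, seed, version and per-stage input/output SHA-256
digests; a stage re-runs when any input digest changes and is otherwise a
recorded cache hit.  The manifest timestamp is a fixed placeholder by
default so that equal config + seed gives byte-identical bundles
(`wall_clock=True` opts into real stamps).

Test problem sizes are chosen so the whole suite runs in a few minutes on
one core: the oracle battery uses ≤ 200-read SAMs; editing-rate recovery
uses ~5,500 planted adenosine positions at 100× with 20 replicates per
rate (pooled-count comparison at 3 binomial SE); calibration uses 2,000
null two-group draws and 20 × 100 null sites; power checks use 100–200
replicates at the reported effect scales; determinism runs the full
default study twice.

## Known limitations

- Mapping-quality floors only approximate unique-mapping enforcement.
- The mate-overlap "count once" mode approximates the mate span from the
  read's own length (mate CIGAR is not inspected).
- Regions passed to the AEI are assumed disjoint; overlapping regions
  would double-count.
- The ISG score's exact published arithmetic varies between pipelines;
  results are comparable within one scoring convention only.
- Clustering output depends on the documented method parameters; no claim
  is made that a different metric/linkage would yield the same tree.
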