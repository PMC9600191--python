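# Methods

## The GI score

A germline heterozygous SNP or indel in a diploid genome has expected
allele fraction 0.5.  cfDNA is modelled as a two-population mixture: a
fraction *f* (the tumor fraction) of molecules from an aberrant clone
whose genome is tiled by allele-specific copy-number segments
`(c_major, c_minor)`, and `1 − f` from diploid normal cells.  At a het
site whose ALT allele sits on a haplotype with `c_alt` clone copies,

    p = ((1 − f) + f·c_alt) / (2(1 − f) + f·(c_major + c_minor)).

This reduces to 0.5 at f = 0 and to `c_alt / (c_major + c_minor)` at
f = 1.  The per-sample statistic is the proportion of *shared germline
het* mutations whose observed AF escapes the quartile band around 0.5:

1. From the leukocyte reference, keep SNV/indel records with AF in
   [0.2, 0.8] (bounds inclusive) — the germline-het filter.
2. Intersect with the assay sample by normalised variant key
   (chrom, pos, ref, alt after suffix/prefix trimming of indel alleles).
3. A shared mutation is a *GI mutation* when its assay AF < 0.25 or
   AF > 0.75 (band edges exclusive).
4. `score = N_GI / N_common`; samples with fewer than `min_common = 20`
   shared mutations are reported indeterminate rather than scored, since
   a ratio of tiny counts is unstable.

Copy-number (CNV) records never enter the score.  Tissue samples, when
present, are scored identically against the same leukocyte reference.

The quartile band is the fixed theoretical band (0.25, 0.75) centred on
the diploid expectation, not per-sample empirical quartiles: empirical
quartiles would place ~50% of mutations outside the IQR by construction
and pin every score near 0.5, destroying the bimodal GS-vs-GI separation
the statistic relies on.

### A structural property worth knowing

At any shared het site the two haplotype AFs sum to 1, so both escape the
band at the same state-dependent tumor-fraction threshold: f > 0.4 for
(3,0), f > 1/3 for (4,0), f > 0.5 for (2,0) (copy-neutral LOH) and (5,1),
f > 2/3 for hemizygous deletion (1,0) — and *balanced* states such as
(3,1) or (4,2) never escape at any f.  The score is therefore blind to
allelic imbalance below roughly one-third tumor fraction regardless of
depth.  This drives several generator defaults (below) and is the main
caveat when applying the score to low-purity samples.

## GI/GS cutoff

Cohort score distributions are bimodal.  The default cutoff method fits a
two-component Gaussian mixture by EM (scikit-learn, 50 restarts, seeded)
and returns the point between the component means where posterior
membership flips — the valley between the modes.  Degenerate fits
(component weight < 0.05 or mean separation < 0.02) fall back to the Otsu
criterion (1000-point grid minimising within-class variance) with a
logged warning; a fixed constant (default 0.07) is available for
reproducing a previously chosen threshold.  Classification uses
`score ≥ cutoff → GI`; the boundary is deliberately assigned to the
unstable class.  Fitting is deterministic given the seed.

By default the cutoff is fitted on CSF scores only; pooling compartments
is a configuration choice.

## Copy-number validation

Binned read counts are normalised to `log2(count / median autosomal
count)`; zero-count bins are flagged missing.  Adjacent bins merge
greedily into segments while a bin stays within `merge_tol = 0.1` of the
open segment's running mean — a deliberately minimal, fully specified
segmenter rather than a CBS implementation, because the validation arm
only needs per-segment means and lengths.  The altered genome fraction
(AGF) is the length fraction of segments with |mean log2| > 0.2, and a
sample is copy-number-unstable when AGF ≥ 0.10.  Concordance compares
this call with the score-based status.  No GC or mappability correction
is applied: the synthetic tracks carry no such bias, and correcting real
tracks is out of scope and should happen upstream.

Greedy merging is sensitive to bin-level noise relative to `merge_tol`;
with Poisson counts the per-bin log2 SD is ≈ 1.44/√(mean count), so mean
counts ≥ ~1000 keep spurious break rates negligible.  The generator's
default of 1000 expected reads per 1 Mb bin corresponds to well under 10×
genome coverage for typical cfDNA fragment sizes.

## Statistical layer

* Categorical group comparisons use Pearson chi-squared *without*
  continuity correction when all expected cell counts are ≥ 5, otherwise
  Fisher's exact test.  This single rule reproduces the printed cohort
  contingency p-values (0.026 for LP shunt, 0.074 for sex, 0.6 for age
  group) from their printed counts.  scipy offers no exact test for r×c
  tables, so low-count multi-level variables fall back to chi-squared
  with a logged note.
* Continuous comparisons use the two-sided Wilcoxon rank-sum test.
* Survival uses Kaplan–Meier estimates with Greenwood confidence bands,
  log-rank tests, and Cox proportional-hazards regression (lifelines).
  Covariates enter the multivariate model when their univariate p < 0.05;
  with a single qualifying covariate the multivariate hazard ratio equals
  the univariate one by construction.  Binary covariates with an
  event-free level are flagged unstable (separation).
* Co-mutation enrichment cross-tabulates carriers of a gene pair against
  genomic status (Fisher's exact, two-sided) and compares carrier vs
  non-carrier scores by rank-sum.  Raw p-values are reported without
  multiple-testing correction — the scan is exploratory and is documented
  as such.
* Correlations default to Pearson; Spearman by flag.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults define the study
conditions everything downstream is validated under.

* **Genome** — 22 autosomes at human-like lengths.  Sex chromosomes are
  excluded because the AF-0.5 assumption fails on the male X.
* **Panel** — 300 germline het sites per patient, placed uniformly
  (chromosomes weighted by length), each with a randomly chosen ALT
  haplotype that is fixed per patient and shared across compartments.
  Panel size is configurable; real panel designs vary.
* **Depths** — Poisson around compartment means (leukocyte 800×, plasma
  1000×, CSF 1500×, tissue 1000×), within the depth range typical of
  clinical hybrid-capture panels; negative-binomial overdispersion is
  available via config.  ALT depths are binomial at the mixing AF.
* **Clones** — a GI clone draws a target altered-genome fraction from
  U(0.2, 0.5) and alters each chromosome with that probability, choosing
  a state from {(3,0): 0.35, (4,0): 0.25, (5,1): 0.25, (2,0): 0.15}.  GS
  clones are diploid (their het AFs stay at 0.5 at any tumor fraction).
  The default state mix deliberately contains only events visible to both
  the AF score and read-depth log2 ratios across the default
  tumor-fraction range, so the two validation arms agree on the same
  ground truth; balanced gains and hemizygous deletions — genuine blind
  spots of one arm or the other — can be added through the config when
  studying exactly those failure modes.
* **Tumor fractions** — CSF and tissue of GI patients draw
  f ~ U(0.55, 0.95); plasma draws U(0, 0.05) except for an 8% chance of
  strong extracranial shedding (then CSF-range), which yields the few
  percent of plasma samples that classify GI.  GS patients shed DNA too
  (their clone is simply diploid), so somatic burden exists in both
  groups.  The high CSF range reflects cytology-positive meningeal
  disease, where CSF cfDNA is predominantly tumor-derived, and respects
  the structural detection thresholds above: at f below ~0.4 the score is
  blind by algebra, not by noise.
* **Artifact floor** — real panels show a small rate of het sites with
  artifactual AFs far from 0.5 even in stable samples (which is why
  published GS score medians sit near 0.03 rather than 0).  The generator
  has an `artifact_rate` channel for this; it defaults to 0 so that the
  null behaviour of the score is exactly the analytic binomial null.
  Simulated GS samples therefore score ≈ 0.000, and a mixture cutoff
  fitted on noise-free cohorts lands near 0 rather than near 0.07.
* **Somatic layer** — driver genes (TP53, EGFR, RB1, ERBB2, KMT2C, …)
  mutate with status-dependent Bernoulli probabilities (config entries,
  not biological claims), are sampled at AF f/2, and survive a simple
  detection rule (ALT reads ≥ 4 and AF ≥ 0.02).  Per-gene CNV records are
  emitted where the mixed copy number deviates from 2 by ≥ 0.5.  This
  makes burden, detection-rate and co-mutation analyses exercisable.
* **Clinical model** — ln(ICP/1.3 kPa) = 2.0·score + N(0, 0.8²); an LP
  shunt is placed when ICP > 2.5 kPa.  KPS = clamp(80 − 40·score +
  N(0, 12²)) rounded to tens.  MFS/OS times are exponential with
  GS-baseline medians 2.9/3.9 years and proportional-hazard multipliers
  2.338/2.109 for GI patients; censoring is administrative, U(0, 10 y),
  giving ~25% censoring.
* **Determinism** — one `numpy` Generator seeded from the config drives
  everything; identical configs produce byte-identical on-disk cohorts
  (VCF + TSV variant tables, manifest and clinical CSVs, BED-like bin
  tracks, ground-truth JSON).

### What passing tests do and do not show

The generator reproduces the *statistical structure* the score detects —
binomial AF noise around a mixture expectation, bimodal cohort score
distributions, compartment contrasts, survival effects — but not
real-data pathologies: no mapping or sequencing artifacts by default, no
GC/mappability bias in bins, no subclonal heterogeneity (one clone per
patient), no germline CNVs, and no panel design effects.  Green tests
demonstrate the pipeline's correctness under the stated model, not
robustness to those pathologies.

## Numerical choices and edge cases

* Coordinates: variant records 1-based (VCF), bins/segments 0-based
  half-open (BED); conversions happen at module boundaries.
* AF precedence: when a stored AF and AD/DP disagree by > 0.01, depths
  win and a warning is logged.  Records with neither are rejected with a
  warning.
* Indels match across samples after minimal-representation trimming
  (common suffix, then prefix, keeping one base each).
* A sample with no shared mutations is indeterminate, never score 0.
* Zero-count bins are excluded from normalisation and segmentation; an
  all-zero track is an error.
* All-tie burden comparisons report p = 1 rather than failing.
* Problem sizes in the test suite and acceptance script (hundreds of
  samples, hundreds of replicates, 400 per survival arm) are chosen so
  every stochastic check has comfortable margins while the whole suite
  runs in about a minute on a laptop core.

## Known limitations

* The score cannot see allelic imbalance below f ≈ 1/3 (algebraic
  threshold), balanced amplifications at any f, or hemizygous deletions
  below f = 2/3.  It is a detection statistic for high-tumor-fraction
  fluids, not a tumor-fraction estimator.
* Copy-neutral LOH is invisible to the read-depth arm, so score/AGF
  concordance is structurally imperfect when cnLOH dominates a genome.
* The greedy segmenter is not a changepoint method; breakpoint accuracy
  degrades when bin noise approaches `merge_tol`.
* The survival layer assumes proportional hazards and uses exponential
  baselines in simulation; no competing risks, landmarking or
  time-dependent covariates.
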