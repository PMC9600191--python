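# csfgi

Genomic-instability (GI) scoring of cerebrospinal-fluid cell-free DNA from
allelic imbalance at germline heterozygous sites.

## The problem

In solid-tumor patients with meningeal metastasis, tumor DNA shed into the
cerebrospinal fluid (CSF) carries the genomic fingerprint of the meningeal
lesion, while plasma cfDNA mostly reflects extracranial disease.  A
genomically unstable tumor accumulates allele-specific copy-number
alterations, and these distort the allele fractions of ordinary germline
heterozygous SNPs/indels: a diploid het site reads AF ≈ 0.5, but when a
fraction *f* of the cfDNA comes from a clone carrying `(c_major, c_minor)`
copies of the two parental haplotypes, the expected ALT fraction becomes

    p = ((1 − f)·1 + f·c_alt) / ((1 − f)·2 + f·(c_major + c_minor))

`csfgi` turns matched leukocyte / CSF / plasma (and optional tissue)
variant tables into a per-sample **GI score**

    GI score = N_GI / N_common

where `N_common` counts germline het mutations shared between the
leukocyte reference (leukocyte AF in [0.2, 0.8]) and the assay sample, and
`N_GI` counts those whose assay AF escapes the theoretical quartile band,
i.e. AF < 0.25 or AF > 0.75.  Samples are classified GI/GS by a
data-driven cutoff (two-component Gaussian mixture; a fixed threshold such
as 0.07 is also supported), validated against binned low-depth WGS
log2-ratio copy-number profiles, and fed into a cohort-level statistical
layer (chi-squared/Fisher group tests, Wilcoxon comparisons, Kaplan–Meier
and Cox survival, co-mutation enrichment, correlations).

A fully ground-truthed synthetic cohort generator produces matched variant
tables (VCF + TSV), WGS bin tracks, clinical covariates and survival times
with the same statistical structure, so every stage is testable without
patient data.

The intended audience is liquid-biopsy method developers and
bioinformaticians who want a reproducible, tested reference implementation
of AF-deviation GI scoring.

## Worked example

Run the full pipeline on a simulated 56-patient cohort:

```bash
csfgi run --seed 1 --out demo_run
```

prints

```
report written to demo_run/report.json
  csf: 67.9% GI of 56 samples
  plasma: 2.0% GI of 50 samples
  tissue: 88.9% GI of 9 samples
```

Two thirds of CSF samples are classified genomically unstable while almost
no plasma sample is — the compartment contrast the score is designed to
expose.  `demo_run/report.md` summarises the run:

```
## GI classification rates
- csf: 67.9% of 56 samples classified GI
- plasma: 2.0% of 50 samples classified GI
- tissue: 88.9% of 9 samples classified GI

## Copy-number validation
- score/AGF concordance: 96.4% over 56 tracks
```

96.4% of samples receive the same GI/GS call from the orthogonal
copy-number arm (altered-genome fraction of segmented log2 ratios ≥ 0.10).
`demo_run/report.json` additionally holds the group comparisons — in this
run, LP-shunt placement differs between GI and GS patients (chi-squared
p = 0.013), KPS is lower in the GI group (rank-sum p = 1.4e-05), and the
intracranial pressure correlates with the GI score (Pearson r = 0.42,
p = 0.0012) — along with per-endpoint Kaplan–Meier medians and Cox hazard
ratios.  Note the fitted mixture cutoff on this noise-free synthetic
cohort sits near 0.004: simulated genome-stable samples score exactly 0,
so the valley between the modes hugs zero.  Real panels have an artifact
noise floor that pushes the valley towards 0.07; the generator models it
through the `artifact_rate` config knob (see `docs/methods.md`).

Individual stages are available as subcommands (`csfgi simulate`,
`csfgi score`, `csfgi cutoff`, `csfgi cnv`, `csfgi report`), all reading
and writing plain VCF/TSV/CSV/JSON, so any stage can consume a previous
run's on-disk outputs.  Library use mirrors the CLI:

```python
import csfgi

dataset = csfgi.simulate_cohort(csfgi.SimulationConfig(rng_seed=1))
results = csfgi.score_cohort(dataset.patients)
model = csfgi.fit_cutoff(
    [r.score for r in results if r.compartment == "csf"], rng_seed=1
)
results = csfgi.classify_all(results, model)
```

## Layout

```
src/csfgi/
  models.py          # data model: variant tables, patients, profiles, results
  variant_io.py      # VCF/TSV tables, manifest and clinical CSVs
  gi_scoring.py      # germline filter, shared-mutation screen, GI score
  gi_cutoff.py       # mixture / Otsu / fixed GI-GS threshold
  cnv_profile.py     # log2 ratios, greedy segmentation, AGF concordance
  cohort_analysis.py # group tests, survival, co-mutation, correlations
  synthetic.py       # ground-truthed cohort generator
  pipeline.py, cli.py# orchestration and the csfgi command
docs/methods.md      # models, parameters, design choices, limitations
```
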