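# hippocase

Single-case ("one patient vs. a control group") and group-level analysis of
hippocampal subfield volumes and MRS metabolite concentrations, with a
synthetic-cohort generator so the whole pipeline is testable offline.

The package starts from measurement tables (no image formats): per-hemisphere
subfield volumes (CA1, CA2, CA3, DG, subiculum), per-hemisphere metabolite
concentrations (tNAA, Glu, Gln, tCho, tCr, Ins; GABA/Lac enter pre-QC) with
CRLB percentages and voxel tissue fractions, and subject demographics.

## What it does

- **`core_io`** — typed records, TSV/CSV readers and writers (round-trip
  exact), validation with file/line context, YAML run configuration.
- **`derived_measures`** — head-size covariance adjustment
  (`adjusted = observed − slope·(TBV − TBV_mean)`, slopes fit per
  sex × hemisphere on an independent reference cohort), uniform subfield
  scaling, CSF partial-volume correction (`c / (1 − f_csf)`), CRLB quality
  filtering (strict `> threshold` rejection, cohort-wide reportability),
  asymmetry indices (`(L − R) / [(L + R)/2]`), ipsi/contra mapping, the
  memory-impairment threshold (z ≤ −1.34) and VOI geometry.
- **`single_case_inference`** — the core: each patient's measures are tested
  against the controls by a permutation test with sign flipping (rotation of
  the null-model residuals into the case slot × all sign patterns; exhaustive
  when the orbit fits a configured bound, Monte Carlo otherwise), after a
  Box-Cox preconditioning of volumes/concentrations (fixed λ = 0 by default;
  MLE policies available). Reports uncorrected p-values, Bonferroni
  family-wise correction over the standard variable families (10 subfield
  volumes, 5 subfield asymmetries, 12 metabolite concentrations, 6 metabolite
  asymmetries), a permutation-native max-statistic alternative, and a
  laterality concordance label per patient and modality.
- **`group_stats`** — Shapiro-Wilk normality gating, ANCOVA controlling for
  age, paired-t symmetry gating of control hemispheres before ipsi/contra
  pooling, one-/two-tailed Pearson and age-adjusted partial correlations,
  repeated-measures ANOVA + ICC(3,1) for repeat-segmentation reliability.
- **`synthetic_data`** — seeded cohort generator with configurable control
  distributions, TBV–hippocampus covariance, injected patient effects,
  CRLB/CSF artefacts, missing hemispheres, and a ground-truth ledger with
  recovery scoring (sensitivity / specificity / laterality accuracy).
- **`cli`** — `hippocase` command with `simulate`, `derive`, `group-stats`,
  `case-tests`, `report` and `all` subcommands, plus a JSON run manifest.

## Quick start

```sh
# generate a synthetic cohort (writes subjects.tsv, volumes.tsv, mrs.tsv,
# a reference cohort for slope fitting, and truth.json)
hippocase simulate --seed 7 --out data/

# run the full pipeline
hippocase all \
    --subjects data/subjects.tsv --volumes data/volumes.tsv --mrs data/mrs.tsv \
    --ref-subjects data/reference/subjects.tsv \
    --ref-volumes data/reference/volumes.tsv \
    --seed 7 --out results/

# re-render the per-patient reports from the saved tables
hippocase report --results results/
```

Outputs: `derived.tsv`, `asymmetry.tsv`, `group_results.tsv` (including
hemisphere-clustered ipsi/contra comparisons for symmetry-poolable measures),
`symmetry.tsv`, `correlations.tsv`, `case_results.tsv`, `concordance.tsv`,
`patient_reports.txt` and `manifest.json`.

Configuration is a YAML file mirroring `AnalysisConfig`
(`alpha`, `tails`, `n_max_exhaustive`, `n_mc`, `rng_seed`, `scaling_mode`,
`crlb_reject_threshold`, `boxcox_policy`, `fwe_method`, ...), passed with
`--config`; `--seed` overrides the configured seed.

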