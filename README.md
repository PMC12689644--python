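# bagpipe

Brain-age-gap (BAG) progression analysis toolkit for longitudinal
neurodegeneration cohorts, exercised end-to-end on a synthetic cohort
generator with known ground truth.

The pipeline covers:

- **`bagpipe.simulate`** — synthetic longitudinal cohorts: multi-outcome
  clinical trajectories drawn from a latent-time joint mixed-effects
  structure (shared per-subject time shifts, two progression subtypes,
  irregular visit schedules), voxel feature grids with age- and
  disease-dependent atrophy (cortical-shell vs subcortical-core
  patterns), ordinal staging, and proportional-hazards event times.
  Every generative parameter is returned as a `GroundTruth` object for
  parameter-recovery testing.
- **`bagpipe.latent`** — the latent disease time joint mixed-effects
  model: min-max outcome normalization with direction harmonization, a
  partially collapsed Gibbs sampler (random effects marginalized out of
  the time-shift/slope/covariate updates), split-R-hat convergence
  reporting, per-visit latent times, and a Kendall tau-b staging
  validation contrast with a subject-level bootstrap.
- **`bagpipe.brainage`** — brain age workflows (Gaussian smoothing +
  linear-interpolation resampling, optional PCA; lasso / Gaussian-process /
  ridge regressors), Cole- and Beheshti-style linear bias corrections,
  cross-validated workflow selection, Lin's concordance correlation, and
  retest/longitudinal-consistency reliability checks.
- **`bagpipe.morphometry`** — mass-univariate voxelwise/parcelwise GLMs
  of subtype contrasts with covariate adjustment and Benjamini-Hochberg
  correction, plus an analytic shell/core parcel atlas.
- **`bagpipe.progression`** — covariate-adjusted BAG group comparisons,
  mixed-model BAG trajectories, empirical-Bayes outcome slopes on the
  latent timescale, and partial-correlation tables with per-family BH
  adjustment.
- **`bagpipe.cox`** — Cox proportional hazards with delayed entry (left
  truncation) and Efron/Breslow ties, implemented directly from the
  partial likelihood, with scaled-Schoenfeld-residual PH diagnostics.
- **`bagpipe.power`** — cognitive composite endpoints, the closed-form
  random-slope sample-size formula with power curves, BAG-percentile
  prognostic enrichment, and Monte Carlo validation of the closed form.

## CLI

```sh
bagpipe simulate --seed 1 --out out/                # cohort + features + staging
bagpipe fit-latent-time --cohort out/ --seed 1 --out fit/
bagpipe brainage select --features out/ --folds 5 --seed 0 --out selection.tsv
bagpipe brainage apply --features out/ --workflow "S0_R4+LR" \
    --correction beheshti --seed 0 --out bag.tsv
bagpipe analyze compare --bag bag.tsv --groups HC,fast
bagpipe analyze trajectory --bag bag.tsv --group fast
bagpipe analyze survival --events events.tsv
bagpipe power --cohort out/ --bag bag.tsv --percentiles 50,70,90 \
    --alpha 0.1 --power 0.8 --effect 0.3 --seed 1 --out power.tsv
```

Cohorts, fits, BAG tables and reports are plain TSV; feature grids are
written as `.npy` arrays with a JSON geometry sidecar (optional NIfTI
export via `nibabel`).
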