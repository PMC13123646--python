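# hsisas

SWIR hyperspectral imaging soft abundance scoring for quantifying
treatment-related spectral change in paired (pre/post) wrist acquisitions,
with power-Doppler ultrasound quantification, nonparametric cohort
statistics, and a fully synthetic cohort generator for offline testing.

## What it does

- **Calibration** (`hsisas.cube_io`) — ENVI-style cube I/O (BSQ/BIL, text
  headers) and flat-field reflectance calibration from white/dark
  reference frames, with QC masking of degenerate pixels.
- **Segmentation** (`hsisas.segmentation`) — hand/background separation by
  the 1303 nm / 1453 nm band ratio and an oracle-tested Otsu threshold;
  wrist ROI extraction as a fixed-height row band anchored at an
  operator-supplied wrist coordinate.
- **Spectral correlation** (`hsisas.correlation`) — intra-subject and
  pooled inter-subject band-pair Pearson cross-correlation matrices over
  paired pre/post wrist pixels, with a ridge-regularized symmetrized
  inverse; a classical CEM autocorrelation mode is available as
  `corr_mode="autocorrelation"`.
- **Scoring** (`hsisas.scoring`) — constrained-energy-minimization soft
  abundance scores against a mean post-treatment target signature
  (subject scope for intra, cohort scope for inter), per-pixel abundance
  maps, and per-wrist scalar reductions.
- **PDUS** (`hsisas.pdus`) — synovial polygon rasterization (even-odd rule,
  boundary inclusive) and power-Doppler area from the red-gray image by a
  fixed or Otsu-within-ROI threshold.
- **Statistics** (`hsisas.stats`) — median/IQR summaries, an exact
  (sign-assignment enumeration / shift-algorithm) Wilcoxon signed-rank
  test with tie handling and a normal fallback, Spearman correlation, and
  improvement-oriented change tables honoring wrist-level vs patient-level
  variables.
- **Synthetic cohorts** (`hsisas.synth`) — deterministic phantom scenes
  with water-absorption dips near 970/1190/1450 nm, a treatment-modulated
  feature near 1250 nm, per-wrist nuisance fields, coupled clinical
  covariates (DAS28/ESR/CRP), and painted PDUS fixtures with exact
  ground-truth pixel counts.
- **Pipeline + figures** (`hsisas.pipeline`, `hsisas.viz`) — an
  end-to-end driver (calibrate → segment → correlate → score → stats →
  figures) with deterministic CSV outputs, mean ±1 SD spectra plots,
  red→green abundance maps, and the intra/inter 2-D score projection.

## CLI

```bash
hsisas simulate --m 11 --effect 0.1 --seed 42 --out simdata/   # synthetic cohort on disk
hsisas calibrate --raw r.img --white w.img --dark d.img --out refl.img
hsisas segment --cube refl.img --coords coords.csv --subject s01 \
    --visit pre --hand L --extension 100 --out roi_s01
hsisas pdus --image us.png --roi roi.csv --mode reddom --threshold auto
hsisas stats --cohort scores.csv --clinical clinical.csv --out report/
hsisas run --config run.json --seed 42 --out report/           # full pipeline
```

`hsisas run` simulates a cohort from the config (JSON or TOML of
`PipelineConfig` fields) and writes `cohort_table.csv`, a pre/post summary
with Wilcoxon p-values, a starred Spearman matrix over improvement deltas,
a Markdown report, and figures.

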