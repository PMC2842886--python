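# sodphrv

Second-order difference plot (SODP) features and ensemble 1-nearest-neighbor
classification for heart-rate-variability RR-interval series, with a
synthetic two-cohort generator so the full pipeline runs without external
data downloads.

The SODP scatters successive RR differences, `x(i+2) − x(i+1)` against
`x(i+1) − x(i)`. Subjects with depressed short-term variability (as in
congestive heart failure) concentrate near the origin, and the package
quantifies that with six features plus SDRR:

| feature   | meaning |
|-----------|---------|
| `ctm`     | fraction of SODP points strictly inside a disc of radius *r* |
| `d_mean`  | mean origin distance of the in-disc points |
| `cctm1..4`| per-quadrant split of `ctm` (half-open quadrants; origin → Q1) |
| `sdrr`    | sample SD of the RR intervals |

Classification is leave-one-subject-out 1-NN (Euclidean or Mahalanobis)
over every non-empty subset of the chosen feature set, repeated over `mc`
evenly spaced test windows of the held-out subject, with strict `>0.95`
voting thresholds at both the realization and feature-subset level. A
simple SDRR threshold rule is included as a baseline.

## Modules

- `sodphrv.synthetic_rr` — AR(1)-based cohort generator with independent
  control of long-term SD and successive-difference SD, plus optional slow
  trends and ectopic (short beat + compensatory pause) contamination.
- `sodphrv.rr_io` — plain-text RR file / manifest I/O and preprocessing
  (running-median ectopic filter, centered moving-average detrend).
- `sodphrv.sodp_features` — SODP construction and the seven features.
- `sodphrv.feature_selection` — radius-grid sweep with a pooled two-sample
  t-test per radius; selects the argmin-p radius per feature.
- `sodphrv.knn_ensemble` — the leave-one-out ensemble classifier and the
  SDRR threshold baseline.
- `sodphrv.cli` — `sodphrv` command with `synth`, `preprocess`, `features`,
  `select-r`, `classify` and `all` subcommands.

## CLI quick start

```sh
cat > config.yaml <<'EOF'
seed: 7
cohort:
  n_subjects_per_group: 12
  n_beats: 7000
  n:   {sd_base_s: 0.05, succ_diff_sd_s: 0.04}
  chf: {sd_base_s: 0.03, succ_diff_sd_s: 0.015}
grid: {start: 0.005, stop: 0.05, step: 0.005}
ensemble: {train_length: 7000, window_length: 3000, mc: 11}
EOF

sodphrv all --config config.yaml --out run/
```

This writes `run/features.csv`, `run/table1.csv` (radius selection),
`run/report.json` + `run/summary.csv` (classification grid: {ctm},
{ctm,d_mean}, all six features, {sdrr} × both distances), and `run/run.json`
(seed, config hash, versions). Stages can also be run individually, e.g.:

```sh
sodphrv synth --config config.yaml --out cohort/
sodphrv select-r --manifest cohort/manifest.csv --grid 0.005:0.05:0.005 --out table1.csv
sodphrv classify --manifest cohort/manifest.csv --distance mahalanobis \
    --features ctm,d_mean --mc 11 --window 3000 --train 7000 --out report.json
```

All outputs are deterministic at a fixed seed (byte-identical reruns).

## Default parameters

Disc radii default to 0.015 s for `ctm`/`cctm` and 0.035 s for `d_mean`;
the reference geometry is 70000-beat training stretches, 30000-beat test
windows and `mc = 31` realizations, all configurable.
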