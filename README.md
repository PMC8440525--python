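# ssvep-rca

Analysis pipeline for frequency-tagging steady-state visual evoked potential
(SSVEP) EEG experiments with an oddball (base/deviant) design:

- **`ssvep_rca.synth`** — synthetic multichannel EEG with planted periodic
  sources (known topographies, per-harmonic amplitudes, group delays),
  spatially mixed 1/f + white sensor noise, injectable blink-like artifacts,
  stimulus schedules and a spherical sensor montage with neighbor structure.
- **`ssvep_rca.preprocess`** — zero-phase Butterworth bandpass (0.3–50 Hz),
  polyphase resampling (500→420 Hz), bad-sensor repair by 6-neighbor
  averaging, average re-reference, 1-s epoching with per-(epoch, sensor)
  rejection (10%/30 µV noise rule, 60 µV artifact rule).
- **`ssvep_rca.spectral`** — analysis-harmonic enumeration (base ladder;
  deviant ladder with optional exclusion of base multiples) and per-epoch
  complex coefficients (on-bin DFT; unit cosine → 1 + 0i; optional true RLS
  estimator behind the same interface).
- **`ssvep_rca.rca`** — Reliable Components Analysis: generalized
  eigendecomposition of across-trial vs within-trial covariance of stacked
  (re, im) coefficients, rank regularization, forward-model topographies,
  sign alignment, reliability-explained fractions, projection, joint
  multi-condition training.
- **`ssvep_rca.inferential`** — one-sample Hotelling T² of complex means
  against the origin, Benjamini–Hochberg FDR, standard-error ellipses,
  paired circular phase comparison, phase-difference → latency conversion.
- **`ssvep_rca.latency`** — group-delay estimation from the slope of phase
  vs frequency over significant harmonics (bounded 2π branch search
  preferring the smallest physical delay, OLS fit, slope standard error).
- **`ssvep_rca.pipeline`** — study orchestration (per-condition and joint
  analyses), CSV/JSON report tables, YAML configuration.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), independent oracles
(dense generalized eigensolver, brute-force FDR, Monte-Carlo calibrations)
and an end-to-end synthetic replica; the full run takes a few minutes.

## CLI

```bash
# simulate the default five-condition study into data/
ssvep-rca simulate --out data/ --seed 1 --n-subjects 4

# preprocess one condition to epoched HDF5
ssvep-rca preprocess --data data/ --condition cond1 --out cond1_epochs.h5

# run per-condition (and joint) analyses, write report tables
ssvep-rca analyze --data data/ --out results/ --seed 1 --joint

# summarize an existing report directory
ssvep-rca report --results results/
```

A custom study is a YAML file with `conditions` (name, `base_hz`,
`items_per_deviant`, `trial_duration_s`, `n_trials`), optional
`preprocessing` overrides, and top-level fields of
`ssvep_rca.pipeline.StudyConfig` (`n_subjects`, `n_sensors`, `seed`, …);
pass it via `--config study.yaml`.

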