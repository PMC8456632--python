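# thermokinesis

Bout-level analysis and stochastic simulation of larval zebrafish
exploratory locomotion under thermal modulation.

The package implements the full quantitative chain for 25-fps tracking
data of freely swimming larvae at bath temperatures of 18–33 °C:

- **Ingestion** of tracker-style delimited tables with ROI clipping and
  heading unwrapping (`tracking_io`).
- **Bout detection and kinematics** — speed-threshold detection with
  refractory and displacement filters, per-bout interbout interval /
  displacement / reorientation angle, the 1/1.6 turn-displacement
  correction, and wall-to-wall trajectory segmentation (`bout_pipeline`).
- **Forward/turn classification** from a Gaussian + gamma fit of the
  one-sided turn-angle distribution; the density crossing defines the
  0.17 rad (~10°) threshold (`bout_classification`).
- **Two-Markov-chain reorientation inference** — ternarized bouts, the
  conditional-mean slope estimator of the flipping probability
  (slope = p_turn(1 − 2 p_flip)), reconstruction of the hidden
  left/right telegraph state and its exp(−2 k t) ACF fit
  (`orientation_markov`).
- **Distribution statistics** — fixed-bandwidth KDEs, per-batch
  averaging, percentile bootstrap CIs, MSD/MSR (`exploration_stats`).
- **Behavioral manifold** — per-trajectory 5-parameter feature matrices,
  per-temperature / pooled / inter-temperature PCA with a deterministic
  sign convention, common 2-PC projections, intra-individual variance
  partitioning (`manifold_pca`).
- **Slow behavioral drift** — Ornstein–Uhlenbeck modelling of PC-score
  series, with the relaxation time fitted by matching finite-window
  simulated ACF ensembles (the sample ACF of short windows has a
  negative overshoot that a naive exponential fit gets wrong)
  (`ou_state`).
- **Navigation simulator** — every kinematic variable factorized as
  X = X̄_T · Y · ε (temperature mean × trajectory multiplier × per-bout
  multiplier) with Gaussian-copula-coupled trajectory multipliers;
  uniform-temperature bout sequences and agent-based simulations in
  linear thermal gradients with reflective walls, yielding thermophobic
  drift, occupancy profiles and t/L² settling-curve collapse
  (`nav_simulator`).
- **Fixture generator** — ground-truth bout sequences from the
  two-chain generator rendered into 25-fps frame tables, so every
  estimator can be validated against planted values (`synthetic_data`).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` carries the acceptance criteria (parameter
recovery at the printed presets, OU self-recovery, gradient kinesis,
analytic property suites); the remaining files are per-module unit and
property tests with independent oracles.

## CLI

```sh
thermokinesis render --preset 18C --n-fish 10 --minutes 30 --seed 1 --out out/render
thermokinesis detect --table out/render/frames.csv --temperature 18 --out out/bouts.tsv
thermokinesis classify --bouts out/bouts.tsv
thermokinesis markov --bouts out/bouts.tsv --out out/markov.tsv
thermokinesis stats --bouts out/bouts.tsv --out out/stats
thermokinesis pca --features features.tsv --out out/pca
thermokinesis ou-fit --projections projections.tsv --pc 1 --tau-min 2000 --tau-max 3000
thermokinesis simulate --mode gradient --pool-length 0.1 --n 500 --seed 42 --out out/grad
```

All inputs and outputs are plain delimited text.

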