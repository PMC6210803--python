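# kfgep

Reconstruction of 2-D drawing and handwriting traces from multichannel
surface-EMG (sEMG) amplitude features, using a hybrid decoder that places
symbolic observation models — evolved by gene expression programming (GEP) —
inside a Kalman filter (KF).

The package is aimed at muscle–computer-interface researchers who want a
fully inspectable, reproducible implementation of the KF-GEP decoding idea:
train on paired (pen trace, sEMG feature) trials, reconstruct unseen trials,
and compare the fused decoder against its KF-only and GEP-only baselines.

## The model

Pen coordinates are sampled every 50 ms and differenced into increments
Δ_t = (Δx_t, Δy_t), which form the filter state. Training fits:

* **State dynamics** — binary linear regression (no intercept) of each next
  increment on the current pair:

  Δx_{i+1} = a₁Δx_i + a₂Δy_i + u_i,  Δy_{i+1} = b₁Δx_i + b₂Δy_i + v_i,

  giving A = [[a₁,a₂],[b₁,b₂]] and process noise Q = cov(u, v).

* **Observation models** — two symbolic regressions GEP_X, GEP_Y mapping the
  7-channel RMS feature vector (T1…T7, one RMS value per channel per 50 ms
  adjacent window) to Δx and Δy. Models are multigenic Karva genomes
  (6 genes × 31 symbols, head 15) over the function set
  {+, −, ×, /, sin, cos, √, x², 1/x, eˣ}, evolved with the standard GEP
  operator suite. The observation noise covariance is R = cov(u′, v′) of the
  paired training residuals.

Reconstruction runs the Kalman recursion with C_t = (GEP_X(RMS_t),
GEP_Y(RMS_t)) as the observation — the measurement matrix is the identity
because the observation already lives in state space — and cumulatively sums
the filtered increments into coordinates. The GEP-only baseline sums the raw
symbolic predictions; the KF-only baseline uses a multivariate linear map
C_t = H·RMS_t in the same recursion.

Accuracy is the squared Pearson correlation R² between true and
reconstructed coordinate sequences, per trial and per coordinate; methods
are compared with one-sided paired Wilcoxon signed-rank tests over 70/30
trial splits.

Because no recordings are distributed with the study this package models, a
first-class synthetic module generates the full symbol inventory (14
one-stroke shapes + 10 digits) and simulates 7-channel feature streams
through a known nonlinear forward model, so every pipeline stage is testable
end to end.

## Worked example

```python
import numpy as np
from kfgep import (
    GepConfig, default_forward_model, generate_dataset,
    run_experiment,
)

dataset = generate_dataset(
    symbols=("fwd_slash", "backslash", "arch", "rev_arch", "triangle"),
    trials_per_symbol=40, n_points=16,
    forward_model=default_forward_model(), rng_seed=5,
)
report = run_experiment(dataset, design="within",
                        gep_config=GepConfig(), rng_seed=1, n_splits=4)
print(report.records.groupby("method")[["r2_x", "r2_y", "r2_avg"]].mean().round(3))
for name, res in report.comparisons.items():
    print(name, f"p = {res['p_value']:.3g}")
```

Output from this exact invocation:

```
         r2_x   r2_y  r2_avg
method
GEP     0.966  0.853   0.910
KF      0.780  0.455   0.617
KF-GEP  0.964  0.873   0.918
KF-GEP_vs_KF p = 3.77e-39
KF-GEP_vs_GEP p = 4.38e-06
```

Reading: the linear-observation KF struggles with the nonlinear
feature-to-velocity map (mean R² 0.62); the symbolic observation models
capture it (0.91); fusing them with the filter's dynamics prior smooths the
noisy symbolic predictions and is significantly more accurate than either
baseline (0.92, paired one-sided Wilcoxon p < 0.05 against both).

The same pipeline is scriptable from a shell:

```bash
kfgep simulate --seed 1 --symbols arch,circle --trials-per-symbol 10 --outdir data/
kfgep train --traces data/traces.csv --features data/features.csv --out model.json
kfgep reconstruct --model model.json --traces data/traces.csv \
      --features data/features.csv --out recon.csv
kfgep compare --traces data/traces.csv --features data/features.csv --design within
```

## Layout

```
src/kfgep/
  synthetic.py      symbol curves, forward model, dataset simulation
  preprocessing.py  onset detection, windowed RMS, delta coordinates
  gep/              the GEP engine (genomes, operators, evolution)
  state_model.py    BiLR dynamics fit + Kalman predict/update
  hybrid.py         training and the three reconstruction paths
  evaluation.py     R², splits, Wilcoxon, experiment driver
  io.py, cli.py     file formats, configuration, command line
docs/methods.md     modeling and numerical choices, in detail
```
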