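# cfentropy

Correlation fuzzy entropy (CFE) for multivariate time series: a complexity
measure that discriminates deterministic (chaotic) signals from stochastic
ones, is robust to additive observation noise, and yields compact feature
vectors for online-signature verification.

## Who this is for

Analysts of short multichannel recordings — physiological or behavioral
signals, pen trajectories, sensor streams — who need a per-series statistic
that separates signal classes without training data, and a reproducible
pipeline that turns it into a biometric verification experiment.

## The measure

For a series *X* with *n* time points and *d* channels:

1. z-score every channel, then reduce to the norm series
   `u_t = ||X_t||_2` (per-time-point Euclidean norm across channels);
2. form all `n − τ + 1` overlapping segments of length τ;
3. for every ordered pair of distinct segments take the sample covariance
   `Cov_ij` and map it to a fuzzy similarity

   `S_ij = exp(−ln2 · (|Cov_ij| / r)^m)`

   with fuzzy exponent `m = 2` and tolerance `r = 0.15` by default, so
   `S = 1` at zero covariance and `S = ½` exactly at `|Cov| = r`;
4. average: `φ(τ) = Σ_{i≠j} S_ij / ((n−τ+1)(n−τ))`;
5. the entropy is the log-ratio across scales:

   `CFE(X, τ) = ln φ(τ) − ln φ(τ+1)`.

A *CFE profile* evaluates this over a τ-grid (the application uses
τ = 13…20, giving an 8-dimensional feature vector per signature).
A correlation mode (Pearson form, dividing by segment standard deviations)
is available as an option; classical fuzzy entropy (Chebyshev distances,
baseline-removed embedding vectors) is included as a baseline.

## Worked example

```python
import numpy as np
from cfentropy import cfe_profile, gen_rossler, gen_wgn

noise = gen_wgn(400, d=2, seed=0)          # stochastic reference
chaos = gen_rossler(400, seed=0)           # Roessler flow, Δt = 1 sampling

for name, series in [("wgn", noise), ("rossler", chaos)]:
    prof = cfe_profile(series, tau_grid=range(13, 21))
    print(name, np.round(prof.values, 4))
```

Output:

```
wgn [-0.0169 -0.0156 -0.0143 -0.0126 -0.0112 -0.0106 -0.0098 -0.0091]
rossler [-0.0048 -0.007  -0.0097 -0.0093 -0.0081 -0.0061 -0.0061 -0.0059]
```

Both profiles drift toward 0 as τ grows, but the white-noise profile rises
monotonically while the chaotic one dips and recovers — with 30 independent
replications per class the per-τ means of the four canonical classes (white
noise, random walk, continuous and discrete chaos) separate pairwise at
several τ (Welch test p < 0.01).

The same machinery runs end to end from the command line:

```sh
cfentropy synth --users 10 --seed 1 -o cohort/          # synthetic writers
cfentropy verify --data-dir cohort/ --models tree,knn -o eval/
cfentropy simulate --experiment classes --reps 30 -o sim/
cfentropy compute mysignal.csv --tau-grid 13:21 -o out/
```

`verify` prints per-model mean FAR/FRR/EER (in percent) aggregated over
users, replications and folds of a stratified 5-fold cross validation.

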