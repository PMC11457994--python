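# Methods

## The statistic

CFE treats the covariance between overlapping segments of a series as a
distance and measures how fast pairwise segment similarity decays when the
segment length grows by one. For a d-channel series the chain is:
per-channel z-scoring (sample sd, ddof = 1), reduction to the per-time-point
Euclidean norm across channels, extraction of all `n − τ + 1` length-τ
windows at stride 1, the sample covariance (denominator τ − 1) of every
ordered pair of distinct windows, the membership map
`S = exp(−ln2 (|Cov|/r)^m)`, the pairwise mean φ(τ), and
`CFE = ln φ(τ) − ln φ(τ+1)`.

Conventions that were genuinely open and the choices made:

* **Pair range.** The double sum defining φ is averaged over *all* ordered
  pairs i ≠ j of the `n − τ + 1` segments and normalized by
  `(n − τ + 1)(n − τ)`. This symmetric convention matches the denominator
  product and makes φ independent of segment order.
* **Distance mode.** The default uses the raw covariance inside the
  membership function; a `correlation` mode divides by the two segment
  standard deviations (Pearson form) and treats a zero-variance segment as
  an error. In covariance mode a constant segment simply contributes
  Cov = 0 → S = 1.
* **Sign.** `|Cov|` is used inside the membership map. For the default
  m = 2 this is identical to squaring; for odd exponents it keeps S ≤ 1 and
  monotone in the covariance magnitude.
* **Standardization.** Channels are z-scored over the whole series before
  the norm reduction (`standardize=True` default), honouring the
  unit-variance assumption under which the tolerance r is meaningful. This
  makes CFE invariant to per-channel affine maps `a·x + b, a ≠ 0` and to
  channel permutation. A constant channel is an error naming the channel.
* **Semantics.** Larger covariance means *lower* similarity — covariance
  plays the role of a distance. The definition is implemented literally;
  note the consequence that a highly self-similar smooth series can carry
  *larger* segment covariances (hence lower φ) than noise after
  standardization.
* **Logs** are natural throughout.

Numerical notes: φ is a mean of values in (0, 1] so it cannot be negative;
with z-scored inputs and the default r = 0.15 it is comfortably inside the
representable range. The membership function itself underflows to exactly
0.0 when `ln2·(|Cov|/r)^m > ~709`; this is outside the regime reachable
from standardized data. Segment covariances are computed as one centered
matrix product per τ, so a length-400 series with the full τ-grid costs a
few milliseconds.

## Classical fuzzy entropy baseline

The baseline is the standard fuzzy-entropy construction: embedding vectors
of length m (default 2) with their own mean removed, Chebyshev distances,
membership `exp(−(d/r)^2)`, and the log-ratio of mean similarities at m and
m + 1, both averaged over the same `n − m` vectors. The tolerance is
interpreted in units of the series standard deviation — the (norm-reduced)
series is scaled to unit variance first, which is the conventional reading
of "r = 0.15". A constant series short-circuits to FE = 0.

## Simulators

* **WGN** — i.i.d. standard normal, default d = 2.
* **Random walk** — per-channel cumulative sum of N(0,1) steps; the first
  output value is the first step.
* **Roessler flow** — x' = −y − z, y' = x + a y, z' = b + z(x − c) with the
  canonical chaotic constants a = b = 0.2, c = 5.7, integrated with
  adaptive RK45 (rtol 1e−8), sampled at Δt = 1 after a 1000-unit transient;
  initial conditions uniform on [−1, 1]³ per replication.
* **Chirikov standard map** — p' = p + K sin x, x' = x + p' iterated
  exactly (it is a map, not a flow); kick strength K = 1.0 (above the
  chaotic threshold K_c ≈ 0.97), x reported mod 2π, initial conditions
  uniform on [0, 2π)².
* **VAR(1)** ("ARMA" reference) — x_t = c + A x_{t−1} + ε_t with
  c = [1, 1], A = [[0.2, −0.1], [−0.4, 0.3]],
  Σ = [[0.2, 0.3], [0.3, 0.7]] (positive definite; det = 0.05) and a
  200-step burn-in. User-supplied innovation covariances that fail PSD are
  projected onto the nearest PSD matrix with a warning.
* **Additive noise** — per-channel white Gaussian noise scaled so that
  `10·log10(var_signal/var_noise) = SNR dB` channel by channel (the
  per-channel reading of SNR; a total-power variant would differ only when
  channel variances are very unequal).

Replication seeding: a master seed plus a `(group, replication)` spawn key
feeds `numpy.random.SeedSequence`, so every realization is bit-reproducible
and extending the replication count preserves earlier draws.

Experiment scales follow the study protocol: series length N = 400, 30
replications per group, τ ∈ {11…20} for class discrimination (the analysis
window starts at 12 where separation first stabilizes) and τ ∈ {10…20} for
the noise experiment with SNR ∈ {10, 3, 1, 0.5} dB.

## Signature verification

Features are the CFE profile of the raw (x, y) locus at τ = 13…20 — the
per-channel standardization inside the profile makes them invariant to
tablet translation and axis scaling, so signatures are used at native
length with only a minimum-length guard. Pen-up points are retained by
default (`SignatureSample.pen_down_only()` filters them when wanted).

Datasets are per user. Single mode: N_G genuine positives vs N_F skilled
forgeries plus N_RU genuine signatures sampled without replacement from
other users. Pairs mode: all C(N_G, 2) genuine-genuine pairs as positives
and every genuine crossed with every negative-pool signature as negatives —
the only composition that yields 300/1250 rows at N = 25 and 190/800 at
N = 20. The pair feature is the concatenation of the elementwise mean and
elementwise absolute difference of the two 8-vectors (16-dim,
order-invariant); plain concatenation is available for comparison.

Models are a fixed roster behind a common fit/score contract: 1-NN, LDA,
QDA (reg 1e−3), logistic regression and RBF-SVM on standardized inputs,
Gaussian naive Bayes, and a fully grown small-leaf decision tree ("fine
tree"). Evaluation is stratified 5-fold cross validation replicated 10
times. FAR and FRR come from hard decisions (FAR is reported both against
all negatives and against forgery rows only, since the negative pool mixes
the two kinds); the EER comes from a full threshold sweep of the scores
with linear interpolation between the operating points bracketing the
FAR = FRR crossing (degenerate all-equal scores give 50%, perfect
separation 0%).

## Synthetic writers

Each writer is an ordered set of 10 random anchors in the unit square
(x-sorted to make strokes left-to-right), per-segment durations defining a
speed profile, and a writer-specific "habit": three sinusoids per axis with
frequencies in 4–12 cycles per signature and amplitude ≈ 0.015. A genuine
signature is the cubic spline through the anchors (jittered with sd 0.006),
plus the habit, plus i.i.d. device noise (sd 0.004). A forgery perturbs the
anchors with sd 0.02 — coarse shape survives — and replaces the habit with
freshly drawn generic oscillation parameters, destroying the fine dynamics.
These four amplitudes were chosen once so the cohort has the statistical
structure the verification analysis assumes: normalized genuine-forgery
pointwise shape distance stays below 0.2 while genuine-genuine CFE-feature
distances are several-fold smaller than genuine-forgery ones, putting the
tree-model EER mid-range (≈ 16–21% over master seeds) — informative rather
than saturated at 0 or chance.

What the generator does *not* emulate: pen-speed/pressure dynamics,
pen-lift segmentation, session-to-session drift, or the stroke statistics
of real handwriting. Passing the end-to-end tests shows the pipeline
(reading, features, dataset assembly, CV, metrics) carries discriminative
signal under the assumed genuine/forgery structure; it does not certify
error rates on real signature corpora.

## Problem sizes

The bundled experiments run the full protocol (N = 400, 30 replications,
30-writer cohort with 20 + 20 signatures each); the complete run of
`scripts/acceptance.py` is a few minutes on one CPU, dominated by the
Roessler integrations and the 1 200 feature extractions.

## Known limitations

* CFE values at these parameters are small in magnitude (|CFE| ≲ 0.03 for
  N = 400), so class separation rests on replication means, not single
  realizations.
* The correlation distance mode errors on zero-variance segments; series
  with long exactly-constant runs must use covariance mode.
* The equal-error rate of score sets from hard-voting classifiers (1-NN,
  pure-leaf trees) is coarse because scores take few distinct values; the
  interpolated crossing is still well defined.
* Verification metrics on the synthetic cohort are not comparable to
  published error rates on licensed signature corpora.
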