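"""Signal generators and the chaos-vs-stochastic discrimination experiments.

Five signal classes are generated: white Gaussian noise (WGN), Gaussian
random walk (RW), the Roessler flow sampled at unit time lag (continuous
chaos), the Chirikov standard map (discrete chaos), and a 2-D first-order
vector autoregression (VAR(1), the "ARMA" reference process of the noise
experiment).  Two experiment runners sweep CFE (optionally FE) over a grid
of segment lengths with independent replications:

* ``run_class_experiment`` — the four-class discrimination protocol
  (N = 400, tau in {11..20}, 30 replications by default);
* ``run_noise_experiment`` — VAR(1) vs clean Roessler vs Roessler mixed
  with additive Gaussian noise at SNR 10, 3, 1 and 0.5 dB.

All generators are pure functions of their arguments and a seed; a master
seed spawns per-(class, replication) child seeds via ``SeedSequence`` spawn
keys, so raising the replication count extends an experiment without
replaying earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .baselines import FEParams, fuzzy_entropy
from .core import CFEParams, SeriesLike, as_series_matrix, cfe_profile

__all__ = [
    "SimulationSpec",
    "simulate",
    "gen_wgn",
    "gen_random_walk",
    "gen_rossler",
    "gen_chirikov",
    "gen_arma2d",
    "add_noise_snr",
    "run_class_experiment",
    "run_noise_experiment",
    "class_experiment_values",
    "noise_experiment_values",
    "CLASS_GENERATORS",
]

SeedLike = "int | np.random.SeedSequence | np.random.Generator"

# Canonical chaotic Roessler constants; the kick strength K = 1.0 puts the
# standard map above its chaotic threshold K_c ~ 0.97.
ROSSLER_DEFAULTS = {"a": 0.2, "b": 0.2, "c": 5.7}
CHIRIKOV_DEFAULT_K = 1.0
ARMA2D_DEFAULTS = {
    "const": (1.0, 1.0),
    "coeffs": ((0.2, -0.1), (-0.4, 0.3)),
    "sigma": ((0.2, 0.3), (0.3, 0.7)),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Declarative description of one simulated series."""

    system: str
    n: int = 400
    d: int = 2
    seed: int = 0
    transient: int = 1000
    snr_db: float | None = None
    system_params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.system not in CLASS_GENERATORS:
            raise ValueError(
                f"unknown system {self.system!r}; choose from {sorted(CLASS_GENERATORS)}"
            )
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


def gen_wgn(n: int, d: int = 2, seed=0) -> np.ndarray:
    """White Gaussian noise: i.i.d. standard normal entries, shape (n, d)."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, d))


def gen_random_walk(n: int, d: int = 2, seed=0) -> np.ndarray:
    """Gaussian random walk: cumulative sum of N(0,1) steps per channel.

    The walk starts at its first increment (output[0] is the first step).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    return np.cumsum(rng.standard_normal((n, d)), axis=0)


def _rossler_rhs(t, state, a, b, c):
    x, y, z = state
    return (-y - z, x + a * y, b + z * (x - c))


def gen_rossler(
    n: int,
    seed=0,
    a: float = ROSSLER_DEFAULTS["a"],
    b: float = ROSSLER_DEFAULTS["b"],
    c: float = ROSSLER_DEFAULTS["c"],
    dt: float = 1.0,
    transient: int = 1000,
) -> np.ndarray:
    """Roessler flow sampled at time lag dt after discarding a transient.

    x' = -y - z, y' = x + a y, z' = b + z (x - c); adaptive Runge-Kutta 4(5)
    integration from an initial condition drawn uniformly from [-1, 1]^3.
    Returns a 3-channel series of shape (n, 3).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    ic = rng.uniform(-1.0, 1.0, size=3)
    t_eval = (transient + np.arange(n)) * dt
    sol = solve_ivp(
        _rossler_rhs,
        (0.0, float(t_eval[-1])),
        ic,
        method="RK45",
        t_eval=t_eval,
        args=(a, b, c),
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"Roessler integration failed: {sol.message}")
    return sol.y.T.copy()


def gen_chirikov(
    n: int,
    seed=0,
    K: float = CHIRIKOV_DEFAULT_K,
    p0: float | None = None,
    x0: float | None = None,
) -> np.ndarray:
    """Chirikov standard map iterated exactly: p' = p + K sin x, x' = x + p'.

    Returns a 2-channel (p, x) series with x taken mod 2*pi; initial
    conditions default to uniform draws on [0, 2*pi).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    two_pi = 2.0 * math.pi
    p = rng.uniform(0.0, two_pi) if p0 is None else float(p0)
    x = rng.uniform(0.0, two_pi) if x0 is None else float(x0)
    out = np.empty((n, 2))
    for i in range(n):
        p = p + K * math.sin(x)
        x = (x + p) % two_pi
        out[i, 0] = p
        out[i, 1] = x
    return out


def _nearest_psd(sigma: np.ndarray) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix onto the PSD cone (clip negative eigenvalues)."""
    sym = (sigma + sigma.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    if np.all(eigval >= 0):
        return sym, False
    clipped = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    return (clipped + clipped.T) / 2.0, True


def gen_arma2d(
    n: int,
    seed=0,
    const: Sequence[float] = ARMA2D_DEFAULTS["const"],
    coeffs: Sequence[Sequence[float]] = ARMA2D_DEFAULTS["coeffs"],
    sigma: Sequence[Sequence[float]] = ARMA2D_DEFAULTS["sigma"],
    burn_in: int = 200,
) -> np.ndarray:
    """First-order vector autoregression x_t = c + A x_{t-1} + e_t.

    Innovations are N(0, Sigma); a non-PSD Sigma is projected onto the
    nearest PSD matrix (negative eigenvalues clipped) before sampling, and
    refused if still invalid.  The burn-in is discarded so the output is
    approximately stationary (mean (I - A)^{-1} c when the spectral radius
    of A is below 1).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    c = np.asarray(const, dtype=float)
    A = np.asarray(coeffs, dtype=float)
    S = np.asarray(sigma, dtype=float)
    d = c.size
    if A.shape != (d, d) or S.shape != (d, d):
        raise ValueError("const, coeffs and sigma dimensions are inconsistent")
    S_psd, projected = _nearest_psd(S)
    if projected:
        import warnings

        warnings.warn(
            "innovation covariance was not PSD; projected onto the nearest "
            "PSD matrix",
            UserWarning,
            stacklevel=2,
        )
    eigval = np.linalg.eigvalsh(S_psd)
    if np.any(eigval < -1e-12):
        raise ValueError("innovation covariance is not PSD after projection")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    if np.allclose(S_psd, 0):
        eps = np.zeros((total, d))
    else:
        eps = rng.multivariate_normal(np.zeros(d), S_psd, size=total, method="eigh")
    out = np.empty((total, d))
    state = np.zeros(d)
    for t in range(total):
        state = c + A @ state + eps[t]
        out[t] = state
    return out[burn_in:]


def add_noise_snr(series: SeriesLike, snr_db: float, seed=0) -> np.ndarray:
    """Add independent Gaussian noise per channel at a fixed per-channel SNR.

    The noise variance of channel j is var(signal_j) / 10**(snr_db / 10),
    i.e. 10 log10(var_signal / var_noise) = snr_db for every channel.
    """
    arr = as_series_matrix(series)
    var = arr.var(axis=0, ddof=1)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ValueError(f"channel {int(bad[0])} has zero variance; SNR undefined")
    rng = np.random.default_rng(seed)
    noise_sd = np.sqrt(var / 10.0 ** (snr_db / 10.0))
    return arr + rng.standard_normal(arr.shape) * noise_sd


def _gen_from_spec(system: str, n: int, seed, d: int = 2, **params) -> np.ndarray:
    if system == "wgn":
        return gen_wgn(n, d=d, seed=seed, **params)
    if system == "random_walk":
        return gen_random_walk(n, d=d, seed=seed, **params)
    if system == "rossler":
        return gen_rossler(n, seed=seed, **params)
    if system == "chirikov":
        return gen_chirikov(n, seed=seed, **params)
    if system == "arma2d":
        return gen_arma2d(n, seed=seed, **params)
    raise ValueError(f"unknown system {system!r}")


CLASS_GENERATORS = ("wgn", "random_walk", "rossler", "chirikov", "arma2d")


def simulate(spec: SimulationSpec) -> np.ndarray:
    """Generate the series described by a :class:`SimulationSpec`."""
    params = dict(spec.system_params)
    if spec.system == "rossler":
        params.setdefault("transient", spec.transient)
    kwargs = {"d": spec.d} if spec.system in ("wgn", "random_walk") else {}
    seq = np.random.SeedSequence(spec.seed)
    gen_seed, noise_seed = seq.spawn(2)
    out = _gen_from_spec(spec.system, spec.n, gen_seed, **kwargs, **params)
    if spec.snr_db is not None:
        out = add_noise_snr(out, spec.snr_db, seed=noise_seed)
    return out


def _child_seed(master_seed: int, *key: int) -> np.random.SeedSequence:
    """Deterministic child seed for a (class, replication, ...) slot."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(key))


def _measure_profiles(
    series: np.ndarray,
    tau_grid: Sequence[int],
    measures: Sequence[str],
    params: CFEParams,
    fe_params: FEParams,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    if "cfe" in measures:
        out["cfe"] = cfe_profile(series, tau_grid, params).values
    if "fe" in measures:
        # FE's embedding dimension plays the role of the segment length.
        out["fe"] = np.array(
            [
                fuzzy_entropy(
                    series,
                    FEParams(m_embed=int(t), r=fe_params.r, n_fuzzy=fe_params.n_fuzzy),
                )
                for t in tau_grid
            ]
        )
    return out


def class_experiment_values(
    classes: Sequence[str] = ("wgn", "random_walk", "rossler", "chirikov"),
    tau_grid: Sequence[int] = tuple(range(11, 21)),
    reps: int = 30,
    n: int = 400,
    measures: Sequence[str] = ("cfe",),
    seed: int = 0,
    params: CFEParams | None = None,
    fe_params: FEParams | None = None,
) -> pd.DataFrame:
    """Per-replication measure values: tidy frame (class, rep, tau, measure, value)."""
    if reps < 1 or n < 50:
        raise ValueError("reps must be >= 1 and n >= 50")
    p = params or CFEParams()
    fep = fe_params or FEParams()
    tau_grid = [int(t) for t in tau_grid]
    rows = []
    for ci, cls in enumerate(classes):
        for rep in range(reps):
            series = _gen_from_spec(cls, n, _child_seed(seed, ci, rep))
            profiles = _measure_profiles(series, tau_grid, measures, p, fep)
            for measure, vals in profiles.items():
                for tau, val in zip(tau_grid, vals):
                    rows.append((cls, rep, tau, measure, float(val)))
    return pd.DataFrame(rows, columns=["class", "rep", "tau", "measure", "value"])


def _summarize(values: pd.DataFrame, group_col: str) -> pd.DataFrame:
    grouped = values.groupby([group_col, "tau", "measure"], sort=False)["value"]
    summary = grouped.agg(mean="mean", std="std", reps="count").reset_index()
    summary["std"] = summary["std"].fillna(0.0)  # single replication: std 0
    summary["reps"] = summary["reps"].astype(int)
    return summary


def run_class_experiment(
    classes: Sequence[str] = ("wgn", "random_walk", "rossler", "chirikov"),
    tau_grid: Sequence[int] = tuple(range(11, 21)),
    reps: int = 30,
    n: int = 400,
    measures: Sequence[str] = ("cfe",),
    seed: int = 0,
    params: CFEParams | None = None,
    fe_params: FEParams | None = None,
) -> pd.DataFrame:
    """Per-(class, tau, measure) mean/std of the measure over replications.

    Returns a tidy summary frame with columns
    ``class, tau, measure, mean, std, reps``.
    """
    values = class_experiment_values(
        classes, tau_grid, reps, n, measures, seed, params, fe_params
    )
    return _summarize(values, "class")


def noise_experiment_values(
    snr_list: Sequence[float] = (10.0, 3.0, 1.0, 0.5),
    tau_grid: Sequence[int] = tuple(range(10, 21)),
    reps: int = 30,
    n: int = 400,
    seed: int = 0,
    params: CFEParams | None = None,
) -> pd.DataFrame:
    """Per-replication CFE values for the noise-robustness layout.

    Groups: ``arma2d``, ``rossler`` (clean) and ``rossler_snr<level>`` for
    each SNR; the noisy groups share each replication's clean trajectory so
    the within-replication shift |CFE_noisy - CFE_clean| is meaningful.
    """
    p = params or CFEParams()
    tau_grid = [int(t) for t in tau_grid]
    rows = []
    for rep in range(reps):
        arma = gen_arma2d(n, seed=_child_seed(seed, 0, rep))
        clean = gen_rossler(n, seed=_child_seed(seed, 1, rep))
        series_by_group = {"arma2d": arma, "rossler": clean}
        for si, snr in enumerate(snr_list):
            noisy = add_noise_snr(clean, snr, seed=_child_seed(seed, 2 + si, rep))
            series_by_group[f"rossler_snr{snr:g}"] = noisy
        for group, series in series_by_group.items():
            vals = cfe_profile(series, tau_grid, p).values
            for tau, val in zip(tau_grid, vals):
                rows.append((group, rep, tau, "cfe", float(val)))
    return pd.DataFrame(rows, columns=["group", "rep", "tau", "measure", "value"])


def run_noise_experiment(
    snr_list: Sequence[float] = (10.0, 3.0, 1.0, 0.5),
    tau_grid: Sequence[int] = tuple(range(10, 21)),
    reps: int = 30,
    n: int = 400,
    seed: int = 0,
    params: CFEParams | None = None,
) -> pd.DataFrame:
    """Summary frame (group, tau, measure, mean, std, reps) for the
    VAR(1) / clean-chaos / noisy-chaos layout: len(snr_list) + 2 groups."""
    values = noise_experiment_values(snr_list, tau_grid, reps, n, seed, params)
    return _summarize(values, "group")
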