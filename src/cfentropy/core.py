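"""Correlation fuzzy entropy (CFE) of multivariate time series.

A d-channel series is reduced to a univariate *norm series* (per-time-point
Euclidean norm across channels), cut into overlapping segments of length
``tau``, and every ordered pair of segments is compared through the sample
covariance of their values.  The covariance acts as a distance: it is mapped
to a fuzzy similarity

    S_ij = exp(-ln 2 * (|Cov_ij| / r) ** m)

so that segments with zero covariance are maximally similar (S = 1) and
S = 1/2 exactly when the covariance equals the tolerance ``r``.  The global
statistic ``phi(tau)`` is the mean similarity over all ordered pairs of
distinct segments, and the correlation fuzzy entropy is

    CFE(X, tau) = ln phi(tau) - ln phi(tau + 1),

the rate at which pairwise segment similarity is lost when the segment
length grows by one.  Deterministic signals keep structured covariances
across scales; stochastic signals decorrelate, and the two classes separate
in CFE as a function of tau.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ConstantChannelError",
    "DegenerateSegmentError",
    "MTSeries",
    "CFEParams",
    "CFEProfile",
    "as_series_matrix",
    "standardize_channels",
    "channel_norm_series",
    "segments",
    "segment_covariance",
    "fuzzy_similarity",
    "phi_statistic",
    "cfe",
    "cfe_profile",
    "read_mtseries",
    "write_mtseries",
]

_LN2 = math.log(2.0)


class ConstantChannelError(ValueError):
    """A channel has zero standard deviation and cannot be standardized."""


class DegenerateSegmentError(ValueError):
    """A segment has zero variance in correlation mode (sigma = 0 division)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

SeriesLike = Union["MTSeries", np.ndarray, Sequence[Sequence[float]], Sequence[float]]


def as_series_matrix(series: SeriesLike) -> np.ndarray:
    """Coerce a series-like object to a validated float matrix (n, d).

    Accepts an :class:`MTSeries`, a DataFrame, or any array-like; 1-D input
    is treated as a single channel.  Requires n >= 2, d >= 1 and all entries
    finite.
    """
    values = getattr(series, "values", series)
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D (time x channel) array, got ndim={arr.ndim}")
    n, d = arr.shape
    if n < 2:
        raise ValueError(f"series must have at least 2 time points, got {n}")
    if d < 1:
        raise ValueError("series must have at least 1 channel")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite entries")
    return arr


@dataclass(frozen=True)
class MTSeries:
    """A multivariate time series: n time points (rows) x d channels (columns)."""

    values: np.ndarray
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = as_series_matrix(self.values)
        object.__setattr__(self, "values", arr)
        if self.channel_names is not None:
            names = tuple(str(c) for c in self.channel_names)
            if len(names) != arr.shape[1]:
                raise ValueError(
                    f"{len(names)} channel names for {arr.shape[1]} channels"
                )
            object.__setattr__(self, "channel_names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CFEParams:
    """Parameters of the CFE computation.

    m
        Fuzzy exponent of the membership function (default 2).
    r
        Tolerance; the covariance at which similarity is exactly 1/2
        for m = 2 (default 0.15).
    tau
        Optional segment length for single-tau use; sweeps pass tau
        explicitly.
    distance_mode
        ``"covariance"`` (default) uses the raw segment covariance inside
        the membership function; ``"correlation"`` divides by the segment
        standard deviations first (Pearson form).
    standardize
        Z-score every channel of the input series before the norm
        reduction (default True), honouring the unit-variance assumption
        of the membership scale.
    """

    m: float = 2.0
    r: float = 0.15
    tau: int | None = None
    distance_mode: str = "covariance"
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise ValueError(f"fuzzy exponent m must be > 0, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"tolerance r must be > 0, got {self.r}")
        if self.distance_mode not in ("covariance", "correlation"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        if self.tau is not None and self.tau < 2:
            raise ValueError(f"tau must be >= 2, got {self.tau}")


@dataclass(frozen=True)
class CFEProfile:
    """CFE evaluated over a grid of segment lengths.

    ``entries`` maps tau -> (phi_tau, phi_tau_plus_1, cfe) in the order the
    grid was given; ``cfe == ln(phi_tau) - ln(phi_tau_plus_1)`` for every
    entry.
    """

    taus: tuple[int, ...]
    phi_tau: tuple[float, ...]
    phi_tau_plus_1: tuple[float, ...]
    cfe: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.taus)
        if not (len(self.phi_tau) == len(self.phi_tau_plus_1) == len(self.cfe) == k):
            raise ValueError("profile columns must have equal length")

    def __len__(self) -> int:
        return len(self.taus)

    def __getitem__(self, tau: int) -> tuple[float, float, float]:
        i = self.taus.index(tau)
        return (self.phi_tau[i], self.phi_tau_plus_1[i], self.cfe[i])

    @property
    def values(self) -> np.ndarray:
        """CFE values as a vector, in grid order (the feature vector)."""
        return np.asarray(self.cfe, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": list(self.taus),
                "phi_tau": list(self.phi_tau),
                "phi_tau1": list(self.phi_tau_plus_1),
                "cfe": list(self.cfe),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "tau": list(self.taus),
                "phi_tau": list(self.phi_tau),
                "phi_tau1": list(self.phi_tau_plus_1),
                "cfe": list(self.cfe),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CFEProfile":
        return cls(
            taus=tuple(int(t) for t in frame["tau"]),
            phi_tau=tuple(float(v) for v in frame["phi_tau"]),
            phi_tau_plus_1=tuple(float(v) for v in frame["phi_tau1"]),
            cfe=tuple(float(v) for v in frame["cfe"]),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CFEProfile":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# computation chain
# ---------------------------------------------------------------------------


def standardize_channels(series: SeriesLike) -> np.ndarray | MTSeries:
    """Z-score every channel: output channels have mean 0 and sample sd 1.

    Raises :class:`ConstantChannelError` naming the first constant channel.
    Returns the same container kind it was given (MTSeries in, MTSeries out).
    """
    arr = as_series_matrix(series)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    # relative threshold: a channel of identical values can still carry
    # rounding noise of order eps * |mean|
    bad = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))
    if bad.size:
        raise ConstantChannelError(
            f"channel {int(bad[0])} is constant (zero standard deviation)"
        )
    out = (arr - mean) / sd
    if isinstance(series, MTSeries):
        return MTSeries(out, channel_names=series.channel_names)
    return out


def channel_norm_series(series: SeriesLike) -> np.ndarray:
    """Per-time-point Euclidean norm across channels (length-n vector)."""
    arr = as_series_matrix(series)
    return np.sqrt(np.einsum("ij,ij->i", arr, arr))


def segments(norms: np.ndarray, tau: int) -> np.ndarray:
    """All n - tau + 1 contiguous windows of length tau, stride 1, in order.

    Returns a read-only (n - tau + 1, tau) view of the input.
    """
    x = np.asarray(norms, dtype=float).ravel()
    n = x.size
    if not 1 <= tau <= n:
        raise ValueError(f"tau must satisfy 1 <= tau <= {n}, got {tau}")
    return sliding_window_view(x, tau)


def segment_covariance(u: np.ndarray, v: np.ndarray) -> float:
    """Sample covariance (denominator tau - 1) of two equal-length segments."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"segment length mismatch: {u.size} != {v.size}")
    if u.size < 2:
        raise ValueError("segments must have length >= 2")
    return float((u - u.mean()) @ (v - v.mean()) / (u.size - 1))


def fuzzy_similarity(cov, m: float = 2.0, r: float = 0.15):
    """Fuzzy membership exp(-ln2 * (|cov| / r) ** m), in (0, 1].

    Equals 1 iff cov = 0, 1/2 at |cov| = r (for m = 2), and decreases
    strictly in |cov|.  Vectorized over ``cov``.
    """
    if not r > 0:
        raise ValueError(f"tolerance r must be > 0, got {r}")
    if not m > 0:
        raise ValueError(f"fuzzy exponent m must be > 0, got {m}")
    out = np.exp(-_LN2 * (np.abs(cov) / r) ** m)
    if np.isscalar(cov) or np.ndim(cov) == 0:
        return float(out)
    return out


def _pairwise_distance_matrix(segs: np.ndarray, mode: str) -> np.ndarray:
    """Pairwise segment covariances (or Pearson correlations) as a matrix."""
    tau = segs.shape[1]
    centered = segs - segs.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (tau - 1)
    if mode == "correlation":
        var = np.diag(cov)
        bad = np.flatnonzero(var <= 0)
        if bad.size:
            raise DegenerateSegmentError(
                f"segment {int(bad[0])} has zero variance; "
                "correlation mode requires non-constant segments"
            )
        sd = np.sqrt(var)
        cov = cov / np.outer(sd, sd)
    elif mode != "covariance":
        raise ValueError(f"unknown distance_mode {mode!r}")
    return cov


def phi_statistic(
    norms: np.ndarray,
    tau: int,
    m: float = 2.0,
    r: float = 0.15,
    mode: str = "covariance",
) -> float:
    """Mean fuzzy similarity over all ordered pairs of distinct segments.

    phi(tau) = sum_{i != j} S_ij / ((N - tau + 1)(N - tau)) over the
    N - tau + 1 segments of length tau; always in (0, 1].
    """
    x = np.asarray(norms, dtype=float).ravel()
    n = x.size
    if not 2 <= tau <= n - 1:
        raise ValueError(
            f"tau must satisfy 2 <= tau <= n - 1 = {n - 1}, got {tau}"
        )
    segs = segments(x, tau)
    dist = _pairwise_distance_matrix(segs, mode)
    sim = fuzzy_similarity(dist, m=m, r=r)
    k = sim.shape[0]
    off_diag_sum = float(sim.sum() - np.trace(sim))
    return off_diag_sum / (k * (k - 1))


def cfe(series: SeriesLike, tau: int, params: CFEParams | None = None) -> float:
    """Correlation fuzzy entropy ln phi(tau) - ln phi(tau + 1) of a series."""
    p = params or CFEParams()
    arr = as_series_matrix(series)
    if tau + 1 > arr.shape[0] - 1:
        raise ValueError(
            f"need tau + 1 <= n - 1; got tau={tau} with n={arr.shape[0]}"
        )
    if p.standardize:
        arr = standardize_channels(arr)
    norms = channel_norm_series(arr)
    phi_t = phi_statistic(norms, tau, m=p.m, r=p.r, mode=p.distance_mode)
    phi_t1 = phi_statistic(norms, tau + 1, m=p.m, r=p.r, mode=p.distance_mode)
    return math.log(phi_t) - math.log(phi_t1)


def cfe_profile(
    series: SeriesLike,
    tau_grid: Iterable[int],
    params: CFEParams | None = None,
) -> CFEProfile:
    """CFE over a grid of segment lengths, sharing one standardization pass.

    phi values are cached so consecutive taus reuse phi(tau + 1).
    """
    p = params or CFEParams()
    grid = [int(t) for t in tau_grid]
    if not grid:
        raise ValueError("tau_grid is empty")
    arr = as_series_matrix(series)
    n = arr.shape[0]
    if max(grid) + 1 > n - 1:
        raise ValueError(
            f"need max(tau_grid) + 1 <= n - 1; got max tau {max(grid)} with n={n}"
        )
    if p.standardize:
        arr = standardize_channels(arr)
    norms = channel_norm_series(arr)

    phi_cache: dict[int, float] = {}

    def phi(t: int) -> float:
        if t not in phi_cache:
            phi_cache[t] = phi_statistic(norms, t, m=p.m, r=p.r, mode=p.distance_mode)
        return phi_cache[t]

    phis = [phi(t) for t in grid]
    phis1 = [phi(t + 1) for t in grid]
    values = [math.log(a) - math.log(b) for a, b in zip(phis, phis1)]
    return CFEProfile(
        taus=tuple(grid),
        phi_tau=tuple(phis),
        phi_tau_plus_1=tuple(phis1),
        cfe=tuple(values),
    )


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------


def read_mtseries(
    path: str | Path,
    sep: str | None = None,
    header: bool = True,
) -> MTSeries:
    """Read a delimited text file (rows = time points, columns = channels).

    ``sep=None`` sniffs the delimiter (csv/tsv/whitespace); ``header=False``
    reads files without a channel-name row.
    """
    if sep is None:
        frame = pd.read_csv(path, sep=None, engine="python", header=0 if header else None)
    else:
        frame = pd.read_csv(path, sep=sep, header=0 if header else None)
    names = tuple(str(c) for c in frame.columns) if header else None
    return MTSeries(frame.to_numpy(dtype=float), channel_names=names)


def write_mtseries(series: SeriesLike, path: str | Path, sep: str = ",") -> None:
    """Write a series as delimited text with a channel-name header row."""
    arr = as_series_matrix(series)
    names = getattr(series, "channel_names", None)
    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[1])]
    pd.DataFrame(arr, columns=list(names)).to_csv(path, sep=sep, index=False)
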