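"""Classical fuzzy entropy (FuzzyEn) as a comparison measure.

FuzzyEn replaces sample entropy's hard Heaviside match criterion with a
continuous membership function.  Embedding vectors of length ``m_embed`` are
formed from the (norm-reduced) series, each vector's own mean is removed
(baseline removal), distances are Chebyshev, and the similarity of a pair is
exp(-(d / r) ** n_fuzzy).  The entropy is ln phi(m) - ln phi(m + 1), with
phi the mean pairwise similarity.

The tolerance r is interpreted in units of the series standard deviation, as
is conventional: the norm-reduced series is scaled to unit variance before
distances are taken, so r = 0.15 means 0.15 standard deviations.  A constant
series has all distances zero, hence FE = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .core import SeriesLike, as_series_matrix, channel_norm_series

__all__ = ["FEParams", "fuzzy_entropy"]


@dataclass(frozen=True)
class FEParams:
    """Fuzzy-entropy parameters: embedding dimension, tolerance, exponent."""

    m_embed: int = 2
    r: float = 0.15
    n_fuzzy: float = 2.0

    def __post_init__(self) -> None:
        if self.m_embed < 1:
            raise ValueError(f"m_embed must be >= 1, got {self.m_embed}")
        if not self.r > 0:
            raise ValueError(f"tolerance r must be > 0, got {self.r}")
        if not self.n_fuzzy > 0:
            raise ValueError(f"fuzzy exponent must be > 0, got {self.n_fuzzy}")


def _phi_fe(u: np.ndarray, m: int, r: float, n_fuzzy: float, count: int) -> float:
    """Mean pairwise similarity of the first ``count`` baseline-removed
    m-length embedding vectors of u."""
    vectors = sliding_window_view(u, m)[:count]
    vectors = vectors - vectors.mean(axis=1, keepdims=True)
    dist = cdist(vectors, vectors, metric="chebyshev")
    sim = np.exp(-((dist / r) ** n_fuzzy))
    k = vectors.shape[0]
    return float((sim.sum() - np.trace(sim)) / (k * (k - 1)))


def fuzzy_entropy(series: SeriesLike, params: FEParams | None = None) -> float:
    """Classical fuzzy entropy of a (multivariate) series.

    A multivariate input is reduced to its channel-norm series first; the
    result is scaled to unit variance so that ``r`` is in SD units.  Both
    phi(m) and phi(m + 1) are averaged over the same n - m_embed vectors so
    the two scales are directly comparable.
    """
    p = params or FEParams()
    arr = as_series_matrix(series)
    u = channel_norm_series(arr) if arr.shape[1] > 1 else arr[:, 0].copy()
    n = u.size
    if n < p.m_embed + 2:
        raise ValueError(
            f"series length {n} too short for m_embed={p.m_embed} "
            f"(need at least {p.m_embed + 2})"
        )
    sd = u.std(ddof=1)
    if sd == 0:
        return 0.0  # all embedding vectors identical: phi(m) = phi(m+1) = 1
    u = u / sd
    count = n - p.m_embed
    if count < 2:
        raise ValueError("too few embedding vectors for a pairwise statistic")
    phi_m = _phi_fe(u, p.m_embed, p.r, p.n_fuzzy, count)
    phi_m1 = _phi_fe(u, p.m_embed + 1, p.r, p.n_fuzzy, count)
    return float(np.log(phi_m) - np.log(phi_m1))
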