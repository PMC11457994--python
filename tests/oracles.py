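"""Independent brute-force transcriptions used to cross-check the package.

Everything here is written as literal nested loops over the defining sums,
deliberately sharing no code with the production implementations.
"""

import math

import numpy as np
from scipy.spatial.distance import chebyshev


def naive_cfe(series, tau, m=2.0, r=0.15, mode="covariance", standardize=True):
    """Literal transcription of the CFE chain (norms, segments, covariance,
    fuzzy similarity, phi, log difference)."""
    x = np.array(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    n = x.shape[0]
    norms = [math.sqrt(sum(x[t, c] ** 2 for c in range(x.shape[1]))) for t in range(n)]

    def phi(t):
        segs = [norms[i : i + t] for i in range(n - t + 1)]
        total = 0.0
        count = 0
        for i in range(len(segs)):
            for j in range(len(segs)):
                if i == j:
                    continue
                u, v = segs[i], segs[j]
                mu_u = sum(u) / t
                mu_v = sum(v) / t
                cov = sum((a - mu_u) * (b - mu_v) for a, b in zip(u, v)) / (t - 1)
                if mode == "correlation":
                    su = math.sqrt(sum((a - mu_u) ** 2 for a in u) / (t - 1))
                    sv = math.sqrt(sum((b - mu_v) ** 2 for b in v) / (t - 1))
                    cov = cov / (su * sv)
                total += math.exp(-math.log(2.0) * (abs(cov) / r) ** m)
                count += 1
        return total / count

    return math.log(phi(tau)) - math.log(phi(tau + 1))


def naive_phi(norms, tau, m=2.0, r=0.15):
    """Double-loop phi statistic over all ordered pairs of segments."""
    norms = list(map(float, norms))
    n = len(norms)
    segs = [norms[i : i + tau] for i in range(n - tau + 1)]
    total = 0.0
    count = 0
    for i in range(len(segs)):
        for j in range(len(segs)):
            if i == j:
                continue
            u, v = segs[i], segs[j]
            mu_u = sum(u) / tau
            mu_v = sum(v) / tau
            cov = sum((a - mu_u) * (b - mu_v) for a, b in zip(u, v)) / (tau - 1)
            total += math.exp(-math.log(2.0) * (abs(cov) / r) ** m)
            count += 1
    return total / count


def naive_fuzzy_entropy(u, m_embed=2, r=0.15, n_fuzzy=2.0):
    """Brute-force classical fuzzy entropy of a univariate sequence.

    Mirrors the package convention: unit-variance scaling, baseline-removed
    embedding vectors, Chebyshev distance, n - m_embed vectors at both
    scales.
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    sd = u.std(ddof=1)
    if sd == 0:
        return 0.0
    u = u / sd
    count = n - m_embed

    def phi(m):
        vecs = []
        for i in range(count):
            w = u[i : i + m]
            vecs.append(w - w.mean())
        total = 0.0
        pairs = 0
        for i in range(count):
            for j in range(count):
                if i == j:
                    continue
                d = chebyshev(vecs[i], vecs[j])
                total += math.exp(-((d / r) ** n_fuzzy))
                pairs += 1
        return total / pairs

    return math.log(phi(m_embed)) - math.log(phi(m_embed + 1))


def exhaustive_eer(scores, labels):
    """EER (in %) by explicit counting at every candidate threshold.

    Thresholds are +inf and each distinct score (acceptance: score >= t);
    the crossing of the FAR and FRR step sequences is found by scanning and
    linearly interpolating between the bracketing operating points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    thresholds = [math.inf] + sorted(set(scores.tolist()), reverse=True)
    points = []
    for t in thresholds:
        far = 100.0 * sum(1 for s in neg if s >= t) / len(neg)
        frr = 100.0 * sum(1 for s in pos if s < t) / len(pos)
        points.append((far, frr))
    for k, (far, frr) in enumerate(points):
        if abs(far - frr) < 1e-12:
            return (far + frr) / 2.0
        if far > frr:
            far0, frr0 = points[k - 1]
            d0, d1 = far0 - frr0, far - frr
            alpha = d0 / (d0 - d1)
            return far0 + alpha * (far - far0)
    raise AssertionError("no FAR/FRR crossing found")
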