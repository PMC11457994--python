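"""Online-signature verification with CFE-profile features.

A signature is a 2-D pen trajectory (x, y over time).  Its feature vector is
the CFE profile of the z-scored locus over segment lengths tau = 13..20
(8 values).  Verification datasets are assembled per user in two modes:

* single mode — one row per signature: N_G genuine positives against
  N_F skilled forgeries plus N_RU genuine signatures randomly drawn from
  other users (the "random user" negatives);
* pairs mode — rows are signature pairs: all C(N_G, 2) genuine-genuine
  pairs are positives, and every genuine crossed with every negative-pool
  signature gives N_G * (N_RU + N_F) negatives.  With N_G = N_RU = N_F = 25
  this yields 300 positive and 1250 negative rows; with 20 each, 190 and
  800.

Models are evaluated per user by replicated stratified k-fold cross
validation; FAR/FRR come from hard decisions and the EER from a threshold
sweep over scores with linear interpolation at the FAR = FRR crossing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import CFEParams, cfe_profile

__all__ = [
    "SignatureSample",
    "VerificationDataset",
    "EERMetrics",
    "DEFAULT_TAU_GRID",
    "read_svc2004",
    "write_svc2004",
    "read_delimited",
    "extract_features",
    "build_single_dataset",
    "build_pairs_dataset",
    "default_models",
    "evaluate",
    "summarize_eval",
    "far_frr_eer",
]

DEFAULT_TAU_GRID: tuple[int, ...] = tuple(range(13, 21))

GENUINE = "genuine"
FORGERY = "forgery"


@dataclass
class SignatureSample:
    """One pen trajectory with its writer id and genuine/forgery label."""

    user_id: str
    label: str
    trajectory: np.ndarray  # (n, 2) x/y locus
    pressure: np.ndarray | None = None
    azimuth: np.ndarray | None = None
    altitude: np.ndarray | None = None
    timestamp: np.ndarray | None = None
    pen_status: np.ndarray | None = None

    def __post_init__(self) -> None:
        traj = np.asarray(self.trajectory, dtype=float)
        if traj.ndim != 2 or traj.shape[1] != 2:
            raise ValueError(f"trajectory must be (n, 2), got shape {traj.shape}")
        if traj.shape[0] < 2:
            raise ValueError(
                f"trajectory too short: {traj.shape[0]} points (need >= 2)"
            )
        if not np.all(np.isfinite(traj)):
            raise ValueError("trajectory contains non-finite coordinates")
        if self.label not in (GENUINE, FORGERY):
            raise ValueError(f"label must be 'genuine' or 'forgery', got {self.label!r}")
        self.trajectory = traj

    @property
    def n(self) -> int:
        return self.trajectory.shape[0]

    def pen_down_only(self) -> "SignatureSample":
        """Copy of the sample keeping only pen-down points (status != 0)."""
        if self.pen_status is None:
            return self
        mask = np.asarray(self.pen_status) != 0
        def pick(a):
            return None if a is None else np.asarray(a)[mask]
        return SignatureSample(
            user_id=self.user_id,
            label=self.label,
            trajectory=self.trajectory[mask],
            pressure=pick(self.pressure),
            azimuth=pick(self.azimuth),
            altitude=pick(self.altitude),
            timestamp=pick(self.timestamp),
            pen_status=pick(self.pen_status),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

# Column order of the SVC2004 plain-text dialect after X and Y.
_SVC_OPTIONAL = ("timestamp", "pen_status", "azimuth", "altitude", "pressure")


def read_svc2004(
    path: str | Path,
    user_id: str = "",
    label: str = GENUINE,
) -> SignatureSample:
    """Read a signature in the SVC2004 plain-text dialect.

    First line: point count.  Each following line: ``X Y timestamp
    pen-status [azimuth altitude pressure]`` whitespace-separated.  The
    count must match the number of point lines.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}:1: expected a point count, got {lines[0]!r}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least X Y, got {line!r}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed numeric field in {line!r}")
    if len(rows) != count:
        raise ValueError(
            f"{path}: header declares {count} points but {len(rows)} follow"
        )
    width = {len(r) for r in rows}
    if len(width) != 1:
        raise ValueError(f"{path}: inconsistent column counts {sorted(width)}")
    data = np.asarray(rows, dtype=float)
    extras: dict[str, np.ndarray] = {}
    for j, name in enumerate(_SVC_OPTIONAL, start=2):
        if data.shape[1] > j:
            extras[name] = data[:, j]
    return SignatureSample(
        user_id=user_id, label=label, trajectory=data[:, :2], **extras
    )


def write_svc2004(sample: SignatureSample, path: str | Path) -> None:
    """Write a sample in the SVC2004 plain-text dialect (full precision)."""
    cols = [sample.trajectory[:, 0], sample.trajectory[:, 1]]
    for name in _SVC_OPTIONAL:
        values = getattr(sample, name)
        if values is None:
            break
        cols.append(np.asarray(values, dtype=float))
    data = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write(f"{data.shape[0]}\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_delimited(
    path: str | Path,
    sep: str | None = None,
    x: str | int = "x",
    y: str | int = "y",
    header: bool = True,
    user_id: str = "",
    label: str = GENUINE,
) -> SignatureSample:
    """Read a signature from generic delimited text (CSV/TSV).

    ``x`` and ``y`` name the coordinate columns (by header name, or by
    integer index when ``header=False``).
    """
    path = Path(path)
    if sep is None:
        frame = pd.read_csv(path, sep=None, engine="python", header=0 if header else None)
    else:
        frame = pd.read_csv(path, sep=sep, header=0 if header else None)
    def col(key):
        if isinstance(key, int):
            if key >= frame.shape[1]:
                raise ValueError(f"{path}: no column index {key}")
            return frame.iloc[:, key]
        if key not in frame.columns:
            raise ValueError(f"{path}: missing column {key!r}")
        return frame[key]
    xs = pd.to_numeric(col(x), errors="coerce")
    ys = pd.to_numeric(col(y), errors="coerce")
    bad = np.flatnonzero(xs.isna() | ys.isna())
    if bad.size:
        raise ValueError(f"{path}: non-numeric coordinate at data row {int(bad[0])}")
    return SignatureSample(
        user_id=user_id, label=label,
        trajectory=np.column_stack([xs.to_numpy(float), ys.to_numpy(float)]),
    )


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def extract_features(
    sample: SignatureSample,
    tau_grid: Sequence[int] = DEFAULT_TAU_GRID,
    params: CFEParams | None = None,
) -> np.ndarray:
    """CFE profile of the z-scored (x, y) locus over tau_grid, in grid order.

    Translation and per-channel scaling of the trajectory leave the features
    unchanged (the profile standardizes channels first).
    """
    p = params or CFEParams()
    min_len = max(tau_grid) + 3
    if sample.n < min_len:
        raise ValueError(
            f"signature of {sample.n} points is too short; need at least "
            f"{min_len} for tau up to {max(tau_grid)}"
        )
    return cfe_profile(sample.trajectory, tau_grid, p).values


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VerificationDataset:
    """Feature rows and binary labels (1 = genuine claim) for one user."""

    mode: str  # "single" | "pairs"
    user_id: str
    features: np.ndarray  # (rows, dim)
    labels: np.ndarray  # (rows,) int, 1 positive / 0 negative
    counts: Mapping[str, int]  # provenance: n_genuine, n_random_user, n_forgery
    # per-row provenance: "genuine", "forgery" or "random_user" (negatives in
    # pairs mode are tagged by the partner's provenance)
    row_kind: np.ndarray | None = None

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())


def _features_of(pool: Sequence, tau_grid, params) -> list[np.ndarray]:
    out = []
    for item in pool:
        if isinstance(item, SignatureSample):
            out.append(extract_features(item, tau_grid, params))
        else:
            out.append(np.asarray(item, dtype=float).ravel())
    return out


def _sample_random_users(other_pool: Sequence, n_ru: int, seed) -> list:
    if len(other_pool) < n_ru:
        raise ValueError(
            f"other-user pool has {len(other_pool)} signatures, need {n_ru}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(other_pool), size=n_ru, replace=False)
    return [other_pool[i] for i in idx]


def build_single_dataset(
    user_id: str,
    genuine_pool: Sequence,
    forgery_pool: Sequence,
    other_users_pool: Sequence,
    n_genuine: int = 20,
    n_random_user: int = 20,
    n_forgery: int = 20,
    seed=0,
    tau_grid: Sequence[int] = DEFAULT_TAU_GRID,
    params: CFEParams | None = None,
) -> VerificationDataset:
    """Single-sample dataset: N_G genuine positives, N_F + N_RU negatives.

    Pools may hold :class:`SignatureSample` objects or precomputed feature
    vectors.  The N_RU random-user negatives are drawn without replacement
    from ``other_users_pool``, reproducibly per seed.
    """
    if len(genuine_pool) < n_genuine or len(forgery_pool) < n_forgery:
        raise ValueError("genuine or forgery pool smaller than requested counts")
    genuine = _features_of(genuine_pool[:n_genuine], tau_grid, params)
    forged = _features_of(forgery_pool[:n_forgery], tau_grid, params)
    random_users = _features_of(
        _sample_random_users(other_users_pool, n_random_user, seed), tau_grid, params
    )
    feats = np.vstack(genuine + forged + random_users)
    labels = np.concatenate(
        [np.ones(len(genuine), int), np.zeros(len(forged) + len(random_users), int)]
    )
    kinds = np.array(
        ["genuine"] * len(genuine)
        + ["forgery"] * len(forged)
        + ["random_user"] * len(random_users)
    )
    return VerificationDataset(
        mode="single",
        user_id=user_id,
        features=feats,
        labels=labels,
        counts={
            "n_genuine": n_genuine,
            "n_random_user": n_random_user,
            "n_forgery": n_forgery,
        },
        row_kind=kinds,
    )


def pair_feature(a: np.ndarray, b: np.ndarray, scheme: str = "mean_absdiff") -> np.ndarray:
    """Order-invariant combination of two per-signature feature vectors.

    ``mean_absdiff`` (default): concat of elementwise mean and elementwise
    absolute difference (2 * dim values).  ``concat``: plain concatenation
    in the given order (not symmetric; provided for comparison).
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if scheme == "mean_absdiff":
        return np.concatenate([(a + b) / 2.0, np.abs(a - b)])
    if scheme == "concat":
        return np.concatenate([a, b])
    raise ValueError(f"unknown pair scheme {scheme!r}")


def build_pairs_dataset(
    user_id: str,
    genuine_pool: Sequence,
    forgery_pool: Sequence,
    other_users_pool: Sequence,
    n_genuine: int = 20,
    n_random_user: int = 20,
    n_forgery: int = 20,
    seed=0,
    tau_grid: Sequence[int] = DEFAULT_TAU_GRID,
    params: CFEParams | None = None,
    scheme: str = "mean_absdiff",
) -> VerificationDataset:
    """Pairs dataset: C(N_G, 2) genuine-genuine positives and
    N_G * (N_RU + N_F) genuine-vs-negative rows.

    With N_G = N_RU = N_F = 25 this gives 300 positives and 1250 negatives;
    with 20 each, 190 and 800.
    """
    if len(genuine_pool) < n_genuine or len(forgery_pool) < n_forgery:
        raise ValueError("genuine or forgery pool smaller than requested counts")
    genuine = _features_of(genuine_pool[:n_genuine], tau_grid, params)
    forged = _features_of(forgery_pool[:n_forgery], tau_grid, params)
    random_users = _features_of(
        _sample_random_users(other_users_pool, n_random_user, seed), tau_grid, params
    )
    negatives = forged + random_users
    neg_kinds = ["forgery"] * len(forged) + ["random_user"] * len(random_users)
    pos_rows = [
        pair_feature(a, b, scheme) for a, b in itertools.combinations(genuine, 2)
    ]
    neg_rows = [pair_feature(g, v, scheme) for g in genuine for v in negatives]
    feats = np.vstack(pos_rows + neg_rows)
    labels = np.concatenate([np.ones(len(pos_rows), int), np.zeros(len(neg_rows), int)])
    kinds = np.array(["genuine"] * len(pos_rows) + neg_kinds * n_genuine)
    return VerificationDataset(
        mode="pairs",
        user_id=user_id,
        features=feats,
        labels=labels,
        counts={
            "n_genuine": n_genuine,
            "n_random_user": n_random_user,
            "n_forgery": n_forgery,
        },
        row_kind=kinds,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EERMetrics:
    """Threshold sweep of a score set (higher score = more genuine)."""

    thresholds: np.ndarray
    far: np.ndarray  # % of negatives accepted at each threshold
    frr: np.ndarray  # % of positives rejected at each threshold
    eer: float  # % at the interpolated FAR = FRR crossing


def far_frr_eer(scores: np.ndarray, labels: np.ndarray) -> EERMetrics:
    """FAR/FRR curves over all decision thresholds and the interpolated EER.

    Acceptance rule: claim is accepted when score >= threshold.  Operating
    points are evaluated at +inf and at every distinct score; the EER is the
    common value at the exact FAR = FRR point when one exists, otherwise by
    linear interpolation between the two adjacent operating points where
    FAR - FRR changes sign.  All rates are percentages.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute FAR/FRR")

    uniq = np.unique(scores)[::-1]  # descending
    thresholds = np.concatenate([[np.inf], uniq])
    # accepted when score >= t
    pos_scores = np.sort(scores[labels == 1])
    neg_scores = np.sort(scores[labels == 0])
    far = np.empty(thresholds.size)
    frr = np.empty(thresholds.size)
    for k, t in enumerate(thresholds):
        far[k] = 100.0 * (n_neg - np.searchsorted(neg_scores, t, side="left")) / n_neg
        frr[k] = 100.0 * np.searchsorted(pos_scores, t, side="left") / n_pos

    diff = far - frr  # monotone: -100 at +inf, +... at min score
    zero = np.flatnonzero(np.isclose(diff, 0.0, atol=1e-12))
    if zero.size:
        k = zero[0]
        eer = (far[k] + frr[k]) / 2.0
    else:
        k = int(np.flatnonzero(diff > 0)[0])  # first sign change
        d0, d1 = diff[k - 1], diff[k]
        alpha = d0 / (d0 - d1)
        eer = far[k - 1] + alpha * (far[k] - far[k - 1])
    return EERMetrics(thresholds=thresholds, far=far, frr=frr, eer=float(eer))


# ---------------------------------------------------------------------------
# models & evaluation
# ---------------------------------------------------------------------------


def default_models(seed: int = 0) -> dict:
    """Roster of verification classifiers under a common fit/score contract.

    knn (k=1), linear and quadratic discriminants, logistic regression,
    Gaussian naive Bayes, RBF SVM on standardized inputs, and a small-leaf
    decision tree ("fine tree").
    """
    return {
        "knn": KNeighborsClassifier(n_neighbors=1),
        "lda": LinearDiscriminantAnalysis(),
        "qda": QuadraticDiscriminantAnalysis(reg_param=1e-3),
        "logreg": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        ),
        "naive_bayes": GaussianNB(),
        "svm": make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed)),
        "tree": DecisionTreeClassifier(min_samples_leaf=1, random_state=seed),
    }


def _score_samples(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, list(est.classes_).index(1)]
    return est.decision_function(X)


def evaluate(
    dataset: VerificationDataset,
    models: Mapping[str, object] | None = None,
    folds: int = 5,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated stratified k-fold CV of each model on one user's dataset.

    Returns a tidy frame (model, rep, fold, far, far_forgery, frr, eer) with
    rates in percent: FAR/FRR from hard decisions on the held-out fold, EER
    from the score sweep.  ``far`` counts all accepted negatives (forgeries
    plus random-user genuines); ``far_forgery`` restricts the denominator to
    forgery rows (NaN when the fold holds none).
    """
    X, y = dataset.features, dataset.labels
    if np.unique(y).size < 2:
        raise ValueError("dataset must contain both classes")
    kind = (
        dataset.row_kind
        if dataset.row_kind is not None
        else np.where(y == 1, "genuine", "forgery")
    )
    models = dict(models) if models is not None else default_models(seed)
    root = np.random.SeedSequence(entropy=int(seed), spawn_key=(101,))
    rows = []
    for rep in range(reps):
        rs = int(root.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        for fold, (train, test) in enumerate(skf.split(X, y)):
            if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
                raise ValueError(f"fold {fold} lost a class; check stratification")
            for name, proto in models.items():
                est = clone(proto)
                est.fit(X[train], y[train])
                pred = est.predict(X[test])
                yt = y[test]
                kt = kind[test]
                neg = yt == 0
                forg = neg & (kt == "forgery")
                far = 100.0 * ((pred == 1) & neg).sum() / neg.sum()
                far_forgery = (
                    100.0 * ((pred == 1) & forg).sum() / forg.sum()
                    if forg.any()
                    else math.nan
                )
                frr = 100.0 * ((pred == 0) & (yt == 1)).sum() / (yt == 1).sum()
                eer = far_frr_eer(_score_samples(est, X[test]), yt).eer
                rows.append((name, rep, fold, far, far_forgery, frr, eer))
    return pd.DataFrame(
        rows, columns=["model", "rep", "fold", "far", "far_forgery", "frr", "eer"]
    )


def summarize_eval(result: pd.DataFrame) -> pd.DataFrame:
    """Mean FAR/FRR/EER per model over all replications and folds."""
    cols = [c for c in ("far", "far_forgery", "frr", "eer") if c in result.columns]
    return result.groupby("model", sort=False)[cols].mean().reset_index()
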