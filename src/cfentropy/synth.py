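"""Synthetic per-writer pen-trajectory cohorts for the verification pipeline.

Each writer is a smooth stroke model: an ordered polygon of control anchors
in the unit square, per-segment durations (the speed profile), and a
writer-specific low-amplitude oscillation — the "habit" — superimposed on
the stroke.  A genuine signature interpolates the writer's anchors with a
cubic spline (small per-signature anchor jitter), adds the writer's habit
oscillation, and i.i.d. Gaussian device noise.  A forgery reproduces the
coarse shape from a perturbed copy of the anchors but replaces the habit
with generic oscillation parameters of its own: the shape survives, the
fine dynamics do not, which is exactly the structure the verification task
assumes.

This is a test fixture emulating genuine/forgery statistics, not a model of
handwriting kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .signatures import FORGERY, GENUINE, SignatureSample, write_svc2004

__all__ = [
    "WriterModel",
    "gen_writer",
    "gen_signature",
    "gen_cohort",
    "write_cohort",
    "DEFAULT_NOISE_SD",
    "DEFAULT_FORGERY_ANCHOR_SD",
]

# Defaults (unit-square coordinates).  Genuine jitter / forgery perturbation /
# habit amplitude / device noise are sized so that genuine-genuine feature
# distances sit clearly below genuine-forgery distances without being
# trivially separable.
DEFAULT_N_ANCHORS = 10
DEFAULT_HABIT_HARMONICS = 3
DEFAULT_HABIT_AMP = 0.015
DEFAULT_HABIT_FREQ_RANGE = (4.0, 12.0)
DEFAULT_GENUINE_ANCHOR_SD = 0.006
DEFAULT_FORGERY_ANCHOR_SD = 0.02
DEFAULT_NOISE_SD = 0.004


@dataclass(frozen=True)
class WriterModel:
    """A writer: control anchors, speed profile and habit oscillation."""

    control_points: np.ndarray  # (k, 2), unit square
    durations: np.ndarray  # (k - 1,), positive per-segment durations
    habit_freqs: np.ndarray  # (2, H) cycles per signature, per axis
    habit_amps: np.ndarray  # (2, H)
    habit_phases: np.ndarray  # (2, H)
    seed: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        if pts.shape[0] < 4:
            raise ValueError("writer needs at least 4 control points")
        if np.any(np.asarray(self.durations) <= 0):
            raise ValueError("durations must be positive")
        object.__setattr__(self, "control_points", pts)


def gen_writer(
    seed: int,
    n_anchors: int = DEFAULT_N_ANCHORS,
    habit_amp: float = DEFAULT_HABIT_AMP,
) -> WriterModel:
    """Draw a reproducible writer model from a seed."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(7,)))
    pts = rng.uniform(0.05, 0.95, size=(n_anchors, 2))
    # left-to-right drift makes strokes signature-like rather than scribbles
    pts[:, 0] = np.sort(pts[:, 0])
    durations = rng.uniform(0.5, 1.5, size=n_anchors - 1)
    lo, hi = DEFAULT_HABIT_FREQ_RANGE
    freqs = rng.uniform(lo, hi, size=(2, DEFAULT_HABIT_HARMONICS))
    amps = habit_amp * rng.uniform(0.5, 1.0, size=(2, DEFAULT_HABIT_HARMONICS))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(2, DEFAULT_HABIT_HARMONICS))
    return WriterModel(
        control_points=pts,
        durations=durations,
        habit_freqs=freqs,
        habit_amps=amps,
        habit_phases=phases,
        seed=int(seed),
    )


def _oscillation(t: np.ndarray, freqs, amps, phases) -> np.ndarray:
    """(n, 2) habit oscillation sampled on normalized time t in [0, 1]."""
    out = np.zeros((t.size, 2))
    for axis in range(2):
        phase_arg = 2.0 * np.pi * np.outer(t, freqs[axis]) + phases[axis]
        out[:, axis] = (np.sin(phase_arg) * amps[axis]).sum(axis=1)
    return out


def gen_signature(
    writer: WriterModel,
    kind: str = GENUINE,
    noise_sd: float = DEFAULT_NOISE_SD,
    length: int = 400,
    seed: int = 0,
    forgery_anchor_sd: float = DEFAULT_FORGERY_ANCHOR_SD,
    genuine_anchor_sd: float = DEFAULT_GENUINE_ANCHOR_SD,
) -> SignatureSample:
    """One signature from a writer model.

    Genuine: the writer's anchors (small jitter), the writer's habit
    oscillation, device noise.  Forgery: anchors perturbed with
    ``forgery_anchor_sd`` and a freshly drawn generic oscillation of the
    same amplitude scale in place of the habit.
    """
    if kind not in (GENUINE, FORGERY):
        raise ValueError(f"kind must be 'genuine' or 'forgery', got {kind!r}")
    if length < 100:
        raise ValueError(f"length must be >= 100, got {length}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(writer.seed % (2**31), 11))
    )
    anchor_sd = genuine_anchor_sd if kind == GENUINE else forgery_anchor_sd
    anchors = writer.control_points + rng.normal(0.0, anchor_sd, writer.control_points.shape)
    knots = np.concatenate([[0.0], np.cumsum(writer.durations)])
    knots = knots / knots[-1]
    spline = CubicSpline(knots, anchors, axis=0)
    t = np.linspace(0.0, 1.0, length)
    locus = spline(t)
    if kind == GENUINE:
        habit = _oscillation(t, writer.habit_freqs, writer.habit_amps, writer.habit_phases)
    else:
        lo, hi = DEFAULT_HABIT_FREQ_RANGE
        freqs = rng.uniform(lo, hi, size=writer.habit_freqs.shape)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=writer.habit_phases.shape)
        habit = _oscillation(t, freqs, writer.habit_amps, phases)
    locus = locus + habit + rng.normal(0.0, noise_sd, (length, 2))
    timestamps = np.arange(length, dtype=float) * 10.0  # 100 Hz tablet clock
    pen_status = np.ones(length)
    return SignatureSample(
        user_id=f"w{writer.seed:04d}",
        label=kind,
        trajectory=locus,
        timestamp=timestamps,
        pen_status=pen_status,
    )


def gen_cohort(
    n_users: int = 40,
    n_genuine: int = 20,
    n_forgery: int = 20,
    seed: int = 0,
    length: int = 400,
    noise_sd: float = DEFAULT_NOISE_SD,
    forgery_anchor_sd: float = DEFAULT_FORGERY_ANCHOR_SD,
) -> list[SignatureSample]:
    """A labeled multi-writer cohort, reproducible from the master seed.

    Returns n_users * (n_genuine + n_forgery) samples; user ids are
    ``u000``, ``u001``, ...  The default (40, 20, 20) layout mirrors a
    1600-signature collection of 40 writers.
    """
    if min(n_users, n_genuine, n_forgery) < 1:
        raise ValueError("all cohort counts must be >= 1")
    root = np.random.SeedSequence(entropy=int(seed))
    samples: list[SignatureSample] = []
    for u in range(n_users):
        writer_seed = int(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(u,)).generate_state(1)[0]
            % (2**31)
        )
        writer = gen_writer(writer_seed)
        for g in range(n_genuine):
            sig_seed = int(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(u, 0, g)).generate_state(1)[0]
                % (2**31)
            )
            sig = gen_signature(
                writer, GENUINE, noise_sd=noise_sd, length=length, seed=sig_seed
            )
            sig.user_id = f"u{u:03d}"
            samples.append(sig)
        for f in range(n_forgery):
            sig_seed = int(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(u, 1, f)).generate_state(1)[0]
                % (2**31)
            )
            sig = gen_signature(
                writer,
                FORGERY,
                noise_sd=noise_sd,
                length=length,
                seed=sig_seed,
                forgery_anchor_sd=forgery_anchor_sd,
            )
            sig.user_id = f"u{u:03d}"
            samples.append(sig)
    return samples


def write_cohort(samples, out_dir, fmt: str = "svc") -> list[str]:
    """Serialize a cohort; one file per signature, named
    ``<user>_<label><index>.<ext>``.  Returns the written paths."""
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counters: dict[tuple[str, str], int] = {}
    paths = []
    for s in samples:
        k = (s.user_id, s.label)
        counters[k] = counters.get(k, 0) + 1
        stem = f"{s.user_id}_{s.label}{counters[k]:03d}"
        if fmt == "svc":
            path = out / f"{stem}.txt"
            write_svc2004(s, path)
        elif fmt == "csv":
            path = out / f"{stem}.csv"
            pd.DataFrame(s.trajectory, columns=["x", "y"]).to_csv(path, index=False)
        else:
            raise ValueError(f"unknown cohort format {fmt!r}")
        paths.append(str(path))
    return paths
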