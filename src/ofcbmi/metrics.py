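"""Performance metrics for decoder comparison.

Acquisition accuracy, trajectory RMS error, decoding SNR, the
roughness coefficient (normalized first-difference energy; smaller is
smoother), pairwise correction rates, and session summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import TrialOutcome

__all__ = [
    "acquisition_accuracy",
    "rms_error",
    "snr",
    "roughness",
    "correction_rate",
    "SessionSummary",
    "summarize_session",
]


def acquisition_accuracy(outcomes: Sequence[TrialOutcome]) -> float:
    """Percent of trials on which the task was successfully completed."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes supplied")
    return 100.0 * sum(o.success for o in outcomes) / len(outcomes)


def _pos(traj: np.ndarray) -> np.ndarray:
    traj = np.asarray(traj, dtype=float)
    return traj[:, :2] if traj.ndim == 2 else traj


def rms_error(est: np.ndarray, truth: np.ndarray) -> float:
    """Root mean square Euclidean position error across bins."""
    est, truth = _pos(est), _pos(truth)
    if est.shape != truth.shape:
        raise ValueError("trajectories must have matching shapes")
    return float(np.sqrt(np.mean(np.sum((est - truth) ** 2, axis=1))))


def snr(est: np.ndarray, truth: np.ndarray) -> float:
    """Signal-to-noise ratio: true-signal variance over MSE.

    Computed per dimension then averaged.  A perfect estimate yields
    ``inf``; an estimate pinned at the signal mean yields exactly 1.
    """
    est, truth = _pos(est), _pos(truth)
    if est.shape != truth.shape:
        raise ValueError("trajectories must have matching shapes")
    var = truth.var(axis=0)
    mse = np.mean((est - truth) ** 2, axis=0)
    with np.errstate(divide="ignore"):
        ratio = np.where(mse == 0, np.inf, var / np.where(mse == 0, 1.0, mse))
    return float(np.mean(ratio))


def roughness(traj: np.ndarray) -> float:
    """Roughness coefficient of a position trajectory.

    For a vector sequence x_1..x_n this is the first-difference energy
    over the centered energy,

        sum_t ||x_t - x_{t-1}||^2 / sum_t ||x_t - x_bar||^2.

    Smoother trajectories score lower.  Constant trajectories have an
    undefined coefficient, returned as ``nan``.
    """
    x = _pos(traj)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 bins")
    num = float(np.sum(np.diff(x, axis=0) ** 2))
    den = float(np.sum((x - x.mean(axis=0)) ** 2))
    if den == 0:
        return float("nan")
    return num / den


def correction_rate(
    outcomes_a: Sequence[TrialOutcome], outcomes_b: Sequence[TrialOutcome]
) -> float:
    """Percent of A's failed trials that decoder B completed correctly.

    Asymmetric by construction.  Undefined (``nan``) when A has no
    failed trials.
    """
    outcomes_a, outcomes_b = list(outcomes_a), list(outcomes_b)
    if len(outcomes_a) != len(outcomes_b):
        raise ValueError("outcome lists must cover the same trials")
    a_wrong = [i for i, o in enumerate(outcomes_a) if not o.success]
    if not a_wrong:
        return float("nan")
    fixed = sum(outcomes_b[i].success for i in a_wrong)
    return 100.0 * fixed / len(a_wrong)


@dataclass(frozen=True)
class SessionSummary:
    accuracy_pct: float
    rms_error: Optional[float]
    snr: Optional[float]
    roughness: Optional[float]
    median_acquisition_s: Optional[float]
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy_pct <= 100:
            raise ValueError("accuracy out of range")


def summarize_session(
    outcomes: Sequence[TrialOutcome],
    est_trajectories: Sequence[np.ndarray] | None = None,
    true_trajectories: Sequence[np.ndarray] | None = None,
) -> SessionSummary:
    """Aggregate per-trial outcomes (and optionally trajectories)."""
    outcomes = list(outcomes)
    table = pd.DataFrame(
        {
            "success": [o.success for o in outcomes],
            "cause": [o.cause for o in outcomes],
            "first_target_hit": [o.first_target_hit for o in outcomes],
            "acquisition_time_ms": [o.acquisition_time_ms for o in outcomes],
        }
    )
    acq = table.loc[table.success, "acquisition_time_ms"].dropna()
    med = float(acq.median()) / 1000.0 if len(acq) else None
    rms_val = snr_val = rough_val = None
    if est_trajectories is not None:
        rough_val = float(np.mean([roughness(t) for t in est_trajectories]))
        if true_trajectories is not None:
            pairs = [
                (e[: len(t)], t[: len(e)])
                for e, t in zip(est_trajectories, true_trajectories)
            ]
            rms_val = float(np.mean([rms_error(e, t) for e, t in pairs]))
            snr_val = float(np.mean([snr(e, t) for e, t in pairs]))
    return SessionSummary(
        accuracy_pct=acquisition_accuracy(outcomes),
        rms_error=rms_val,
        snr=snr_val,
        roughness=rough_val,
        median_acquisition_s=med,
        outcomes=table,
    )
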