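"""Ridge-regression trajectory decoding baseline.

Position at each 5 ms step is reconstructed as a linear combination of
the history of standardized ensemble firing rates, computed in sliding
(trailing) 100 ms windows.  Coefficients per output dimension solve

    f = (R'R + delta I)^{-1} R' q

where R stacks the lagged standardized rates and q is the
mean-subtracted position.  delta = 0 recovers ordinary least squares.
History length and delta are selected by leave-one-trial-out
cross-validated mean-square error.  Shuffling each neuron's rates
across time and trials (preserving its rate distribution) provides the
chance-level control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RateMatrix",
    "RidgeFit",
    "sliding_rates",
    "standardize_rates",
    "lagged_design",
    "fit_ridge",
    "select_model",
    "shuffle_rates",
    "predict_position",
]

DEFAULT_HISTORIES_MS = (200, 400, 600, 800)


def sliding_rates(
    spikes: np.ndarray, window_ms: int = 100, step_ms: int = 5
) -> np.ndarray:
    """Trailing-window firing rates, spikes/s, one row per 5 ms step.

    At step t the rate is the spike count in the window of bins
    (t - K + 1 .. t) divided by the window duration, with K =
    window_ms / step_ms.  Leading steps, where the trailing window
    would extend before the trial, use the truncated window's own
    duration as the normalizer, so an early steady train still reads
    as its true rate.
    """
    if window_ms % step_ms != 0:
        raise ValueError("window must be a multiple of the step")
    spikes = np.asarray(spikes, dtype=float)
    K = window_ms // step_ms
    csum = np.cumsum(spikes, axis=1)
    n_bins = spikes.shape[1]
    counts = csum.copy()
    if n_bins > K:
        counts[:, K:] = csum[:, K:] - csum[:, :-K]
    durations = np.minimum(np.arange(1, n_bins + 1), K) * (step_ms / 1000.0)
    return (counts / durations[None, :]).T  # (n_steps, n_neurons)


@dataclass(frozen=True)
class RateMatrix:
    """Standardized rates with the training moments kept for reuse."""

    values: np.ndarray  # (n_steps, n_neurons), standardized
    mean: np.ndarray  # per-neuron training mean, spikes/s
    sd: np.ndarray  # per-neuron training s.d.


def standardize_rates(
    rates: np.ndarray, mean: np.ndarray | None = None, sd: np.ndarray | None = None
) -> RateMatrix:
    """Z-score rates per neuron; moments frozen from training if given."""
    rates = np.asarray(rates, dtype=float)
    if mean is None:
        mean = rates.mean(axis=0)
    if sd is None:
        sd = rates.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return RateMatrix(values=(rates - mean) / sd, mean=mean, sd=sd)


def lagged_design(values: np.ndarray, n_lags: int) -> np.ndarray:
    """Stack trailing lags 0..n_lags-1 of each neuron column.

    Row t holds [r(t), r(t-1), ..., r(t-n_lags+1)] for every neuron;
    lags before the trial start are zero (the standardized mean).
    """
    n_steps, n_neurons = values.shape
    X = np.zeros((n_steps, n_neurons * n_lags))
    for k in range(min(n_lags, n_steps)):
        X[k:, k * n_neurons:(k + 1) * n_neurons] = values[: n_steps - k]
    return X


@dataclass(frozen=True)
class RidgeFit:
    """Fitted ridge decoder for 2-d position."""

    coef: np.ndarray  # (n_features, 2)
    delta: float
    history_ms: int
    rate_mean: np.ndarray
    rate_sd: np.ndarray
    pos_mean: np.ndarray  # (2,)
    train_mse: float
    cv_mse: float | None = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")


def fit_ridge(R: np.ndarray, q: np.ndarray, delta: float) -> np.ndarray:
    """Closed-form ridge solution per output dimension.

    ``R`` is the (n_samples, n_features) design, ``q`` the
    (n_samples, k) mean-subtracted outputs.  Returns the
    (n_features, k) coefficient matrix (R'R + delta I)^{-1} R'q.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    R = np.asarray(R, dtype=float)
    q = np.asarray(q, dtype=float)
    G = R.T @ R + delta * np.eye(R.shape[1])
    return np.linalg.solve(G, R.T @ q)


def _session_design(
    trial_rates: Sequence[np.ndarray], history_ms: int, step_ms: int,
    mean: np.ndarray | None = None, sd: np.ndarray | None = None,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Per-trial lagged designs from raw rate matrices (lags reset per trial)."""
    pooled = np.vstack(trial_rates)
    rm = standardize_rates(pooled, mean, sd)
    n_lags = history_ms // step_ms
    designs = []
    start = 0
    for r in trial_rates:
        z = rm.values[start:start + r.shape[0]]
        designs.append(lagged_design(z, n_lags))
        start += r.shape[0]
    return designs, rm.mean, rm.sd


def select_model(
    trial_rates: Sequence[np.ndarray],
    trial_positions: Sequence[np.ndarray],
    histories_ms: Sequence[int] = DEFAULT_HISTORIES_MS,
    delta_grid: np.ndarray | None = None,
    step_ms: int = 5,
) -> RidgeFit:
    """Leave-one-trial-out selection of history length and regularizer.

    For every (history, delta) candidate, each trial is predicted from
    a model fitted on the remaining trials (standardization moments
    refrozen per training fold); the candidate minimising the pooled
    CV mean-square error wins and is refitted on all trials.
    """
    trial_rates = [np.asarray(r, dtype=float) for r in trial_rates]
    trial_positions = [np.asarray(p, dtype=float) for p in trial_positions]
    n_trials = len(trial_rates)
    if n_trials < 3:
        raise ValueError("need at least 3 trials for cross-validated selection")
    if delta_grid is None:
        delta_grid = np.logspace(-4, 4, 9)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.size == 0 or not len(histories_ms):
        raise ValueError("empty candidate grid")

    best = None
    for hist in histories_ms:
        n_lags = hist // step_ms
        # per-fold fitting; Gram matrices assembled per fold
        cv_sse = np.zeros(delta_grid.size)
        cv_n = 0
        for i in range(n_trials):
            train_idx = [j for j in range(n_trials) if j != i]
            designs, mu, sd = _session_design(
                [trial_rates[j] for j in train_idx], hist, step_ms)
            Xtr = np.vstack(designs)
            qtr = np.vstack([trial_positions[j] for j in train_idx])
            pos_mean = qtr.mean(axis=0)
            qtr = qtr - pos_mean
            # scale the delta grid by the mean diagonal of R'R so the
            # logarithmic grid spans the problem's natural range
            G = Xtr.T @ Xtr
            scale = np.trace(G) / G.shape[0]
            Rtq = Xtr.T @ qtr
            z_test = (trial_rates[i] - mu) / sd
            Xte = lagged_design(z_test, n_lags)
            qte = trial_positions[i] - pos_mean
            for k, delta in enumerate(delta_grid):
                coef = np.linalg.solve(
                    G + delta * scale * np.eye(G.shape[0]), Rtq)
                err = Xte @ coef - qte
                cv_sse[k] += float((err**2).sum())
            cv_n += qte.size
        cv_mse = cv_sse / cv_n
        k_best = int(np.argmin(cv_mse))
        if best is None or cv_mse[k_best] < best[0]:
            best = (cv_mse[k_best], hist, delta_grid[k_best])

    _, hist, delta_rel = best
    designs, mu, sd = _session_design(trial_rates, hist, step_ms)
    X = np.vstack(designs)
    q = np.vstack(trial_positions)
    pos_mean = q.mean(axis=0)
    G = X.T @ X
    scale = np.trace(G) / G.shape[0]
    delta = float(delta_rel * scale)
    coef = np.linalg.solve(G + delta * np.eye(G.shape[0]), X.T @ (q - pos_mean))
    resid = X @ coef - (q - pos_mean)
    return RidgeFit(
        coef=coef, delta=delta, history_ms=int(hist),
        rate_mean=mu, rate_sd=sd, pos_mean=pos_mean,
        train_mse=float((resid**2).mean()), cv_mse=float(best[0]),
    )


def predict_position(fit: RidgeFit, rates: np.ndarray, step_ms: int = 5) -> np.ndarray:
    """Decode a trial's position series from its raw rate matrix."""
    z = (np.asarray(rates, dtype=float) - fit.rate_mean) / fit.rate_sd
    X = lagged_design(z, fit.history_ms // step_ms)
    return X @ fit.coef + fit.pos_mean


def shuffle_rates(
    trial_rates: Sequence[np.ndarray], seed: int
) -> list[np.ndarray]:
    """Permute each neuron's rates independently across time and trials.

    The multiset of values per neuron (hence its mean rate) is exactly
    preserved; all temporal and kinematic structure is destroyed.
    """
    trial_rates = [np.asarray(r, dtype=float) for r in trial_rates]
    pooled = np.vstack(trial_rates)
    rng = np.random.default_rng(seed)
    for c in range(pooled.shape[1]):
        pooled[:, c] = rng.permutation(pooled[:, c])
    out = []
    start = 0
    for r in trial_rates:
        out.append(pooled[start:start + r.shape[0]])
        start += r.shape[0]
    return out
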