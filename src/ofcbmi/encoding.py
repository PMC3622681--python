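"""Point-process encoding models of delay-period and peri-movement spiking.

Two models are fitted per neuron from a training (manual-control)
session:

* a homogeneous-Poisson **target rate model** for the instructed-delay
  epoch, one constant rate per (neuron, target), estimated from the
  800 ms decode window before the go cue;
* a log-linear **kinematic tuning model** for the movement epoch,
  lambda_c(t) = exp(alpha_c + beta_c' [px, py, vx, vy]), a modified
  cosine-tuning form fitted as a Poisson GLM on 5 ms binned counts.

Per-coefficient Wald p-values from the GLM fit classify each neuron as
position-only, velocity-only, both, or untuned after Bonferroni
correction across all (neuron, coefficient) tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .task import TaskConfig, TrialRecord

__all__ = [
    "TargetRateModel",
    "KinematicTuningModel",
    "TuningStats",
    "RATE_FLOOR",
    "LAMBDA_DT_CLAMP",
    "fit_target_model",
    "fit_kinematic_model",
    "rate_at",
]

#: Minimum admissible rate, spikes/s.  The maximum-likelihood rate for a
#: silent cell is zero, which makes log(lambda*dt) ill-posed in the
#: target decoder, so rates are floored here.
RATE_FLOOR = 0.1

#: Upper clamp on the per-bin event probability lambda*dt, keeping it a
#: valid Bernoulli parameter at 5 ms bins.
LAMBDA_DT_CLAMP = 0.95

_KIN_NAMES = ("p_x", "p_y", "v_x", "v_y")


@dataclass(frozen=True)
class TargetRateModel:
    """Constant delay-period firing rate per (neuron, target), spikes/s."""

    rates: np.ndarray  # (n_neurons, n_targets)
    exposure_s: np.ndarray  # (n_neurons,) total fitting exposure

    def __post_init__(self) -> None:
        if np.any(self.rates < RATE_FLOOR):
            raise ValueError("rates must be floored at RATE_FLOOR")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_targets(self) -> int:
        return self.rates.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {"schema": "ofcbmi.target_rate_model/1",
             "rates": self.rates.tolist(),
             "exposure_s": self.exposure_s.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "TargetRateModel":
        d = json.loads(text)
        return cls(np.asarray(d["rates"]), np.asarray(d["exposure_s"]))


@dataclass(frozen=True)
class KinematicTuningModel:
    """Log-linear position/velocity tuning per neuron.

    ``alpha`` is the log baseline rate (log spikes/s at the origin) and
    ``beta`` the (n_neurons, 4) array of log-rate gradients over
    [p_x, p_y, v_x, v_y].
    """

    alpha: np.ndarray  # (n_neurons,)
    beta: np.ndarray  # (n_neurons, 4)

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.alpha)) and np.all(np.isfinite(self.beta))):
            raise ValueError("tuning coefficients must be finite")
        if self.beta.shape != (self.alpha.shape[0], 4):
            raise ValueError("beta must be (n_neurons, 4)")

    @property
    def n_neurons(self) -> int:
        return self.alpha.shape[0]

    def rates(self, x_kin: np.ndarray, bin_s: float) -> np.ndarray:
        """Vector of clamped rates (spikes/s) for all neurons at ``x_kin``.

        ``x_kin`` is the 4-vector [p_x, p_y, v_x, v_y]; the returned
        rates satisfy rate * bin_s <= LAMBDA_DT_CLAMP.
        """
        log_rate = self.alpha + self.beta @ np.asarray(x_kin, dtype=float)
        cap = np.log(LAMBDA_DT_CLAMP / bin_s)
        return np.exp(np.minimum(log_rate, cap))

    def to_json(self) -> str:
        return json.dumps(
            {"schema": "ofcbmi.kinematic_tuning_model/1",
             "alpha": self.alpha.tolist(), "beta": self.beta.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "KinematicTuningModel":
        d = json.loads(text)
        return cls(np.asarray(d["alpha"]), np.asarray(d["beta"]))


@dataclass(frozen=True)
class TuningStats:
    """Per-neuron coefficient p-values and tuning classification."""

    p_values: np.ndarray  # (n_neurons, 4) Wald p-values
    se: np.ndarray  # (n_neurons, 4) coefficient standard errors, native units
    significant: np.ndarray  # (n_neurons, 4) bool, after Bonferroni
    category: tuple[str, ...]  # per neuron
    converged: np.ndarray  # (n_neurons,) bool

    _CATEGORIES = ("position_only", "velocity_only", "both", "untuned")

    def __post_init__(self) -> None:
        for cat, sig in zip(self.category, self.significant):
            pos, vel = sig[:2].any(), sig[2:].any()
            expect = ("both" if pos and vel else "position_only" if pos
                      else "velocity_only" if vel else "untuned")
            if cat != expect:
                raise ValueError("category inconsistent with significance flags")

    def fraction_tuned(self) -> float:
        return float(np.mean([c != "untuned" for c in self.category]))


def rate_at(model: KinematicTuningModel, neuron: int, x: np.ndarray,
            bin_s: float = 0.005) -> float:
    """Clamped instantaneous rate of one neuron, spikes/s.

    ``x`` may be a 4-vector [p_x, p_y, v_x, v_y] or a 6-vector state
    whose first four entries are position and velocity.
    """
    x = np.asarray(x, dtype=float)
    return float(model.rates(x[:4], bin_s)[neuron])


def _delay_windows(trials: Sequence[TrialRecord], config: TaskConfig):
    for tr in trials:
        yield tr.cued_target, tr.delay_decode_spikes(config)


def fit_target_model(
    trials: Sequence[TrialRecord], config: TaskConfig
) -> TargetRateModel:
    """Maximum-likelihood delay rates: spike count over exposure.

    For each (neuron, target) the homogeneous-Poisson ML rate is the
    total spike count in the 800 ms decode windows of that target's
    trials divided by the total exposure, floored at ``RATE_FLOOR``.
    This coincides with a Poisson GLM with log link on a target-
    indicator design.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials supplied")
    n_neurons = trials[0].n_neurons
    n_targets = config.n_targets
    counts = np.zeros((n_neurons, n_targets))
    exposure = np.zeros(n_targets)
    for cued, win in _delay_windows(trials, config):
        counts[:, cued] += win.sum(axis=1)
        exposure[cued] += win.shape[1] * config.bin_s
    missing = np.flatnonzero(exposure == 0)
    if missing.size:
        raise ValueError(f"no trials for targets {missing.tolist()}")
    rates = np.maximum(counts / exposure[None, :], RATE_FLOOR)
    return TargetRateModel(rates=rates, exposure_s=np.full(n_neurons, exposure.sum()))


def fit_kinematic_model(
    trials: Sequence[TrialRecord],
    bin_s: float = 0.005,
    alpha_level: float = 0.05,
) -> tuple[KinematicTuningModel, TuningStats]:
    """Fit per-neuron Poisson GLMs of movement-epoch counts on kinematics.

    The design is [1, p_x, p_y, v_x, v_y] per 5 ms bin with a
    log-exposure offset, pooled over the movement epochs of all trials.
    Covariates are standardized internally for conditioning and the
    coefficients mapped back to native units.  Wald p-values are
    Bonferroni-corrected across (n_neurons x 4) coefficient tests at
    family level ``alpha_level``.  A neuron whose fit fails to converge
    (e.g., separation) is flagged unconverged and classified untuned.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials supplied")
    X_rows, count_rows = [], []
    for tr in trials:
        kin = tr.movement_kinematics()[:, :4]
        X_rows.append(kin)
        count_rows.append(tr.movement_spikes().T)
    X = np.vstack(X_rows)
    counts = np.vstack(count_rows)  # (n_bins_total, n_neurons)
    n_neurons = counts.shape[1]

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    design = sm.add_constant(Z, has_constant="add")
    offset = np.full(X.shape[0], np.log(bin_s))

    alpha = np.zeros(n_neurons)
    beta = np.zeros((n_neurons, 4))
    pvals = np.ones((n_neurons, 4))
    ses = np.full((n_neurons, 4), np.inf)
    converged = np.zeros(n_neurons, dtype=bool)
    for c in range(n_neurons):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    counts[:, c], design, family=sm.families.Poisson(),
                    offset=offset,
                ).fit(maxiter=100, tol=1e-8)
            ok = np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse))
        except Exception:
            ok = False
        if not ok:
            # unconverged cells fall back to a constant-rate fit
            mean_rate = max(counts[:, c].mean() / bin_s, RATE_FLOOR)
            alpha[c] = np.log(mean_rate)
            continue
        converged[c] = True
        b_std = res.params[1:]
        beta[c] = b_std / sd
        alpha[c] = res.params[0] - float(beta[c] @ mu)
        pvals[c] = res.pvalues[1:]
        ses[c] = res.bse[1:] / sd

    n_tests = n_neurons * 4
    significant = (pvals < alpha_level / n_tests) & converged[:, None]
    category = []
    for sig in significant:
        pos, vel = sig[:2].any(), sig[2:].any()
        category.append("both" if pos and vel else "position_only" if pos
                        else "velocity_only" if vel else "untuned")
    stats = TuningStats(
        p_values=pvals, se=ses, significant=significant,
        category=tuple(category), converged=converged,
    )
    return KinematicTuningModel(alpha=alpha, beta=beta), stats
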