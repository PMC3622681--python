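"""Stage 1: maximum-likelihood target decoding from delay-period spiking.

With delay spiking modelled per neuron as a homogeneous Poisson process
whose rate depends on the cued target, and neurons conditionally
independent given the target, the log-likelihood of the binned ensemble
activity under target m is the Bernoulli point-process sum

    sum_c sum_t [ dN_c(t) log(lambda_c(m) dt)
                  + (1 - dN_c(t)) log(1 - lambda_c(m) dt) ].

The decoder predicts the target maximising this ensemble likelihood.
The neuron-dropping analysis ranks neurons by leave-one-out single-cell
accuracy and reports cumulative top-k ensemble accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .encoding import LAMBDA_DT_CLAMP, RATE_FLOOR, TargetRateModel
from .task import TaskConfig, TrialRecord

__all__ = [
    "TargetPosterior",
    "ensemble_delay_loglik",
    "decode_target_ml",
    "neuron_dropping_curve",
    "NeuronDroppingResult",
]


@dataclass(frozen=True)
class TargetPosterior:
    """Per-target log-likelihoods and the ML decision."""

    loglik: np.ndarray  # (n_targets,)
    predicted: int
    margin: float  # gap between best and runner-up

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")
        if self.loglik[self.predicted] < self.loglik.max() - 1e-12:
            raise ValueError("predicted target must attain the maximum")


def _log_p(model_rates: np.ndarray, bin_s: float) -> tuple[np.ndarray, np.ndarray]:
    lam_dt = np.clip(model_rates * bin_s, RATE_FLOOR * bin_s, LAMBDA_DT_CLAMP)
    return np.log(lam_dt), np.log1p(-lam_dt)


def ensemble_delay_loglik(
    spikes: np.ndarray, model: TargetRateModel, bin_s: float
) -> np.ndarray:
    """Per-target Bernoulli log-likelihood of a delay-window spike array.

    ``spikes`` is (n_neurons, n_bins) binary.  Because the rates are
    constant over the window, the sum over bins collapses to per-neuron
    spike counts.
    """
    spikes = np.asarray(spikes)
    if spikes.shape[0] != model.n_neurons:
        raise ValueError(
            f"spike array has {spikes.shape[0]} neurons, model has {model.n_neurons}"
        )
    n_bins = spikes.shape[1]
    n_spk = spikes.sum(axis=1).astype(float)  # (n_neurons,)
    log_lam, log_1m = _log_p(model.rates, bin_s)  # (n_neurons, n_targets)
    return n_spk @ log_lam + (n_bins - n_spk) @ log_1m


def decode_target_ml(
    spikes: np.ndarray,
    model: TargetRateModel,
    bin_s: float,
    rng: np.random.Generator | None = None,
) -> TargetPosterior:
    """ML target decision; exact ties broken uniformly at random."""
    ll = ensemble_delay_loglik(spikes, model, bin_s)
    best = ll.max()
    tied = np.flatnonzero(ll >= best - 1e-12)
    if tied.size > 1:
        if rng is None:
            rng = np.random.default_rng()
        predicted = int(rng.choice(tied))
    else:
        predicted = int(tied[0])
    order = np.sort(ll)
    margin = float(order[-1] - order[-2]) if ll.size > 1 else 0.0
    return TargetPosterior(loglik=ll, predicted=predicted, margin=margin)


# ---------------------------------------------------------------------------
# Leave-one-out decoding and neuron dropping
# ---------------------------------------------------------------------------

def _loo_rates(
    counts: np.ndarray, cued: np.ndarray, n_targets: int, exposure_per_trial: float
) -> tuple[np.ndarray, np.ndarray]:
    """Totals needed for leave-one-trial-out refitting of delay rates."""
    n_neurons = counts.shape[1]
    tot_counts = np.zeros((n_targets, n_neurons))
    tot_expo = np.zeros(n_targets)
    for m in range(n_targets):
        sel = cued == m
        tot_counts[m] = counts[sel].sum(axis=0)
        tot_expo[m] = sel.sum() * exposure_per_trial
    return tot_counts, tot_expo


def loo_target_accuracy(
    trials: Sequence[TrialRecord],
    config: TaskConfig,
    neuron_subset: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Leave-one-out cross-validated target prediction accuracy.

    For each held-out trial the homogeneous-Poisson rates are refitted
    from the remaining trials (a cheap count/exposure update) and the
    held-out delay window decoded.
    """
    trials = list(trials)
    bin_s = config.bin_s
    windows = np.stack([tr.delay_decode_spikes(config) for tr in trials])
    cued = np.array([tr.cued_target for tr in trials])
    if neuron_subset is not None:
        windows = windows[:, neuron_subset, :]
    counts = windows.sum(axis=2)  # (n_trials, n_neurons)
    expo = windows.shape[2] * bin_s
    tot_counts, tot_expo = _loo_rates(counts, cued, config.n_targets, expo)
    if rng is None:
        rng = np.random.default_rng()
    correct = 0
    for i, tr in enumerate(trials):
        c = tot_counts.copy()
        e = tot_expo.copy()
        c[cued[i]] -= counts[i]
        e[cued[i]] -= expo
        if np.any(e == 0):
            raise ValueError("leave-one-out needs >= 2 trials per target")
        rates = np.maximum(c.T / e[None, :], RATE_FLOOR)
        model = TargetRateModel(rates=rates, exposure_s=np.full(rates.shape[0], e.sum()))
        post = decode_target_ml(windows[i], model, bin_s, rng)
        correct += post.predicted == cued[i]
    return correct / len(trials)


@dataclass(frozen=True)
class NeuronDroppingResult:
    """Ranked single-cell accuracies and cumulative top-k accuracy."""

    single_accuracy: np.ndarray  # (n_neurons,), in original neuron order
    ranking: np.ndarray  # neuron indices, best first
    cumulative_accuracy: np.ndarray  # (k_max,), top-k ensembles
    k_90pct: int  # smallest k with accuracy >= 0.9 * full-ensemble accuracy
    full_accuracy: float


def neuron_dropping_curve(
    trials: Sequence[TrialRecord],
    config: TaskConfig,
    k_max: int | None = None,
    seed: int = 0,
) -> NeuronDroppingResult:
    """Accuracy versus ensemble size with neurons ranked by single-cell skill.

    Each neuron's leave-one-out single-cell accuracy is computed first;
    neurons are sorted by it, and the top-k ensemble accuracy evaluated
    for k = 1..k_max.  Also reports the smallest k whose accuracy
    reaches 90% of the full-ensemble accuracy.
    """
    trials = list(trials)
    n_neurons = trials[0].n_neurons
    if k_max is None:
        k_max = n_neurons
    if k_max > n_neurons:
        k_max = n_neurons
    rng = np.random.default_rng(seed)
    single = np.array([
        loo_target_accuracy(trials, config, np.array([c]), rng)
        for c in range(n_neurons)
    ])
    ranking = np.argsort(-single, kind="stable")
    cumulative = np.array([
        loo_target_accuracy(trials, config, ranking[:k], rng)
        for k in range(1, k_max + 1)
    ])
    full = (cumulative[-1] if k_max == n_neurons
            else loo_target_accuracy(trials, config, ranking, rng))
    reach = np.flatnonzero(cumulative >= 0.9 * full)
    k90 = int(reach[0]) + 1 if reach.size else k_max
    return NeuronDroppingResult(
        single_accuracy=single, ranking=ranking,
        cumulative_accuracy=cumulative, k_90pct=k90, full_accuracy=float(full),
    )
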