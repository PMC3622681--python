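"""Online (per-bin) decoders for closed-loop operation.

Every decoder implements the same minimal real-time interface: at trial
start :meth:`start_trial` resets state, :meth:`decode_delay` consumes
the instruction-epoch spikes and (for target-aware decoders) predicts
the intended target, and :meth:`step` consumes one 5 ms bin of spike
indicators and returns the cursor position to display.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .encoding import KinematicTuningModel, TargetRateModel
from .ofc import CostSpec, GainSchedule, LTISystem, goal_state, solve_lqg
from .ridge import RidgeFit
from .target_decoding import decode_target_ml
from .task import TaskConfig, target_positions
from .trajectory import (
    DurationGrid,
    FCPPFBank,
    GaussianBelief,
    ppf_predict,
    ppf_update,
)

__all__ = [
    "OnlineDecoder",
    "TwoStageDecoder",
    "RWPPFDecoder",
    "RidgeDecoder",
    "OracleDecoder",
    "FrozenDecoder",
]


class OnlineDecoder:
    """Base class for per-bin decoders (the real-time interface)."""

    #: True for decoders that must be told the cued target (oracle only).
    wants_cue = False

    def start_trial(self, cue: Optional[int] = None) -> None:
        raise NotImplementedError

    def decode_delay(self, delay_spikes: np.ndarray) -> Optional[int]:
        """Consume instruction-epoch spikes; return predicted target or None."""
        return None

    def step(self, dN: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _init_belief() -> GaussianBelief:
    return GaussianBelief(mean=np.zeros(6), cov=1e-10 * np.eye(6))


class TwoStageDecoder(OnlineDecoder):
    """Stage-1 ML target prediction feeding a stage-2 FC-P-PPF.

    LQG gain schedules depend on the duration but not on the target
    (only the goal state x* does), so one gain array per grid duration
    is precomputed at construction and rebound to the decoded target
    each trial.
    """

    def __init__(
        self,
        target_model: TargetRateModel,
        kin_model: KinematicTuningModel,
        sys: LTISystem,
        cost_template: CostSpec,
        config: TaskConfig,
        grid: DurationGrid | None = None,
        seed: int = 0,
        closed_loop_cov: bool = False,
    ) -> None:
        self.target_model = target_model
        self.kin_model = kin_model
        self.sys = sys
        self.config = config
        self.grid = grid or DurationGrid.from_seconds(bin_s=config.bin_s)
        self.closed_loop_cov = closed_loop_cov
        self.rng = np.random.default_rng(seed)
        self._gain_arrays = [
            solve_lqg(sys, replace(cost_template, target=np.zeros(2), T=T)).L
            for T in self.grid.durations
        ]
        self._targets = target_positions(config)
        self.bank: FCPPFBank | None = None
        self.predicted_target: Optional[int] = None

    def start_trial(self, cue: Optional[int] = None) -> None:
        self.bank = None
        self.predicted_target = None

    def decode_delay(self, delay_spikes: np.ndarray) -> int:
        window = delay_spikes[:, -self.config.n_decode_bins:]
        post = decode_target_ml(
            window, self.target_model, self.config.bin_s, self.rng)
        self.predicted_target = post.predicted
        x_star = goal_state(self._targets[post.predicted])
        gains = [GainSchedule(L=L, x_star=x_star) for L in self._gain_arrays]
        self.bank = FCPPFBank(
            self.grid, gains, self.sys, self.kin_model, _init_belief(),
            self.config.bin_s, self.closed_loop_cov,
        )
        return post.predicted

    def step(self, dN: np.ndarray) -> np.ndarray:
        if self.bank is None:
            raise RuntimeError("decode_delay must run before stepping")
        return self.bank.step(dN)[:2]

    def duration_weights(self) -> np.ndarray:
        if self.bank is None:
            raise RuntimeError("no active trial")
        return self.bank.weights()


class RWPPFDecoder(OnlineDecoder):
    """Second stage alone with the random-walk prior (no target info)."""

    def __init__(
        self,
        kin_model: KinematicTuningModel,
        sys: LTISystem,
        bin_s: float = 0.005,
    ) -> None:
        self.kin_model = kin_model
        self.sys = sys
        self.bin_s = bin_s
        self._zero_gain = np.zeros((2, 6))
        self._x_star = np.zeros(6)
        self.belief = _init_belief()

    def start_trial(self, cue: Optional[int] = None) -> None:
        self.belief = _init_belief()

    def step(self, dN: np.ndarray) -> np.ndarray:
        pred = ppf_predict(self.belief, self.sys, self._zero_gain, self._x_star)
        self.belief = ppf_update(pred, dN, self.kin_model, self.bin_s)
        return self.belief.mean[:2]


class RidgeDecoder(OnlineDecoder):
    """Causal ridge-regression decoder over trailing 100 ms rates."""

    def __init__(self, fit: RidgeFit, n_neurons: int,
                 window_ms: int = 100, step_ms: int = 5) -> None:
        self.fit = fit
        self.n_neurons = n_neurons
        self.window_bins = window_ms // step_ms
        self.n_lags = fit.history_ms // step_ms
        self.step_s = step_ms / 1000.0
        self.start_trial()

    def start_trial(self, cue: Optional[int] = None) -> None:
        self._spike_hist: list[np.ndarray] = []
        # lag buffer of standardized rates, most recent first
        self._lags = np.zeros((self.n_lags, self.n_neurons))

    def step(self, dN: np.ndarray) -> np.ndarray:
        self._spike_hist.append(np.asarray(dN, dtype=float))
        win = self._spike_hist[-self.window_bins:]
        rate = np.sum(win, axis=0) / (len(win) * self.step_s)
        z = (rate - self.fit.rate_mean) / self.fit.rate_sd
        self._lags = np.roll(self._lags, 1, axis=0)
        self._lags[0] = z
        x = self._lags.reshape(-1)
        return x @ self.fit.coef + self.fit.pos_mean


class OracleDecoder(OnlineDecoder):
    """Geometry-sanity decoder: replays the noiseless prior rollout.

    Ignores the spikes entirely and moves the cursor along the
    noiseless LQG reach to the cued target; used to verify that the
    closed-loop harness spans the top of the performance range.
    """

    wants_cue = True

    def __init__(self, sys: LTISystem, cost_template: CostSpec,
                 config: TaskConfig, duration_bins: int = 120) -> None:
        from .ofc import rollout_prior

        self._paths = []
        for target in target_positions(config):
            cost = replace(cost_template, target=target, T=duration_bins)
            gains = solve_lqg(sys, cost)
            traj = rollout_prior(sys, gains, np.zeros(6), noiseless=True)
            self._paths.append(traj[1:, :2])
        self._t = 0
        self._cue = 0

    def start_trial(self, cue: Optional[int] = None) -> None:
        if cue is None:
            raise ValueError("oracle decoder needs the cued target")
        self._cue = int(cue)
        self._t = 0

    def step(self, dN: np.ndarray) -> np.ndarray:
        path = self._paths[self._cue]
        pos = path[min(self._t, len(path) - 1)]
        self._t += 1
        return pos


class FrozenDecoder(OnlineDecoder):
    """Degenerate decoder: the cursor never leaves the center."""

    def start_trial(self, cue: Optional[int] = None) -> None:
        pass

    def step(self, dN: np.ndarray) -> np.ndarray:
        return np.zeros(2)
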