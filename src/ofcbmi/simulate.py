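"""Synthetic neural populations and the closed-loop task harness.

The generator builds a ground-truth population whose statistics follow
the recording conditions the decoder is designed for: ~20 isolated
premotor units, about half of them with target-dependent delay-period
rates, and about half with log-linear position/velocity tuning during
movement (position-only, velocity-only, or both, in roughly a
57/15/28 split among the tuned cells).

Manual-control (training) trials move the cursor with a noisy LQG
reach and generate spikes from the ground-truth encoding models along
the realized kinematics.  Closed-loop trials put a simulated LQG
subject in the loop: each 5 ms bin the subject reads the displayed
(decoded) cursor position — perfect visual feedback — keeps its own
intended velocity and force, issues its LQG corrective command toward
the cued target, and emits spikes from the kinematic model evaluated
at that internal state; the decoder consumes the spikes and moves the
cursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .decoders import OnlineDecoder
from .encoding import LAMBDA_DT_CLAMP, RATE_FLOOR
from .metrics import SessionSummary, summarize_session
from .ofc import (
    CostSpec,
    GainSchedule,
    LTISystem,
    PlantParams,
    discretize_plant,
    goal_state,
    solve_lqg,
)
from .task import TaskConfig, TrialOutcome, TrialRecord, make_center_out_config, \
    score_trial, target_positions
from .trajectory import DEFAULT_DURATION_GRID_S

__all__ = [
    "PopulationSpec",
    "GroundTruthPopulation",
    "make_population",
    "simulate_manual_trial",
    "simulate_closed_loop_trial",
    "run_session",
    "default_cost_template",
]


def default_cost_template(target=np.zeros(2), T: int = 120) -> CostSpec:
    """Reach cost with the package's calibrated default weights."""
    return CostSpec(target=np.asarray(target, dtype=float), T=T)


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical description of a simulated premotor ensemble.

    Baseline rates are log-normal around 5 spikes/s.  Target tuning is
    cosine-shaped in target angle with log-depth ``target_kappa``;
    kinematic tuning strengths are scaled so that position modulation
    at the reach distance and velocity modulation at a typical peak
    speed are both order exp(+-1).
    """

    n_neurons: int = 20
    fraction_target_tuned: float = 0.48
    fraction_kinematic_tuned: float = 0.47
    baseline_rate: float = 5.0
    baseline_log_sd: float = 0.5
    target_kappa: float = 0.5
    position_gain: float = 10.0  # log-rate per workspace unit
    velocity_gain: float = 12.0  # log-rate per (workspace unit / s)
    kin_category_probs: tuple[float, float, float] = (0.57, 0.15, 0.28)

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        for f in (self.fraction_target_tuned, self.fraction_kinematic_tuned):
            if not 0 <= f <= 1:
                raise ValueError("tuning fractions must lie in [0, 1]")
        if abs(sum(self.kin_category_probs) - 1) > 1e-9:
            raise ValueError("kinematic category probabilities must sum to 1")


@dataclass(frozen=True)
class GroundTruthPopulation:
    """True encoding parameters of a simulated ensemble."""

    delay_rates: np.ndarray  # (n_neurons, n_targets), spikes/s
    alpha: np.ndarray  # (n_neurons,) log baseline rate
    beta: np.ndarray  # (n_neurons, 4) kinematic tuning
    target_tuned: np.ndarray  # (n_neurons,) bool
    kinematic_tuned: np.ndarray  # (n_neurons,) bool

    @property
    def n_neurons(self) -> int:
        return self.alpha.shape[0]


def make_population(
    spec: PopulationSpec = PopulationSpec(),
    seed: int = 0,
    config: TaskConfig | None = None,
) -> GroundTruthPopulation:
    """Draw a ground-truth population; deterministic given the seed."""
    config = config or make_center_out_config()
    rng = np.random.default_rng(seed)
    n = spec.n_neurons
    baseline = np.exp(
        np.log(spec.baseline_rate)
        + spec.baseline_log_sd * rng.standard_normal(n)
    )
    baseline = np.maximum(baseline, RATE_FLOOR)

    target_tuned = rng.random(n) < spec.fraction_target_tuned
    angles = np.asarray(config.target_angles)
    pref = rng.uniform(0, 2 * np.pi, size=n)
    kappa = np.abs(rng.normal(spec.target_kappa, 0.3 * spec.target_kappa, size=n))
    delay_rates = np.tile(baseline[:, None], (1, config.n_targets))
    mod = np.exp(kappa[:, None] * np.cos(angles[None, :] - pref[:, None]))
    delay_rates = np.where(target_tuned[:, None], baseline[:, None] * mod,
                           delay_rates)
    delay_rates = np.maximum(delay_rates, RATE_FLOOR)

    kinematic_tuned = rng.random(n) < spec.fraction_kinematic_tuned
    beta = np.zeros((n, 4))
    cats = rng.choice(3, size=n, p=spec.kin_category_probs)
    for c in range(n):
        if not kinematic_tuned[c]:
            continue
        gain_jitter = np.abs(rng.normal(1.0, 0.3))
        theta_p, theta_v = rng.uniform(0, 2 * np.pi, size=2)
        if cats[c] in (0, 2):  # position tuned
            beta[c, 0:2] = spec.position_gain * gain_jitter * np.array(
                [np.cos(theta_p), np.sin(theta_p)])
        if cats[c] in (1, 2):  # velocity tuned
            beta[c, 2:4] = spec.velocity_gain * gain_jitter * np.array(
                [np.cos(theta_v), np.sin(theta_v)])
    return GroundTruthPopulation(
        delay_rates=delay_rates, alpha=np.log(baseline), beta=beta,
        target_tuned=target_tuned, kinematic_tuned=kinematic_tuned,
    )


def _bernoulli_spikes(rates: np.ndarray, bin_s: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-bin Bernoulli thinning with the lambda*dt clamp."""
    p = np.clip(rates * bin_s, 0.0, LAMBDA_DT_CLAMP)
    return (rng.random(p.shape) < p).astype(np.uint8)


def _delay_spikes(pop: GroundTruthPopulation, cued: int, n_bins: int,
                  bin_s: float, rng: np.random.Generator) -> np.ndarray:
    rates = np.tile(pop.delay_rates[:, cued][:, None], (1, n_bins))
    return _bernoulli_spikes(rates, bin_s, rng)


def _movement_rates(pop: GroundTruthPopulation, kin: np.ndarray) -> np.ndarray:
    """(n_neurons, n_bins) intensities along a kinematic sequence."""
    log_rate = pop.alpha[:, None] + pop.beta @ kin[:, :4].T
    return np.exp(log_rate)


def _draw_duration_bins(rng: np.random.Generator, bin_s: float) -> int:
    lo, hi = DEFAULT_DURATION_GRID_S[0], DEFAULT_DURATION_GRID_S[-1]
    return int(round(rng.uniform(lo, hi) / bin_s))


def simulate_manual_trial(
    pop: GroundTruthPopulation,
    config: TaskConfig,
    sys: LTISystem,
    cost_template: CostSpec,
    seed: int | np.random.Generator = 0,
    cued: int | None = None,
) -> TrialRecord:
    """One manual-control (training) trial.

    The cued target is drawn uniformly, the intended duration uniformly
    over the duration-grid range, and the trajectory is a noisy
    feedback-controlled rollout to the cued target.  Delay spikes come
    from the target rates over the full 1000 ms instruction epoch;
    movement spikes from the log-linear kinematic model along the
    realized kinematics.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if cued is None:
        cued = int(rng.integers(config.n_targets))
    T = _draw_duration_bins(rng, config.bin_s)
    target = target_positions(config)[cued]
    gains = solve_lqg(sys, replace(cost_template, target=target, T=T))

    from .ofc import rollout_prior

    traj = rollout_prior(sys, gains, np.zeros(6), n_steps=T, rng=rng)
    move_kin = traj[1:]  # (T, 6)

    n_delay = config.n_instruct_bins
    delay = _delay_spikes(pop, cued, n_delay, config.bin_s, rng)
    move = _bernoulli_spikes(_movement_rates(pop, move_kin), config.bin_s, rng)
    spikes = np.concatenate([delay, move], axis=1)
    kinematics = np.vstack([np.zeros((n_delay, 6)), move_kin])
    outcome = score_trial(move_kin[:, :2], config, cued)
    return TrialRecord(
        cued_target=cued, spikes=spikes, kinematics=kinematics,
        epoch_marks=(0, n_delay), outcome=outcome,
        intended_duration_bins=T,
    )


def simulate_closed_loop_trial(
    pop: GroundTruthPopulation,
    decoder: OnlineDecoder,
    config: TaskConfig,
    sys: LTISystem,
    cost_template: CostSpec,
    seed: int | np.random.Generator = 0,
    cued: int | None = None,
) -> TrialRecord:
    """One closed-loop BMI trial with a simulated LQG subject.

    During the delay the subject emits target-tuned spikes and the
    cursor stays pinned at the center while the decoder runs its first
    stage.  During movement, each bin the subject slaves its internal
    position to the displayed cursor (perfect visual feedback), keeps
    its intended velocity and force, computes its LQG corrective
    command toward the cued target, advances its internal state, and
    emits spikes from the kinematic model at that state.  The decoder
    consumes the spikes and moves the cursor; the trial ends at the
    first target-disk entry or at the timeout.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if cued is None:
        cued = int(rng.integers(config.n_targets))
    target = target_positions(config)[cued]
    T_int = _draw_duration_bins(rng, config.bin_s)
    gains = solve_lqg(sys, replace(cost_template, target=target, T=T_int))
    x_star = goal_state(target)

    decoder.start_trial(cue=cued if decoder.wants_cue else None)
    n_delay = config.n_instruct_bins
    delay = _delay_spikes(pop, cued, n_delay, config.bin_s, rng)
    decoder.decode_delay(delay)

    chol = np.linalg.cholesky(sys.W + 1e-300 * np.eye(6))
    cursor = np.zeros(2)
    v_int = np.zeros(2)
    f_int = np.zeros(2)
    spikes_move, kin_move, positions = [], [], []
    centers = target_positions(config)
    for t in range(1, config.n_timeout_bins + 1):
        x_fb = np.concatenate([cursor, v_int, f_int])
        u = -gains.gain(t) @ (x_fb - x_star)
        x_int = sys.A @ x_fb + sys.B @ u + chol @ rng.standard_normal(6)
        v_int, f_int = x_int[2:4], x_int[4:6]
        state = np.concatenate([cursor, v_int, f_int])
        dN = _bernoulli_spikes(
            _movement_rates(pop, state[None, :])[:, 0], config.bin_s, rng)
        cursor = np.asarray(decoder.step(dN), dtype=float)
        spikes_move.append(dN)
        kin_move.append(np.concatenate([cursor, v_int, f_int]))
        positions.append(cursor.copy())
        d2 = np.sum((centers - cursor) ** 2, axis=1)
        if np.any(d2 <= config.target_radius**2):
            break
    positions = np.asarray(positions)
    outcome = score_trial(positions, config, cued)
    spikes = np.concatenate([delay, np.array(spikes_move).T], axis=1)
    kinematics = np.vstack([np.zeros((n_delay, 6)), np.asarray(kin_move)])
    return TrialRecord(
        cued_target=cued, spikes=spikes, kinematics=kinematics,
        epoch_marks=(0, n_delay), outcome=outcome,
        intended_duration_bins=T_int,
    )


def run_session(
    n_trials: int = 89,
    mode: str = "manual",
    pop: GroundTruthPopulation | None = None,
    decoder: OnlineDecoder | None = None,
    config: TaskConfig | None = None,
    sys: LTISystem | None = None,
    cost_template: CostSpec | None = None,
    seed: int = 0,
) -> tuple[list[TrialRecord], SessionSummary]:
    """Simulate a seeded session of manual or closed-loop trials.

    Per-trial random streams are split from the session seed by trial
    counter, so sessions are reproducible and insensitive to trial
    order changes elsewhere.  Decoder exceptions abort the trial and
    the session continues.
    """
    if mode not in ("manual", "closed_loop"):
        raise ValueError("mode must be 'manual' or 'closed_loop'")
    config = config or make_center_out_config()
    if pop is None:
        pop = make_population(seed=seed, config=config)
    if sys is None:
        sys = discretize_plant(PlantParams(dt=config.bin_s))
    cost_template = cost_template or default_cost_template()
    if mode == "closed_loop" and decoder is None:
        raise ValueError("closed-loop mode needs a decoder")
    records: list[TrialRecord] = []
    for i in range(n_trials):
        trial_rng = np.random.default_rng([seed % (2**31), i])
        try:
            if mode == "manual":
                rec = simulate_manual_trial(
                    pop, config, sys, cost_template, trial_rng)
            else:
                rec = simulate_closed_loop_trial(
                    pop, decoder, config, sys, cost_template, trial_rng)
        except Exception:
            if mode == "manual":
                raise
            continue  # decoder failure: trial aborted, session continues
        records.append(rec)
    outcomes = [r.outcome for r in records]
    est = [r.movement_kinematics()[:, :2] for r in records]
    summary = summarize_session(outcomes, est_trajectories=est)
    return records, summary
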