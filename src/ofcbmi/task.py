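"""Center-out task geometry, trial timing, and trial scoring.

The task is an instructed-delay center-out reach: the subject holds a
cursor at the center, one of ``n_targets`` peripheral targets is cued,
a delay elapses, and after the go cue the cursor must enter the cued
target's disk without first touching any other target, all within a
timeout.  A trial in which an incorrect target disk is touched first is
an error even if the correct target is reached afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "TrialOutcome",
    "TrialRecord",
    "make_center_out_config",
    "target_positions",
    "score_trial",
]


class ConfigurationError(ValueError):
    """Raised when a task configuration violates an invariant."""


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and timing of the instructed-delay center-out task.

    Durations are in milliseconds; distances in workspace units
    (``target_distance = 0.1`` corresponds to a ~10 cm reach).
    """

    n_targets: int = 4
    target_angles: tuple[float, ...] = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
    target_distance: float = 0.1
    target_radius: float = 0.025
    hold_ms: int = 500
    instruct_ms: int = 1000
    delay_window_ms: int = 800
    discard_ms: int = 200
    timeout_ms: int = 3000
    bin_ms: int = 5

    def __post_init__(self) -> None:
        if self.n_targets < 2:
            raise ConfigurationError("n_targets must be >= 2")
        if len(self.target_angles) != self.n_targets:
            raise ConfigurationError(
                f"expected {self.n_targets} target angles, got {len(self.target_angles)}"
            )
        if not (0 < self.target_radius < self.target_distance):
            raise ConfigurationError("need 0 < target_radius < target_distance")
        if self.delay_window_ms + self.discard_ms > self.instruct_ms:
            raise ConfigurationError(
                "delay_window_ms + discard_ms must fit inside instruct_ms"
            )
        for name in ("hold_ms", "instruct_ms", "delay_window_ms", "discard_ms",
                     "timeout_ms"):
            if getattr(self, name) % self.bin_ms != 0:
                raise ConfigurationError(f"{name} must be a multiple of bin_ms")

    # -- derived quantities used throughout -----------------------------
    @property
    def bin_s(self) -> float:
        return self.bin_ms / 1000.0

    @property
    def n_instruct_bins(self) -> int:
        return self.instruct_ms // self.bin_ms

    @property
    def n_decode_bins(self) -> int:
        """Number of delay bins entering target decoding (last 800 ms)."""
        return self.delay_window_ms // self.bin_ms

    @property
    def n_timeout_bins(self) -> int:
        return self.timeout_ms // self.bin_ms


def target_positions(config: TaskConfig) -> np.ndarray:
    """(n_targets, 2) array of target center coordinates."""
    ang = np.asarray(config.target_angles, dtype=float)
    return config.target_distance * np.column_stack([np.cos(ang), np.sin(ang)])


def make_center_out_config(**overrides) -> TaskConfig:
    """Build a :class:`TaskConfig` with the standard task defaults.

    Defaults: four targets at the cardinal angles, 500 ms center hold,
    1000 ms instructed delay of which the last 800 ms are used for
    target decoding (the first 200 ms after cue onset are discarded to
    allow the visual information to reach premotor cortex), 3 s
    timeout, 5 ms bins.
    """
    valid = TaskConfig.__dataclass_fields__
    bad = set(overrides) - set(valid)
    if bad:
        raise ConfigurationError(f"unknown TaskConfig fields: {sorted(bad)}")
    if "n_targets" in overrides and "target_angles" not in overrides:
        n = overrides["n_targets"]
        if not isinstance(n, int) or n < 2:
            raise ConfigurationError("n_targets must be an integer >= 2")
        overrides["target_angles"] = tuple(2 * np.pi * k / n for k in range(n))
    return TaskConfig(**overrides)


@dataclass(frozen=True)
class TrialOutcome:
    """Result of scoring one movement-epoch path."""

    success: bool
    first_target_hit: Optional[int]
    cause: str  # "correct" | "incorrect_touch" | "timeout"
    acquisition_time_ms: Optional[float]

    def __post_init__(self) -> None:
        if self.cause not in ("correct", "incorrect_touch", "timeout"):
            raise ValueError(f"invalid cause {self.cause!r}")
        if self.success != (self.cause == "correct"):
            raise ValueError("success flag inconsistent with cause")


@dataclass
class TrialRecord:
    """One trial: spikes, kinematics, and metadata.

    ``spikes`` is a (n_neurons, n_bins) binary array; ``kinematics`` a
    (n_bins, 6) array of [px, py, vx, vy, fx, fy] per bin.  Both cover
    the instruction epoch followed by the movement epoch.
    ``epoch_marks`` are the bin indices of target onset and go cue.
    """

    cued_target: int
    spikes: np.ndarray
    kinematics: np.ndarray
    epoch_marks: tuple[int, int]
    outcome: Optional[TrialOutcome] = None
    intended_duration_bins: Optional[int] = None

    def __post_init__(self) -> None:
        self.spikes = np.ascontiguousarray(self.spikes, dtype=np.uint8)
        self.kinematics = np.ascontiguousarray(self.kinematics, dtype=float)
        if self.spikes.shape[1] != self.kinematics.shape[0]:
            raise ValueError("spikes and kinematics must share the bin count")
        if not self.epoch_marks[0] < self.epoch_marks[1]:
            raise ValueError("epoch marks must be strictly increasing")

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    def delay_decode_spikes(self, config: TaskConfig) -> np.ndarray:
        """Spikes in the decode window: the last 800 ms before the go cue."""
        go = self.epoch_marks[1]
        return self.spikes[:, go - config.n_decode_bins: go]

    def movement_spikes(self) -> np.ndarray:
        return self.spikes[:, self.epoch_marks[1]:]

    def movement_kinematics(self) -> np.ndarray:
        return self.kinematics[self.epoch_marks[1]:]


def score_trial(
    positions: np.ndarray, config: TaskConfig, cued: int
) -> TrialOutcome:
    """Score a movement path against the incorrect-target penalty rule.

    ``positions`` is an (n_bins, 2) sequence of cursor positions sampled
    every ``bin_ms`` starting at the go cue.  The path is walked bin by
    bin; the first bin at which the cursor lies within any target's
    closed disk ends the trial.  The trial succeeds iff that disk is the
    cued target's and the entry time is within the timeout; touching any
    other disk first is an ``incorrect_touch``; never entering a disk
    within the timeout is a ``timeout``.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        raise ValueError("empty movement path")
    if not 0 <= cued < config.n_targets:
        raise ValueError(f"cued target {cued} out of range")
    centers = target_positions(config)
    n_bins = min(positions.shape[0], config.n_timeout_bins)
    # squared distance of every bin to every target center
    d2 = ((positions[:n_bins, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    inside = d2 <= config.target_radius**2
    hit_bins = np.flatnonzero(inside.any(axis=1))
    if hit_bins.size == 0:
        return TrialOutcome(False, None, "timeout", None)
    k = int(hit_bins[0])
    # ties (overlapping disks) resolved by nearest center
    hit = int(np.argmin(np.where(inside[k], d2[k], np.inf)))
    t_ms = (k + 1) * config.bin_ms
    if hit == cued:
        return TrialOutcome(True, hit, "correct", float(t_ms))
    return TrialOutcome(False, hit, "incorrect_touch", float(t_ms))
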