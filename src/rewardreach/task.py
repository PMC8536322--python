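"""Domain types for the speed+accuracy center-out reaching task.

Coordinate convention: positions are in millimeters, with the origin at the
center (start) target's center and y pointing up.  All times are in
milliseconds measured from trial start (the moment the cursor acquired the
center target).

A trial unfolds in three epochs:

* **delay** -- the cursor holds the center target; the reward cue appears
  ``cue_onset_delay`` ms after trial start, and the go cue follows after a
  variable delay drawn from ``delay_range``.
* **reach** -- after the go cue the cursor must enter the peripheral target
  within ``reach_timeout`` ms.
* **target hold** -- the cursor must remain inside the target for
  ``hold_duration`` ms to earn the cued reward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ConfigError",
    "SchemaError",
    "ValidationError",
    "InsufficientDataError",
    "RewardCue",
    "TaskConfig",
    "Trajectory",
    "TrialRecord",
    "ChoiceTrial",
    "OUTCOME_LABELS",
    "FAILURE_LABELS",
    "DEFAULT_REWARD_CUES",
]


class ConfigError(ValueError):
    """Invalid task or generator configuration."""


class SchemaError(ValueError):
    """A data file does not conform to the documented schema."""


class ValidationError(ValueError):
    """Trial-level data failed validation."""


class InsufficientDataError(ValueError):
    """A trajectory is too short for the requested computation."""


#: Exhaustive, mutually exclusive per-trial outcome taxonomy.
OUTCOME_LABELS: Tuple[str, ...] = (
    "success",
    "false_start",
    "delay_drift",
    "undershoot",
    "overshoot",
    "target_hold_drift",
    "other",
)

FAILURE_LABELS: Tuple[str, ...] = tuple(l for l in OUTCOME_LABELS if l != "success")


@dataclass(frozen=True)
class RewardCue:
    """A reward condition: label, juice volume (mL) and presentation frequency."""

    label: str
    magnitude_ml: float
    frequency: float


def _default_cues() -> Tuple[RewardCue, ...]:
    # Jackpot is rare (5% of trials) and 10x the Medium magnitude; the three
    # ordinary cues split the remaining probability mass evenly.
    common = (1.0 - 0.05) / 3.0
    return (
        RewardCue("Small", 0.1, common),
        RewardCue("Medium", 0.2, common),
        RewardCue("Large", 0.3, common),
        RewardCue("Jackpot", 2.0, 0.05),
    )


DEFAULT_REWARD_CUES = _default_cues()


@dataclass(frozen=True)
class TaskConfig:
    """Geometry, timing and reward structure of the speed+accuracy task.

    Defaults are representative of a two-target layout for a macaque reaching
    session.  Lengths are mm, durations ms.
    """

    center_radius: float = 8.0
    target_distance: float = 85.0
    target_radius: float = 8.0
    target_angles: Tuple[float, ...] = (0.0, 180.0)
    cue_onset_delay: float = 200.0
    delay_range: Tuple[float, float] = (400.0, 800.0)
    reach_timeout: float = 900.0
    hold_duration: float = 400.0
    homing_start_fraction: float = 2.0 / 3.0
    homing_proximity: float = 1.0
    homing_buffer: float = 150.0
    #: "boundary": homing ends within ``homing_proximity`` of the target
    #: acceptance boundary (distance to target center <= radius + proximity).
    #: "center": distance to target center <= proximity.
    homing_reference: str = "boundary"
    reward_cues: Tuple[RewardCue, ...] = field(default_factory=_default_cues)

    def __post_init__(self) -> None:
        for name in ("center_radius", "target_distance", "target_radius",
                     "hold_duration", "reach_timeout"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not self.target_angles:
            raise ConfigError("target_angles must be non-empty")
        if not 0.0 < self.homing_start_fraction < 1.0:
            raise ConfigError("homing_start_fraction must lie in (0, 1)")
        if self.homing_proximity <= 0:
            raise ConfigError("homing_proximity must be positive")
        lo, hi = self.delay_range
        if lo > hi:
            raise ConfigError("delay_range min must not exceed max")
        if self.homing_reference not in ("boundary", "center"):
            raise ConfigError("homing_reference must be 'boundary' or 'center'")
        total = sum(c.frequency for c in self.reward_cues)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"reward cue frequencies must sum to 1 (got {total!r})")
        labels = [c.label for c in self.reward_cues]
        if len(set(labels)) != len(labels):
            raise ConfigError("reward cue labels must be unique")

    # -- convenience accessors -------------------------------------------------

    @property
    def cue_labels(self) -> Tuple[str, ...]:
        return tuple(c.label for c in self.reward_cues)

    @property
    def cue_frequencies(self) -> Tuple[float, ...]:
        return tuple(c.frequency for c in self.reward_cues)

    def cue(self, label: str) -> RewardCue:
        for c in self.reward_cues:
            if c.label == label:
                return c
        raise ConfigError(
            f"unknown reward cue {label!r}; configured cues: {list(self.cue_labels)}")

    def magnitude(self, label: str) -> float:
        return self.cue(label).magnitude_ml

    def target_center(self, angle_deg: float) -> np.ndarray:
        """Center of the reach target at ``angle_deg`` (mm, 2-vector)."""
        a = math.radians(angle_deg)
        return self.target_distance * np.array([math.cos(a), math.sin(a)])

    def with_cues(self, cues: Sequence[RewardCue]) -> "TaskConfig":
        return replace(self, reward_cues=tuple(cues))


@dataclass
class Trajectory:
    """Uniformly sampled 2D cursor positions.

    positions : (n, 2) float array, mm.
    sample_period : ms between samples (> 0).
    t0 : time of the first sample relative to trial start, ms.
    """

    positions: np.ndarray
    sample_period: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("positions must be an (n, 2) array")
        if len(self.positions) < 2:
            raise ValidationError("a trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("trajectory contains non-finite coordinates")
        if self.sample_period <= 0:
            raise ValidationError("sample_period must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        """Sample times (ms) relative to trial start."""
        return self.t0 + self.sample_period * np.arange(len(self.positions))

    @classmethod
    def from_irregular(cls, t: np.ndarray, xy: np.ndarray,
                       sample_period: float = 1.0) -> "Trajectory":
        """Resample irregularly timed samples onto a uniform grid.

        Linear interpolation onto a grid starting at ``t[0]`` with step
        ``sample_period`` (ms).
        """
        t = np.asarray(t, dtype=float)
        xy = np.asarray(xy, dtype=float)
        if t.ndim != 1 or len(t) != len(xy):
            raise ValidationError("t and xy must have matching lengths")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        grid = np.arange(t[0], t[-1] + 0.5 * sample_period, sample_period)
        out = np.column_stack([np.interp(grid, t, xy[:, k]) for k in range(2)])
        return cls(out, sample_period=sample_period, t0=float(grid[0]))


@dataclass
class TrialRecord:
    """One trial: metadata, event times, optional recorded outcome, trajectory."""

    subject_id: str
    session_id: str
    trial_index: int
    reward_cue: str
    reward_magnitude: float
    target_angle: float
    delay_duration: float
    go_cue_time: float
    trial_end_time: float
    trajectory: Trajectory
    recorded_outcome: Optional[str] = None

    def validate(self, task: Optional[TaskConfig] = None) -> None:
        if task is not None:
            if self.reward_cue not in task.cue_labels:
                raise ValidationError(
                    f"trial {self.trial_index}: reward_cue {self.reward_cue!r} "
                    f"not among configured cues {list(task.cue_labels)}")
            if self.go_cue_time < task.cue_onset_delay:
                raise ValidationError(
                    f"trial {self.trial_index}: go cue precedes cue onset")
        if self.recorded_outcome is not None and \
                self.recorded_outcome not in OUTCOME_LABELS:
            raise ValidationError(
                f"trial {self.trial_index}: unknown outcome "
                f"{self.recorded_outcome!r}")
        if self.trial_end_time <= 0:
            raise ValidationError(
                f"trial {self.trial_index}: non-positive trial_end_time")


@dataclass(frozen=True)
class ChoiceTrial:
    """One two-target choice trial used to verify cue valuation."""

    subject_id: str
    left_cue: str
    right_cue: str
    chosen_side: str  # "left" or "right"

    def __post_init__(self) -> None:
        if self.chosen_side not in ("left", "right"):
            raise ValidationError("chosen_side must be 'left' or 'right'")

    @property
    def chosen_cue(self) -> str:
        return self.left_cue if self.chosen_side == "left" else self.right_cue
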