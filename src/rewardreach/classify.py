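"""Trial outcome classification.

Every trial receives exactly one label from the task's failure taxonomy, by
checking violations in the temporal order in which the task could end:

1. ``false_start``   -- smoothed speed exceeds an absolute initiation
                        threshold before the go cue;
2. ``delay_drift``   -- the cursor leaves the center target before the go cue
                        without reach-like speed;
3. ``success``       -- the cursor stops inside the reach target (speed below
                        a fraction of the trial's peak) before the reach
                        timeout and remains inside through the hold;
4. ``overshoot``     -- the path passes through or beyond the target region
                        within the timeout without a qualifying stop;
5. ``undershoot``    -- the timeout expires with the target never entered;
6. ``target_hold_drift`` -- the cursor stopped inside the target but exited
                        before the hold completed;
7. ``other``         -- anything else (e.g. a trajectory truncated before the
                        reach epoch), flagged.

The initiation and stop thresholds are configurable; the defaults (50 mm/s
absolute for initiation, 10% of the trial's peak speed for a stop) separate
reach onsets from slow positional drift and a stop from a transit.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .kinematics import DEFAULT_SMOOTHING_MS, speed_profile
from .task import TaskConfig, TrialRecord

__all__ = [
    "INITIATION_SPEED_MM_S",
    "STOP_SPEED_FRACTION",
    "classify_trial",
    "classify_trials",
    "epoch_of_failure",
    "confusion_table",
]

INITIATION_SPEED_MM_S = 50.0
STOP_SPEED_FRACTION = 0.1

_EPOCH_OF = {
    "false_start": "delay",
    "delay_drift": "delay",
    "undershoot": "reach",
    "overshoot": "reach",
    "target_hold_drift": "target_hold",
    "success": "none",
    "other": "none",
}


def classify_trial(trial: TrialRecord, config: TaskConfig,
                   smoothing_window: float = DEFAULT_SMOOTHING_MS,
                   initiation_speed: float = INITIATION_SPEED_MM_S,
                   stop_fraction: float = STOP_SPEED_FRACTION) -> str:
    """Assign one outcome label to a trial (see module docstring)."""
    traj = trial.trajectory
    t = traj.times
    pos = traj.positions
    go = trial.go_cue_time
    speed = speed_profile(traj, smoothing_window)

    # (1) and (2): delay epoch.
    pre = t < go
    if pre.any():
        if np.any(speed[pre] > initiation_speed):
            return "false_start"
        if np.any(np.linalg.norm(pos[pre], axis=1) > config.center_radius):
            return "delay_drift"

    post = (t >= go) & (t <= go + config.reach_timeout)
    if not post.any():
        return "other"
    idx = np.flatnonzero(post)
    tgt = config.target_center(trial.target_angle)
    dist = np.linalg.norm(pos - tgt, axis=1)
    inside = dist <= config.target_radius

    peak = float(speed[idx].max())
    stopped = speed <= stop_fraction * peak if peak > 0 else \
        np.ones_like(speed, dtype=bool)

    # (3)/(6): a qualifying stop inside the target within the timeout.
    cand = np.flatnonzero(post & inside & stopped)
    if cand.size:
        i0 = cand[0]
        hold_end = t[i0] + config.hold_duration
        win = (t >= t[i0]) & (t <= hold_end)
        if t[-1] >= hold_end and bool(inside[win].all()):
            return "success"
        if not bool(inside[win].all()):
            return "target_hold_drift"
        return "other"  # trial truncated during the hold

    # (4): transit through or beyond the target without stopping.
    p_go = pos[idx[0]]
    axis = tgt - p_go
    u = axis / np.linalg.norm(axis)
    proj = (pos[idx] - p_go) @ u
    beyond = np.any(proj > config.target_distance + config.target_radius)
    if bool(inside[idx].any()) or bool(beyond):
        return "overshoot"

    # (5): timed out short of the target.
    if t[-1] >= go + config.reach_timeout - traj.sample_period:
        return "undershoot"
    return "other"


def classify_trials(trials: Sequence[TrialRecord], config: TaskConfig,
                    **kwargs) -> pd.Series:
    """Classify many trials; index follows the input order."""
    return pd.Series([classify_trial(tr, config, **kwargs) for tr in trials],
                     name="outcome")


def epoch_of_failure(label: str) -> str:
    """Map an outcome label to its task epoch (delay / reach / target_hold /
    none)."""
    try:
        return _EPOCH_OF[label]
    except KeyError:
        raise ValueError(f"unknown outcome label {label!r}")


def confusion_table(trials: Sequence[TrialRecord], config: TaskConfig,
                    labels: Optional[Iterable[str]] = None,
                    **kwargs) -> pd.DataFrame:
    """Cross-tabulate classifier labels against recorded outcomes.

    Rows are recorded outcomes, columns classifier labels.  Trials without a
    recorded outcome are omitted.  When recorded outcomes exist they take
    precedence for downstream statistics; this table reports discrepancies.
    """
    recorded, predicted = [], []
    given = list(labels) if labels is not None else None
    for i, tr in enumerate(trials):
        if tr.recorded_outcome is None:
            continue
        recorded.append(tr.recorded_outcome)
        predicted.append(given[i] if given is not None
                         else classify_trial(tr, config, **kwargs))
    if not recorded:
        return pd.DataFrame()
    return pd.crosstab(pd.Series(recorded, name="recorded"),
                       pd.Series(predicted, name="classified"))
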