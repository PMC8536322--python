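"""Per-trial reach kinematics.

Two bespoke metrics drive the analysis:

* **Ballistic endpoint prediction** -- where the reach would have landed with
  no visual-feedback correction.  The vector velocity profile from the go cue
  to the time of peak speed is reflected about the peak (the peak sample used
  once); the resulting symmetric profile is integrated (trapezoid rule) and
  added to the position at the go cue.  For a movement whose velocity really
  is time-symmetric about its peak, the prediction equals the true endpoint;
  in general the mirrored integral equals twice the displacement accrued by
  peak speed.

* **Homing time** -- how long the cursor took to travel from a fixed fraction
  (default 2/3) of the way to the target to within ``homing_proximity``
  (default 1 mm) of the target acceptance boundary, searched up to
  ``reach_timeout + homing_buffer`` after the go cue so that near-miss
  undershoot failures are included.  Progress is measured radially, as the
  projection of displacement since the go cue onto the start->target axis.

Speed profiles use central-difference velocities smoothed with a moving
average (default 25 ms); integration for the ballistic prediction uses the
raw (unsmoothed) velocities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .task import InsufficientDataError, TaskConfig, Trajectory, TrialRecord

__all__ = [
    "DEFAULT_SMOOTHING_MS",
    "speed_profile",
    "vector_velocity",
    "reaction_time",
    "ballistic_endpoint",
    "homing_time",
    "KinematicSummary",
    "summarize_trial",
    "kinematics_frame",
    "RTResult",
    "BallisticResult",
    "HomingResult",
]

DEFAULT_SMOOTHING_MS = 25.0


def vector_velocity(traj: Trajectory) -> np.ndarray:
    """Raw central-difference vector velocity, mm/ms, shape (n, 2)."""
    if len(traj) < 3:
        raise InsufficientDataError("need at least 3 samples for velocity")
    return np.gradient(traj.positions, traj.sample_period, axis=0)


def speed_profile(traj: Trajectory,
                  smoothing_window: float = DEFAULT_SMOOTHING_MS) -> np.ndarray:
    """Smoothed speed (mm/s), same length as the trajectory.

    Central-difference velocity, Euclidean norm, moving average over
    ``smoothing_window`` ms (edges renormalized over the available samples).
    """
    v = vector_velocity(traj)
    speed = np.linalg.norm(v, axis=1) * 1000.0  # mm/ms -> mm/s
    w = max(1, int(round(smoothing_window / traj.sample_period)))
    if w % 2 == 0:
        w += 1
    if w == 1:
        return speed
    kernel = np.ones(w)
    num = np.convolve(speed, kernel, mode="same")
    den = np.convolve(np.ones_like(speed), kernel, mode="same")
    return num / den


@dataclass
class RTResult:
    """Reaction time relative to the go cue (ms); negative values indicate
    pre-go movement (false starts) and are flagged."""

    value: float
    defined: bool
    pre_go: bool = False


def reaction_time(trial: TrialRecord, config: TaskConfig,
                  method: str = "center_exit",
                  speed_fraction: float = 0.1,
                  smoothing_window: float = DEFAULT_SMOOTHING_MS) -> RTResult:
    """Reaction time by center exit or a peak-speed-fraction threshold.

    ``center_exit``: first time the cursor leaves the center target.
    ``speed_threshold``: first time smoothed speed exceeds ``speed_fraction``
    of this trial's (post-go) peak speed.  Both are measured relative to the
    go cue and searched over the whole trajectory, so a false start yields a
    negative, flagged value.
    """
    traj = trial.trajectory
    t = traj.times
    go = trial.go_cue_time
    if method == "center_exit":
        dist = np.linalg.norm(traj.positions, axis=1)
        hits = np.flatnonzero(dist > config.center_radius)
    elif method == "speed_threshold":
        speed = speed_profile(traj, smoothing_window)
        post = t >= go
        if not post.any():
            return RTResult(float("nan"), defined=False)
        peak = float(speed[post].max())
        if peak <= 0:
            return RTResult(float("nan"), defined=False)
        hits = np.flatnonzero(speed > speed_fraction * peak)
    else:
        raise ValueError(f"unknown reaction-time method {method!r}")
    if hits.size == 0:
        return RTResult(float("nan"), defined=False)
    rt = float(t[hits[0]] - go)
    return RTResult(rt, defined=True, pre_go=rt < 0)


@dataclass
class BallisticResult:
    """Ballistic endpoint prediction for one trial."""

    endpoint: np.ndarray          # mm, 2-vector
    distance: float               # mm from the center-target center
    peak_speed: float             # mm/s (smoothed)
    time_of_peak: float           # ms, relative to trial start
    degenerate: bool = False      # peak at the first reach sample


def ballistic_endpoint(trial: TrialRecord, config: TaskConfig,
                       smoothing_window: float = DEFAULT_SMOOTHING_MS
                       ) -> BallisticResult:
    """Mirror the go-to-peak velocity about the peak and integrate.

    The peak is the earliest maximum of the smoothed speed on
    ``[go, go + reach_timeout]``; integration uses the raw vector velocity.
    """
    traj = trial.trajectory
    t = traj.times
    go = trial.go_cue_time
    window = (t >= go) & (t <= go + config.reach_timeout)
    idx = np.flatnonzero(window)
    if idx.size < 2:
        raise InsufficientDataError("trajectory does not cover the reach epoch")
    speed = speed_profile(traj, smoothing_window)
    i_go = idx[0]
    i_peak = idx[int(np.argmax(speed[idx]))]  # argmax -> earliest tie
    p_go = traj.positions[i_go]
    peak_speed = float(speed[i_peak])
    t_peak = float(t[i_peak])
    if i_peak == i_go:
        return BallisticResult(endpoint=p_go.copy(),
                               distance=float(np.linalg.norm(p_go)),
                               peak_speed=peak_speed, time_of_peak=t_peak,
                               degenerate=True)
    v = vector_velocity(traj)[i_go:i_peak + 1]
    mirrored = np.vstack([v, v[-2::-1]])  # peak sample used once
    disp = np.trapezoid(mirrored, dx=traj.sample_period, axis=0)
    endpoint = p_go + disp
    return BallisticResult(endpoint=endpoint,
                           distance=float(np.linalg.norm(endpoint)),
                           peak_speed=peak_speed, time_of_peak=t_peak)


@dataclass
class HomingResult:
    """Homing time for one trial (ms); undefined results are flagged."""

    value: float
    defined: bool
    start_time: float = float("nan")
    end_time: float = float("nan")


def homing_time(trial: TrialRecord, config: TaskConfig) -> HomingResult:
    """Time from ``homing_start_fraction`` of the way to the target until
    first arrival within ``homing_proximity`` of it (see module docstring)."""
    traj = trial.trajectory
    t = traj.times
    go = trial.go_cue_time
    cap = go + config.reach_timeout + config.homing_buffer
    window = (t >= go) & (t <= cap)
    idx = np.flatnonzero(window)
    if idx.size < 2:
        return HomingResult(float("nan"), defined=False)
    pos = traj.positions
    p_go = pos[idx[0]]
    tgt = config.target_center(trial.target_angle)
    axis = tgt - p_go
    u = axis / np.linalg.norm(axis)
    progress = (pos[idx] - p_go) @ u / config.target_distance
    started = np.flatnonzero(progress >= config.homing_start_fraction)
    if started.size == 0:
        return HomingResult(float("nan"), defined=False)
    i_start = idx[started[0]]
    if config.homing_reference == "boundary":
        thresh = config.target_radius + config.homing_proximity
    else:
        thresh = config.homing_proximity
    dist = np.linalg.norm(pos[idx] - tgt, axis=1)
    near = np.flatnonzero((dist <= thresh) & (idx >= i_start))
    if near.size == 0:
        return HomingResult(float("nan"), defined=False)
    i_end = idx[near[0]]
    return HomingResult(float(t[i_end] - t[i_start]), defined=True,
                        start_time=float(t[i_start]),
                        end_time=float(t[i_end]))


@dataclass
class KinematicSummary:
    """Per-trial kinematic metrics."""

    reaction_time: float
    reaction_defined: bool
    pre_go_movement: bool
    peak_speed: float
    time_of_peak: float
    ballistic_endpoint: Tuple[float, float]
    ballistic_distance: float
    ballistic_degenerate: bool
    homing_time: float
    homing_defined: bool


def summarize_trial(trial: TrialRecord, config: TaskConfig,
                    rt_method: str = "center_exit",
                    smoothing_window: float = DEFAULT_SMOOTHING_MS
                    ) -> KinematicSummary:
    rt = reaction_time(trial, config, method=rt_method,
                       smoothing_window=smoothing_window)
    try:
        bal = ballistic_endpoint(trial, config,
                                 smoothing_window=smoothing_window)
    except InsufficientDataError:
        # trial ended before the reach epoch (delay failure)
        nan2 = np.full(2, np.nan)
        bal = BallisticResult(endpoint=nan2, distance=float("nan"),
                              peak_speed=float("nan"),
                              time_of_peak=float("nan"), degenerate=True)
    hom = homing_time(trial, config)
    return KinematicSummary(
        reaction_time=rt.value,
        reaction_defined=rt.defined,
        pre_go_movement=rt.pre_go,
        peak_speed=bal.peak_speed,
        time_of_peak=bal.time_of_peak,
        ballistic_endpoint=(float(bal.endpoint[0]), float(bal.endpoint[1])),
        ballistic_distance=bal.distance,
        ballistic_degenerate=bal.degenerate,
        homing_time=hom.value,
        homing_defined=hom.defined,
    )


def kinematics_frame(trials: Sequence[TrialRecord], config: TaskConfig,
                     **kwargs) -> pd.DataFrame:
    """Flat per-trial metrics table keyed by subject/session/trial_index."""
    rows = []
    for trial in trials:
        s = summarize_trial(trial, config, **kwargs)
        rows.append({
            "subject_id": trial.subject_id,
            "session_id": trial.session_id,
            "trial_index": trial.trial_index,
            "reward_cue": trial.reward_cue,
            "reaction_time": s.reaction_time,
            "reaction_defined": s.reaction_defined,
            "pre_go_movement": s.pre_go_movement,
            "peak_speed": s.peak_speed,
            "time_of_peak": s.time_of_peak,
            "ballistic_x": s.ballistic_endpoint[0],
            "ballistic_y": s.ballistic_endpoint[1],
            "ballistic_distance": s.ballistic_distance,
            "homing_time": s.homing_time,
            "homing_defined": s.homing_defined,
        })
    return pd.DataFrame(rows)
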