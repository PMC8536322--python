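import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rewardreach import (
    TaskConfig,
    Trajectory,
    TrialRecord,
    ballistic_endpoint,
    classify_trial,
    generate_session,
    homing_time,
    paper_like_params,
)
from rewardreach.synth import minimum_jerk_position

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

SWEEP_N = 10_000
SWEEP_SEED = 20_210_823


@pytest.fixture(scope="session")
def task():
    return TaskConfig()


@pytest.fixture(scope="session")
def paper_params():
    return paper_like_params()


@pytest.fixture(scope="session")
def sweep(paper_params):
    """10,000 rendered trials from the reward-graded preset, streamed through
    the classifier and kinematics; one summary row per trial."""
    params = paper_params
    cfg = params.task
    rows = []
    for s in generate_session(params, SWEEP_N, SWEEP_SEED):
        rec = s.record
        row = {
            "cue": rec.reward_cue,
            "truth": s.truth.label,
            "classified": classify_trial(rec, cfg),
            "truth_corrections": s.truth.n_corrections,
            "doubling_rel_err": np.nan,
            "ballistic_distance": np.nan,
            "homing": np.nan,
            "homing_defined": False,
        }
        if s.truth.label not in ("false_start", "delay_drift"):
            traj = rec.trajectory
            t = traj.times
            go = rec.go_cue_time
            bal = ballistic_endpoint(rec, cfg)
            if not bal.degenerate:
                idx = np.flatnonzero((t >= go) & (t <= go + cfg.reach_timeout))
                i_go = idx[0]
                i_pk = int(np.argmin(np.abs(t - bal.time_of_peak)))
                pred = bal.endpoint - traj.positions[i_go]
                doubled = 2.0 * (traj.positions[i_pk] - traj.positions[i_go])
                denom = np.linalg.norm(doubled)
                if denom > 1.0:
                    row["doubling_rel_err"] = \
                        np.linalg.norm(pred - doubled) / denom
                row["ballistic_distance"] = bal.distance
            hom = homing_time(rec, cfg)
            row["homing"] = hom.value
            row["homing_defined"] = hom.defined
        rows.append(row)
    return pd.DataFrame(rows)


def minjerk_trajectory(amplitude, duration, sample_period=1.0, angle=0.0,
                       pre_ms=0.0, post_ms=0.0, truncate_at_peak=False):
    """Noise-free minimum-jerk reach along ``angle`` with optional flat
    padding before and after the movement."""
    u = np.array([np.cos(np.radians(angle)), np.sin(np.radians(angle))])
    t_end = duration / 2.0 if truncate_at_peak else duration + post_ms
    t = np.arange(0.0, pre_ms + t_end + 0.5 * sample_period, sample_period)
    tau = np.clip((t - pre_ms) / duration, 0.0, 1.0)
    pos = amplitude * minimum_jerk_position(tau)[:, None] * u
    return Trajectory(pos, sample_period=sample_period, t0=0.0)


def make_trial(traj, go=0.0, cue="Small", angle=0.0, magnitude=0.1,
               delay=400.0, outcome=None):
    return TrialRecord(
        subject_id="t", session_id="t0", trial_index=0, reward_cue=cue,
        reward_magnitude=magnitude, target_angle=angle, delay_duration=delay,
        go_cue_time=go, trial_end_time=float(traj.times[-1]),
        trajectory=traj, recorded_outcome=outcome)
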