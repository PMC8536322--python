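"""Synthetic session generator for the speed+accuracy task.

The generator is an event-level model of one trial, optionally rendered into a
full cursor trajectory.  Movements are minimum-jerk submovements (symmetric,
bell-shaped velocity profiles), the standard primitive of discrete reaching
models.  Per reward cue the model controls:

* the **ballistic** submovement: fraction of the target distance it covers
  (``ballistic_fraction``), its duration, and 2D Gaussian endpoint noise;
* **corrective** submovements: a Poisson-distributed count, each covering a
  fixed fraction of the remaining distance to the target center;
* per-epoch failure hazards: ``false_start_hazard`` and ``delay_drift_hazard``
  during the delay, ``overshoot_hazard`` for reaches carried through/past the
  target without stopping, and ``hold_drift_hazard`` during the target hold;
* the homing tempo, via ``correction_duration`` and ``ballistic_duration``.

The event simulation assigns a ground-truth outcome label using the task rules
(first violation wins, in temporal order), which makes every rendered trial a
labeled oracle for the outcome classifier and the kinematics code.

RNG contract: ``generate_session(params, n, seed)`` draws the reward sequence
from substream ``[seed, 0]`` and trial ``i`` from substream ``[seed, i + 1]``
(rendering noise from ``[seed, i + 1, 7]``), so trials are independent and any
trial can be regenerated in isolation.  Identical ``(params, seed)`` give
bitwise-identical sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .task import (
    ConfigError,
    RewardCue,
    TaskConfig,
    Trajectory,
    TrialRecord,
)

__all__ = [
    "CueParams",
    "GeneratorParams",
    "TruthInfo",
    "SyntheticTrial",
    "draw_reward_sequence",
    "generate_trial",
    "generate_session",
    "simulate_labels",
    "paper_like_params",
    "null_params",
    "load_preset",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CueParams:
    """Per-reward-condition generator parameters.

    ballistic_fraction : fraction of the target distance covered by the
        ballistic submovement, in (0, 1.5].
    ballistic_duration, correction_duration : ms.
    n_corrections_mean : Poisson mean number of corrective submovements.
    endpoint_noise_sd : per-axis SD (mm) of ballistic endpoint noise.
    false_start_hazard, delay_drift_hazard, hold_drift_hazard,
    overshoot_hazard : per-trial probabilities of the named failure events.
    """

    ballistic_fraction: float = 0.9
    ballistic_duration: float = 300.0
    n_corrections_mean: float = 1.0
    correction_duration: float = 180.0
    endpoint_noise_sd: float = 3.0
    false_start_hazard: float = 0.0
    delay_drift_hazard: float = 0.0
    hold_drift_hazard: float = 0.0
    overshoot_hazard: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.ballistic_fraction <= 1.5:
            raise ConfigError("ballistic_fraction must lie in (0, 1.5]")
        for name in ("ballistic_duration", "correction_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_corrections_mean < 0:
            raise ConfigError("n_corrections_mean must be non-negative")
        if self.endpoint_noise_sd < 0:
            raise ConfigError("endpoint_noise_sd must be non-negative")
        for name in ("false_start_hazard", "delay_drift_hazard",
                     "hold_drift_hazard", "overshoot_hazard"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")


@dataclass(frozen=True)
class GeneratorParams:
    """Full generator configuration: per-cue parameters plus globals."""

    cues: Dict[str, CueParams]
    task: TaskConfig = field(default_factory=TaskConfig)
    sample_period: float = 1.0
    #: SD (mm) of i.i.d. cursor measurement jitter added to rendered samples.
    jitter_sd: float = 0.005
    #: Fraction of the remaining distance covered by each correction.
    correction_gain: float = 0.8
    #: Reaction-time distribution (truncated normal), ms.
    reaction_mean: float = 250.0
    reaction_sd: float = 30.0
    reaction_min: float = 160.0

    def __post_init__(self) -> None:
        if self.sample_period <= 0:
            raise ConfigError("sample_period must be positive")
        missing = [l for l in self.task.cue_labels if l not in self.cues]
        if missing:
            raise ConfigError(f"missing CueParams for cues: {missing}")

    def cue_params(self, label: str) -> CueParams:
        try:
            return self.cues[label]
        except KeyError:
            raise ConfigError(f"no generator parameters for cue {label!r}")


def paper_like_params(task: Optional[TaskConfig] = None) -> GeneratorParams:
    """Preset emulating the published behavioral signatures.

    Ballistic reach fraction shortens and homing slows monotonically with
    reward; overshoots dominate failures for Small rewards and undershoots for
    Jackpots, producing an inverted-U success profile peaking at Large.
    """
    task = task or TaskConfig()
    cues = {
        "Small": CueParams(ballistic_fraction=0.97, ballistic_duration=280.0,
                           n_corrections_mean=1.2, correction_duration=150.0,
                           endpoint_noise_sd=3.0, false_start_hazard=0.03,
                           delay_drift_hazard=0.03, hold_drift_hazard=0.02,
                           overshoot_hazard=0.28),
        "Medium": CueParams(ballistic_fraction=0.93, ballistic_duration=300.0,
                            n_corrections_mean=1.1, correction_duration=170.0,
                            endpoint_noise_sd=3.0, false_start_hazard=0.03,
                            delay_drift_hazard=0.03, hold_drift_hazard=0.02,
                            overshoot_hazard=0.17),
        "Large": CueParams(ballistic_fraction=0.90, ballistic_duration=320.0,
                           n_corrections_mean=1.5, correction_duration=190.0,
                           endpoint_noise_sd=3.0, false_start_hazard=0.03,
                           delay_drift_hazard=0.03, hold_drift_hazard=0.02,
                           overshoot_hazard=0.07),
        "Jackpot": CueParams(ballistic_fraction=0.80, ballistic_duration=340.0,
                             n_corrections_mean=1.0, correction_duration=220.0,
                             endpoint_noise_sd=3.0, false_start_hazard=0.05,
                             delay_drift_hazard=0.03, hold_drift_hazard=0.02,
                             overshoot_hazard=0.02),
    }
    return GeneratorParams(cues=cues, task=task)


def null_params(task: Optional[TaskConfig] = None) -> GeneratorParams:
    """Preset with no reward modulation (all cues behave like Medium)."""
    task = task or TaskConfig()
    base = CueParams(ballistic_fraction=0.93, ballistic_duration=300.0,
                     n_corrections_mean=1.1, correction_duration=170.0,
                     endpoint_noise_sd=3.0, false_start_hazard=0.03,
                     delay_drift_hazard=0.03, hold_drift_hazard=0.02,
                     overshoot_hazard=0.17)
    return GeneratorParams(cues={l: base for l in task.cue_labels}, task=task)


_PRESETS = {"paper_like": paper_like_params, "null": null_params}


def load_preset(name: str, task: Optional[TaskConfig] = None) -> GeneratorParams:
    """Load a named preset ('paper_like' or 'null').

    Presets are also shipped as YAML files under ``rewardreach/presets`` for
    use as CLI config starting points; this function returns the canonical
    in-memory form.
    """
    try:
        return _PRESETS[name](task)
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}")


# ---------------------------------------------------------------------------
# Minimum-jerk primitives
# ---------------------------------------------------------------------------

def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile s(tau) on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


_TAU_GRID = np.linspace(0.0, 1.0, 2049)
_S_GRID = minimum_jerk_position(_TAU_GRID)


def _tau_of_s(s: float) -> float:
    """Inverse of the minimum-jerk position profile (monotone on [0, 1])."""
    return float(np.interp(s, _S_GRID, _TAU_GRID))


def _segment_entry_s(p_a: np.ndarray, p_b: np.ndarray, center: np.ndarray,
                     radius: float) -> Optional[float]:
    """Smallest path fraction s in [0, 1] at which the straight segment
    ``p_a -> p_b`` comes within ``radius`` of ``center`` (None if never)."""
    d = p_b - p_a
    f = p_a - center
    a = float(d @ d)
    c0 = float(f @ f) - radius * radius
    if c0 <= 0.0:
        return 0.0
    if a == 0.0:
        return None
    b = 2.0 * float(d @ f)
    disc = b * b - 4 * a * c0
    if disc < 0.0:
        return None
    s = (-b - np.sqrt(disc)) / (2 * a)
    if 0.0 <= s <= 1.0:
        return float(s)
    return None


def _axis_cross_s(p_a: np.ndarray, p_b: np.ndarray, u: np.ndarray,
                  level: float) -> Optional[float]:
    """Path fraction at which the projection on ``u`` first exceeds ``level``."""
    a0 = float(p_a @ u)
    a1 = float(p_b @ u)
    if a0 >= level:
        return 0.0
    if a1 < level or a1 == a0:
        return None
    s = (level - a0) / (a1 - a0)
    return float(s) if 0.0 <= s <= 1.0 else None


# ---------------------------------------------------------------------------
# Event-level trial simulation
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    """One minimum-jerk submovement from ``p_a`` to ``p_b``."""
    t_start: float
    duration: float
    p_a: np.ndarray
    p_b: np.ndarray


@dataclass
class _Drift:
    """Constant-velocity drift starting at ``t_start`` (mm/ms)."""
    t_start: float
    origin: np.ndarray
    velocity: np.ndarray
    max_dist: Optional[float] = None  # displacement cap, mm


@dataclass
class TrialEvents:
    """Ground-truth event description of one simulated trial."""

    cue: str
    target_angle: float
    delay_duration: float
    go_time: float
    label: str
    end_time: float
    reaction_time: Optional[float] = None
    segments: List[_Segment] = field(default_factory=list)
    drift: Optional[_Drift] = None
    hold_start: Optional[float] = None
    n_corrections: int = 0
    ballistic_endpoint: Optional[np.ndarray] = None
    homing_time: float = float("nan")


@dataclass
class TruthInfo:
    """Generator ground truth attached to a synthetic trial."""

    label: str
    ballistic_endpoint: Optional[np.ndarray]
    homing_time: float
    n_corrections: int
    reaction_time: Optional[float]


@dataclass
class SyntheticTrial:
    """A rendered TrialRecord plus its generator ground truth."""

    record: TrialRecord
    truth: TruthInfo


def _truth_homing(segments: List[_Segment], tgt: np.ndarray, task: TaskConfig,
                  go: float) -> float:
    """Homing time implied by the continuous event description (ms, NaN if
    undefined)."""
    if not segments:
        return float("nan")
    D = task.target_distance
    u = tgt / np.linalg.norm(tgt)
    start_level = task.homing_start_fraction * D
    if task.homing_reference == "boundary":
        prox = task.target_radius + task.homing_proximity
    else:
        prox = task.homing_proximity
    cap = go + task.reach_timeout + task.homing_buffer

    def seg_time(seg: _Segment, s: float) -> float:
        return seg.t_start + seg.duration * _tau_of_s(s)

    t_start = None
    for seg in segments:
        s = _axis_cross_s(seg.p_a, seg.p_b, u, start_level)
        if s is not None:
            t_start = seg_time(seg, s)
            break
    if t_start is None or t_start > cap:
        return float("nan")
    t_end = None
    for seg in segments:
        if seg.t_start + seg.duration < t_start:
            continue
        s = _segment_entry_s(seg.p_a, seg.p_b, tgt, prox)
        if s is not None:
            t = seg_time(seg, s)
            if t >= t_start:
                t_end = t
                break
    if t_end is None or t_end > cap:
        return float("nan")
    return t_end - t_start


def _simulate_events(params: GeneratorParams, cue: str,
                     rng: np.random.Generator) -> TrialEvents:
    """Draw one trial's events and ground-truth label."""
    task = params.task
    cp = params.cue_params(cue)
    D = task.target_distance
    r = task.target_radius

    delay = rng.uniform(*task.delay_range)
    go = task.cue_onset_delay + delay
    angle = float(task.target_angles[rng.integers(len(task.target_angles))])
    tgt = task.target_center(angle)
    u = tgt / np.linalg.norm(tgt)
    ev = TrialEvents(cue=cue, target_angle=angle, delay_duration=delay,
                     go_time=go, label="other", end_time=go)

    # ---- delay epoch ------------------------------------------------------
    if rng.random() < cp.false_start_hazard:
        # Reach initiated before the go cue; the trial aborts shortly after.
        lead = rng.uniform(80.0, 160.0)
        amp = cp.ballistic_fraction * D
        p1 = u * amp + rng.normal(0.0, cp.endpoint_noise_sd, 2)
        ev.reaction_time = -lead
        ev.segments.append(_Segment(go - lead, cp.ballistic_duration,
                                    np.zeros(2), p1))
        ev.label = "false_start"
        ev.end_time = go + 100.0
        return ev

    if rng.random() < cp.delay_drift_hazard:
        # Slow positional drift out of the center target before the go cue.
        onset = task.cue_onset_delay + rng.uniform(0.1, 0.3) * delay
        remaining = go - onset
        speed = (task.center_radius + 2.0) / remaining  # exits with margin
        theta = rng.uniform(0.0, 2 * np.pi)
        vel = speed * np.array([np.cos(theta), np.sin(theta)])
        exit_time = onset + task.center_radius / speed
        ev.drift = _Drift(onset, np.zeros(2), vel)
        ev.label = "delay_drift"
        ev.end_time = exit_time + 100.0
        return ev

    # ---- reach epoch ------------------------------------------------------
    rt = max(params.reaction_min, rng.normal(params.reaction_mean,
                                             params.reaction_sd))
    ev.reaction_time = rt
    t_move = go + rt
    deadline = go + task.reach_timeout

    if rng.random() < cp.overshoot_hazard:
        # Fly-through: the reach is carried through/past the target without a
        # stop inside it.
        amp = (1.15 + rng.exponential(0.08)) * D
        p1 = u * amp + rng.normal(0.0, cp.endpoint_noise_sd, 2)
        k = 0
    else:
        amp = cp.ballistic_fraction * D
        p1 = u * amp + rng.normal(0.0, cp.endpoint_noise_sd, 2)
        k = int(rng.poisson(cp.n_corrections_mean))
    # Brake-failure margin: a reach that fails to stop inside the target does
    # not come to rest a razor's edge past the acceptance boundary.
    d1 = float(np.linalg.norm(p1 - tgt))
    if r < d1 <= r + 1.0 and float(p1 @ u) > D:
        p1 = tgt + (p1 - tgt) * ((r + 1.05) / d1)

    ev.ballistic_endpoint = p1.copy()
    segments = ev.segments
    segments.append(_Segment(t_move, cp.ballistic_duration, np.zeros(2), p1))

    first_entry = np.inf    # time the path first comes within r of target
    first_beyond = np.inf   # time the projection first exceeds D + r

    def note(seg: _Segment) -> None:
        nonlocal first_entry, first_beyond
        s = _segment_entry_s(seg.p_a, seg.p_b, tgt, r)
        if s is not None:
            t = seg.t_start + seg.duration * _tau_of_s(s)
            first_entry = min(first_entry, t)
        s = _axis_cross_s(seg.p_a, seg.p_b, u, D + r)
        if s is not None:
            t = seg.t_start + seg.duration * _tau_of_s(s)
            first_beyond = min(first_beyond, t)

    note(segments[0])
    t_rest = t_move + cp.ballistic_duration
    p = p1
    used = 0
    while True:
        if t_rest > deadline:
            break
        if np.linalg.norm(p - tgt) <= r:
            # Stopped inside the target: hold epoch.
            ev.hold_start = t_rest
            if rng.random() < cp.hold_drift_hazard:
                drift_t = t_rest + rng.uniform(50.0, 180.0)
                theta = rng.uniform(0.0, 2 * np.pi)
                out = p - tgt
                nrm = np.linalg.norm(out)
                direction = out / nrm if nrm > 1e-9 else \
                    np.array([np.cos(theta), np.sin(theta)])
                speed = 0.1  # mm/ms
                travel = r + 4.0 - min(nrm, r)
                ev.drift = _Drift(drift_t, p.copy(), speed * direction,
                                  max_dist=travel)
                ev.label = "target_hold_drift"
                ev.end_time = drift_t + travel / speed + 100.0
            else:
                ev.label = "success"
                ev.end_time = t_rest + task.hold_duration + 60.0
            ev.n_corrections = used
            ev.homing_time = _truth_homing(segments, tgt, task, go)
            return ev
        if used >= k:
            break
        newp = p + params.correction_gain * (tgt - p) + \
            rng.normal(0.0, 0.35 * cp.endpoint_noise_sd, 2)
        seg = _Segment(t_rest, cp.correction_duration, p, newp)
        segments.append(seg)
        note(seg)
        p = newp
        t_rest += cp.correction_duration
        used += 1

    # Reach timeout reached without a qualifying stop inside the target.
    ev.n_corrections = used
    entered = min(first_entry, first_beyond) <= deadline
    ev.label = "overshoot" if entered else "undershoot"
    ev.end_time = deadline + 50.0
    ev.homing_time = _truth_homing(segments, tgt, task, go)
    return ev


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render(ev: TrialEvents, params: GeneratorParams,
            rng: np.random.Generator) -> Trajectory:
    """Render an event description into a uniformly sampled trajectory."""
    sp = params.sample_period
    n = int(np.ceil(ev.end_time / sp)) + 1
    t = np.arange(n) * sp
    pos = np.zeros((n, 2))

    for seg in ev.segments:
        # Rest at the endpoint from segment start onward, then overwrite the
        # in-flight window with the minimum-jerk profile.
        i0 = np.searchsorted(t, seg.t_start)
        pos[i0:] = seg.p_b
        i1 = np.searchsorted(t, seg.t_start + seg.duration, side="right")
        tau = (t[i0:i1] - seg.t_start) / seg.duration
        s = minimum_jerk_position(tau)[:, None]
        pos[i0:i1] = seg.p_a + s * (seg.p_b - seg.p_a)

    if ev.drift is not None:
        d = ev.drift
        i0 = np.searchsorted(t, d.t_start)
        disp = (t[i0:, None] - d.t_start) * d.velocity
        if d.max_dist is not None:
            mag = np.linalg.norm(disp, axis=1)
            scale = np.minimum(mag, d.max_dist) / np.maximum(mag, 1e-12)
            disp = disp * scale[:, None]
        pos[i0:] = d.origin + disp

    if params.jitter_sd > 0:
        pos = pos + rng.normal(0.0, params.jitter_sd, pos.shape)
    return Trajectory(pos, sample_period=sp, t0=0.0)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def draw_reward_sequence(params: GeneratorParams, n_trials: int,
                         rng_seed: int) -> List[str]:
    """Draw ``n_trials`` i.i.d. reward cue labels at the configured
    frequencies (reproducible given ``rng_seed``)."""
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    task = params.task
    freqs = np.asarray(task.cue_frequencies, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ConfigError("reward cue frequencies must sum to 1")
    rng = np.random.default_rng([rng_seed, 0])
    idx = rng.choice(len(freqs), size=n_trials, p=freqs / freqs.sum())
    labels = task.cue_labels
    return [labels[i] for i in idx]


def generate_trial(params: GeneratorParams, cue: str, seed: int,
                   trial_index: int = 0,
                   session_id: str = "synthetic") -> SyntheticTrial:
    """Generate and render a single synthetic trial for ``cue``."""
    rng = np.random.default_rng([seed, trial_index + 1])
    ev = _simulate_events(params, cue, rng)
    noise_rng = np.random.default_rng([seed, trial_index + 1, 7])
    traj = _render(ev, params, noise_rng)
    record = TrialRecord(
        subject_id="synthetic",
        session_id=session_id,
        trial_index=trial_index,
        reward_cue=cue,
        reward_magnitude=params.task.magnitude(cue),
        target_angle=ev.target_angle,
        delay_duration=ev.delay_duration,
        go_cue_time=ev.go_time,
        trial_end_time=float(traj.times[-1]),
        trajectory=traj,
    )
    truth = TruthInfo(label=ev.label, ballistic_endpoint=ev.ballistic_endpoint,
                      homing_time=ev.homing_time,
                      n_corrections=ev.n_corrections,
                      reaction_time=ev.reaction_time)
    return SyntheticTrial(record=record, truth=truth)


def generate_session(params: GeneratorParams, n_trials: int,
                     seed: int) -> List[SyntheticTrial]:
    """Generate a full session of rendered, truth-labeled trials."""
    cues = draw_reward_sequence(params, n_trials, seed)
    sid = f"synthetic-{seed}"
    return [generate_trial(params, cue, seed, i, session_id=sid)
            for i, cue in enumerate(cues)]


def simulate_labels(params: GeneratorParams, n_trials: int, seed: int
                    ) -> Tuple[List[str], List[str]]:
    """Simulate trial outcomes without rendering trajectories.

    Uses the identical event model and RNG substreams as
    :func:`generate_session`, so the returned ``(cues, labels)`` match the
    truth labels of the rendered session for the same seed.  Intended for
    large power / type-I simulations where trajectories are not needed.
    """
    cues = draw_reward_sequence(params, n_trials, seed)
    labels = []
    for i, cue in enumerate(cues):
        rng = np.random.default_rng([seed, i + 1])
        labels.append(_simulate_events(params, cue, rng).label)
    return cues, labels
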