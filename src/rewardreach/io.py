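"""Readers and writers for trial-level behavioral data.

Portable text format (``csv_json``): a directory holding

* ``trials.csv`` -- one row per trial with the metadata fields of
  :class:`~rewardreach.task.TrialRecord` plus the trajectory's sample period
  and first-sample time;
* ``trajectories.csv`` -- long-format samples ``(subject_id, session_id,
  trial_index, t, x, y)``, times in ms, positions in mm.

The round trip ``load_trials(write_trials(trials))`` is the identity on
validated trial lists.

MAT format: deposited kinematic ``.mat`` files vary in internal layout, so
the reader takes a ``field_map`` from the schema's field names to the names
used inside the file.  The expected content is one 1-D array per metadata
field plus an object/cell array of per-trial ``(n_i, 3)`` matrices
``[t, x, y]``.  Both classic (scipy.io) and v7.3 (HDF5, via h5py) files are
supported.  Irregularly timed samples are resampled by linear interpolation
to a uniform grid (default 1 ms).
"""

from __future__ import annotations

import math
import os
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .task import SchemaError, TaskConfig, Trajectory, TrialRecord, ValidationError

__all__ = ["load_trials", "write_trials", "DEFAULT_MAT_FIELD_MAP"]

_META_COLUMNS = [
    "subject_id", "session_id", "trial_index", "reward_cue",
    "reward_magnitude", "target_angle", "delay_duration", "go_cue_time",
    "trial_end_time", "recorded_outcome", "sample_period", "t0",
]
_TRAJ_COLUMNS = ["subject_id", "session_id", "trial_index", "t", "x", "y"]

#: Identity field map for MAT files written by this package's conventions.
DEFAULT_MAT_FIELD_MAP: Dict[str, str] = {
    "subject_id": "subject_id",
    "session_id": "session_id",
    "trial_index": "trial_index",
    "reward_cue": "reward_cue",
    "reward_magnitude": "reward_magnitude",
    "target_angle": "target_angle",
    "delay_duration": "delay_duration",
    "go_cue_time": "go_cue_time",
    "trial_end_time": "trial_end_time",
    "recorded_outcome": "recorded_outcome",
    "trajectories": "trajectories",
}


def write_trials(trials: Sequence[TrialRecord], path, fmt: str = "csv_json"
                 ) -> None:
    """Write trials to ``path`` (a directory) in the portable text format."""
    if fmt != "csv_json":
        raise ValueError(f"write_trials supports 'csv_json', not {fmt!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta_rows, traj_rows = [], []
    for tr in trials:
        meta_rows.append({
            "subject_id": tr.subject_id,
            "session_id": tr.session_id,
            "trial_index": tr.trial_index,
            "reward_cue": tr.reward_cue,
            "reward_magnitude": tr.reward_magnitude,
            "target_angle": tr.target_angle,
            "delay_duration": tr.delay_duration,
            "go_cue_time": tr.go_cue_time,
            "trial_end_time": tr.trial_end_time,
            "recorded_outcome": tr.recorded_outcome,
            "sample_period": tr.trajectory.sample_period,
            "t0": tr.trajectory.t0,
        })
        t = tr.trajectory.times
        xy = tr.trajectory.positions
        traj_rows.append(pd.DataFrame({
            "subject_id": tr.subject_id,
            "session_id": tr.session_id,
            "trial_index": tr.trial_index,
            "t": t, "x": xy[:, 0], "y": xy[:, 1],
        }))
    meta = pd.DataFrame(meta_rows, columns=_META_COLUMNS)
    # %.17g keeps the float64 round trip exact
    meta.to_csv(path / "trials.csv", index=False, float_format="%.17g")
    traj = (pd.concat(traj_rows, ignore_index=True) if traj_rows
            else pd.DataFrame(columns=_TRAJ_COLUMNS))
    traj.to_csv(path / "trajectories.csv", index=False, float_format="%.17g")


def load_trials(path, fmt: str = "csv_json",
                task: Optional[TaskConfig] = None,
                field_map: Optional[Mapping[str, str]] = None,
                resample_period: float = 1.0) -> List[TrialRecord]:
    """Load and validate trials from ``path``.

    ``fmt`` is ``csv_json`` (portable directory format) or ``mat``.
    ``task``, when given, is used to validate reward cues and event times.
    ``field_map`` applies to MAT files only (see module docstring).
    """
    if fmt == "csv_json":
        trials = _load_csv(Path(path), resample_period)
    elif fmt == "mat":
        trials = _load_mat(Path(path), field_map or DEFAULT_MAT_FIELD_MAP,
                           resample_period)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    for tr in trials:
        tr.validate(task)
    return trials


# ---------------------------------------------------------------------------

def _build_trajectory(t: np.ndarray, xy: np.ndarray, trial_index,
                      resample_period: float) -> Trajectory:
    if not np.all(np.isfinite(xy)) or not np.all(np.isfinite(t)):
        raise ValidationError(
            f"trial {trial_index}: non-finite trajectory coordinates")
    dts = np.diff(t)
    if len(dts) == 0:
        raise ValidationError(f"trial {trial_index}: fewer than 2 samples")
    if np.ptp(dts) <= 1e-9:
        return Trajectory(xy, sample_period=float(dts[0]), t0=float(t[0]))
    return Trajectory.from_irregular(t, xy, sample_period=resample_period)


def _load_csv(path: Path, resample_period: float) -> List[TrialRecord]:
    meta_path = path / "trials.csv"
    traj_path = path / "trajectories.csv"
    for p in (meta_path, traj_path):
        if not p.exists():
            raise SchemaError(f"missing file: {p}")
    meta = pd.read_csv(meta_path, dtype={"subject_id": str, "session_id": str},
                       float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"trials.csv missing mandatory fields: {missing}")
    traj = pd.read_csv(traj_path, dtype={"subject_id": str, "session_id": str},
                       float_precision="round_trip")
    missing = [c for c in _TRAJ_COLUMNS if c not in traj.columns]
    if missing:
        raise SchemaError(f"trajectories.csv missing mandatory fields: {missing}")
    grouped = {key: g for key, g in
               traj.groupby(["subject_id", "session_id", "trial_index"])}
    trials = []
    for row in meta.itertuples(index=False):
        key = (row.subject_id, row.session_id, row.trial_index)
        if key not in grouped:
            raise SchemaError(f"no trajectory samples for trial {key}")
        g = grouped[key].sort_values("t")
        t = g["t"].to_numpy(dtype=float)
        xy = g[["x", "y"]].to_numpy(dtype=float)
        trajectory = _build_trajectory(t, xy, row.trial_index, resample_period)
        outcome = row.recorded_outcome
        if isinstance(outcome, float) and math.isnan(outcome):
            outcome = None
        trials.append(TrialRecord(
            subject_id=row.subject_id,
            session_id=row.session_id,
            trial_index=int(row.trial_index),
            reward_cue=row.reward_cue,
            reward_magnitude=float(row.reward_magnitude),
            target_angle=float(row.target_angle),
            delay_duration=float(row.delay_duration),
            go_cue_time=float(row.go_cue_time),
            trial_end_time=float(row.trial_end_time),
            trajectory=trajectory,
            recorded_outcome=outcome,
        ))
    return trials


# ---------------------------------------------------------------------------

def _mat_to_str(value) -> str:
    if isinstance(value, bytes):
        return value.decode()
    if isinstance(value, np.ndarray):
        if value.dtype.kind in ("U", "S"):
            return str(value.ravel()[0]) if value.size else ""
        if value.dtype.kind == "u" and value.ndim >= 1:  # HDF5 char codes
            return "".join(chr(int(c)) for c in np.ravel(value))
    return str(value)


def _load_mat(path: Path, field_map: Mapping[str, str],
              resample_period: float) -> List[TrialRecord]:
    required = set(DEFAULT_MAT_FIELD_MAP) - {"recorded_outcome"}
    missing = required - set(field_map)
    if missing:
        raise SchemaError(f"field_map missing entries for: {sorted(missing)}")
    try:
        from scipy.io import loadmat
        raw = loadmat(path, squeeze_me=False, simplify_cells=False)
        data = {k: raw[v] for k, v in field_map.items() if v in raw}
        reader = "scipy"
    except (NotImplementedError, ValueError):
        import h5py
        data, reader = {}, "h5py"
        with h5py.File(path, "r") as fh:
            for k, v in field_map.items():
                if v in fh:
                    node = fh[v]
                    if isinstance(node, __import__("h5py").Group):
                        data[k] = [np.array(node[name]) for name in
                                   sorted(node, key=lambda s: int(s))]
                    else:
                        data[k] = np.array(node)
    missing = required - set(data)
    if missing:
        raise SchemaError(
            f"MAT file lacks mapped variables for: {sorted(missing)}")

    def column(key):
        return np.ravel(np.asarray(data[key], dtype=object)) \
            if not isinstance(data[key], list) else data[key]

    n = len(column("trial_index"))
    trajs = data["trajectories"]
    if isinstance(trajs, np.ndarray) and trajs.dtype == object:
        trajs = [np.asarray(m, dtype=float) for m in trajs.ravel()]
    if len(trajs) != n:
        raise SchemaError("trajectory count does not match trial count")
    trials = []
    for i in range(n):
        mat = np.asarray(trajs[i], dtype=float)
        if reader == "h5py" and mat.shape[0] == 3 and mat.shape[1] != 3:
            mat = mat.T  # MATLAB v7.3 stores column-major
        if mat.ndim != 2 or mat.shape[1] != 3:
            raise SchemaError(f"trajectory {i} must be an (n, 3) [t, x, y] array")
        trajectory = _build_trajectory(mat[:, 0], mat[:, 1:3],
                                       int(np.ravel(column("trial_index")[i])[0])
                                       if isinstance(column("trial_index")[i],
                                                     np.ndarray)
                                       else column("trial_index")[i],
                                       resample_period)
        outcome = None
        if "recorded_outcome" in data:
            s = _mat_to_str(column("recorded_outcome")[i]).strip()
            outcome = s or None
        trials.append(TrialRecord(
            subject_id=_mat_to_str(column("subject_id")[i]),
            session_id=_mat_to_str(column("session_id")[i]),
            trial_index=int(np.ravel(column("trial_index")[i])[-1]),
            reward_cue=_mat_to_str(column("reward_cue")[i]),
            reward_magnitude=float(np.ravel(column("reward_magnitude")[i])[-1]),
            target_angle=float(np.ravel(column("target_angle")[i])[-1]),
            delay_duration=float(np.ravel(column("delay_duration")[i])[-1]),
            go_cue_time=float(np.ravel(column("go_cue_time")[i])[-1]),
            trial_end_time=float(np.ravel(column("trial_end_time")[i])[-1]),
            trajectory=trajectory,
            recorded_outcome=outcome,
        ))
    return trials
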