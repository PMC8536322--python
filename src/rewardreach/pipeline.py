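"""End-to-end analysis pipeline: config -> tables, metrics, log, report.

A run configuration is a single mapping (YAML/JSON) with sections:

.. code-block:: yaml

    task: {}                      # TaskConfig overrides
    data:
      synthetic:                  # either synthetic ...
        preset: paper_like        # or explicit generator cue params
        n_trials: 2000
        seed: 1
      # trials_path: some/dir     # ... or trial files on disk
      # format: csv_json
    analysis:
      ordering: [Small, Medium, Large, Jackpot]
      n_boot: 10000
      alpha: 0.05
      use_truth_labels: false     # synthetic only: bypass the classifier
    out_dir: results/run1

``run_analysis`` loads or generates trials, classifies them, computes per
trial kinematics and the reward-condition statistics, and writes
``trial_metrics.csv``, ``condition_stats.csv``, ``comparisons.csv``,
``sessions.csv``, ``summary.txt`` and ``run_log.json`` into ``out_dir``.
Given the same config and seed the output bundle is bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .classify import classify_trial
from .kinematics import kinematics_frame
from .model import ChokingModel, ChokingResults
from .stats import DEFAULT_ORDERING, trials_to_frame
from .synth import GeneratorParams, CueParams, generate_session, load_preset
from .task import ConfigError, TaskConfig

__all__ = ["RunBundle", "run_analysis", "make_report", "load_config"]

log = logging.getLogger("rewardreach")

_TABLES = ["trial_metrics.csv", "condition_stats.csv", "comparisons.csv",
           "sessions.csv"]


@dataclass
class RunBundle:
    """Paths and in-memory results of one pipeline run."""

    out_dir: Path
    results: ChokingResults
    tables: Dict[str, Path]
    log_path: Path


def load_config(source) -> dict:
    """Load a config mapping from a dict, YAML/JSON file path, or string."""
    if isinstance(source, dict):
        return source
    path = Path(source)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("run configuration must be a mapping")
    return cfg


def _task_from_config(cfg: dict) -> TaskConfig:
    overrides = dict(cfg.get("task") or {})
    if "reward_cues" in overrides:
        from .task import RewardCue
        overrides["reward_cues"] = tuple(
            RewardCue(**c) if isinstance(c, dict) else RewardCue(*c)
            for c in overrides["reward_cues"])
    if "delay_range" in overrides:
        overrides["delay_range"] = tuple(overrides["delay_range"])
    if "target_angles" in overrides:
        overrides["target_angles"] = tuple(overrides["target_angles"])
    return TaskConfig(**overrides)


def _generator_from_config(data_cfg: dict, task: TaskConfig) -> GeneratorParams:
    syn = data_cfg["synthetic"]
    if "preset" in syn:
        params = load_preset(syn["preset"], task)
    elif "cues" in syn:
        cues = {label: CueParams(**cp) for label, cp in syn["cues"].items()}
        params = GeneratorParams(cues=cues, task=task)
    else:
        raise ConfigError("synthetic data config needs 'preset' or 'cues'")
    globals_ = {k: syn[k] for k in
                ("sample_period", "jitter_sd", "correction_gain",
                 "reaction_mean", "reaction_sd", "reaction_min") if k in syn}
    if globals_:
        params = dataclasses.replace(params, **globals_)
    return params


def run_analysis(config, out_dir=None) -> RunBundle:
    """Execute the full pipeline for ``config`` (see module docstring)."""
    cfg = load_config(config)
    if "data" not in cfg:
        raise ConfigError("config lacks a 'data' section")
    task = _task_from_config(cfg)
    analysis = dict(cfg.get("analysis") or {})
    out_dir = Path(out_dir or cfg.get("out_dir") or "rewardreach_run")

    data_cfg = cfg["data"]
    seed = int(data_cfg.get("synthetic", {}).get("seed", 0))
    if "synthetic" in data_cfg:
        params = _generator_from_config(data_cfg, task)
        n_trials = int(data_cfg["synthetic"].get("n_trials", 1000))
        log.info("generating %d synthetic trials (seed=%d)", n_trials, seed)
        synthetic = generate_session(params, n_trials, seed)
        records = [s.record for s in synthetic]
        if analysis.get("use_truth_labels"):
            outcomes = [s.truth.label for s in synthetic]
        else:
            outcomes = [classify_trial(r, task) for r in records]
    elif "trials_path" in data_cfg:
        from .io import load_trials
        path = Path(data_cfg["trials_path"])
        if not path.exists():
            raise FileNotFoundError(f"trial data not found: {path}")
        records = load_trials(path, fmt=data_cfg.get("format", "csv_json"),
                              task=task,
                              field_map=data_cfg.get("field_map"))
        log.info("loaded %d trials from %s", len(records), path)
        outcomes = [r.recorded_outcome if r.recorded_outcome is not None
                    else classify_trial(r, task) for r in records]
    else:
        raise ConfigError("data section needs 'synthetic' or 'trials_path'")

    out_dir.mkdir(parents=True, exist_ok=True)
    metrics = kinematics_frame(records, task)
    metrics["outcome"] = outcomes
    frame = trials_to_frame(records, outcomes=outcomes)

    ordering = tuple(analysis.get("ordering", DEFAULT_ORDERING))
    model = ChokingModel(frame, ordering=ordering)
    results = model.fit(n_boot=int(analysis.get("n_boot", 10_000)),
                        seed=seed,
                        alpha=float(analysis.get("alpha", 0.05)),
                        extra_pairs=[tuple(p) for p in
                                     analysis.get("extra_pairs", [])])

    tables = {}
    metrics.to_csv(out_dir / "trial_metrics.csv", index=False)
    tables["trial_metrics"] = out_dir / "trial_metrics.csv"
    results.condition_frame().to_csv(out_dir / "condition_stats.csv", index=False)
    tables["condition_stats"] = out_dir / "condition_stats.csv"
    results.comparisons_frame().to_csv(out_dir / "comparisons.csv", index=False)
    tables["comparisons"] = out_dir / "comparisons.csv"
    sessions = (results.sessions.sessions if results.sessions is not None
                else pd.DataFrame())
    sessions.to_csv(out_dir / "sessions.csv", index=False)
    tables["sessions"] = out_dir / "sessions.csv"
    (out_dir / "summary.txt").write_text(results.summary() + "\n")
    tables["summary"] = out_dir / "summary.txt"

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    log_payload = {
        "package_version": __version__,
        "seed": seed,
        "n_trials": len(records),
        "config_hash": cfg_hash,
        "config": cfg,
        "choking": bool(results.choking),
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log_payload, indent=2, sort_keys=True,
                                   default=str) + "\n")
    return RunBundle(out_dir=out_dir, results=results, tables=tables,
                     log_path=log_path)


def make_report(bundle, out_dir=None) -> List[Path]:
    """Render summary figures and text from a completed run bundle.

    Accepts a :class:`RunBundle` or a bundle directory; returns the paths
    written (success curve, outcome proportions, kinematic medians by cue,
    and a plain-text report).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(bundle, RunBundle):
        directory = bundle.out_dir
    else:
        directory = Path(bundle)
    missing = [name for name in _TABLES
               if not (directory / name).exists()]
    if missing:
        raise FileNotFoundError(
            f"bundle at {directory} is missing tables: {missing}")
    out_dir = Path(out_dir or directory)
    out_dir.mkdir(parents=True, exist_ok=True)

    cond = pd.read_csv(directory / "condition_stats.csv")
    metrics = pd.read_csv(directory / "trial_metrics.csv")
    written = []

    fig, ax = plt.subplots(figsize=(5, 4))
    x = range(len(cond))
    yerr = cond["bootstrap_se"].fillna(0.0)
    ax.errorbar(x, cond["success_rate"], yerr=yerr, marker="o", color="k")
    ax.set_xticks(list(x), cond["reward_cue"])
    ax.set_ylim(0, 1)
    ax.set_ylabel("success rate")
    fig.tight_layout()
    p = out_dir / "success_curve.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    prop_cols = [c for c in cond.columns if c.startswith("prop_")]
    fig, ax = plt.subplots(figsize=(5, 4))
    bottom = cond["success_rate"].to_numpy().copy()
    ax.bar(x, cond["success_rate"], label="success", color="forestgreen")
    for c in prop_cols:
        vals = cond[c].to_numpy()
        if vals.sum() == 0:
            continue
        ax.bar(x, vals, bottom=bottom, label=c.removeprefix("prop_"))
        bottom = bottom + vals
    ax.set_xticks(list(x), cond["reward_cue"])
    ax.set_ylabel("proportion of trials")
    ax.legend(fontsize="small")
    fig.tight_layout()
    p = out_dir / "outcome_proportions.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    order = list(cond["reward_cue"])
    med = (metrics[metrics["homing_defined"] == True]  # noqa: E712
           .groupby("reward_cue")["homing_time"].median()
           .reindex(order))
    ax.plot(range(len(order)), med, marker="s", color="tab:blue",
            label="median homing time (ms)")
    bal = metrics.groupby("reward_cue")["ballistic_distance"].mean() \
        .reindex(order)
    ax2 = ax.twinx()
    ax2.plot(range(len(order)), bal, marker="o", color="tab:red",
             label="mean ballistic distance (mm)")
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel("median homing time (ms)", color="tab:blue")
    ax2.set_ylabel("mean ballistic distance (mm)", color="tab:red")
    fig.tight_layout()
    p = out_dir / "kinematics_by_reward.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    report = out_dir / "report.txt"
    lines = ["rewardreach analysis report", "=" * 28, "",
             (directory / "summary.txt").read_text()]
    report.write_text("\n".join(lines))
    written.append(report)
    return written
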