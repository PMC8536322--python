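"""Model / Results interface over the choking analysis.

``ChokingModel`` is built from trial-level data (a tidy DataFrame, or trial
records which it classifies); ``fit`` runs the reward-condition battery and
returns a ``ChokingResults`` carrying the estimates, bootstrap uncertainties,
pairwise tests and plotting/summary helpers, in the style of a statsmodels
model.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import classify as _classify
from . import stats as _stats
from .task import TaskConfig

__all__ = ["ChokingModel", "ChokingResults"]


class ChokingModel:
    """Reward-graded performance model for one or more pooled sessions.

    Parameters
    ----------
    trials : DataFrame with ``reward_cue`` and ``outcome`` columns
        (``subject_id`` / ``session_id`` enable the per-session analysis).
    ordering : reward cues from smallest to largest incentive; defaults to
        Small / Medium / Large / Jackpot.
    """

    def __init__(self, trials: pd.DataFrame,
                 ordering: Sequence[str] = _stats.DEFAULT_ORDERING):
        if not {"reward_cue", "outcome"} <= set(trials.columns):
            raise ValueError("trials must have 'reward_cue' and 'outcome' columns")
        self.data = trials.reset_index(drop=True)
        self.ordering = tuple(ordering)

    @classmethod
    def from_trials(cls, trials: Sequence, task: Optional[TaskConfig] = None,
                    ordering: Sequence[str] = _stats.DEFAULT_ORDERING,
                    use_recorded: bool = True) -> "ChokingModel":
        """Build from TrialRecords / SyntheticTrials.

        Outcomes come from, in order of preference: the recorded outcome
        (when present and ``use_recorded``), the generator truth label, or the
        outcome classifier (which requires ``task``).
        """
        outcomes = []
        for tr in trials:
            rec = getattr(tr, "record", tr)
            if use_recorded and rec.recorded_outcome is not None:
                outcomes.append(rec.recorded_outcome)
            elif hasattr(tr, "truth"):
                outcomes.append(tr.truth.label)
            else:
                if task is None:
                    raise ValueError("task config required to classify trials")
                outcomes.append(_classify.classify_trial(rec, task))
        frame = _stats.trials_to_frame(trials, outcomes=outcomes)
        return cls(frame, ordering=ordering)

    def fit(self, n_boot: int = _stats.DEFAULT_N_BOOT, seed=None,
            alpha: float = 0.05,
            extra_pairs: Sequence[Tuple[str, str]] = ()) -> "ChokingResults":
        profile = _stats.choking_profile(
            self.data, ordering=self.ordering, n_boot=n_boot, seed=seed,
            alpha=alpha, extra_pairs=extra_pairs)
        sessions = None
        if {"subject_id", "session_id"} <= set(self.data.columns):
            peak, top = self.ordering[-2], self.ordering[-1]
            sessions = _stats.session_choking_counts(
                self.data, peak_cue=peak, top_cue=top, alpha=alpha)
        return ChokingResults(self, profile, sessions)


class ChokingResults:
    """Fitted choking analysis: estimates, uncertainties, tests, summaries."""

    def __init__(self, model: ChokingModel, profile: _stats.ChokingProfile,
                 sessions: Optional[_stats.SessionChokingResult] = None):
        self.model = model
        self.profile = profile
        self.sessions = sessions

    # -- accessors -----------------------------------------------------------

    @property
    def ordering(self) -> Tuple[str, ...]:
        return self.profile.ordering

    @property
    def success_rates(self) -> pd.Series:
        return self.profile.success_rates

    @property
    def bootstrap_se(self) -> pd.Series:
        return pd.Series({c: self.profile.stats[c].bootstrap_se
                          for c in self.ordering})

    @property
    def choking(self) -> bool:
        """True when the top condition underperforms the peak significantly."""
        return self.profile.choking

    def condition_frame(self) -> pd.DataFrame:
        rows = []
        for cue in self.ordering:
            s = self.profile.stats[cue]
            row = {"reward_cue": cue, "n_trials": s.n_trials,
                   "n_success": s.n_success, "success_rate": s.success_rate,
                   "bootstrap_se": s.bootstrap_se}
            for mode, p in sorted(s.failure_mode_proportions.items()):
                row[f"prop_{mode}"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.profile.comparisons:
            rows.append({"cue_a": c.cue_a, "cue_b": c.cue_b,
                         "delta_pp": c.delta_pp, "statistic": c.statistic,
                         "p_value": c.p_value, "stars": c.significant_at,
                         "test": c.test_name})
        return pd.DataFrame(rows)

    def decompose(self, cue_a: str, cue_b: str) -> Dict[str, float]:
        """Failure-mode contributions (pp) to the cue_a -> cue_b change."""
        return _stats.failure_mode_decomposition(self.profile.stats[cue_a],
                                                 self.profile.stats[cue_b])

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable summary table."""
        cond_rows = []
        for cue in self.ordering:
            s = self.profile.stats[cue]
            cond_rows.append([cue, str(s.n_trials),
                              f"{100 * s.success_rate:.1f}",
                              f"{100 * s.bootstrap_se:.2f}"
                              if np.isfinite(s.bootstrap_se) else "--"])
        cond = SimpleTable(
            cond_rows,
            headers=["reward", "trials", "success %", "boot SE (pp)"],
            title="Success by reward condition")
        comp_rows = []
        for c in self.profile.comparisons:
            comp_rows.append([f"{c.cue_a} vs {c.cue_b}",
                              f"{c.delta_pp:+.1f}", f"{c.statistic:+.2f}",
                              f"{c.p_value:.3g}", c.significant_at])
        comp = SimpleTable(
            comp_rows,
            headers=["comparison", "delta (pp)", "z", "p", ""],
            title="Binomial proportion tests")
        peak, top = self.ordering[-2], self.ordering[-1]
        verdict = (f"Choking detected: {top} success rate is significantly "
                   f"below {peak} (alpha={self.profile.alpha})."
                   if self.choking else
                   f"No significant {peak}->{top} performance decrement "
                   f"(alpha={self.profile.alpha}).")
        parts = [cond.as_text(), "", comp.as_text(), "", verdict]
        if self.sessions is not None and self.sessions.counts:
            lines = [f"  {subj}: choked in {nc}/{nt} sessions"
                     for subj, (nc, nt) in sorted(self.sessions.counts.items())]
            parts += ["", "Per-session point decrements:"] + lines
        return "\n".join(parts)

    def plot_success_curve(self, ax=None):
        """Success rate vs reward condition with bootstrap error bars."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(self.ordering))
        rates = self.success_rates.to_numpy()
        ses = self.bootstrap_se.to_numpy()
        ax.errorbar(x, rates, yerr=np.where(np.isfinite(ses), ses, 0.0),
                    marker="o", color="k")
        ax.set_xticks(x, self.ordering)
        ax.set_ylabel("success rate")
        ax.set_xlabel("reward condition")
        ax.set_ylim(0, 1)
        return ax

    def plot_failure_modes(self, ax=None):
        """Stacked per-condition outcome proportions (success at the base)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(self.ordering))
        bottom = np.zeros(len(self.ordering))
        rates = self.success_rates.to_numpy()
        ax.bar(x, rates, bottom=bottom, label="success", color="forestgreen")
        bottom += rates
        modes = sorted({m for cue in self.ordering
                        for m, p in
                        self.profile.stats[cue].failure_mode_proportions.items()
                        if p > 0})
        for mode in modes:
            props = np.array([self.profile.stats[c]
                              .failure_mode_proportions.get(mode, 0.0)
                              for c in self.ordering])
            ax.bar(x, props, bottom=bottom, label=mode)
            bottom += props
        ax.plot(x, rates, color="k", marker="o")
        ax.set_xticks(x, self.ordering)
        ax.set_ylabel("proportion of trials")
        ax.legend(fontsize="small")
        return ax
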