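"""Reward-condition statistics for choking-under-pressure analyses.

The battery mirrors standard practice for this kind of behavioral dataset:

* per-condition success rates with bootstrap standard errors (SD over
  resamples-with-replacement of the trials, default 10,000 resamples);
* two-sample binomial proportion z-tests (pooled variance, two-sided) for
  rates, Welch's t for means, Mann-Whitney U (with medians) for heavy-tailed
  timing metrics;
* the "choking profile": condition stats along a reward ordering plus the
  low-vs-peak and peak-vs-top comparisons, with a choking flag when the top
  (Jackpot-like) condition performs significantly worse than the peak
  (Large-like) condition;
* per-session choking counts (point decrement rule, significance reported
  alongside);
* the failure-mode decomposition of a success-rate difference;
* choice-task preference summaries.

Trial-level inputs are tidy pandas DataFrames with at least ``reward_cue``
and ``outcome`` columns (``subject_id`` / ``session_id`` where needed);
``trials_to_frame`` builds one from TrialRecord / SyntheticTrial sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .task import FAILURE_LABELS, OUTCOME_LABELS, ChoiceTrial

__all__ = [
    "RewardConditionStats",
    "ComparisonResult",
    "ChokingProfile",
    "SessionChokingResult",
    "trials_to_frame",
    "condition_stats",
    "binomial_proportion_test",
    "welch_t",
    "mann_whitney",
    "choking_profile",
    "session_choking_counts",
    "failure_mode_decomposition",
    "choice_preference",
]

DEFAULT_N_BOOT = 10_000
DEFAULT_ORDERING = ("Small", "Medium", "Large", "Jackpot")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class RewardConditionStats:
    """Summary of one reward condition."""

    cue: str
    n_trials: int
    n_success: int
    success_rate: float
    bootstrap_se: float
    failure_mode_proportions: Dict[str, float]

    def proportion(self, label: str) -> float:
        if label == "success":
            return self.success_rate
        return self.failure_mode_proportions.get(label, 0.0)


@dataclass
class ComparisonResult:
    """A two-condition comparison."""

    cue_a: str
    cue_b: str
    delta_pp: float          # (rate_a - rate_b) * 100, percentage points
    statistic: float
    p_value: float
    test_name: str
    extra: Dict[str, float] = field(default_factory=dict)

    @property
    def significant_at(self) -> str:
        """Star code at the conventional 0.01 / 0.001 levels."""
        if self.p_value < 1e-3:
            return "***"
        if self.p_value < 1e-2:
            return "**"
        return ""


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def trials_to_frame(trials: Sequence, outcomes: Optional[Sequence[str]] = None
                    ) -> pd.DataFrame:
    """Tidy trial table from TrialRecords or SyntheticTrials.

    For SyntheticTrials the generator truth label fills ``outcome`` unless
    ``outcomes`` (e.g. classifier output) is given; for TrialRecords the
    recorded outcome is used when present.
    """
    rows = []
    for i, tr in enumerate(trials):
        rec = getattr(tr, "record", tr)
        if outcomes is not None:
            outcome = outcomes[i]
        elif hasattr(tr, "truth"):
            outcome = tr.truth.label
        else:
            outcome = rec.recorded_outcome
        rows.append({
            "subject_id": rec.subject_id,
            "session_id": rec.session_id,
            "trial_index": rec.trial_index,
            "reward_cue": rec.reward_cue,
            "outcome": outcome,
        })
    return pd.DataFrame(rows)


def condition_stats(trials: pd.DataFrame, cue: str,
                    n_boot: int = DEFAULT_N_BOOT,
                    seed=None) -> RewardConditionStats:
    """Success rate, bootstrap SE and failure-mode proportions for one cue.

    The bootstrap resamples the cue's trials with replacement ``n_boot``
    times (same size as the original) and takes the SD of the resampled
    success rates; ``n_boot = 0`` skips it (SE reported as NaN).
    """
    sub = trials.loc[trials["reward_cue"] == cue, "outcome"]
    n = len(sub)
    if n == 0:
        present = sorted(trials["reward_cue"].unique())
        raise ValueError(f"no trials for cue {cue!r}; cues present: {present}")
    succ = (sub == "success").to_numpy()
    k = int(succ.sum())
    rate = k / n
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        rates = np.empty(n_boot)
        chunk = max(1, min(n_boot, 4_000_000 // max(n, 1)))
        for start in range(0, n_boot, chunk):
            m = min(chunk, n_boot - start)
            idx = rng.integers(0, n, size=(m, n))
            rates[start:start + m] = succ[idx].mean(axis=1)
        se = float(rates.std(ddof=1))
    else:
        se = float("nan")
    counts = sub.value_counts()
    failure_props = {lab: float(counts.get(lab, 0)) / n
                     for lab in FAILURE_LABELS}
    return RewardConditionStats(cue=cue, n_trials=n, n_success=k,
                                success_rate=rate, bootstrap_se=se,
                                failure_mode_proportions=failure_props)


def binomial_proportion_test(k1: int, n1: int, k2: int, n2: int
                             ) -> ComparisonResult:
    """Two-sided two-sample binomial proportion z-test (pooled variance)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("success counts must satisfy 0 <= k <= n")
    total = k1 + k2
    if total == 0 or total == n1 + n2:
        z, p = 0.0, 1.0
    else:
        z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    delta_pp = (k1 / n1 - k2 / n2) * 100.0
    return ComparisonResult(cue_a="a", cue_b="b", delta_pp=delta_pp,
                            statistic=float(z), p_value=float(p),
                            test_name="binomial_proportion_z")


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]
            ) -> ComparisonResult:
    """Welch's unequal-variance t-test (two-sided)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise ValueError("degenerate zero-variance samples")
    res = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        cue_a="a", cue_b="b",
        delta_pp=float(a.mean() - b.mean()),
        statistic=float(res.statistic), p_value=float(res.pvalue),
        test_name="welch_t",
        extra={"mean_a": float(a.mean()), "mean_b": float(b.mean()),
               "df": float(res.df)})


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]
                 ) -> ComparisonResult:
    """Two-sided Mann-Whitney U with tie correction; medians reported."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each sample needs at least 1 value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u, p = len(a) * len(b) / 2.0, 1.0
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        u, p = float(res.statistic), float(res.pvalue)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return ComparisonResult(cue_a="a", cue_b="b",
                            delta_pp=med_a - med_b,
                            statistic=u, p_value=p,
                            test_name="mann_whitney_u",
                            extra={"median_a": med_a, "median_b": med_b})


# ---------------------------------------------------------------------------
# Choking profile and session analysis
# ---------------------------------------------------------------------------

@dataclass
class ChokingProfile:
    """Per-cue statistics plus the key pairwise comparisons."""

    stats: Dict[str, RewardConditionStats]
    comparisons: List[ComparisonResult]
    ordering: Tuple[str, ...]
    alpha: float
    choking: bool

    def comparison(self, cue_a: str, cue_b: str) -> ComparisonResult:
        for c in self.comparisons:
            if (c.cue_a, c.cue_b) == (cue_a, cue_b):
                return c
        raise KeyError(f"no comparison {cue_a!r} vs {cue_b!r}")

    @property
    def success_rates(self) -> pd.Series:
        return pd.Series({c: self.stats[c].success_rate for c in self.ordering})


def choking_profile(trials: pd.DataFrame,
                    ordering: Sequence[str] = DEFAULT_ORDERING,
                    n_boot: int = DEFAULT_N_BOOT,
                    seed=None, alpha: float = 0.05,
                    extra_pairs: Sequence[Tuple[str, str]] = ()
                    ) -> ChokingProfile:
    """Pooled-trial choking analysis along a reward ordering.

    Compares the lowest condition against the penultimate ("peak") condition
    and the peak against the top (Jackpot-like) condition, plus any
    ``extra_pairs``.  The choking flag is set when the peak condition's
    success rate exceeds the top condition's with p < alpha.
    """
    ordering = tuple(ordering)
    if len(ordering) < 2:
        raise ValueError("ordering needs at least two cues")
    present = set(trials["reward_cue"].unique())
    missing = [c for c in ordering if c not in present]
    if missing:
        raise ValueError(
            f"cues {missing} absent from data; cues present: {sorted(present)}")
    low, peak, top = ordering[0], ordering[-2], ordering[-1]
    pairs = [(low, peak), (peak, top)] + list(extra_pairs)
    wanted = list(ordering) + [c for pair in extra_pairs for c in pair
                               if c not in ordering]
    stats = {}
    for j, cue in enumerate(wanted):
        sub_seed = None if seed is None else [int(seed), j]
        stats[cue] = condition_stats(trials, cue, n_boot=n_boot, seed=sub_seed)
    comparisons = []
    for cue_a, cue_b in pairs:
        sa, sb = stats[cue_a], stats[cue_b]
        c = binomial_proportion_test(sa.n_success, sa.n_trials,
                                     sb.n_success, sb.n_trials)
        c.cue_a, c.cue_b = cue_a, cue_b
        comparisons.append(c)
    peak_vs_top = comparisons[1]
    choking = (stats[peak].success_rate > stats[top].success_rate
               and peak_vs_top.p_value < alpha)
    return ChokingProfile(stats=stats, comparisons=comparisons,
                          ordering=ordering, alpha=alpha, choking=choking)


@dataclass
class SessionChokingResult:
    """Session-by-session choking summary."""

    counts: Dict[str, Tuple[int, int]]   # subject -> (n_choking, n_total)
    sessions: pd.DataFrame
    excluded: List[Tuple[str, str]]      # (subject, session) lacking a cue


def session_choking_counts(trials: pd.DataFrame,
                           peak_cue: str = "Large",
                           top_cue: str = "Jackpot",
                           alpha: float = 0.05) -> SessionChokingResult:
    """Count sessions where the top-reward success rate sits below the peak's.

    A session counts as choking on a point decrement (top rate strictly below
    peak rate); per-session binomial-test significance is reported alongside,
    because top-reward trials are rare within single sessions.  Sessions
    lacking either cue are excluded and listed.
    """
    rows, excluded = [], []
    counts: Dict[str, List[int]] = {}
    for (subject, session), sub in trials.groupby(["subject_id", "session_id"],
                                                  sort=True):
        by_cue = sub.groupby("reward_cue")["outcome"]
        have = set(by_cue.groups)
        if peak_cue not in have or top_cue not in have:
            excluded.append((subject, session))
            continue
        peak = by_cue.get_group(peak_cue)
        top = by_cue.get_group(top_cue)
        kp, np_ = int((peak == "success").sum()), len(peak)
        kt, nt = int((top == "success").sum()), len(top)
        test = binomial_proportion_test(kp, np_, kt, nt)
        choked = (kp / np_) > (kt / nt)
        rows.append({
            "subject_id": subject, "session_id": session,
            "n_peak": np_, "rate_peak": kp / np_,
            "n_top": nt, "rate_top": kt / nt,
            "delta_pp": test.delta_pp, "p_value": test.p_value,
            "choked": choked, "significant": test.p_value < alpha,
        })
        c = counts.setdefault(subject, [0, 0])
        c[0] += int(choked)
        c[1] += 1
    return SessionChokingResult(
        counts={s: (c[0], c[1]) for s, c in counts.items()},
        sessions=pd.DataFrame(rows),
        excluded=excluded)


def failure_mode_decomposition(stats_a: RewardConditionStats,
                               stats_b: RewardConditionStats
                               ) -> Dict[str, float]:
    """Per-failure-mode contribution (pp) to the success-rate change a -> b.

    Each mode contributes ``(proportion_b - proportion_a) * 100``; because
    proportions sum to one within each condition, the contributions sum to
    the negated success-rate difference exactly.
    """
    modes = sorted(set(stats_a.failure_mode_proportions)
                   | set(stats_b.failure_mode_proportions))
    return {m: (stats_b.failure_mode_proportions.get(m, 0.0)
                - stats_a.failure_mode_proportions.get(m, 0.0)) * 100.0
            for m in modes}


def choice_preference(choices: Sequence[ChoiceTrial],
                      magnitudes: Mapping[str, float]) -> pd.DataFrame:
    """Preference for the higher-magnitude cue, per unordered cue pair.

    For pairs of equal magnitude the ``preference`` column is NaN and
    ``side_bias`` reports the proportion of rightward choices.
    """
    if not choices:
        raise ValueError("need at least one choice trial")
    buckets: Dict[Tuple[str, str], List[ChoiceTrial]] = {}
    for ch in choices:
        key = tuple(sorted((ch.left_cue, ch.right_cue)))
        buckets.setdefault(key, []).append(ch)
    rows = []
    for (cue_a, cue_b), trs in sorted(buckets.items()):
        ma, mb = magnitudes[cue_a], magnitudes[cue_b]
        n = len(trs)
        if ma == mb:
            right = sum(ch.chosen_side == "right" for ch in trs)
            rows.append({"cue_a": cue_a, "cue_b": cue_b, "n": n,
                         "preference": float("nan"),
                         "side_bias": right / n})
        else:
            higher = cue_a if ma > mb else cue_b
            won = sum(ch.chosen_cue == higher for ch in trs)
            rows.append({"cue_a": cue_a, "cue_b": cue_b, "n": n,
                         "preference": won / n,
                         "side_bias": float("nan")})
    return pd.DataFrame(rows)
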