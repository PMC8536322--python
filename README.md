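# rewardreach

Analysis toolkit for **reward-modulated reaching behavior** — in particular,
"choking under pressure": the paradoxical drop in success rate when an
exceptionally large, rare (Jackpot) reward is at stake, after performance has
improved monotonically from small to large rewards (an inverted-U).

It is aimed at motor-psychophysics and behavioral-neuroscience labs running
center-out reaching tasks in which each trial cues one of several graded
rewards and the subject must reach fast *and* accurately: acquire a center
target, wait through a delay, reach to a peripheral target within a timeout,
and hold it (400 ms by default) to earn the cued reward.

## What it computes

**Reach kinematics** (`rewardreach.kinematics`)

- *Ballistic endpoint prediction*: where the reach would have landed without
  visual-feedback correction. With $v(t)$ the vector velocity from the go cue
  and $t_p$ the time of peak speed, the go-to-peak profile is reflected about
  $t_p$ and integrated:

  $$\hat{x}_{\text{ball}} = x(t_{go}) + \int v_{\text{mirrored}}(t)\,dt
    = x(t_{go}) + 2\big(x(t_p) - x(t_{go})\big).$$

  For a movement with a time-symmetric velocity profile this equals the true
  endpoint exactly.
- *Homing time*: the time to travel from a fixed fraction (default 2/3) of
  the way to the target until first coming within 1 mm of the target
  acceptance boundary, searched up to 150 ms past the reach timeout so that
  near-miss undershoots are included.
- Reaction time (center-exit or speed-threshold), smoothed speed profiles,
  peak speed.

**Outcome classification** (`rewardreach.classify`) — every trial gets exactly
one label, first violation wins in temporal order: `false_start`,
`delay_drift`, `success`, `overshoot`, `undershoot`, `target_hold_drift`,
`other`, each mapped to its task epoch (delay / reach / target-hold).

**Reward statistics** (`rewardreach.stats`, `rewardreach.model`) — per-cue
success rates with 10,000-resample bootstrap SEs; two-sample binomial
proportion z-tests (pooled variance), Welch's t, Mann–Whitney U with medians;
the choking profile (Small↔Large and Large↔Jackpot comparisons, with a
choking flag when Jackpot significantly underperforms Large); per-session
choking counts; the failure-mode decomposition of any success-rate change
(contributions sum exactly to the negated success delta); choice-task
preference summaries.

**Synthetic sessions** (`rewardreach.synth`) — an event-level generative model
of a trial (minimum-jerk ballistic submovement + Poisson corrective
submovements + per-epoch failure hazards) with ground-truth labels, used to
validate the entire pipeline. The `paper_like` preset reproduces the
signature phenomenology: reward-graded ballistic shortening, reward-graded
homing slowing, overshoot-dominant failures for Small rewards and
undershoot-dominant failures for Jackpots, yielding an inverted-U.

## Worked example

```python
import pandas as pd
from rewardreach import ChokingModel, paper_like_params, simulate_labels

params = paper_like_params()
cues, labels = simulate_labels(params, 4000, seed=55)
frame = pd.DataFrame({"subject_id": "m", "session_id": "s0",
                      "trial_index": range(len(cues)),
                      "reward_cue": cues, "outcome": labels})
results = ChokingModel(frame).fit(n_boot=10_000, seed=55)
print(results.summary())
```

```
     Success by reward condition     
=====================================
 reward trials success % boot SE (pp)
-------------------------------------
  Small   1269      66.3         1.32
 Medium   1247      69.4         1.30
  Large   1273      72.1         1.27
Jackpot    211      63.0         3.30
-------------------------------------

         Binomial proportion tests          
============================================
   comparison    delta (pp)   z      p      
--------------------------------------------
  Small vs Large       -5.8 -3.19 0.00143 **
Large vs Jackpot       +9.1 +2.69  0.0072 **
--------------------------------------------

Choking detected: Jackpot success rate is significantly below Large (alpha=0.05).

Per-session point decrements:
  m: choked in 1/1 sessions
```

Success improves from Small (66.3%) to Large (72.1%), then drops for Jackpot
(63.0%) — a 9.1 percentage-point decrement (z = 2.7, p = 0.007) despite the
Jackpot being the most valuable reward: the inverted-U.
`results.decompose("Large", "Jackpot")` attributes +16.7 pp of the change to
extra undershoots (over-cautious reaches that come up short), partly offset
by fewer overshoots (−5.4 pp).

The same analysis runs from the shell on simulated or recorded sessions:

```bash
rewardreach simulate --preset paper_like -n 2000 --seed 1 --out session/
rewardreach analyze --config run.yaml
rewardreach report results/run/
```

## Data formats

Portable text format: a directory with `trials.csv` (one row per trial:
`subject_id, session_id, trial_index, reward_cue, reward_magnitude,
target_angle, delay_duration, go_cue_time, trial_end_time, recorded_outcome,
sample_period, t0`; times in ms, positions in mm, origin at the center
target) and `trajectories.csv` (`subject_id, session_id, trial_index, t, x,
y`). `write_trials`/`load_trials` round-trip losslessly. MAT files
(classic or v7.3) are read through a user-supplied `field_map`, since
deposited files differ in internal naming; irregular timestamps are
resampled to a uniform grid (default 1 ms).

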