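# Methods

## Task model

A trial of the speed+accuracy task unfolds in three epochs. The cursor
acquires a center target (radius 8 mm by default); the reward cue appears
200 ms later; the go cue follows a variable delay (uniform on 400–800 ms).
The subject must then bring the cursor into a peripheral target (default
85 mm away, radius 8 mm, at one of two diametrically opposed angles) within
the reach timeout (900 ms) and hold it for 400 ms. Coordinates are mm with
the origin at the center-target center; times are ms from trial start. Four
reward cues are drawn i.i.d. per trial: Small / Medium / Large at equal
frequency and a Jackpot worth 10× the Medium volume on 5% of trials. All
geometry, timing and cue structure are configurable (`TaskConfig`).

## Outcome taxonomy

Every trial receives exactly one label, assigned by the first rule violated
in temporal order:

1. **false_start** — smoothed speed exceeds an absolute initiation threshold
   (50 mm/s) before the go cue;
2. **delay_drift** — the cursor leaves the center target pre-go without
   reach-like speed;
3. **success** — a qualifying stop inside the target (speed below 10% of the
   trial's peak) before the timeout, remaining inside through the hold;
4. **overshoot** — the path passes through or beyond the target region within
   the timeout without a qualifying stop;
5. **undershoot** — the timeout expires with the target never entered;
6. **target_hold_drift** — a qualifying stop followed by an exit before the
   hold completes;
7. **other** — anything else (flagged), e.g. a trajectory truncated before
   the reach epoch.

The initiation and stop thresholds are declared approximations: the
experimental control software that produced any given dataset had its own
debounce rules, so when a recorded outcome is present it takes precedence
for statistics and the classifier's label is only used for a discrepancy
report (`confusion_table`).

## Kinematic metrics

**Speed profile.** Central-difference velocities, Euclidean norm, moving
average over 25 ms (configurable; edges renormalized). Integration for the
ballistic prediction uses the *raw* velocities; smoothing only locates the
peak (earliest maximum on [go, go+timeout], ties broken by earliest time).

**Ballistic endpoint.** The vector velocity from the go cue to the time of
peak speed is reflected about the peak (peak sample used once) and
integrated by the trapezoid rule. Algebraically the prediction equals the
go-cue position plus twice the displacement accrued by peak time, which the
test suite exploits as a cross-check ("doubling identity", asserted to 0.1%
on every generated reach). A peak at the first reach sample is degenerate:
the go-cue position is returned, flagged.

**Homing time.** Progress is the projection of displacement since the go cue
onto the start→target axis, divided by the target distance (a path-length
option is deliberately not provided; radial projection is the simplest
reading of "fraction of the way to the target"). The window starts when
progress first reaches `homing_start_fraction` (default 2/3) and ends at
first arrival within `homing_proximity` (default 1 mm) of the target
*acceptance boundary* (distance to target center ≤ radius + proximity); a
center-referenced variant is available via `homing_reference="center"`. The
boundary reference is the default because the proximity buffer exists to
include near-miss undershoots, which implies closeness to the region the
subject must enter. The search is truncated at timeout + 150 ms; windows
that never start or never end are undefined, flagged, excluded from medians
and counted in exclusion tallies. Note that raising the start fraction can
only shorten the window (the endpoint is unchanged), and widening the
proximity can only advance the endpoint; both monotonicities are enforced by
property tests.

## Statistics

Success rates are compared with a two-sample binomial proportion z-test
(pooled variance, two-sided; delegated to
`statsmodels.stats.proportion.proportions_ztest`); means (peak speed,
ballistic distances) with Welch's t; timing metrics (reaction, homing) with
medians and Mann–Whitney U, because their distributions are heavy-tailed.
Standard errors of any per-condition summary are bootstrap SEs: resample the
condition's trials with replacement (same n) 10,000 times and take the SD of
the resampled metric. No multiple-testing correction is applied —
comparisons are reported per pair with conventional star levels (0.01,
0.001) — matching standard practice for this analysis style.

The **choking profile** pools trials across sessions (within-session Jackpot
counts are small at 5% frequency), computes per-cue stats along a reward
ordering, and tests low-vs-peak (Small↔Large) and peak-vs-top
(Large↔Jackpot) plus any configured extra pairs (e.g. rarity- or
magnitude-matched control cues). The choking flag requires the top condition
to sit below the peak with p < α (default 0.05). **Session counts** use a
point decrement (top rate strictly below peak rate; ties do not count)
because per-session significance is underpowered at realistic Jackpot
counts; per-session p-values are reported alongside. The **failure-mode
decomposition** of a success-rate change is exact bookkeeping: per-condition
label proportions partition unity, so per-mode differences (in percentage
points) sum to the negated success delta identically.

## Synthetic generator

The generator is an event-level trial model rendered, on demand, into
uniformly sampled trajectories; it exists to give the pipeline labeled
ground truth, not to be a biomechanical model.

* **Submovements** are minimum-jerk: position profile
  s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, giving a symmetric velocity profile with peak
  speed 1.875·A/T. This symmetry makes the ballistic-endpoint metric
  analytically checkable, which is why the primitive was chosen.
* **Ballistic phase**: amplitude `ballistic_fraction` × target distance plus
  2D Gaussian endpoint noise; reaction times are truncated normal
  (250 ± 30 ms, floor 160 ms).
* **Corrections**: a Poisson count, each covering a fixed fraction (0.8) of
  the remaining vector to the target center with scaled-down noise; each
  correction costs `correction_duration` ms, so slow homing plus a finite
  timeout produces undershoots mechanically.
* **Hazards**: per-trial Bernoulli events for false starts (movement onset
  80–160 ms pre-go), delay drifts (slow constant-velocity drift that exits
  the center before the go cue at well under the initiation threshold),
  target-hold drifts (outward drift 50–180 ms into the hold at 100 mm/s),
  and fly-through overshoots (the reach is carried to ≥1.15× target distance
  without stopping). Fly-through overshoot is a separate hazard rather than
  an amplitude tail because reaches that "fail to stop" a fraction of a
  millimeter past the acceptance boundary are classifiable only by
  arbitrary convention; for the same reason a non-stopping rest point is
  never placed within 1 mm beyond the boundary (brake-failure margin).
* **Rendering** adds i.i.d. cursor jitter (SD 0.005 mm) to every sample —
  measurement noise, deliberately small so that razor-edge boundary crossings
  are rare. Trial-end behavior matches the task rules (delay failures end
  ~100 ms after detection, timeouts 50 ms after the deadline, successes after
  the hold completes).
* **RNG contract**: one root seed; the reward sequence uses substream
  `[seed, 0]` and trial i uses `[seed, i+1]` (rendering noise `[seed, i+1,
  7]`), so sessions are bitwise reproducible, trials are independent, and
  the label-only fast path (`simulate_labels`) replays exactly the rendered
  session's event stream.

The `paper_like` preset grades `ballistic_fraction` 0.97→0.80,
`ballistic_duration` 280→340 ms and `correction_duration` 150→220 ms from
Small to Jackpot, with overshoot hazard falling (0.28→0.02) and a slightly
elevated Jackpot false-start hazard. These constants are engineering
choices, set once to produce the qualitative signatures the analysis is
meant to detect — a Small→Large improvement of roughly 8 pp, a
Large→Jackpot decrement of roughly 17 pp carried by undershoots, and
homing-time medians ordered by reward — at magnitudes representative of the
phenomenon. The `null` preset gives all cues the Medium parameters and is
used for type-I error checks.

**What the generator does not emulate**: across-trial learning or
adaptation, satiation, biomechanics (curvature, joint dynamics), eye
movements, session-to-session drift, and any correlation between consecutive
trials. Passing tests therefore demonstrate that the pipeline's measurements
and inferences are correct for data with the assumed structure, not that the
behavioral phenomenon itself is inevitable in real subjects.

## Numerical choices and problem sizes

Sampling is 1 ms throughout (configurable). Segment/region intersection
times in the generator's truth bookkeeping are found by inverting the
minimum-jerk position profile on a 2049-point grid (max interpolation error
≪ 1 ms). CSV round trips use 17-significant-digit floats so
`load_trials(write_trials(x)) == x` bitwise. The classifier/ground-truth
agreement and the doubling identity are validated on a 10,000-trial rendered
sweep; detection power and false-positive rates on 200 replicates of
4,000-trial sessions (label-only fast path); these sizes give binomial
standard errors comfortably below the margins being asserted while keeping
the default test suite around two minutes. Residual classifier/truth
disagreement (~0.3%) consists of rest points within cursor jitter of the
target boundary — decision-boundary geometry on which any convention is
defensible.

## Known limitations

- The generator's failure hazards are Bernoulli per trial, not time-resolved
  hazard rates; epoch durations therefore do not modulate failure risk.
- Reaction-time distributions do not vary with reward by default, although
  per-cue timing parameters make idiosyncratic patterns easy to emulate.
- The MAT reader expects one variable per metadata field plus a cell array
  of per-trial [t, x, y] matrices; struct-array layouts must be flattened to
  that shape (the `field_map` handles renaming only).
- `binomial_proportion_test` is asymptotic; for very small arms an exact
  test would be preferable (the test suite bounds its disagreement with
  Fisher's exact test on representative counts).
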