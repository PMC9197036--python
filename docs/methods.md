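# Methods

## Trajectory model

Each subject starts at time 0 in state S1 (first catheter in place). The
S1 sojourn `T1` is drawn from a configurable family with the arm's mean
first-catheter duration (defaults 1.8269 d standard, 2.1226 d bundled). If
`T1` reaches the 14-day horizon the subject is censored in S1. Otherwise
the removal class is drawn: with the arm's unscheduled-removal probability
(235/495, 172/494) the exit is a complication (E4–E8, type from a
configurable mix) and the subject enters S3 with a second catheter;
otherwise the exit is a routine removal (E1–E3, uniform mix) into S2. The
S2/S3 sojourn is then drawn (means 3.59/3.85 d and 7.79/7.77 d); if it
ends before the horizon the subject is absorbed — death with the arm's
death probability (5/495, 8/494), discharge otherwise — else censored.
Time is continuous in days; "day k" means the half-open interval
[k−1, k). Subjects are censored, not absorbed, at 14 days.

This factorisation (sojourn, then removal class, then event type, then
death at trajectory end) reproduces the three published marginals —
removal proportions, S1 sojourn means, death proportions — without access
to the joint patient-level data. It also makes event class independent of
catheter duration, which the real data need not satisfy.

### Sojourn families

Only sojourn *means* are published, plus the observed S1 occupancy
fractions at 1.4/2.8/4.2 days (51/19/6% standard, 58/27/11% bundled).
An exponential S1 sojourn with the published means puts too much early
mass: its bundled-arm survival at 1.4 d is 0.52, incompatible with the
observed 0.58 even under a generous ±0.05 band. A gamma with shape 2 and
the same means reproduces all six published fractions within ~0.03, so S1
defaults to `gamma(shape=2)`. For S2/S3 no shape information is published
and the default stays exponential (the maximum-entropy choice given a
mean). Family (`exponential | gamma | weibull`) and shape are
configurable per state group; all choices preserve the configured means.

The unpublished mixture over the five complication types defaults to
uniform. Reverse-engineering the two scenario analyses' published cost
drops implies a mean complication-treatment cost of ≈ €7.4–7.5, very
close to the uniform-mix mean €7.56, which supports the default.

## Cost accrual

Per catheter, from the unit-cost schedule (Euro 2022, antiseptic cost
already averaged in):

* S1: day 1 = initial placement + one daily use; every further *started*
  day one daily use (this reproduces the published day-1 sums 20.51/23.01
  exactly).
* Event at S1 exit: removal (E1–E3), or removal + complication treatment
  + second-catheter placement (E4–E8). The published per-catheter event
  cells satisfy this additive identity exactly in the bundled column and
  to €0.01 in the standard column (printed carry); the component sum is
  treated as canonical.
* S3: daily use over the *fractional* duration of the second-catheter
  episode. The episode's end is the subject's absorption; when the
  subject is still in S3 at the horizon the episode runs to the horizon,
  i.e. its duration is horizon − placement day, the stated convention for
  an unknown removal date.
* Terminal: one removal if the subject reaches discharge or death with a
  catheter in place (from S1 or S3). Censored subjects are still
  hospitalised, so no removal is charged.

Per-patient cost = per-catheter cost × catheters-per-patient coefficient
(1.5/1.3), rounded to cents **half-even** only at reporting (half-even,
not half-up, reproduces the published per-patient cells 30.76 and 24.38
simultaneously); all internal arithmetic keeps full precision.

### Catheter-time adjustment

The reported "mean cost per patient, adjusted on catheter-time"
multiplies each arm's raw mean by (longest arm mean S1 sojourn)/(own arm
mean S1 sojourn), so the shorter-exposure standard arm is scaled up by
the coefficient 2.1226/1.8269 = 1.1618 and the bundled arm is unchanged.
Two published facts pin this down: the coefficient is introduced together
with the adjusted cost table, and the scenario-without-complication-costs
deltas (€13.12/€7.92 per arm) reconcile with the component arithmetic
only when the standard column carries the 1.1618 factor. The adjustment
sojourns default to the unscheduled-removal subgroup's durations (the
published convention; configurable to whole-arm). Per-PVC-day values are
the per-patient values divided by the same arm mean S1 sojourn, and the
report layer cross-checks that identity at render time.

### Scenarios

* **base** — 0–14 days, all subjects, all components.
* **s1** — subgroup with first-catheter duration > 24 h, or ≤ 24 h with a
  studied complication; full accrual for included subjects. The published
  scenario-1 means *rise* relative to base, which subgroup selection
  produces and day-window clipping cannot, so the 2–14-day observation
  window is implemented as this inclusion rule. (A general day-window
  clip remains available on `trajectory_cost`.)
* **s2** — all subjects, complication-specific costs (treatment +
  second-catheter placement) excluded. The published per-arm drops match
  this definition to ≈ €0.1; excluding treatment alone cannot reach them.

## Inference

Exact odds-ratio inference for the 2×2 removal table uses the conditional
maximum-likelihood estimate with the exact central interval from the
noncentral hypergeometric distribution (scipy), cross-checked in the
tests against an independent likelihood-grid maximiser; the logistic
check is a one-covariate binomial GLM (statsmodels) whose saturated-case
closed form (ad/bc) anchors its test.

Bootstrap: subjects are resampled with replacement within arm; cost,
effectiveness, and the sojourn means entering the adjustment are
recomputed jointly in each replicate; intervals are empirical percentile
intervals (linear order-statistic interpolation, numpy quantile
convention), the only interval type implemented. The CE plane is the
scatter of (Δ removals per PVC-day, Δ cost per PVC-day), bundled minus
standard, over replicates; deltas are oriented so negative cost and
negative removal differences favour the bundle, stated in every output
header. The dominance verdict uses the point deltas: dominant/dominated
for concordant signs, an ICER otherwise, with a "cost difference only"
label when the effectiveness difference is exactly zero.

## Numerical and degenerate-input conventions

* Occupancy at an entry instant uses the half-open convention: the
  subject is in the new state at its entry time; absorbing/censored
  occupancy persists through the horizon (the final segment is closed).
* `markov_cycle_length` is the pooled mean over all transient-state
  segments. Under the default parameters this is ≈ 3.2 d (S1 ≈ 2.0 d,
  S2 ≈ 3.5 d, S3 ≈ 6 d pooled); the published 1.4-day reporting cycle is
  close to the pooled S1 *median* and any grid is accepted.
* Config and schedule validation raises errors naming the offending
  field; empty arms, never-visited states, unsorted grids, zero margins
  and sub-2 bootstrap samples raise explicit `ValueError`s.
* Seeds: cohort generation and every bootstrap are driven by explicit
  integer seeds (numpy `default_rng`); identical seeds give bit-identical
  cohorts, reports and CE planes.

## What the synthetic generator does and does not show

The generator reproduces the published arm sizes, removal probabilities,
sojourn means, S1 occupancy curve, death rates and censoring scheme, so
passing tests show the *pipeline* (occupancy, costing, adjustment,
bootstrap, dominance logic) is correct under the trial's marginal
conditions. It does not reproduce joint features of the real data —
duration/complication dependence, non-gamma duration shapes, per-type
complication frequencies — so simulated cost levels are expected to match
the published means only to within their published bootstrap intervals
(checked over many seeds in the tests: large-cohort expectations ≈ €147
standard / €106 bundled vs published €144.24 / €102.11), not exactly.
The published state-3 occupancy percentages (24/45% standard at 1.4/4.2
days) are not reachable by any sojourn family consistent with the
published removal probabilities and are treated as descriptive, not as
calibration targets.

## Problem sizes used in the checks

Trial-scale runs use the published 495/494 subjects and 1,000 bootstrap
replicates. Distribution-level calibration checks (occupancy anchors,
marginal probabilities, sojourn means, cost-level inclusion) use 10,000
subjects per arm, where binomial noise (±1%) is small against the
published intervals; trial-size inclusion is additionally checked across
20 seeds, where sampling scatter makes inclusion a majority property
rather than a certainty.
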