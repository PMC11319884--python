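# Methods

## Scope

`inrkit` implements the computational core of a two-arm warfarin
anticoagulation management study: the quality metric (Rosendaal TTR), the
management protocol engines (dose titration, monitoring schedule), the
cohort comparison statistics, and a synthetic cohort generator that stands
in for patient data. The patient-facing management application itself
(education modules, reminders, messaging) is out of scope; only the
decision rules it operationalises are modelled.

## INR classification and target ranges

Target ranges ship as a versioned config (indication → [lower, upper],
overridable per deployment, since valve ranges vary between centres). With
margin 0.2 and extreme cut-off 4.5, the five classes partition (0, ∞):

| class | band |
|---|---|
| extreme subtherapeutic | INR < L − 0.2 |
| subtherapeutic | L − 0.2 ≤ INR < L |
| therapeutic | L ≤ INR ≤ U |
| supratherapeutic | U < INR ≤ 4.5 |
| extreme supratherapeutic | INR > 4.5 |

Printed definitions of the supratherapeutic band sometimes start it at
U + 0.2, which would leave (U, U+0.2] unassigned; we treat that as a
transcription slip and let supratherapeutic cover all of (U, 4.5], because
the subtherapeutic side shows the 0.2 margin lies *inside* the adjacent
band, not outside the partition. A `boundary_policy: therapeutic` config
switch instead folds (U, U+0.2] into the therapeutic class (mirroring the
dose engine's no-change zone) for sites that classify that way. Combined
indications resolve to the range with the highest upper limit; ties break
by the higher lower limit (the tie-break is our plumbing choice — only
"higher range wins" is protocol).

## Rosendaal TTR

Crossing times of L and U are computed in continuous days (no rounding —
whole-day rounding shifts TTR by >1% on short series) and each consecutive
pair contributes the half-open interval [t₁, t₂), so days are never double
counted and below+in+above equals the interpolated span exactly. Same-day
duplicate measurements collapse to the last value of the day (logged).
Fewer than two usable measurements leave the TTR undefined; undefined
patients are excluded from effectiveness denominators. Interpolation
crosses gaps of any length by default, as in the original formulation; a
`max_gap_days` cap (56 days is a common choice elsewhere) can exclude long
gaps. Effectiveness is the strict inequality TTR > 0.65.

## Dose engine

Rules in priority order at each check, doses in tablets/day quantised to
0.25 (tablet strength in mg is deliberately not modelled):

1. holding and INR ≤ 3 → resume at pre-hold dose − 0.25 (applied once
   regardless of hold length);
2. holding and INR > 3 → keep holding, recheck in 1 day;
3. INR > 3 → hold one day, recheck in 1 day;
4. INR < L − 0.2 → +0.25;
5. U + 0.2 < INR ≤ 3 → −0.25;
6. otherwise (within ±0.2 of the limits) → no change.

The hold rule is unconditional, so for ranges with U ≥ 2.8 the decrease
window (U+0.2, 3] is empty — the printed inequality already implies this.
Doses floor at 0 with a logged warning. The monitoring ladder judges "in
range" against the strict therapeutic class by default (a
`schedule_in_range: margin` switch uses the ±0.2 band instead, since
protocol wording is ambiguous).

## Synthetic cohort generative model

Per patient *i* with prescribed dose *d* (tablets/day):

* sensitivity s_i ~ LogNormal(median 2.0 INR/tablet, CV 0.30); log s
  performs a random walk with daily SD 0.02 (diet/interaction drift);
* steady state INR_ss(d) = 1 + s_i·d_effective, where d_effective = d on
  adherent days (Bernoulli with per-patient probability ~ Beta matched to
  the arm mean, concentration 8) and 0 otherwise;
* daily dynamics INR_{t+1} = INR_t + 0.18·(INR_ss − INR_t) + N(0, 0.06),
  floored at 0.6 (the approach rate 0.18/day gives warfarin's ~3–4-day
  response half-time);
* observed INR = true INR · exp(N(0, 0.05)) at each visit;
* visits follow the monitoring ladder, stretched by a multiplicative
  log-normal delay factor floored at 1 (patients are late, never early):
  sigma 0.05 (web arm) / 0.6 (conventional arm); hold rechecks are subject
  to the same delay;
* daily hazards: minor bleed 3.5·10⁻⁴·exp(8.0·max(0, INR−U)), severe
  bleed 2.5·10⁻⁵ with the same supratherapeutic slope, thromboembolism
  6·10⁻⁵·exp(1.2·max(0, L−INR)); severe bleeding or thromboembolism is
  fatal with probability 0.2, and death censors the trajectory;
* indication mix 97% valve surgery (30/55/12 aortic/mitral/tricuspid) and
  3% atrial fibrillation/VTE; initial dose titrated to the range midpoint
  and discharge INR 80% of the way to steady state.

The two arms share identical dose and schedule rules; they differ **only**
in adherence (0.98 web vs 0.74 conventional) and visit delay — the two
behavioural mechanisms remote management plausibly improves. The
conventional arm's low adherence value is an *effective* parameter: it
absorbs every unmodelled compliance mechanism (missed and self-adjusted
doses, diet nonadherence), not a literal pill count.

### Calibration

Defaults are a documented calibration, not an empirical claim: they were
chosen so that at cohort scale the arms bracket mean TTRs of roughly 82%
vs 72%, effectiveness proportions near 83% vs 65%, therapeutic-class
record shares ordered web > conventional, and minor-bleeding incidence
near 7% vs 12%. Two findings from the calibration are worth recording.
First, visit delay alone cannot separate *measured* TTR: sparse Rosendaal
interpolation smooths away almost exactly the extra out-of-range time that
longer gaps create, so delay is a secondary mechanism. Second, the
dominant separating mechanism is daily adherence noise — intake variance
p(1−p)(s·d)² filtered through the AR(1) — which both depresses the
conventional arm's mean INR and makes the titration engine chase it.
The supratherapeutic hazard slope is steep (8 per INR unit) because the
arms' supratherapeutic *exposure* differs much less than their bleeding
incidence should; the slope converts the conventional arm's deeper
excursions into the required event gradient.

Reproducibility: every patient draws from an independent RNG substream
spawned from the master seed, so cohorts are byte-identical across runs
and stable under cohort-size changes.

### What the simulator does not emulate

No pharmacokinetic/genotype model (CYP2C9/VKORC1), no clinician deviation
from the written rules (real protocols were applied "empirically" around
the stated principles), no seasonal or illness-driven sensitivity shifts,
no informative loss to follow-up, and conventional-arm dosing is assumed
to follow the same rule engine as the app arm rather than heterogeneous
local practice. Passing tests therefore show that the *pipeline* recovers
the truth of this generative model and reproduces published arm-level
arithmetic — not that the model captures real warfarin pharmacology.

## Comparison statistics

* Continuous: Kolmogorov–Smirnov test of each sample against a normal with
  its own fitted mean/SD gates Student t (mean/SD summaries) vs
  Mann–Whitney U (median/IQR). Using plain KS with estimated parameters is
  an approximation (a Lilliefors correction would be stricter); it matches
  common clinical-statistics practice.
* Categorical 2×2: Fisher's exact test when any expected count is < 5 *or*
  any observed cell is 0 (the chi-square approximation is unreliable in
  both situations); otherwise chi-square with Yates continuity correction
  (disable with `yates=False`). Per-row p-values are unadjusted — no
  multiple-testing correction, matching the reporting convention of the
  tables this reproduces.
* Percentages are always recomputed from counts (1-decimal, round half
  up); denominators always come from the data at analysis time, never
  constants, because published group sizes are frequently internally
  inconsistent.
* Time-to-event: first event per patient per type, Kaplan–Meier per arm
  with censoring at exit or death from another cause, log-rank comparison
  (`lifelines`); the test is skipped when neither arm has events.
* Sample size: pooled-variance normal-approximation two-proportion
  formula, then attrition inflation ⌈n/(1−loss)⌉ per group. The published
  figure of 206 evaluable per group is *not* reproducible from the printed
  proportions (73.1% vs 66%, α=.05, power 80% give ≈659 per group with
  this closed form; the original used a proprietary PASS procedure whose
  inputs are not fully printed) — only the attrition chain 206 → 258 → 516
  is arithmetic, and that is what the acceptance check asserts.

## Numerical and degenerate-input choices

Dates are calendar dates at day resolution (ISO-8601 only); durations in
days. Zero-margin contingency tables, empty INR logs, single-measurement
patients and event-free cohorts all return explicit degenerate results
rather than raising. Reports are written deterministically (sorted file
sets, fixed float formatting, SHA-256 manifest) so reruns can be verified
byte-for-byte.

## Problem sizes

Default synthetic cohorts are 260 + 259 patients over 180 days (~12 INR
records per patient, ~6,000 records per cohort). The test suite's largest
run uses 2,000 patients per arm for the arm-separation check; the
TTR-vs-discretization oracle uses 1,000 random series against a
10,000-step-per-segment midpoint rule. These sizes give stable Monte-Carlo
estimates for every directional claim the tests make while keeping the
full suite under a few minutes on one CPU.
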