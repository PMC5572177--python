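# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Synthetic trial generator

**What it emulates.** A three-arm randomised screening trial: 101 299
control, 50 624 MMS and 50 623 USS women; entry staggered uniformly over a
4.4-year recruitment window; administrative censoring at 13.6 years minus
the entry offset, so follow-up spans 9.2–13.6 years (mean ≈ 11.4); a rare
primary event (ovarian-cancer death); eight annual screens per screened
woman; yearly cost accrual from screening, screen-triggered assessment and
stage-specific treatment.

**Event-time model.** Piecewise-exponential with a single change-point at
the 7-year lead time: control hazard λ is constant; a screened arm's hazard
is λ(1−ρ₀) before the lead time and λ(1−ρ₁) after. Two reduction
parameters per arm are necessary, not a modelling flourish: the three
calibration targets — a 0.34% → 0.29% shift in observed death proportions,
a 15% overall reduction, and a 23% reduction restricted to years 7–14 —
over-determine a model with ρ₀ ≡ 0. With follow-up time splitting ≈ 61%/39%
around year 7, ρ₁ = 0.23 alone yields only ≈ 9% overall reduction;
matching 15% overall with one parameter would force ρ₁ ≈ 0.39 and a 39%
late-window reduction. `calibrate_hazard` therefore solves (λ, ρ₀, ρ₁)
numerically so that all targets hold *in expectation* under the censoring
distribution (expectations over uniform entry reduce to closed-form
differences of exponentials). The solved defaults are λ ≈ 2.99 × 10⁻⁴/yr,
MMS (ρ₀, ρ₁) ≈ (0.100, 0.230), USS ≈ (0.047, 0.210) — i.e. a small early
benefit plus the dominant delayed one, which is also how the published
cumulative-hazard curves read.

**Censoring.** Administrative only (loss to follow-up in such trials is
negligible). With `recruitment_window = 0` every woman is censored at
exactly `max_followup`, which the tests exploit: under a common horizon the
censoring-adjusted cost estimator must equal the naive discounted mean.

**Costs.** Screen-year costs are charged while a woman is alive, on-screen
and not past her diagnosis year: an MMS screen year costs the test (£20
default) plus phlebotomy (£3) plus the expected second-line ultrasound
(referral fraction × £150); a USS screen year costs the scan plus the
expected repeat. Referral costs enter in expectation rather than as
Bernoulli draws — they matter for the mean, and leaving them deterministic
removes a variance source the analysis does not study. Women who die of
the disease are diagnosed one year before death (floored to a year index)
and incur one stage-specific treatment cost in the diagnosis year: £3422
early / £5666 advanced, the published weighted per-case treatment costs.
Stage is Bernoulli with early fraction 0.39 (screened) / 0.26 (control) —
the trial-reported magnitude of the stage shift; the generator does not
model diagnoses among women who survive the trial, so absolute per-arm
cost levels sit below the published Table-3 values while the *differences*
(screening plus the small treatment offset) are of the right size.

**Randomness.** One master seed; each arm consumes an independent
`SeedSequence` child (entry, event, other-cause and stage streams split
again below that), so resizing or re-costing one arm never reshuffles
another, and the test-cost sensitivity sweep sees byte-identical event
histories across sweep points.

**What passing tests do not show.** The generator has no screen-episode
sensitivity/specificity, no diagnosis-to-death survival distribution, no
incident cases among survivors, and no quality-of-life trajectories; tests
passing on these data validate the *estimators* (which see only arm,
follow-up, event flag and yearly costs) — they do not validate clinical
realism beyond the calibrated arm-level outcomes.

## Survival effects

Kaplan–Meier estimation (via lifelines) treats `event = 1` as
ovarian-cancer death and everything else as right-censoring; risk-set
bookkeeping (at-risk counts, deaths, Greenwood variance) is retained on the
curve object.

**Discounting convention.** Nothing forces one convention; the package uses
annual-step discounting with the first follow-up year undiscounted:
survival experienced in year k is weighted (1+δ)^(−k). The choice is
empirically pinned: with near-certain survival over 13.557 years this
yields 12.3668 at 1.5% and 11.019 at 3.5%, within 0.1% of the published
per-arm discounted means (12.36565 / 11.01755), whereas continuous
discounting gives ≈ 12.27. The same convention is used for costs, the
extrapolation and the Markov model, so discounted quantities are
comparable across stages.

**Restricted mean.** The discount-weighted area under the KM step function
up to the restriction time τ, computed exactly on the merged grid of step
times and year boundaries. τ defaults to the *minimum over arms* of the
largest observed time, the largest horizon at which every arm's curve is
defined without extrapolation; horizons beyond an arm's data raise an
error. The variance generalises the usual restricted-mean formula: each
event time contributes its remaining weighted area squared times
d/(n(n−d)).

## Censoring-adjusted costs

The yearly-partition estimator: Σₖ (1+δ)^(−k) Ŝ(aₖ) C̄ₖ. The survival
weight is the all-cause "alive and under observation" KM evaluated just
before aₖ (so a death exactly at a boundary is not double-counted); the
interval mean C̄ₖ averages year-k costs over patients observed through the
whole interval, keeping deaths inside the interval with their full
interval cost and excluding within-interval censorings (whose year-k cost
is truncated and would bias C̄ₖ down). Within the trial a single interval
mean pools survivors and decedents; the survivor/decedent split is used
only for the extrapolation, where the two groups' annual costs genuinely
diverge. Variance is by patient-level bootstrap (seeded); the same joint
bootstrap provides the cost–effect covariance the Fieller interval needs,
which is why no analytic cost variance is implemented.

## ICER statistics

Point ICERs classify the cost-effectiveness quadrant (tradeoff / dominant
/ dominated / undefined at ΔE = 0, with no division in the undefined
case). Fieller intervals solve the standard quadratic; a non-positive
leading coefficient (effect not significantly nonzero at level α) returns
an explicit unbounded flag — never a truncated finite interval. Arms are
independent, so ΔC/ΔE variances and covariance are sums of per-arm
bootstrap moments; a zero-covariance analytic mode (restricted-mean
variance only) is available for fast runs. All monetary values are carried
at full precision and rounded only at rendering.

The univariate test-cost sweep regenerates the trial at each candidate
test cost under the same seed: event histories are identical by
construction, so the ICER moves through the cost channel alone.

## Extrapolation

**Model.** Royston–Parmar: ln H(t) = γ₀ + γ₁ ln t + Σⱼ γⱼ vⱼ(ln t) with
restricted-cubic-spline terms vⱼ; natural (linear-beyond-boundary) tails
make the extrapolated log cumulative hazard log-linear in log time, taming
the 25-year tail. df = 1 is exactly Weibull (verified against an
independent Weibull fit in the tests). Knots sit at quantiles of the
uncensored log event times, boundary knots at their extremes. Fitting
maximises the censored-data log-likelihood by BFGS from a Weibull-type
initialisation (log cumulative hazard regressed on log time at the KM
event times); monotonicity of H over the data range is enforced by a
penalty and re-checked after the fit, with violations raised as errors
rather than silently accepted. The df grid defaults to {1, 2, 3} with AIC
selection, ties toward smaller df.

**Life-years.** Hybrid by default: within-trial discounted restricted mean
from the KM curve, plus the fitted model's survival integrated (by
quadrature, year segment by year segment) from the trial boundary to the
horizon. The post-trial part deliberately uses the model's own
unconditional survival rather than rescaling through the KM value at the
trial boundary: that boundary estimate rests on the thin late-follow-up
risk set, and its noise — multiplied by a decade of extrapolation — would
swamp a between-arm survival difference of a few parts in 10⁴. An
all-parametric mode sits behind a flag. No competing-risk adjustment is
applied in this module; competing mortality is the Markov model's job.

**Costs.** Two-part projection per whole post-trial year k:
(1+δ)^(−k)[S(k+1)·c_surv + (S(k)−S(k+1))·c_dec]. The survivor annual cost
comes from fully-observed survivor person-years within the trial — for the
screened arm restricted to the on-screen years, so that screening (and its
cost) is assumed to continue through the extrapolation period, the
conservative reading of the continued-care assumption; the decedent annual
cost averages year-of-death costs. Both are overridable.

## Markov cohort model

Annual cycles from age 60; states well, benign oophorectomy, early ovarian
cancer, advanced ovarian cancer, ovarian-cancer death, other-cause death.
Competing mortality from the life table applies first in every alive
state; disease transitions act on the surviving mass, so outgoing
probabilities sum to one by construction and cohort occupancy is conserved
to 10⁻¹² every cycle (checked, and refused if violated). Benign
oophorectomy is a one-cycle tunnel back to well — a one-off surgical event
with a one-off cost (£2275 + £139 follow-up). Cancer states persist until
death, accrue their utility per cycle (0.718 early / 0.649 advanced; well
and the surgical tunnel default to 1.0, which the literature leaves
unstated), and charge their weighted treatment cost once on entry, since
those are per-case, not per-year, costs. Screening does not alter
incidence; it shifts the early/advanced split at diagnosis (0.39 vs 0.26
early) and adds the annual screen cost (£20 test + £3 phlebotomy + £109
outpatient, charged per well-year under screening — the literal reading;
a per-referral mode would need only a different `screen_cost_per_well_year`).
Annual incidence defaults to 1 × 10⁻³; cancer-state death probabilities
(0.0209 early, 0.45 advanced per year) are set from the familiar ~90% and
<5% five-year survival of early- and late-stage disease. These transition
inputs are deliberately config-first: the published analysis derived its
transition probabilities from unpublished within-trial hazards, so exact
cost-per-QALY figures are not reproducible and only structural properties
(quadrant, monotonicity, PSA bracketing, oracle equality of the
disease-free model against direct life-table expectancy) are asserted.

Accrual is state-at-cycle-start with cycle 0 undiscounted, matching the
pipeline-wide discounting convention; a half-cycle correction is available
behind a flag (for the disease-free cohort it shifts life-years by exactly
one half, which the tests verify). The cohort stops when alive mass falls
below 10⁻⁹, trimming a tail of the same order.

**Life table.** A synthetic Gompertz table stands in for a national female
life table: the annual mortality hazard grows exponentially with age
(shape 0.095/yr) with its level solved so remaining life expectancy at 60
equals the published 25.22 years. With state-at-cycle-start accrual the
disease-free cohort therefore returns ≈ 25.7 discounted-at-0% life-years
(the half-cycle offset above the complete expectancy). Any `age,qx` CSV
can replace it.

**PSA.** Uniform redraws of the test cost over £15–£50 (the £10–£50
variant is a matter of passing a different range), rebuilding the
screening strategy's well-state cost per draw; deterministic under a fixed
seed. The ICER is strictly increasing in the drawn cost, so the sample
extremes occur at the boundary draws — asserted, not assumed.

## Pipeline, sizes and determinism

One master seed fans out to named sub-seeds (generator, bootstrap, PSA).
Reruns with the same config produce byte-identical JSON summaries; every
rendered CSV carries the config digest in a comment header. Default
problem sizes: the full 202 546-woman trial for generation and within-trial
estimation (sub-second to a few seconds per stage); bootstrap replicates
are config-controlled and default off for the fast analytic mode. The
acceptance script pools 384 replicate trials: each target is a rare-event
rate whose single-replicate Monte-Carlo error (≈ 4–9 percentage points on
the reduction estimates) would dominate the comparison, and pooling
shrinks the error toward the calibrated expectation without touching the
design, the calibration, or per-replicate sample sizes.

## Known limitations

- The generator ties diagnosis to eventual death; absolute per-arm cost
  levels are therefore lower than a real trial's, though cost differences
  are realistic.
- Fieller intervals at full trial scale are wide (the effect difference is
  small relative to its standard error); published interval widths for
  such trials depend on variance inputs that are not public and are not a
  target.
- The Royston–Parmar change-point behaviour is approximated by smooth
  splines; a df = 1 fit under-captures the late hazard divergence, and the
  AIC choice between df values is data-dependent at rare-event counts.
- The Markov transition defaults are literature-magnitude placeholders,
  not trial estimates; cost-per-QALY outputs are structurally, not
  numerically, comparable to published figures.
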