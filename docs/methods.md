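# Methods

## Model structure

The model is a discrete-time Markov cohort simulation with six states —
NGT, IFG, IGT, IFG&IGT, T2D and death — an annual cycle, and a lifetime
horizon (hard stop at age 105; the residual living mass at the stop,
well under 1% with the default mortality, contributes its final-cycle
accrual only).  The cohort is represented at population level: every
categorical risk factor carries a probability vector over its categories,
and transitions are evaluated at the probability-weighted mean of numeric
category codes.  This is a cohort-level (mean-covariate) evaluation, not
the expectation of individual-level probabilities; the test suite
quantifies the agreement with an individual-level microsimulation driven by
the same matrices.

Allowed transitions per cycle: NGT to each pre-diabetic state, each
pre-diabetic state back to NGT, each pre-diabetic state to T2D, and T2D
back to each pre-diabetic state.  NGT→T2D within one year and direct moves
between pre-diabetic states are structurally zero.  Death is available from
every living state and absorbing.

### Within-cycle ordering

Death is resolved first; glucose-state transitions are conditional on
survival, with residual probability mass remaining in the current state.
This keeps every row of the transition matrix stochastic without rescaling.
No half-cycle correction is applied: costs and QALYs accrue to cycle-start
occupants, and the starting year (cycle 0) is undiscounted.  Model year 1
is cycle index 0 throughout: the first-year programme cost, the full
intervention effect (decay weight 1) and the undiscounted accrual all refer
to the same year.

### Transition probabilities

Twelve logistic risk equations (one per allowed glucose transition, from a
published regression table) give `logit P = intercept + Σ coef·x`.  The
covariate coding is not published with the equations; the package codes
binary factors 0/1 with the lowest-risk level at 0, three-level factors
ordinally 0/1/2, and BMI as underweight/normal 0, overweight 1, obese 2.
The coding lives in `data/coding.yaml` so alternatives are a file edit.
Two factors are listed risk-level-first in the source (family history,
self-perceived health); the lowest-risk-equals-zero rule wins there.

### Mortality

Age-banded annual probabilities (5-year bands, step function, no
interpolation) with two columns: all-cause and the T2D-cause-specific
component.  Living non-T2D states receive the cause-deleted rate
(all-cause minus T2D-specific); T2D occupants additionally receive the
population T2D death rate divided by the T2D prevalence share (default
0.061), so cause-specific deaths load entirely on prevalent cases.  Whether
the original analysis allocated an excess to the T2D state is not stated;
this allocation is one defensible reading and the prevalence share is a
config parameter.  No pre-diabetic excess mortality is assumed.

The regional life table behind the original analysis is not published.  The
synthetic stand-in uses a Gompertz–Makeham hazard `A + B·exp(c·age)` with
defaults A = 3·10⁻⁴, B = 2.5·10⁻⁵, c = 0.095 (per-year), evaluated at band
midpoints, giving a remaining life expectancy at age 30 of 50.5 years —
the order of magnitude of Swedish period life tables for the 2000s.  The
T2D cause fraction steps from 0.5% of deaths below 45 to 2.5% above 65,
roughly matching national cause-of-death proportions.  The stand-in
preserves the shape and level of adult mortality but not regional,
sex-specific or year-specific detail; absolute ICERs therefore depend on
it, while the package's invariants (row-stochasticity, conservation,
oracle agreements) do not.

### Intervention effect and decay

At the starting year the intervention (i) moves a fraction f = 0.05 of the
obese share to overweight and of the overweight share to normal weight,
(ii) replaces the physical-activity vector with the target distribution
18.6/62.4/19.0 and the diet vector with 18.3/81.7, and leaves everything
else unchanged.  The published baseline physical-activity column
over-counts (sums to 104%); it is renormalized on load, which is also why
the target vectors are used directly rather than derived from the "+13%"
statement.  The effect fades linearly: weight w(t) = max(0, (d+1−t)/d) on a
1-based cycle counter with duration d = 7 years, so w = 1 in year 1 and 0
from year 8.  Decay is applied to the risk-factor profile itself (hence to
both transition probabilities and utilities through one mechanism), by
blending expected covariates — exact, because expected covariates are
linear in the category vectors.

### Utilities and costs

Health utility weights come from an SF-6D-based table keyed by sex, anchor
age (30/50/70), arm and state, with death at 0.  Attained age interpolates
linearly between anchors and clamps outside [30, 70] (conservative: no
extrapolated decline after 70, applied identically to both arms).
Intervention-arm values blend toward control with the same decay weight as
the risk factors.  The education/BMI adjustability of the underlying
utility regression is not reproduced — its coefficients are unpublished and
the anchor table already reflects the scenario profiles.

Costs (euros, societal perspective): T2D total = direct 3602.00 € grossed
up by the 57% indirect share → 8376.74 €/yr; each pre-diabetic state 46% of
that → 3853.30 €/yr; NGT and death free.  Programme costs 390.43 € (year 1)
and 189.93 € (years 2–5) are charged per living cohort member — whether the
dead stop incurring them is unstated in the source; charging only the
living is the natural reading.  Both costs and QALYs discount at 3%/yr.

## Probabilistic sensitivity analysis

Per replicate one parameter set is drawn and used for both arms (common
random numbers), preserving the within-replicate arm correlation:

- Transition probabilities: one beta draw per equation, fitted by the
  method of moments around the equation's probability p₀ at the scenario's
  baseline covariates and starting age, with SD = cv·p₀ (default cv = 0.10;
  the source regressions' standard errors are unpublished, so this is an
  assumption, and no acceptance result depends on it).  The draw is applied
  as a logit-scale intercept shift `logit(p′) − logit(p₀)` so a single draw
  acts coherently at every age of the run and stays inside (0, 1).
- Utility weights: one beta draw per living state around the control-arm
  starting value (cv = 0.05), applied as an additive shift to all anchors
  of that state, clamped to [0, 1].
- Costs: gamma draws with SD = mean (shape 1) for the T2D total (the
  pre-diabetic cost stays at 46% of the draw) and for each programme cost
  level.

Draws are per replicate, held fixed across cycles (the source is silent on
redraw granularity; per-replicate draws are the standard reading of
parameter uncertainty).  Infeasible beta moments fall back to a degenerate
draw at the mean with a warning.  Because competing exits are drawn
independently, a row's exits can jointly exceed 1 (the IFG reversion
probability is ≈0.81 at baseline); inside the PSA such rows are rescaled
proportionally to sum to 1, while the deterministic matrix builder treats
the same condition as an error.

Summaries: mean, median and ordered-value percentile intervals (1-based
ranks ⌈n·0.025⌉ and ⌈n·0.975⌉), the ICER of mean increments, CE-plane
quadrant counts, and CEAC values P(λ·ΔQALY − Δcost > 0) over a threshold
grid.  With 1000 replicates one scenario's PSA runs in a few seconds.

## Scenarios and sensitivity analyses

The base case evaluates six scenarios (men and women starting at 30, 50,
70).  Deterministic sensitivity variants: (a) the PSA itself; (b) removing
T2D→pre-diabetic reversion; (c) all state and programme costs ±10%;
(d) effect duration doubled to 14 years; (e) weight reduction weakened to
3.3%, with and without the activity/diet effects.  A run manifest records
the seed, a digest of every parameter actually used, and all written
artifacts; fixed seeds reproduce results bit-identically.

## Magnitude of the incremental effect

Under the coded parameter surface, the intervention shifts expected
covariates by at most |ΔBMI| ≈ 0.03, |ΔPA| ≈ 0.15, |Δdiet| ≈ 0.09, which
moves annual transition probabilities by 0.4–8% relative, decaying over
7 years.  The resulting increments are small: ΔQALY 0.0008–0.017 and ICERs
from ≈49,000 €/QALY (men, 70) to over 10⁶ €/QALY (women, 30).  This is a
structural property, not a tuning artifact: any category coding compatible
with the printed intercepts bounds the achievable logit shift, and even a
permanent (non-decaying) effect only reaches ΔQALY ≈ 0.023.  Published
evaluations of comparable programmes report incremental QALYs one to two
orders of magnitude larger; reproducing them would require an effect
translation (e.g. continuous risk-factor scales) that the available
parameter surface does not contain.  Consequently, in this implementation
the older cohorts — where preventable T2D incidence and excess mortality
are concentrated — are the most favourable, men benefit more than women
(whose progression risk is lower to begin with), and removing the
T2D→pre-diabetic reversion *lowers* young-age ICERs by increasing the T2D
burden the effect can act on.

## Numerical choices and degenerate inputs

- Probability vectors validate to sum 1 within 10⁻⁹; blended vectors are
  renormalized.
- Transition rows: structural zeros exact; exits above 1 raise (or rescale
  in PSA, above); matrices validate row sums to 10⁻⁹ under fuzzing.
- The cycle loop evaluates equations through a precompiled coefficient
  matrix; it is numerically equivalent to the per-equation reference path,
  which the microsimulation oracle exercises independently.
- A horizon equal to the starting age yields exactly one (undiscounted)
  accrual cycle.  A two-state reduction with constant hazard matches the
  closed-form geometric sum to 10⁻⁹.
- Seeds: a single `numpy` generator per PSA; scenario-level seeds derive
  from the user seed as `(seed·1009 + index) mod 2³¹`.

## Known limitations

No T2D complication sub-states, no memory of prior T2D, no tunnel states;
no pre-diabetic excess mortality; mortality not sex-specific; utilities
clamp outside the anchor ages; the synthetic mortality table and the
covariate coding are documented substitutes for unpublished inputs, so
absolute cost-effectiveness levels should be read as properties of this
parameterization rather than of any real programme.
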