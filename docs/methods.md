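# Methods

## Estimation framework

Active-travel time is modeled as the product of three person-level
regressions, estimated separately by mode (walk, bike) and stratum
(working adults, non-working adults):

1. **Trip counts.** Daily walk/bike trip counts are zero-inflated
   Poisson: with probability π(x) = logit⁻¹(x′γ) a person is a
   structural non-traveler of that mode; otherwise the count is Poisson
   with rate λ(x) = exp(x′β). Both stages see the same candidate
   covariates and are selected independently. The expected count is
   (1 − π)λ.
2. **Trip purposes.** Conditional on a trip, its purpose (work,
   shopping, social, recreational, personal/family — no work category
   for non-workers) follows a multinomial logit with a declared base
   outcome (work for workers, recreational for non-workers).
3. **Durations.** Trip duration has a log-link mean d = exp(x′δ),
   estimated by GEE with trips clustered within persons, an exchangeable
   working correlation, variance proportional to the mean on the natural
   scale, and cluster-robust covariance. Built-environment covariates,
   commute mode, and (for workers) log travel time to work are
   interacted with purpose.

Expected daily minutes are E(t)·Σₚ Pr(p)·dₚ; the identity is verified
against a brute-force generative simulator in the test suite. Minutes
convert to MET-hours at 3.5 (walking) and 6.8 (cycling) per hour;
weekly doses are 5 × weekday + 2 × weekend evaluations.

## Data preparation

Raw person/trip tables are harmonized via a column-mapping config: modes
collapse to {private vehicle (incl. carpool), transit (incl.
paratransit), walk, bike}; negative sentinel codes become missing;
months collapse to seasons (Dec–Feb winter, etc.); density is carried in
thousands of persons per square mile. Cleaning removes out-of-town
respondents, airplane/"other" commuters, commutes strictly over 120
minutes (the boundary value is kept), non-active and vacation trips, and
active trips strictly above the mode-specific 99th-percentile duration
(empirical quantile with linear interpolation; ties kept). Missing race,
education, medical-condition, or (workers only) commute mode removes the
person and their trips. Adults (18+) split into working/non-working
strata.

The 99th-percentile cut is a property of the survey's full duration
distribution: it is estimated once from the incoming data and recorded in
the cleaning report. Re-estimating it on already-truncated data would
shave the tail again on every pass (the quantile of a truncated sample
sits below its maximum under any standard quantile definition), so
re-cleaning uses the recorded thresholds, making the operation exactly
idempotent.

## Covariance of the zero-inflated fits

The packaged analytic Hessian for the zero-inflated Poisson likelihood
omits the inflation/count cross-derivative block and understates
coefficient variance (confirmed by comparing it with a finite-difference
Hessian, the outer product of per-observation scores, and the sampling
variance over simulated replicates — the latter three agree). The
covariance is therefore computed in-package: a central finite-difference
Jacobian of the analytic score gives the observed information; the
robust (default) covariance sandwiches the outer product of
per-observation scores between its inverse. Design columns are rescaled
to unit maximum absolute value during optimization (quadratic age terms
otherwise dominate the gradient) and estimates are mapped back
afterwards.

## Model selection and marginal effects

Backward elimination refits after removing the single least significant
candidate term (joint Wald test over a categorical term's dummy block;
ties break toward the larger p, then the lexicographically larger name)
until every candidate has p < 0.10. Education, medical condition, proxy
response, season, weekday/weekend, heavy-rail presence, and geography
fixed effects are always-kept controls in the walk models. Average
marginal effects are sample-averaged counterfactual prediction
differences (categorical) or derivatives (continuous), with delta-method
standard errors from a numerical gradient in the coefficients; combined
effects on daily minutes redraw all three models' coefficients from
their estimated joint-normal laws (independently across models — no
cross-model covariance is available) and report percentile intervals.

The daily-trip-total control that travel-diary studies sometimes carry in
count models is generated by the synthetic survey but excluded from the
default designs: it contains the response as a summand, and at desk-scale
sample sizes the induced endogeneity dominates. The bike-mode designs are
deliberately leaner than the walk designs (own-mode/transit commute
indicators, minimal controls): cycling days are roughly an order of
magnitude scarcer than walking days, and a full control set is separated
at these sample sizes.

## Regional application

For every (commute category, age, sex, race/ethnicity, block group)
cell, the composition is evaluated under weekday and weekend settings,
averaging predictions over the block group's education distribution and
(by default) over the four seasons with equal weight; non-worker cells
use the non-working-adult models. Recreational trip durations are
excluded by default in the regional matrix (purpose-oriented travel
only) and included when validating against observed diaries. Mode-specific
mean travel times to work come from the block group, falling back to
tract then county aggregates (observed values are never overwritten, and
each filled cell is tagged with its source level); the pooled
bicycle/motorcycle/taxi census time is capped at the private-vehicle
time. Cell SDs come from re-evaluating the matrix under joint-normal
coefficient draws per component model (default 40–60 draws), with the
point estimate taken at the fitted coefficients. Predictions clip the
linear predictor's exponent at 30 as a guard against overflow from
extrapolated covariate corners; sane fits never approach the bound.

Block-group populations distribute over the same cells by multiplying
normalized marginals under independence: age×sex counts (spread
uniformly within bins, aggregated to the evaluation age grid), a
worker/non-worker split from county labor-force participation, commute
shares over workers, and race/ethnicity shares. "Fourth-order spline"
smoothing of binned participation is implemented as a least-squares
spline of polynomial order 4 (cubic pieces) with interior knots at every
other interior bin midpoint — knots at every midpoint leave the
least-squares system underdetermined and oscillating at the boundaries —
clamped to [0, 1], with a step-function fallback below four bins.
Zero-population special districts are carried as all-zero cells so joins
stay aligned.

## Health impact assessment

All-cause mortality relative risk is RR(TPA) = 0.90^(TPA/11.25), i.e.
log-linear with a 10% risk reduction per 11.25 MET-hours/week. Doses are
carried as separate walking and cycling components; each is zeroed
outside its eligibility window (walking 20–74, cycling 20–64) before RR
evaluation. The attributable fraction per cell defaults to the standard
potential-impact-fraction form (B_cf − B_est)/(1 − B_est), which is
positive for activity-increasing counterfactuals; the alternative form
(B_est − B_cf)/(1 + B_est) is available as `formula_mode="as_printed"`.
Because each cell is dose-homogeneous, the fraction is evaluated cellwise
and results can be aggregated over any margin (county, sex, block group,
density quintile). Avoided deaths are AF × baseline death rate ×
persons, with county age/sex rates computed as pooled deaths over pooled
person-years across five calendar years (stabilizing small counts).
Baseline doses can exceed a counterfactual's dose, in which case that
cell's contribution is legitimately negative.

Scenarios: a fixed weekly walking time for everyone (default 37.4
minutes/week — the package also accepts the alternative 34.7 sometimes
quoted for this counterfactual); percentage scaling of the walking
component (directly, or derived from built-environment elasticities
combined additively by default, e.g. 0.29 × 50% = 14.5%); and commute
mode shifts that move a population share from one commute category to
another, re-reading doses from the destination cells with population
conserved. Uncertainty intervals perturb each cell's total dose with
independent normal noise of its SD, truncated at zero with components
rescaled proportionally (a zero-dose cell receives the perturbed mass in
its walking component), re-apply the scenario, and take 2.5/97.5
percentiles over ≥100 draws.

## Synthetic data

The generator is the exact inverse of the estimation pipeline.
Covariates are drawn from independent marginals calibrated to plausible
US values (age ≈ N(47, 17²) clipped to 18–95; commute shares
0.88/0.05/0.04/0.03 across car/transit/walk/bike; density lognormal with
median ≈ 1,350 persons/mi²; travel time to work lognormal with median 20
minutes). Default coefficients are chosen so the synthetic margins echo
published travel-survey behavior: ~77% of person-days have no walking,
~97% no cycling; walk trips average ~14 minutes and bike trips ~22;
commuting on foot multiplies walk-trip odds and counts strongly.
Durations are lognormal about the log-link mean with a person-level
random effect (intraclass correlation 0.30 of a total log-scale SD 0.55)
and a −σ²/2 offset so E[d|x] = exp(x′δ) exactly. The regional generator
plants missingness in travel-time attributes at block-group (15%) and
tract (10%) levels to exercise the fallback ladder, draws 5-year death
counts around an exponential-in-age rate (doubling every 8 years from
8×10⁻⁴ at age 20), and perturbs a smooth logistic-in-age participation
curve.

What the generator does not emulate: survey design weights and their
effects, covariate dependence (age–mode correlations), measurement error
in diaries, real census margins of error, or spatial autocorrelation.
Passing tests therefore demonstrate statistical correctness of the
machinery under the assumed laws, not predictive validity on real survey
data.

## Problem sizes and defaults

Synthetic surveys default to 10,000 persons (tests use 2,500–30,000;
coverage checks use 200 replicates at n = 5,000 with compact designs).
The default region is 2 counties × 3 tracts × 5 block groups, scalable to
hundreds of block groups. Regional matrices in tests use coarse age
grids (5–15-year steps) and 4–10 coefficient draws; pipeline defaults are
single-year-capable with 40 draws. Dose-uncertainty intervals use 100–200
draws. All randomness flows from a single master seed through named,
independently derived child seeds; identical seeds reproduce every
artifact byte for byte.

## Known limitations

* The three component models are fitted on overlapping data but treated
  as independent when drawing coefficients; combined intervals are
  approximate.
* Independence of race with the other population dimensions is assumed
  where joint tabulations are unavailable; a raking adjustment is not
  implemented.
* The log-linear dose–response is extrapolated across the whole dose
  range; no non-mortality endpoints, life-table years, or competing
  transportation risks (air pollution, injury) are modeled.
* Backward selection is optional in the pipeline (off by default) since
  repeated refitting of the zero-inflated models dominates runtime at
  small sample sizes.
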