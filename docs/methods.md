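# Methods

## Setting and causal structure

The package addresses a hospitalised-cohort study of the effect of ethnic
group on death during admission. Both the exposure and the outcome are
taken to influence the probability of hospitalisation — minority
ethnicities through higher infection and admission risk among survivors,
death because almost all fatal cases pass through hospital — so restricting
the analysis to admitted patients conditions on a collider and biases the
exposure–outcome association. The correction follows the
externally-informed IPW approach: model the probability of cohort inclusion
(hospitalisation) from published summary data as a function of exposure,
outcome and epidemic wave, and weight each patient by the inverse of that
probability so the weighted cohort stands in for the community
("pseudo-population").

## The inclusion model

The inclusion probability is modelled on the log scale, saturated in the
stratification cells:

* single-wave form (10 coefficients):
  `ln P(hosp) = γ₀ + γ₁·death + λa[e] + λb[e]·death`
* two-wave form (20 coefficients), adding
  `γ₂·wave₂ + γ₃·death·wave₂ + λc[e]·wave₂ + λd[e]·death·wave₂`

with White ethnicity and wave 1 as reference levels. Because the design is
saturated, the maximum-likelihood log-binomial fit is available in closed
form: fitted probabilities equal observed stratum risks exactly, and every
coefficient is a signed sum of log cell risks (each exponentiated
coefficient a risk ratio, e.g. `exp(λa[Black]) = risk(Black survivors) /
risk(White survivors)`). Standard errors come from the observed information
of the log-binomial likelihood, `var(ln p̂) = (1 − p̂)/(n·p̂)` per cell,
summed over the cells entering a contrast and delta-transformed to the
exponentiated scale. An iterative GLM route (statsmodels, binomial family,
log link, denominator weights, started at the closed form) is provided for
non-saturated extensions and agrees with the closed form to ~1e-13 on
saturated inputs.

A strata table whose non-reference ethnicity is entirely absent is fitted
with that ethnicity's ratio coefficients at 1 (log 0), with a warning;
partially observed ethnicities are rejected. A cell risk of 0 makes its
coefficient non-identifiable (error); a risk above 1 — possible with
fractional pseudo-counts — is an evidence-inconsistency error.

### From marginal tables to strata

Published national tables report, per (ethnicity, wave): population
denominator, number hospitalised and number died, without a
hospitalisation × survival cross-tabulation. The evidence module closes the
gap with a single assumed **hospitalised-death fraction** f (default 0.90):
the died stratum gets risk f; the survived stratum gets
`(n_hosp − f·n_died) / (n_total − n_died)`. Counts stay fractional by
default — rounding f·n_died biases small strata and the saturated fit
consumes risks, not integers — with an integer mode for count-based
fitters. A negative implied survivor count is refused as inconsistent
evidence.

## Weighted survival analysis

Death during admission is analysed with a cause-specific Cox model:
discharge (like administrative censoring) terminates follow-up without an
event. This is the standard Cox reading of "discharge as a competing
event"; a subdistribution (Fine–Gray) estimator is a documented alternative
that is deliberately out of scope, since the target here is the
cause-specific effect of ethnicity on dying in hospital. Three iterations
are fitted: ethnicity only; ethnicity plus the nine baseline covariates
(age, sex, IMD quintile entered as four indicators against quintile 1, DNR,
cardiovascular disease, COPD, diabetes, chronic liver and kidney disease);
and the covariate model with IPW. Variances are robust (Lin–Wei sandwich)
throughout; confidence intervals are normal-approximation on the log scale
at 95%.

Tie handling: the default engine is lifelines' Efron approximation. A
Breslow engine (internal Newton–Raphson with an analytic sandwich,
cross-checked against R `survival::coxph` during development) is provided
because one contract — integer case weights ≡ record replication — holds
exactly only under Breslow: Efron's correction treats duplicated deaths as
tied and downweights their shared risk set, so the two representations
genuinely differ there. Point estimates are invariant to rescaling all
weights by a constant; robust standard errors are not invariant to
replication by design (replication asserts more information).

Degenerate designs (constant or collinear columns) are detected by rank
check and refused rather than silently dropped; a cohort with no death
events is unestimable; a single-ethnicity cohort yields an empty ethnicity
term set with a warning.

## Misspecification sensitivity

The inclusion model is fitted to national evidence but applied locally, so
each coefficient may be systematically off. The sensitivity grid shifts one
coefficient at a time, additively on the log scale, at three graded levels
(50%, 100%, 200% of the discrepancy suggested by comparing national and
local catchment data — the bundled comparison table's log risk/RR
differences). Raising a survivor-side coefficient (λa, and the wave terms
γ₂, λc, λd) would push died-stratum probabilities already near 0.90 above
1, so those scenarios carry a mandatory companion shift of γ₁ − 0.15. The
grid ships as package YAML data and is overridable.

Every scenario's predicted stratum probabilities are validity-checked
against (0, 1]. Out-of-range scenarios are handled by a configurable
policy, recorded in the outputs and never dropped silently:

* `skip` (default): omit the scenario with a warning — the conservative
  choice when the intended perturbation cannot be represented as a valid
  probability model;
* `clip`: cap implied probabilities at 1 − 1e-9 (i.e. floor the weights);
* `shrink`: reduce the target delta to the largest value keeping all
  probabilities valid (closed form, since each affected stratum scales as
  `A·e^δ`).

The policy choice for invalid scenarios is genuinely open — published
practice reports "adjustments" without a rule — and the default errs
towards not analysing a model that violates its own domain.

## Synthetic data generator

The generator realises the collider DAG directly: ethnicity and wave are
drawn marginally; death is a latent Bernoulli conditional on (ethnicity,
wave); hospitalisation is Bernoulli conditional on (ethnicity, wave,
death); event times are drawn conditional on survival status (exponential,
death rate 0.10/day, discharge rate 0.125/day) with administrative
censoring at 60 days. The mixture formulation makes every stratum
probability exactly controllable — the property the inclusion model must
recover — at the cost that the cause-specific death hazard ratio only
approximates the configured death-risk ratio; with death risks of order
10⁻², the approximation error is far below Monte-Carlo noise.

Default conditions mirror the magnitudes of the published national
evidence: survivor hospitalisation risks 0.00126 (White baseline) scaled by
ethnicity ratios 1.889/1.563/1.230/0.802 (Black/Asian/Mixed-Other/Unknown)
and by 0.54 in wave 2; P(hospitalised | died) = 0.90 uniformly; ethnicity
mix London-like (0.55/0.15/0.15/0.08/0.07). The baseline death risk
(0.005) and the true Black-vs-White death risk ratio (1.1) define the
reference recovery scenario: at population 200,000 they yield a cohort of
~1,200 admissions, large enough for stable Cox fits and small enough for
second-scale runs. Covariates are drawn independently of the
ethnicity→death path by default so that true hazard ratios are known
analytically; per-ethnicity prevalences can be configured. The nine
baseline covariates carry admitted-cohort-typical marginals (age N(65,16)
clipped to 18–100, 55% male, deprivation-skewed IMD, DNR 15%, CVD 30%,
COPD 10%, diabetes 25%, liver 3%, kidney 15%).

What the generator does *not* emulate: transmission dynamics or calendar
epidemic curves, multiple admissions, time-varying DNR status, covariate–
outcome confounding, or realistic within-hospital length-of-stay
distributions (event-time families are configurable but the defaults are
chosen for testability, not clinical realism). Passing tests therefore
demonstrate that the estimator chain recovers known truths under the
assumed selection structure — not that any particular real cohort satisfies
that structure.

## Reproducibility and numerics

All randomness flows from one top-level seed through numpy `SeedSequence`
stream-splitting; the same configuration and seed reproduce every artifact
byte-for-byte, and artifacts are written/parsed with round-trip float
precision so resumed runs refit bit-identically. A manifest records the
seed, package version and a configuration hash. Newton solvers use
step-halving with convergence at 1e-12; the saturated fit is closed-form
and exact to machine precision; probability-validity uses a strict (0, 1]
check with a 1e-9 clip margin.

## Known limitations

* The inclusion model cannot include patient-level covariates (age, sex):
  the external evidence exists only as marginal summaries.
* Weights are unstabilised; with survivor inclusion probabilities of order
  10⁻³ the weighted analyses trade wide confidence intervals for
  unbiasedness. Weight stabilisation is a natural extension.
* Only one coefficient is misspecified at a time (plus mandated
  companions); joint misspecification surfaces are out of scope.
* Breslow is the only tie method with the replication-equivalence
  guarantee; the Efron default matches standard practice but differs on
  heavily tied weighted data.
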