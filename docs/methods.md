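# Methods

This note records the modelling conventions, default parameters and design
choices behind `healthmarkov`, and what the synthetic-data tests do and do
not demonstrate about real data.

## The latent Markov health model

Health of an older adult is summarised by a discrete latent state with
`M − 1` living levels plus death (default `M = 4`: good, moderate, poor,
death). The model has a structural and a measurement component.

**Structural component.** The initial living state follows a multinomial
logit on age (linear, per decade, centred at 75) and sex. Annual
transitions follow a separate multinomial logit per origin state over all
destinations, with covariates sex, partner status, age and education (two
dummies, reference: low). The origin's own state is the logit reference
category; death is absorbing by construction, not by estimation. Age enters
all logits linearly per decade; a quadratic term is not used (the linear
form is an assumption, chosen for parsimony and stable extrapolation to the
highest ages).

**Measurement component.** Each of the seven indicators has intercept-only
multinomial logits per living state (no covariates). Costs follow a
two-part model per service and state: a use logit and, conditional on use,
a Gamma distribution with log-link mean and a shape parameter shared across
states within a service (dispersion is a service property; letting it vary
by state adds little and destabilises sparse states). Cost covariates are
sex, partner, age, education and calendar-year dummies (reference: first
panel year).

**Death and missingness conventions.** Death is observed exactly through
vital status: the death-year record carries no indicator or cost values,
the death state's emission is 1 in that year and 0 in any alive year, and
living states have emission 0 in the death year. Missing indicators and
unobserved services contribute a factor 1, so years without survey data are
carried by the hospital-cost density alone. Individuals are assumed
administratively observed every year until death or the panel end;
non-mortality attrition is neither modelled nor simulated.

## Estimation

The observed-data likelihood is maximised by EM.

* **E-step**: scaled forward–backward recursions over each individual's
  consecutive years, vectorised across individuals; numerically stable for
  horizons of at least 60 years (verified by test). A brute-force
  enumeration of all `M^T` paths serves as an independent oracle for small
  `T` and is never used in production fitting.
* **M-step**: posterior-weighted maximum likelihood for every block, each
  iterated to full convergence (which is what makes the EM ascent property
  hold exactly): a damped-Newton weighted multinomial logit (written
  in-package because no installed library accepts fractional per-category
  observation weights) for the initial-state and transition blocks and the
  use part of the cost models; closed-form weighted category frequencies
  (floored at 1e−12) for the indicator intercepts; a Gamma GLM with
  variance weights for positive costs (statsmodels IRLS, with a damped,
  step-halving Fisher-scoring fallback for degenerate weighted subsamples),
  followed by a one-dimensional profile-likelihood solve for the shape.
* **Initialisation**: a deterministic partition of individual-years by mean
  standardised indicator severity (1-D k-means), softened to 0.85/0.075
  posteriors, followed by one M-step. Additional random-posterior restarts
  are available (`n_restarts`); the default is the single deterministic
  start, which in recovery experiments always attains the same optimum as
  restarted runs.
* **Convergence**: relative log-likelihood change below 1e−7 (default) or
  500 iterations. Gamma-mean linear predictors are clipped at ±30 inside
  the E-step so that a runaway intermediate fit on a near-empty state
  cannot produce non-finite posteriors.
* **Identification**: the mixture is unconstrained during estimation;
  states are labelled afterwards by mean standardised severity (death-risk
  at the reference profile breaks ties), which leaves the likelihood
  unchanged.

Information criteria (AIC, BIC with `n` = individual-year records) support
choosing the number of states; non-converged candidates are flagged rather
than compared.

**Ex-post cost models.** Home-care and institutional LTC costs are observed
only in a late registry window (2004–2007 in the default design). Their
two-part models are fitted after the main fit, holding all structural and
indicator parameters fixed: starting from the converged posteriors, the
service's parameters are fitted by posterior-weighted likelihood on the
window, the posteriors are refreshed with the service's own emission
included, and the fit repeated (5 refinements by default). The refresh step
matters: a single soft-weighted pass leaks the poor state's high LTC use
into the moderate state (errors of 70–110 % on the moderate state's
expected cost in recovery experiments); with refinement the materially-used
states recover within roughly 15 %. Expected costs of a state that barely
uses a service (good-state LTC) sit at the noise floor and are only
meaningful on the scale of the material states. Calendar-year dummies in
ex-post fits span the window years only (the full dummy set is collinear on
the window).

## Scenarios and calibration

All scenarios share the fitted 2010 model and differ in how transition
rows are adjusted from 2011 on, always by a compounding annual factor
`(1 − x)^(year − 2010)` applied as a multiplier to selected entries with
the freed probability mass reallocated:

* **Expansion of morbidity** (`1o`, `1++`): the death entry of every living
  row is scaled; freed mass stays in the current state. Only the death and
  diagonal entries change.
* **Compression of morbidity** (`2o`, `2+`, `2++`): for good and moderate
  origins, all strictly worse living destinations and death are scaled;
  freed mass goes to the diagonal. The poor-origin row is bit-identical to
  baseline. (Reallocating to the diagonal is the minimal reading of
  "remaining in good or moderate health"; it is the one genuinely open
  operator choice.)
* **Dynamic equilibrium** (`3o`, `3+`, `3++`): for good and moderate
  origins, the poor and death entries are scaled and the freed mass goes to
  the moderate entry; a second rate scales dying out of poor health, with
  freed mass staying in poor.

Scenarios `2+`, `2++`, `3+`, `3++` additionally move the entrant profile at
65 linearly in calendar year from its 2010 value to a 2050 endpoint (100 %
good health, or 45 % moderate), scaling the other living states
proportionally; the ramp endpoints follow the stated percentages exactly.
The ramp is fixed first, then the transition rate(s) solved.

**Life-table conventions.** Remaining LE at 65 in year Y uses the period
convention: rates frozen at their Y-adjusted values while the synthetic
cohort ages. Per-state years sum start-of-year occupancies with a half-year
credit in the year of death; ages are capped at 110 (nobody lives past age
109; survivors reaching the cap are removed). Both conventions are
configurable on `ScenarioModel`. Transition covariates besides age and sex
are fixed at representative values (partnered, low education).

**Calibration.** Expansion/compression: Brent root finding on the annual
rate (bracket grown adaptively from 0.01, cap 0.5; xtol 1e−7, far below
the 0.005-year acceptance band on LE). Dynamic: a nested solve — the inner
Brent solve sets the poor-death rate so expected poor-state years equal
their baseline value, the outer solve sets the main rate so total LE hits
the target. LE is strictly increasing in each scenario's rate over the
bracket (verified by sweep), so roots are unique. Targets are per sex
(21.1/24.6 years standard, 24.1/27.6 optimistic); unreachable targets raise
an error reporting the achievable LE range.

## Cohort projection and outcomes

The 65+ population is projected 2010–2050 as expected values: counts over
age (65–109) × sex × living state are redistributed each year by the
scenario matrices of that calendar year, ages advance, deaths accumulate,
and a new entrant cohort of 65-year-olds joins with the scenario's ramped
profile. The projection is linear in the population, satisfies the exact
accounting identity alive(t+1) = alive(t) − deaths(t) + entrants(t+1), and
matches a seeded 50,000-individual microsimulation of the same model within
Monte-Carlo error (the microsimulation exists as a test oracle, not a
production path).

Costs are undiscounted, in abstract cost units, accrue to the state
occupied at the start of each year, and the year of death carries the same
half-year credit as the life table — so a lone entering cohort's aggregate
expenditure series equals its lifetime cost stream identically. Calendar-
year cost effects apply only inside the estimation window; projection years
use the reference-year level. Aggregate growth is reported as the geometric
mean over 2010–2050.

**Demographic inputs.** Real base-population and entrant series are
configuration inputs. The bundled synthetic default uses flat entrant
cohorts (10,000 per sex per year) and, for the 2010 stock, the baseline
model's stationary age profile truncated at age 95, with age/sex state
shares obtained by ageing the 65-year-old baseline profile. A flat stock
would be demographically inconsistent with flat entrants (the population
would decay ~45 % toward equilibrium and swamp the scenario signal).

## The synthetic-data generator

The generator emulates the statistical structure of a linked survey–
registry panel of older adults: entry ages uniform on 55–85 at the 1995
panel start, a refreshment cohort of 55–64-year-olds in 2002 sized at about
24 % of all respondents, tri-annual indicator interviews plus exact
observation of death, annual hospital costs, and home-care/LTC costs
observed 2004–2007 only. Partner status decays by a 3 %/year widowhood
hazard; education is fixed at entry (40/40/20 % low/mid/high).

The default ground truth anchors its demographic core to published
quantities: the baseline transition rows for men at 75 (good row
0.87/0.07/0.04/0.02; printed zero entries are replaced by small positive
values a logit can represent) and the baseline health profile at 65
(0.66/0.27/0.06). Death-logit slopes are fixed at demographically plausible
values — mortality odds doubling per decade of age, a −0.5 female shift —
giving baseline remaining LE at 65 of 15.0 years (men) and 17.8 (women),
consistent with the Netherlands over the emulated 1995–2007 window and
below every 2050 calibration target. Indicator emissions are binomial-
shaped category distributions whose standardised severities rise strictly
good → moderate → poor on all seven indicators, mirroring the qualitative
pattern of the estimated model (state 2: high chronic disease, low
cognitive/depressive problems; state 3: high disability and mental-health
problems, self-perceived health only slightly worse than state 2). Cost
anchors give poor > moderate > good expected costs at ages 65–85, with LTC
by far the most state-sensitive service. Across seeds the demographic core
is identical (so scenario calibrations are stable); indicator severities
and cost anchors carry a small seeded jitter.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: informative non-mortality dropout, irregular
interview spacing, measurement error in the linkage, within-person serial
correlation of costs beyond the state, price inflation or cost weights
(costs are abstract units), and real Dutch demography (the euro amounts and
growth-rate ranges of the original study depend on those undeposited
inputs and are out of scope).

## Problem sizes and numerical tolerances used in the tests

Unit tests use panels of 40–700 individuals; the parameter-recovery
experiment uses the stated 2000 individuals × 13 years over 10 seeds with
EM at tol 1e−6 (pass sets are identical at 1e−7); the microsimulation
cross-check uses 50,000 individuals in 10 batches, compared at 3 batch-mean
standard errors. Forward–backward equals brute-force enumeration to 1e−10
relative on 100+ random instances; EM ascent is asserted at 1e−8; operator
row sums at 1e−12; projection accounting and cohort/aggregate consistency
at 1e−9 relative.

## Known limitations

* The EM estimates are exact MLEs, but the recovery experiment shows the
  max-over-cells errors at n = 2000 sit near ±0.02 (transitions) / ±0.03
  (emissions) — max statistics over ~80 cells at roughly their information
  bound — so individual seeds can exceed those bands without any bias
  (worst observed |mean error| across seeds is below 0.008 everywhere).
* Ex-post cost estimates for states that barely use a service are noise-
  floor quantities; interpret them on the scale of the material states.
* The projection fixes partner status and education at representative
  values rather than integrating over their joint distribution with age.
* Standard errors for the fitted parameters are not computed (the original
  analyses report point projections); the bootstrap would be the natural
  addition.
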