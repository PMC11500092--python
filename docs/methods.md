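# Methods

## Trajectory reconstruction and the medication possession ratio

For each person and medication class, purchases are ordered by date (ties
broken by ATC code, lexicographically), same-day purchases of the same
formulation are merged by summing tablets, and dose-distribution service
purchases (biweekly pharmacy dispensing) are removed with their reason
recorded. Each purchase carries a supply of `tablets / daily_dose` days
(default daily dose: 1 tablet for every class).

The MPR is an interval-sum ratio over *included* purchases:

* the final purchase is always excluded (it opens no interval);
* in the `finregistry` dialect, a purchase followed by at least 150
  tablet-free days (interval − supply ≥ 150) is a treatment break and
  contributes neither its tablets nor its interval; the trajectory is not
  split — a single pooled ratio is computed across the break;
* in the `estbb` dialect no break exclusion applies: all gaps count as true
  treatment interruptions and remain in the denominator, which is why the
  Estonian reading yields systematically lower MPR on cohorts with breaks;
* at a formulation switch (different full 7-character ATC code) arriving
  before supply exhaustion, leftover tablets are discarded
  (`effective = interval × dose`); same-formulation surplus carries over,
  which is how MPR can exceed 1.

Eligibility for the adherence analysis requires a first-to-last purchase
span ≥ 365 days (computed over all non-dose-distribution purchases, before
the last-purchase exclusion), ≥ 2 included purchases, and MPR ≤ 1.1 (the
value 1.1 itself is retained). The Estonian dialect additionally requires
≥ 150 total tablets. Exclusion reasons are attributed with precedence
span → purchase count → tablet minimum → cap; the order affects reason
labels only, never membership. All date arithmetic is integer days.

An independent **day-by-day tablet ledger** (`adherekit.reference`) recomputes
the MPR by walking the calendar one day at a time with a tablet stock,
deriving breaks, switch truncation and observation days from first
principles. The test suite asserts exact agreement (flags identical, MPR
within 1e-12) on handcrafted cases, hypothesis-generated trajectories and
1,000 simulated persons spanning all archetypes. The ledger's day
resolution matches the interval arithmetic whenever per-purchase supply is
a whole number of days, which the generator guarantees.

## Persistence

Primary definition: persons with exactly one purchase made at least
`censor_buffer_days = 730` days before the end of follow-up
(min(death, emigration, registry end — default 2020-01-01)) are
**non-persistent**; the adherence-eligible set is **persistent**; a single
purchase inside the buffer is `excluded_censored`; two or more purchases
without adherence eligibility is `excluded_intermediate`. The Estonian
dialect additionally requires the discontinuation purchase to contain fewer
than 3 packages and fewer than 100 tablets (bulk purchases may be stocking
up before emigration), to be dated before 2022-01-01 and at least one year
before death; a bulk single purchase is assigned `excluded_intermediate`.

Sensitivity definition: among persons whose first purchase lies at least
365 days before the end of follow-up, anyone whose last purchase falls
within 365 days of the first is non-persistent — no stockpiling exclusion.
The 365-day observability window is this package's choice: without it the
definition is biased near the registry end.

Cohort rules: age ≥ 18 at first purchase; breast-cancer medications
restricted to females with a prior C50 diagnosis; DOACs require a prior
I48/I26/I80/I87.1 diagnosis; antiplatelets get adherence only (persistence
marked not-applicable, the class being commonly prescribed for 6–12-month
courses). Every exclusion is tallied stage by stage and the audit must
reconcile: rows in = rows out + Σ excluded.

## Covariates

Eight baseline factors at treatment initiation: sex, age, secondary
prevention (class-specific ICD-10 lists, shipped as a plain-text table;
not defined for BP medications), Charlson comorbidity index, education
years, urban living, Finnish/Swedish mother tongue, social assistance in
the year before initiation; plus polytherapy (other study classes purchased
within ±365 days of initiation). The CCI uses the Quan (2005) ICD-10
mapping with the original Charlson weights (1/2/3/6), each of the 17
condition groups counted once, with the standard hierarchy (complicated
diabetes over uncomplicated, severe over mild liver disease, metastatic
over non-metastatic cancer). ICD-10 matching is dot-stripped
longest-prefix. "University or higher" is operationalized as ≥ 16 education
years in the synthetic schema. Dichotomized encoding: age > 60 (strict),
CCI > 5, university-or-higher; continuous encoding standardizes age, CCI
and education to mean 0, variance 1 (population SD) within the cohort.
Analyses are complete-case with the dropped count reported.

## Association models

Persistence: maximum-likelihood logistic regression (statsmodels `Logit`),
persistent coded 1, excluded statuses dropped; effects as odds ratios with
Wald 95% CIs and two-sided p-values from the standard-normal reference.
Adherence: OLS with t-based intervals; coefficients and CIs rescaled to
percentage change in adherence by `100/1.1` exactly (the phrase "rescaling
the log(OR) from the linear model" is read as rescaling the linear
coefficient — linear models have no odds ratios). All models adjust for
year of birth; no multiplicity adjustment. Separation or non-convergence
produces flagged results, never silent output; a single-class outcome is an
error. Variance explained is adjusted R² (linear) or McFadden pseudo-R²
(logistic), always labelled. Categorical pharmacogene-style phenotypes are
fit with one indicator per non-reference level; levels with fewer than 5
individuals in the relevant analysis set are suppressed with their rows
removed and the level reported back.

## GWAS power

Single-variant additive power for a quantitative trait under Hardy-Weinberg
genotype variance `2p(1−p)`: noncentrality `λ = n·2·maf·(1−maf)·(β/σ)²`,
power = P(noncentral χ²(1, λ) > central χ²(1) critical value at α).
Covariate adjustment is ignored (standardized-residual approximation);
α defaults to 5×10⁻⁸ with 1×10⁻⁸ also exposed. At β = 0 the function
returns α exactly. The Monte-Carlo verification simulates the
known-variance Wald statistic — the quantity this formula describes; an
estimated-variance Wald is a squared t whose heavier tails are visible at
extreme thresholds and tiny n (at n = 200, α = 5×10⁻⁸ the squared-t power
is ~7.5×10⁻⁴ against the formula's 4.0×10⁻⁴), a property of the statistic
rather than a defect of either computation.

## Synthetic register generator

The generator emulates the statistical structure of a national purchase
register for one medication class; everything is a deterministic function
of the mandatory seed. Defaults (chosen once, as a realistic well-adhering
statin-like cohort): 10-year registry window (2010–2020), initiation
uniform up to 3 years before the registry end, one 100-tablet package per
purchase at 1 tablet/day, mean refill interval 110 days (so the mean target
MPR is 100/110 ≈ 0.91), refill jitter SD 10 days, archetype mix 80%
regular / 5% early discontinuer / 6% break taker / 3% stockpiler /
4% switcher / 2% short course, death 3% and emigration 1% with uniform
dates, covariate prevalences: social assistance 10%, Finnish/Swedish
mother tongue 95%, urban 70%.

Adherence is induced **mechanistically**: each person's refill interval is
`supply / m + jitter`, where the person-level target MPR `m` is drawn as
`1 − Gamma` with mean `base_mpr` and SD `adherence_person_sd = 0.06`. The
`1 − Gamma` shape is deliberate: observed MPR distributions are
left-skewed with a mode near full possession, and a regular refiller can at
most refill on schedule — systematically early purchasing is the stockpiler
archetype (cadence rate 1.25–1.6, driving MPR past the 1.1 cap). Keeping
the regular-refiller distribution below 1 also keeps it clear of the
analysis cap, which makes injected covariate effects identifiable: a
distribution with tail mass at the cap suffers differential
truncation-by-exclusion between covariate groups, an n-independent bias
that would break parameter recovery (with a Gaussian tail at the cap the
attenuation is ~0.02 percentage points of adherence — measurable against a
CI half-width of ~0.2 at n = 20,000).

Covariate adherence effects shift `m` additively; persistence effects shift
the log-odds of the early-discontinuer archetype (so a fitted logistic
model of persistent vs non-persistent recovers the injected log-odds
directly). Break takers get one guaranteed gap of supply + 150 + Exp(60)
days; switchers one early refill (0.3–0.8 of supply) with a formulation
change; short courses 2–3 purchases within a year. Diagnoses: a
configurable fraction of persons receive one class-relevant qualifying code
before first purchase, and comorbidity burden is a Poisson number of
distinct Charlson conditions (one representative code each), validated
against a Monte-Carlo expectation of the same sampling scheme.

What the generator does **not** emulate: package-size heterogeneity and
national formularies (VNR catalogs), dose titration, seasonal purchasing,
reimbursement tiers, correlated covariates, or the long lower tail of
severely non-adherent patients (real statin cohorts show adherence SDs
around 0.12, against ~0.06 here). Passing tests therefore demonstrate the correctness of the
accounting rules and the recoverability of injected effects under clean
conditions — not calibration to any real population.

## Experiment scales and calibration checks

Replicated experiments (parameter recovery, null calibration) run on a
4-year registry window with initiation in the first 18 months — every
person has ample follow-up for both phenotypes while 100 replicates of a
20,000-person cohort remain desk-sized. Recovery: injected effects
(−0.03 MPR on adherence, −0.5 log-odds on persistence, prevalence-0.3
indicator) are covered by their fitted 95% intervals at nominal frequency.
Null calibration: with no injected effects, per-term Wald tests at
α = 0.05 are calibrated; the empirical type-I error is assessed pooled
over all covariate terms and both models against the exact binomial
acceptance region — per-term-per-model checking would multiply 95% checks
and reject a correct implementation ~25% of the time by chance.

## Known limitations

* Formulation identity is the full ATC code; package-level (VNR)
  granularity is not modelled.
* The interval-sum denominator and a last-minus-first-minus-gaps
  denominator coincide only when exclusions are interval-contiguous; the
  interval-sum reading is implemented throughout (and is what the
  day-by-day ledger verifies).
* The monotonicity guarantee — delaying a refill never increases MPR —
  holds for single-formulation trajectories; with switch truncation a
  delayed switch lengthens the truncated interval and can raise the ratio.
* Fractional per-purchase supplies (non-integer tablets/dose) would differ
  from the day-resolution ledger at the one-day level; the generator emits
  integer supplies.
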