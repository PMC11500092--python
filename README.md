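# adherekit

Phenotyping of drug **adherence** and **persistence** from pharmacy
purchase registers, with a synthetic-register simulator, multivariable
risk-factor models, and an analytic GWAS power calculation.

## The problem

Nationwide prescription registers record every reimbursed pharmacy purchase
(date, ATC code, package count, tablets per package). From these
longitudinal purchase trajectories two established drug-taking phenotypes
can be reconstructed for medications requiring long-term regular therapy
(statins, blood-pressure medications, antiplatelets, direct oral
anticoagulants, breast cancer endocrine therapy):

* **Adherence** — the medication possession ratio,

  ```
  MPR = days of supply obtained during the observation period
        ─────────────────────────────────────────────────────
        days in the observation period
  ```

  where the numerator is total tablets purchased normalized by the
  class-specific daily dose, and the denominator is the sum of
  inter-purchase intervals. Reconstruction excludes the final purchase,
  dose-distribution service purchases, and (in the Finnish rule dialect)
  purchases followed by ≥150 tablet-free days (treatment breaks); leftover
  tablets are discarded at formulation switches. Individuals need ≥1 year
  of purchases and MPR ≤ 1.1 (stockpiling exclusion) to enter the analysis.

* **Persistence** — a binary contrast between individuals purchasing for at
  least 12 months (the adherence-eligible set) and early discontinuers who
  stop after a single purchase observed at least 2 years before the end of
  follow-up (death, emigration, or registry end). A sensitivity definition
  instead counts anyone stopping within one year of the first purchase.

Because individual-level register data are access-controlled, the package
ships a **synthetic register generator** whose cohorts realize known
behavioral archetypes (regular refillers, early discontinuers, break
takers, stockpilers, formulation switchers, short courses) and carry
injected covariate effects on adherence and persistence — so the whole
pipeline is testable end to end against generative ground truth.

Downstream, the **association module** fits the multivariable models used
in registry studies: logistic regression for persistence (effects as odds
ratios, Wald 95% CIs) and OLS for adherence, with coefficients rescaled to
the percentage change in adherence by `100·β/1.1` (1.1 being the maximum
admissible MPR). `gwas_power` computes single-variant additive test power
via the noncentral chi-square with `λ = n·2p(1−p)·(β/σ)²`.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # 20,000-person synthetic statin register
python analysis/02_phenotype_cohort.py    # trajectories → phenotypes, both dialects
python analysis/03_derive_covariates.py   # eight baseline risk factors
python analysis/04_fit_risk_factors.py    # multivariable models vs injected truth
python analysis/05_power_analysis.py      # analytic power grid + Monte-Carlo check
```

Step 02 prints the cohort summary for the Finnish dialect (seed 2026):

```
n_individuals  proportion_persistent  mean_adherence  sd_adherence  mean_treatment_length_years
        18713                 0.9449           0.907        0.0634                       6.3125
```

— 18,713 of 20,000 simulated persons enter an analysis (the rest are
censored or excluded as stockpilers/short spans), 94.5% persist, and mean
MPR is 0.91: the generator's defaults emulate a well-adhering statin
cohort. Step 04 then recovers the injected social-assistance effects:

```
persistence OR 0.530 [0.447, 0.628]   vs injected 0.607
adherence change -2.83% [-3.11, -2.55] vs injected -2.73%
```

Both 95% intervals cover the generative truth (an absolute −0.03 MPR shift
equals −2.73% after the 100/1.1 rescaling). Step 05 reports ~100% power to
detect a 2.7-percentage-point adherence effect at MAF 0.3 for a cohort of
116,439 — comfortably above the 80% benchmark — and verifies the analytic
formula against 100,000 simulated Wald tests.

The same stages are scriptable via the CLI
(`adherekit run --config run.yaml --out DIR`, plus `simulate`,
`phenotype`, `covariates`, `associate`, `power`, `summarize` subcommands);
a run writes `manifest.json` with the config hash, per-stage row counts and
a reconciled attrition audit.

## Layout

```
src/adherekit/     library: simulate, trajectories, phenotypes, covariates,
                   charlson, association, harness, pipeline, cli
analysis/          numbered narrative drivers writing results/
tests/             pytest suite (unit, property, acceptance-level)
docs/methods.md    model, assumptions, parameter choices, limitations
```
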