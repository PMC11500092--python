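"""Parameter-recovery and calibration harnesses.

These run the full simulate -> phenotype -> covariates -> associate chain on
cohorts with known injected effects (or none) and report whether the fitted
models recover the generative truth.  Study windows are kept at four
registry years with initiation in the first eighteen months so that every
person has ample follow-up for both phenotypes while replicated runs stay
cheap; the injected-effect magnitudes (an absolute MPR shift of -0.03 and a
persistence log-odds shift of -0.5 on a prevalence-0.3 indicator) are the
harness's reference conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .association import ModelSpec, fit_adherence, fit_persistence
from .covariates import build_covariates, encode_covariates
from .phenotypes import build_phenotypes
from .rules import estbb_rules, finregistry_rules
from .simulate import CovariateEffect, SimulationConfig, simulate_cohort

INJECTED_ADHERENCE_EFFECT = -0.03  # absolute MPR change
INJECTED_PERSISTENCE_LOGODDS = -0.5
EFFECT_COVARIATE = "social_assistance"
EFFECT_PREVALENCE = 0.3

_WINDOW = dict(
    study_start=date(2010, 1, 1),
    study_end=date(2014, 1, 1),
    initiation_latest=date(2011, 6, 1),
)


@dataclass
class RecoveryResult:
    pct_change: float
    pct_ci: tuple[float, float]
    pct_truth: float
    log_or: float
    log_or_ci: tuple[float, float]
    log_or_truth: float

    @property
    def adherence_covered(self) -> bool:
        return self.pct_ci[0] <= self.pct_truth <= self.pct_ci[1]

    @property
    def persistence_covered(self) -> bool:
        return self.log_or_ci[0] <= self.log_or_truth <= self.log_or_ci[1]


def _fit_cohort(cfg: SimulationConfig, terms: list[str]):
    purchases, diagnoses, persons, _ = simulate_cohort(cfg)
    rules = finregistry_rules(registry_end=cfg.study_end, daily_dose=cfg.daily_dose)
    phenotypes, _ = build_phenotypes(purchases, persons, diagnoses, cfg.medication_class, rules)
    raw = build_covariates(persons, diagnoses, purchases, phenotypes, cfg.medication_class)
    encoded, _ = encode_covariates(raw, "dichotomized")
    data = phenotypes.merge(encoded, on="person_id")
    res_a = fit_adherence(ModelSpec("adherence", terms), data)
    res_p = fit_persistence(ModelSpec("persistence_primary", terms), data)
    return res_a, res_p


def recovery_replicate(seed: int, n_persons: int = 20_000) -> RecoveryResult:
    """One seeded replicate of the injected-effect recovery experiment."""
    cfg = SimulationConfig(
        n_persons=n_persons,
        seed=seed,
        archetype_mix={"regular": 0.8, "early_discontinuer": 0.2},
        covariate_effects={
            EFFECT_COVARIATE: CovariateEffect(
                INJECTED_ADHERENCE_EFFECT, INJECTED_PERSISTENCE_LOGODDS
            )
        },
        covariate_prevalences={
            EFFECT_COVARIATE: EFFECT_PREVALENCE,
            "language_fi_sv": 0.95,
            "urban": 0.7,
        },
        **_WINDOW,
    )
    res_a, res_p = _fit_cohort(cfg, [EFFECT_COVARIATE])
    ra, rp = res_a[0], res_p[0]
    return RecoveryResult(
        pct_change=ra.effect,
        pct_ci=(ra.ci_low, ra.ci_high),
        pct_truth=100.0 * INJECTED_ADHERENCE_EFFECT / 1.1,
        log_or=rp.estimate,
        log_or_ci=(np.log(rp.ci_low), np.log(rp.ci_high)),
        log_or_truth=INJECTED_PERSISTENCE_LOGODDS,
    )


def null_replicate(seed: int, n_persons: int = 1500) -> list[float]:
    """P-values of every per-term Wald test under the generator's null."""
    terms = ["social_assistance", "language_fi_sv", "urban"]
    cfg = SimulationConfig(
        n_persons=n_persons,
        seed=seed,
        archetype_mix={"regular": 0.85, "early_discontinuer": 0.15},
        **_WINDOW,
    )
    res_a, res_p = _fit_cohort(cfg, terms)
    return [r.p_value for r in res_a + res_p]


def dialect_contrast(seed: int, n_persons: int = 1500) -> tuple[float, float]:
    """Mean adherence under the Finnish vs Estonian dialect on a cohort with
    break takers; the Estonian reading keeps gap days in the denominator."""
    cfg = SimulationConfig(
        n_persons=n_persons,
        seed=seed,
        archetype_mix={"regular": 0.5, "break_taker": 0.5},
        **_WINDOW,
    )
    purchases, diagnoses, persons, _ = simulate_cohort(cfg)
    means = []
    for rules in (
        finregistry_rules(registry_end=cfg.study_end),
        estbb_rules(registry_end=cfg.study_end),
    ):
        phenotypes, _ = build_phenotypes(purchases, persons, diagnoses, "statins", rules)
        means.append(float(phenotypes["adherence"].mean()))
    return means[0], means[1]


def simulate_wald_power(
    n: int,
    maf: float,
    beta: float,
    trait_sd: float,
    alpha: float,
    n_sims: int,
    seed: int,
    chunk: int = 20_000,
) -> tuple[float, float]:
    """Monte-Carlo power of the single-variant Wald chi-square test.

    Simulates genotype/trait pairs, regresses the trait on allele count and
    rejects when the 1-df Wald statistic exceeds the central chi-square
    critical value.  The statistic uses the true residual variance — the
    quantity the noncentral chi-square formula describes; plugging in the
    estimated variance instead turns the statistic into a squared t, whose
    heavier tails are visible at extreme significance thresholds and tiny n.

    Returns (power estimate, Monte-Carlo standard error).
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    crit = stats.chi2.isf(alpha, df=1)
    hits = 0
    done = 0
    while done < n_sims:
        r = min(chunk, n_sims - done)
        g = rng.binomial(2, maf, size=(r, n)).astype(float)
        y = g * beta + rng.normal(0.0, trait_sd, size=(r, n))
        gc = g - g.mean(axis=1, keepdims=True)
        sxx = (gc**2).sum(axis=1)
        slope = (gc * y).sum(axis=1) / sxx
        wald = slope**2 * sxx / trait_sd**2
        hits += int((wald > crit).sum())
        done += r
    p = hits / n_sims
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_sims))
    return p, se
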