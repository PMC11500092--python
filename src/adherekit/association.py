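"""Multivariable risk-factor models for persistence and adherence.

Persistence (persistent vs early-discontinuer) is modelled with multivariable
logistic regression; effects are reported as odds ratios with Wald 95%
confidence intervals and two-sided p-values from the standard-normal
reference.  Adherence (MPR in (0, 1.1]) is modelled with ordinary least
squares; coefficients are rescaled to the percentage change in adherence by
100 * beta / 1.1 (1.1 being the maximum admissible adherence value), with CIs
rescaled identically and p-values from the t reference.  All models adjust
for year of birth by default and are complete-case; no multiple-testing
adjustment is applied.

Variance explained is adjusted R-squared for linear models and McFadden's
pseudo R-squared for logistic models.

:func:`gwas_power` is the analytic power of a single-variant additive
association test for a quantitative trait: with Hardy-Weinberg genotype
variance 2p(1-p), the 1-df Wald chi-square has noncentrality
lambda = n * 2 * maf * (1 - maf) * (beta / trait_sd)^2 and power is the
probability that a noncentral chi-square(1, lambda) exceeds the central
chi-square critical value at the chosen significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phenotypes import NON_PERSISTENT, PERSISTENT

#: Maximum admissible adherence; the rescaling divisor for percentage change.
ADHERENCE_RESCALE = 1.1


@dataclass
class ModelSpec:
    outcome: str  # persistence_primary | persistence_sensitivity | adherence
    covariates: list[str]
    encoding: str = "dichotomized"
    adjust_for: tuple[str, ...] = ("year_of_birth",)
    medication_class: str | None = None

    def design_columns(self) -> list[str]:
        return list(self.covariates) + [c for c in self.adjust_for if c not in self.covariates]


@dataclass
class AssociationResult:
    term: str
    estimate: float  # log-odds or raw linear coefficient
    effect: float  # odds ratio or percentage change in adherence
    effect_type: str  # "odds_ratio" | "pct_change_adherence"
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    model: str  # "logistic" | "linear"
    converged: bool
    variance_explained: float
    variance_explained_metric: str
    note: str = ""


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    cols = spec.design_columns()
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"design columns absent from data: {missing}")
    X = data[cols].astype(float)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    return X, rank


def _binary_outcome(data: pd.DataFrame, outcome: str) -> pd.Series:
    y = data[outcome]
    if y.dtype == object or str(y.dtype) == "category":
        keep = y.isin([PERSISTENT, NON_PERSISTENT])
        y = y[keep].map({PERSISTENT: 1, NON_PERSISTENT: 0})
    else:
        y = y.dropna().astype(int)
    return y


def fit_persistence(spec: ModelSpec, data: pd.DataFrame) -> list[AssociationResult]:
    """Multivariable logistic model of persistence; one result per covariate term.

    Excluded persistence statuses are dropped; the persistent class is coded
    1.  Non-convergence or separation yields flagged (``converged=False``)
    results rather than silent output; a single-class outcome is an error.
    """
    y = _binary_outcome(data, spec.outcome)
    rows = data.loc[y.index]
    sub = rows[spec.design_columns()].dropna()
    y = y.loc[sub.index].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome has a single class; logistic model is undefined")
    X, rank = _design(sub, spec)
    note = "" if rank == X.shape[1] else "collinear_design"
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False)) and note == ""
        ve = float(res.prsquared)
    except Exception as exc:  # separation and friends
        return [
            AssociationResult(
                term, np.nan, np.nan, "odds_ratio", np.nan, np.nan, np.nan,
                int(len(y)), "logistic", False, np.nan, "mcfadden_pseudo_r2",
                note=f"fit_failed:{type(exc).__name__}",
            )
            for term in spec.covariates
        ]
    ci = res.conf_int(alpha=0.05)
    out = []
    for term in spec.covariates:
        out.append(
            AssociationResult(
                term=term,
                estimate=float(res.params[term]),
                effect=float(np.exp(res.params[term])),
                effect_type="odds_ratio",
                ci_low=float(np.exp(ci.loc[term, 0])),
                ci_high=float(np.exp(ci.loc[term, 1])),
                p_value=float(res.pvalues[term]),
                n=int(len(y)),
                model="logistic",
                converged=converged,
                variance_explained=ve,
                variance_explained_metric="mcfadden_pseudo_r2",
                note=note,
            )
        )
    return out


def fit_adherence(spec: ModelSpec, data: pd.DataFrame) -> list[AssociationResult]:
    """Multivariable linear model of adherence with the 1.1 percentage rescaling."""
    sub = data.dropna(subset=[spec.outcome] + spec.design_columns())
    if sub.empty:
        raise ValueError("no complete-case rows for the adherence model")
    y = sub[spec.outcome].astype(float)
    X, rank = _design(sub, spec)
    note = "" if rank == X.shape[1] else "collinear_design"
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    scale = 100.0 / ADHERENCE_RESCALE
    out = []
    for term in spec.covariates:
        out.append(
            AssociationResult(
                term=term,
                estimate=float(res.params[term]),
                effect=float(res.params[term] * scale),
                effect_type="pct_change_adherence",
                ci_low=float(ci.loc[term, 0] * scale),
                ci_high=float(ci.loc[term, 1] * scale),
                p_value=float(res.pvalues[term]),
                n=int(len(y)),
                model="linear",
                converged=note == "",
                variance_explained=float(res.rsquared_adj),
                variance_explained_metric="adjusted_r2",
                note=note,
            )
        )
    return out


def variance_explained(fitted) -> tuple[float, str]:
    """Variance explained by a fitted statsmodels result, with its metric label."""
    if hasattr(fitted, "prsquared"):
        return float(fitted.prsquared), "mcfadden_pseudo_r2"
    if hasattr(fitted, "rsquared_adj"):
        return float(fitted.rsquared_adj), "adjusted_r2"
    raise TypeError("unsupported model result")


def fit_categorical_phenotype(
    spec: ModelSpec,
    data: pd.DataFrame,
    phenotype_column: str,
    reference_level: str,
    min_group: int = 5,
) -> tuple[list[AssociationResult], list[str]]:
    """Fit a categorical predictor (e.g. metabolizer phenotype) with one
    indicator per non-reference level.

    Levels observed in fewer than ``min_group`` analysis rows are suppressed
    (their rows dropped, the level reported back).  Returns
    ``(results, suppressed_levels)``.
    """
    levels = data[phenotype_column].dropna().unique().tolist()
    if reference_level not in levels:
        raise ValueError(f"reference level {reference_level!r} absent from data")
    if spec.outcome == "adherence":
        analysis = data.dropna(subset=[spec.outcome])
    else:
        analysis = data[data[spec.outcome].isin([PERSISTENT, NON_PERSISTENT])]
    counts = analysis[phenotype_column].value_counts()
    suppressed = [
        lv for lv in levels if lv != reference_level and counts.get(lv, 0) < min_group
    ]
    kept = [lv for lv in levels if lv not in suppressed]
    sub = data[data[phenotype_column].isin(kept)].copy()
    indicator_terms = []
    for lv in kept:
        if lv == reference_level:
            continue
        col = f"{phenotype_column}__{lv}"
        sub[col] = (sub[phenotype_column] == lv).astype(int)
        indicator_terms.append(col)
    level_spec = ModelSpec(
        outcome=spec.outcome,
        covariates=indicator_terms,
        encoding=spec.encoding,
        adjust_for=tuple(spec.adjust_for) + tuple(spec.covariates),
        medication_class=spec.medication_class,
    )
    if spec.outcome == "adherence":
        results = fit_adherence(level_spec, sub)
    else:
        results = fit_persistence(level_spec, sub)
    return results, suppressed


def gwas_power(
    n: float, maf: float, beta: float, trait_sd: float, alpha: float = 5e-8
) -> float:
    """Analytic power of a 1-df additive single-variant test on a quantitative trait."""
    if not 0 < maf < 1:
        raise ValueError("maf must be in (0, 1)")
    if trait_sd <= 0:
        raise ValueError("trait_sd must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    lam = n * 2.0 * maf * (1.0 - maf) * (beta / trait_sd) ** 2
    crit = stats.chi2.isf(alpha, df=1)
    if lam == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results (one row per term)."""
    return pd.DataFrame([r.__dict__ for r in results])
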