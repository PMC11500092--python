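"""Baseline risk-factor derivation at treatment initiation.

Eight epidemiological factors are measured at the time of the first purchase:
sex, age at initiation, secondary prevention (treatment started after a
class-related disease event), Charlson comorbidity index over all prior
diagnoses, years of education, living area (urban/rural), mother tongue
(Finnish/Swedish vs other, a proxy for first-generation immigration), and
receipt of social assistance in the year before initiation; plus polytherapy
(number of the other study medication classes purchased around initiation).

Two encodings are produced: dichotomized (age > 60, CCI > 5, university
degree or higher) for comparable effect sizes, and continuous (age, CCI and
education standardized to mean 0, variance 1 within the analysis cohort).
Analyses are complete-case; the dropped-row count is reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import codelists
from .charlson import cci_by_person
from .rules import RuleSet

#: Education-years threshold standing in for "university degree or higher".
UNIVERSITY_MIN_YEARS = 16.0

CONTINUOUS_FIELDS = ("age_at_init", "cci", "education_years")


def classify_secondary_prevention(
    diagnoses: pd.DataFrame,
    first_purchase_date,
    medication_class: str,
    codelist: dict[str, tuple[str, ...]] | None = None,
):
    """Secondary-prevention flag for one person.

    True iff any qualifying class-specific ICD-10 code strictly precedes the
    first purchase; ``None`` (not applicable) for BP medications, for which
    no specific preceding event is defined.
    """
    if medication_class not in codelists.MEDICATION_CLASSES:
        raise ValueError(f"unknown medication class: {medication_class!r}")
    if medication_class not in codelists.SECONDARY_PREVENTION_DEFINED:
        return None
    codelist = codelist or codelists.load_secondary_prevention_codelist()
    prefixes = codelist[medication_class]
    if diagnoses is None or len(diagnoses) == 0:
        return False
    dates = pd.to_datetime(diagnoses["date"])
    qualifying = diagnoses["icd10"].map(lambda c: codelists.matches_any_prefix(c, prefixes))
    return bool((qualifying & (dates < pd.Timestamp(first_purchase_date))).any())


def secondary_prevention_by_person(
    diagnoses: pd.DataFrame, first_purchase: pd.Series, medication_class: str
) -> pd.Series:
    """Vectorized secondary-prevention flags (person_id -> bool or NA)."""
    if medication_class not in codelists.SECONDARY_PREVENTION_DEFINED:
        return pd.Series(pd.NA, index=first_purchase.index, dtype="object")
    prefixes = codelists.load_secondary_prevention_codelist()[medication_class]
    out = pd.Series(False, index=first_purchase.index)
    if diagnoses is None or diagnoses.empty:
        return out
    dx = diagnoses[diagnoses["person_id"].isin(first_purchase.index)].copy()
    dx["norm"] = dx["icd10"].map(codelists.normalize_icd10)
    dx = dx[dx["norm"].map(lambda c: any(c.startswith(p) for p in prefixes))]
    if dx.empty:
        return out
    dx["date"] = pd.to_datetime(dx["date"])
    dx["cutoff"] = dx["person_id"].map(first_purchase)
    hits = dx[dx["date"] < dx["cutoff"]]["person_id"].unique()
    out.loc[out.index.intersection(hits)] = True
    return out


def count_polytherapy(
    purchases: pd.DataFrame,
    person_id,
    medication_class: str,
    first_purchase_date,
    window_days: int = 365,
) -> int:
    """Number of *other* study medication classes purchased within a window
    around treatment initiation (default +/- 365 days)."""
    rows = purchases[purchases["person_id"] == person_id]
    return int(
        polytherapy_by_person(
            rows, pd.Series([pd.Timestamp(first_purchase_date)], index=[person_id]),
            medication_class, window_days,
        ).iloc[0]
    )


def polytherapy_by_person(
    purchases: pd.DataFrame,
    first_purchase: pd.Series,
    medication_class: str,
    window_days: int = 365,
) -> pd.Series:
    """Vectorized polytherapy counts (person_id -> 0..4)."""
    out = pd.Series(0, index=first_purchase.index, dtype=int)
    rows = purchases[purchases["person_id"].isin(first_purchase.index)].copy()
    if rows.empty:
        return out
    atc = rows["atc"].astype(str)
    rows["pclass"] = pd.NA
    for cls, prefixes in codelists.ATC_CLASS_PREFIXES.items():
        rows.loc[atc.str.startswith(prefixes), "pclass"] = cls
    rows = rows.dropna(subset=["pclass"])
    rows = rows[rows["pclass"] != medication_class]
    if rows.empty:
        return out
    rows["date"] = pd.to_datetime(rows["date"])
    rows["anchor"] = rows["person_id"].map(first_purchase)
    w = pd.Timedelta(days=window_days)
    rows = rows[(rows["date"] >= rows["anchor"] - w) & (rows["date"] <= rows["anchor"] + w)]
    counts = rows.groupby("person_id")["pclass"].nunique()
    out.loc[counts.index] = counts.astype(int)
    return out


def build_covariates(
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    purchases: pd.DataFrame,
    phenotypes: pd.DataFrame,
    medication_class: str,
    polytherapy_window_days: int = 365,
) -> pd.DataFrame:
    """Raw covariate table for the phenotyped cohort (one row per person)."""
    cohort = phenotypes[["person_id", "first_purchase_date"]].copy()
    first = pd.Series(
        pd.to_datetime(cohort["first_purchase_date"]).to_numpy(),
        index=cohort["person_id"].to_numpy(),
    )
    people = persons.set_index("person_id").reindex(first.index)
    birth = pd.to_datetime(people["birth_date"])
    age = (first - birth).dt.days / 365.25

    cov = pd.DataFrame(
        {
            "person_id": first.index,
            "medication_class": medication_class,
            "age_at_init": age.to_numpy(),
            "year_of_birth": birth.dt.year.to_numpy(),
            "education_years": people["education_years"].to_numpy(),
            "urban": people["urban"].to_numpy(),
            "language_fi_sv": people["language_fi_sv"].to_numpy(),
            "social_assistance": people["social_assistance"].to_numpy(),
        }
    )
    if medication_class != "breast_cancer":  # all-female cohort: sex dropped
        cov["sex_female"] = (
            people["sex"].astype(str).str.lower().isin(["female", "f", "2"]).astype(int).to_numpy()
        )
    cov["secondary_prevention"] = secondary_prevention_by_person(
        diagnoses, first, medication_class
    ).to_numpy()
    cov["cci"] = cci_by_person(diagnoses, first).to_numpy()
    cov["n_concurrent_treatments"] = polytherapy_by_person(
        purchases, first, medication_class, polytherapy_window_days
    ).to_numpy()
    return cov


def encode_covariates(
    raw: pd.DataFrame, mode: str = "dichotomized", university_min_years: float = UNIVERSITY_MIN_YEARS
) -> tuple[pd.DataFrame, int]:
    """Encode the raw covariate table for modelling; complete-case only.

    ``dichotomized`` adds the binary cutpoints age_gt_60 (strictly > 60),
    cci_gt_5 and university_or_higher; ``continuous`` standardizes age, CCI
    and education to mean 0 / variance 1 within the cohort.  Returns the
    encoded table and the number of incomplete rows dropped.
    """
    if mode not in ("dichotomized", "continuous"):
        raise ValueError(f"unknown encoding mode: {mode!r}")
    df = raw.copy()
    check_cols = [c for c in df.columns if c not in ("secondary_prevention",)]
    complete = df[check_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    df = df[complete].copy()
    if df.empty:
        raise ValueError("no complete-case rows to encode")

    if mode == "dichotomized":
        df["age_gt_60"] = (df["age_at_init"] > 60).astype(int)
        df["cci_gt_5"] = (df["cci"] > 5).astype(int)
        df["university_or_higher"] = (df["education_years"] >= university_min_years).astype(int)
    else:
        for col in CONTINUOUS_FIELDS:
            x = df[col].astype(float)
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"zero-variance column in standardization: {col}")
            df[f"{col}_std"] = (x - x.mean()) / sd
    if "secondary_prevention" in df.columns and df["secondary_prevention"].notna().any():
        df["secondary_prevention"] = df["secondary_prevention"].astype("boolean").astype("Int64")
    return df, n_dropped
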