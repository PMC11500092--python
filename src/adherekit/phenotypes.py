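"""Per-person drug-taking phenotypes: adherence eligibility and persistence.

Persistence is a binary phenotype contrasting individuals who kept purchasing
the medication for at least 12 months (operationally: the adherence-eligible
set) against early discontinuers who stopped after a single purchase.  To
avoid right-censoring bias, a single purchase only counts as early
discontinuation when made at least ``censor_buffer_days`` (default two
years) before the end of follow-up — the earliest of death, emigration and
the registry end.  Everyone else is excluded from the contrast:

* ``excluded_censored`` — single purchase inside the censoring buffer;
* ``excluded_intermediate`` — two or more purchases but not
  adherence-eligible (e.g. stockpilers above the MPR cap, spans under a
  year).

The Estonian dialect additionally requires the discontinuation purchase to
contain fewer than 3 packages and fewer than 100 tablets (single bulk
purchases may be stocking up before e.g. moving abroad), to be dated before
the dialect's registry cutoff and at least a year before death.

The sensitivity definition instead asks whether the person stopped
purchasing within one year of the first purchase, among everyone observable
for at least a year, with no stockpiling exclusion.

:func:`build_phenotypes` applies the cohort rules (adults only; breast
cancer medications: females with a prior C50 diagnosis; DOAC: a prior atrial
fibrillation / venous thromboembolism diagnosis; antiplatelets: adherence
only, persistence not applicable) and emits one record per person with a
stage-by-stage attrition audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codelists
from .rules import RuleSet
from .trajectories import reconstruct, summarize_mpr

PERSISTENT = "persistent"
NON_PERSISTENT = "non_persistent"
EXCLUDED_CENSORED = "excluded_censored"
EXCLUDED_INTERMEDIATE = "excluded_intermediate"
NOT_APPLICABLE = "not_applicable"

PRIMARY_STATUSES = (PERSISTENT, NON_PERSISTENT, EXCLUDED_CENSORED, EXCLUDED_INTERMEDIATE)


@dataclass
class AttritionAudit:
    """Stage-wise exclusion tallies; rows_in == rows_out + sum(excluded)."""

    stages: list = field(default_factory=list)

    def record(self, stage: str, rows_in: int, rows_out: int, excluded: dict[str, int]) -> None:
        if rows_in != rows_out + sum(excluded.values()):
            raise ValueError(
                f"attrition does not reconcile at stage {stage!r}: "
                f"{rows_in} != {rows_out} + {sum(excluded.values())}"
            )
        self.stages.append(
            {"stage": stage, "rows_in": rows_in, "rows_out": rows_out, "excluded": dict(excluded)}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            for reason, count in s["excluded"].items():
                rows.append({"stage": s["stage"], "reason": reason, "count": count})
        return pd.DataFrame(rows, columns=["stage", "reason", "count"])

    def reconciles(self) -> bool:
        return all(
            s["rows_in"] == s["rows_out"] + sum(s["excluded"].values()) for s in self.stages
        )


def end_of_followup(persons: pd.DataFrame, ruleset: RuleSet) -> pd.Series:
    """min(death, emigration, registry end) per person, indexed by person_id."""
    end = pd.Timestamp(ruleset.registry_end)
    death = pd.to_datetime(persons.get("death_date"), errors="coerce")
    emig = pd.to_datetime(persons.get("emigration_date"), errors="coerce")
    eof = pd.concat(
        [death.fillna(end), emig.fillna(end)], axis=1
    ).min(axis=1).clip(upper=end)
    eof.index = persons["person_id"].to_numpy()
    return eof


def classify_persistence_primary(
    summary: pd.DataFrame, eof: pd.Series, ruleset: RuleSet, death: pd.Series | None = None
) -> pd.Series:
    """Primary persistence status per person from an adherence summary frame.

    ``summary`` is the output of :func:`adherekit.trajectories.summarize_mpr`;
    ``eof`` maps person_id to end of follow-up.  ``death`` (person_id ->
    death date) is only consulted by the Estonian dialect.
    """
    idx = summary["person_id"].to_numpy()
    eof_v = eof.reindex(idx)
    if eof_v.isna().any():
        raise ValueError("missing end_of_followup for some persons")
    single = summary["n_purchases"].to_numpy() == 1
    first = summary["first_purchase_date"]
    buffer_ok = (
        first.to_numpy() <= (eof_v - pd.Timedelta(days=ruleset.censor_buffer_days)).to_numpy()
    )

    if ruleset.dialect == "estbb":
        small = (
            (summary["total_packages"].to_numpy() < ruleset.estbb_nonpersist_max_packages)
            & (summary["total_tablets"].to_numpy() < ruleset.estbb_nonpersist_max_tablets)
        )
        cutoff_ok = first.to_numpy() < np.datetime64(ruleset.estbb_registry_cutoff)
        if death is not None:
            death_v = pd.to_datetime(death.reindex(idx), errors="coerce")
            death_ok = (
                death_v.isna().to_numpy()
                | (
                    first.to_numpy()
                    <= (death_v - pd.Timedelta(days=ruleset.estbb_death_buffer_days)).to_numpy()
                )
            )
        else:
            death_ok = np.ones(len(summary), bool)
        nonpersist = single & small & cutoff_ok & death_ok
        censored = single & small & ~(cutoff_ok & death_ok)
    else:
        nonpersist = single & buffer_ok
        censored = single & ~buffer_ok

    status = np.full(len(summary), EXCLUDED_INTERMEDIATE, dtype=object)
    status[summary["adherence_eligible"].to_numpy()] = PERSISTENT
    status[censored] = EXCLUDED_CENSORED
    status[nonpersist] = NON_PERSISTENT
    return pd.Series(status, index=summary.index)


def classify_persistence_sensitivity(
    summary: pd.DataFrame, eof: pd.Series, ruleset: RuleSet
) -> pd.Series:
    """Sensitivity persistence: stopping within one year of the first purchase.

    Counts anyone with at least one purchase; a person is non-persistent when
    the last purchase falls within ``sensitivity_censor_days`` of the first
    and no further purchase ever occurs.  Persons whose first purchase is not
    observable for a full censoring window before end of follow-up are
    ``excluded_censored``.  No stockpiling (MPR-cap) exclusion applies.
    """
    idx = summary["person_id"].to_numpy()
    eof_v = eof.reindex(idx)
    if eof_v.isna().any():
        raise ValueError("missing end_of_followup for some persons")
    observable = (
        summary["first_purchase_date"].to_numpy()
        <= (eof_v - pd.Timedelta(days=ruleset.sensitivity_censor_days)).to_numpy()
    )
    stopped_within_year = (
        summary["span_days"].to_numpy() < ruleset.sensitivity_censor_days
    )
    status = np.where(
        ~observable,
        EXCLUDED_CENSORED,
        np.where(stopped_within_year, NON_PERSISTENT, PERSISTENT),
    )
    return pd.Series(status, index=summary.index)


def _prior_diagnosis_mask(
    cohort: pd.DataFrame, diagnoses: pd.DataFrame, prefixes: tuple[str, ...]
) -> pd.Series:
    """True per cohort row if any diagnosis with a listed prefix strictly precedes
    the first purchase."""
    if diagnoses is None or diagnoses.empty:
        return pd.Series(False, index=cohort.index)
    dx = diagnoses.copy()
    dx["icd10_norm"] = dx["icd10"].map(codelists.normalize_icd10)
    dx = dx[dx["icd10_norm"].map(lambda c: any(c.startswith(p) for p in prefixes))]
    if dx.empty:
        return pd.Series(False, index=cohort.index)
    dx["date"] = pd.to_datetime(dx["date"])
    earliest = dx.groupby("person_id")["date"].min()
    first = cohort.set_index("person_id")["first_purchase_date"]
    ok = earliest.reindex(first.index) < first
    return pd.Series(ok.fillna(False).to_numpy(), index=cohort.index)


def build_phenotypes(
    purchases: pd.DataFrame,
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    medication_class: str,
    ruleset: RuleSet,
) -> tuple[pd.DataFrame, AttritionAudit]:
    """Compute the per-person phenotype table for one medication class.

    Returns ``(phenotypes, audit)`` where ``phenotypes`` has one row per
    person surviving the cohort filters with columns: adherence value and
    eligibility flags, primary and sensitivity persistence status, first
    purchase date, treatment length and purchase counts.
    """
    if medication_class not in codelists.MEDICATION_CLASSES:
        raise ValueError(f"unknown medication class: {medication_class!r}")
    audit = AttritionAudit()

    mask = purchases["atc"].map(lambda a: codelists.atc_in_class(a, medication_class))
    class_purchases = purchases[mask].copy()
    if class_purchases.empty:
        raise ValueError(f"no purchases with ATC codes of class {medication_class!r}")

    missing = set(class_purchases["person_id"]) - set(persons["person_id"])
    if missing:
        raise ValueError(
            f"{len(missing)} persons present in purchases but absent from the person register"
        )

    frame = reconstruct(class_purchases, ruleset)
    summary = summarize_mpr(frame, ruleset)

    people = persons.set_index("person_id")
    summary = summary.merge(
        people[["birth_date", "sex"]], left_on="person_id", right_index=True, how="left"
    )
    summary["birth_date"] = pd.to_datetime(summary["birth_date"])
    age = (
        summary["first_purchase_date"] - summary["birth_date"]
    ).dt.days / 365.25

    n0 = len(summary)
    excl: dict[str, int] = {}
    keep = age >= 18
    excl["under_18_at_initiation"] = int((~keep).sum())

    if medication_class == "breast_cancer":
        female = summary["sex"].astype(str).str.lower().isin(["female", "f", "2"])
        excl["not_female"] = int((keep & ~female).sum())
        keep &= female
    if medication_class in codelists.COHORT_PREREQUISITE_CLASSES:
        prereq_prefixes = codelists.load_secondary_prevention_codelist()[medication_class]
        has_prior = _prior_diagnosis_mask(summary, diagnoses, prereq_prefixes)
        excl["no_qualifying_prior_diagnosis"] = int((keep & ~has_prior).sum())
        keep &= has_prior

    cohort = summary[keep].reset_index(drop=True)
    audit.record("cohort_filters", n0, len(cohort), excl)

    eof = end_of_followup(persons, ruleset)
    death = pd.Series(
        pd.to_datetime(persons.get("death_date"), errors="coerce").to_numpy(),
        index=persons["person_id"].to_numpy(),
    )
    if medication_class == "antiplatelets":
        primary = pd.Series(NOT_APPLICABLE, index=cohort.index)
        sensitivity = pd.Series(NOT_APPLICABLE, index=cohort.index)
    else:
        primary = classify_persistence_primary(cohort, eof, ruleset, death=death)
        sensitivity = classify_persistence_sensitivity(cohort, eof, ruleset)

    phenotypes = pd.DataFrame(
        {
            "person_id": cohort["person_id"],
            "medication_class": medication_class,
            "adherence": cohort["adherence"],
            "adherence_eligible": cohort["adherence_eligible"],
            "adherence_excluded_reason": cohort["adherence_excluded_reason"],
            "persistence_primary": primary,
            "persistence_sensitivity": sensitivity,
            "first_purchase_date": cohort["first_purchase_date"],
            "treatment_length_years": cohort["treatment_length_years"],
            "n_purchases": cohort["n_purchases"],
        }
    )

    # adherence-stage audit over the cohort
    reason_counts = cohort["adherence_excluded_reason"].value_counts().to_dict()
    n_eligible = int(cohort["adherence_eligible"].sum())
    audit.record(
        "adherence_eligibility",
        len(cohort),
        n_eligible,
        {k: int(v) for k, v in reason_counts.items() if k != "none"},
    )
    if medication_class != "antiplatelets":
        status_counts = primary.value_counts().to_dict()
        audit.record(
            "persistence_primary",
            len(cohort),
            int(status_counts.get(PERSISTENT, 0)) + int(status_counts.get(NON_PERSISTENT, 0)),
            {
                k: int(v)
                for k, v in status_counts.items()
                if k in (EXCLUDED_CENSORED, EXCLUDED_INTERMEDIATE)
            },
        )
    return phenotypes, audit
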