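"""Purchase-trajectory reconstruction and medication possession ratio (MPR).

The adherence measure is the medication possession ratio

    MPR = (days of supply during the observation period)
          / (days in the observation period)

where the numerator is the total number of tablets purchased in the
trajectory normalized by a class-specific daily dose, and the denominator is
the sum of the intervals (in days) between consecutive purchases kept in the
trajectory.  Reconstruction applies, in order:

1. removal of dose-distribution service purchases (biweekly pharmacy
   dispensing that distorts refill intervals);
2. merging of same-day purchases of the same formulation (full ATC code);
3. exclusion of the final purchase (it opens no interval);
4. treatment-break exclusion: a purchase followed by at least
   ``break_threshold_days`` tablet-free days contributes neither tablets nor
   its interval (Finnish dialect only — the Estonian dialect keeps all gaps
   in the denominator);
5. formulation-switch truncation: when the next purchase is a different
   formulation and arrives before the current supply is exhausted, the
   leftover tablets are discarded (same-formulation surplus carries over,
   which is why MPR can exceed 1).

Eligibility for the adherence analysis requires a first-to-last purchase
span of at least ``eligibility_min_days`` (computed before the last-purchase
exclusion), at least two purchases contributing to the ratio, and
MPR <= ``mpr_cap``; the Estonian dialect additionally requires at least
``estbb_min_tablets`` tablets in total.

All functions operate on a purchase ``DataFrame`` covering any number of
persons (vectorized, grouped by ``person_id``); the :class:`Trajectory`
wrapper exposes the same steps for a single person.

Exclusion-reason flags per purchase: ``none`` (included), ``last_purchase``,
``break``, ``dose_distribution``.  Per-person adherence exclusion reasons:
``none``, ``span_below_min``, ``too_few_purchases``, ``below_min_tablets``
(Estonian dialect only), ``mpr_above_cap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rules import RuleSet

REASON_NONE = "none"
REASON_LAST = "last_purchase"
REASON_BREAK = "break"
REASON_DOSE_DISTRIBUTION = "dose_distribution"

ADH_REASONS = ("none", "span_below_min", "too_few_purchases", "below_min_tablets", "mpr_above_cap")


def prepare_purchases(purchases: pd.DataFrame, ruleset: RuleSet) -> pd.DataFrame:
    """Sort, merge and annotate raw purchase records for any number of persons.

    Expects columns ``person_id, date, atc`` and either ``tablets`` or the
    register pair ``n_packages, tablets_per_package``; an optional
    ``dose_distribution`` 0/1 column marks dose-distribution service
    purchases.  Returns a purchase-level frame with supply, interval to the
    next purchase, and exclusion flags (``last_purchase`` and
    ``dose_distribution`` set here; breaks and switch truncation are applied
    by :func:`flag_breaks` and :func:`truncate_switches`).
    """
    if ruleset.daily_dose <= 0:
        raise ValueError("daily_dose must be positive")
    df = purchases.copy()
    if "tablets" not in df.columns:
        df["tablets"] = df["n_packages"].astype(float) * df["tablets_per_package"].astype(float)
    if "n_packages" not in df.columns:
        df["n_packages"] = 1
    if "dose_distribution" not in df.columns:
        df["dose_distribution"] = 0
    if (df["tablets"] <= 0).any():
        raise ValueError("purchase tablet quantities must be positive")
    df["date"] = pd.to_datetime(df["date"])

    # merge same-day purchases of the same formulation (dose-distribution
    # purchases are merged separately so the flag survives)
    df = (
        df.groupby(["person_id", "date", "atc", "dose_distribution"], as_index=False, sort=False)
        .agg(n_packages=("n_packages", "sum"), tablets=("tablets", "sum"))
    )
    # deterministic ordering: date, then ATC lexicographically for same-day ties
    df = df.sort_values(["person_id", "date", "atc"], kind="mergesort").reset_index(drop=True)

    active = df["dose_distribution"].to_numpy() == 0
    df["supply_days"] = df["tablets"] / ruleset.daily_dose

    # chain (next date / next formulation) over non-dose-distribution purchases
    next_date = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns]")
    next_atc = pd.Series(pd.NA, index=df.index, dtype="object")
    sub = df.loc[active]
    grp = sub.groupby("person_id", sort=False)
    next_date.loc[sub.index] = grp["date"].shift(-1)
    next_atc.loc[sub.index] = grp["atc"].shift(-1)
    df["interval_days"] = (next_date - df["date"]).dt.days.astype(float)
    df["next_atc"] = next_atc

    reason = np.full(len(df), REASON_NONE, dtype=object)
    reason[~active] = REASON_DOSE_DISTRIBUTION
    reason[active & next_date.isna().to_numpy()] = REASON_LAST
    df["exclusion_reason"] = reason
    df["effective_tablets"] = df["tablets"].astype(float)
    return df


def flag_breaks(df: pd.DataFrame, ruleset: RuleSet) -> pd.DataFrame:
    """Flag treatment breaks: interval minus supply >= threshold tablet-free days.

    No-op in dialects with ``apply_break_exclusion`` false (all gaps count as
    true treatment breaks and remain in the MPR denominator).
    """
    df = df.copy()
    if not ruleset.apply_break_exclusion:
        return df
    gap = df["interval_days"] - df["supply_days"]
    is_break = (df["exclusion_reason"] == REASON_NONE) & (gap >= ruleset.break_threshold_days)
    df.loc[is_break, "exclusion_reason"] = REASON_BREAK
    return df


def truncate_switches(df: pd.DataFrame, ruleset: RuleSet) -> pd.DataFrame:
    """Discard leftover tablets at formulation switches.

    Where the next purchase is a different formulation (full ATC code) and
    arrives before the current supply runs out, the purchase only contributes
    the tablets consumable within the interval.  Same-formulation surplus
    carries over untouched.
    """
    df = df.copy()
    switching = (
        df["next_atc"].notna()
        & (df["next_atc"] != df["atc"])
        & (df["interval_days"] < df["supply_days"])
        & (df["exclusion_reason"] != REASON_DOSE_DISTRIBUTION)
    )
    df.loc[switching, "effective_tablets"] = (
        df.loc[switching, "interval_days"] * ruleset.daily_dose
    )
    return df


def summarize_mpr(df: pd.DataFrame, ruleset: RuleSet) -> pd.DataFrame:
    """Aggregate a flagged purchase frame into per-person adherence records.

    Returns one row per person: ``mpr``, ``adherence`` (MPR when eligible,
    else NaN), ``adherence_eligible``, ``adherence_excluded_reason``,
    purchase counts, dates, spans and tablet totals.  The observation span is
    first-to-last purchase over all non-dose-distribution purchases (before
    the last-purchase exclusion).
    """
    active = df[df["exclusion_reason"] != REASON_DOSE_DISTRIBUTION]
    if active.empty:
        raise ValueError("no purchases left after exclusions")
    per = active.groupby("person_id", sort=True).agg(
        n_purchases=("date", "size"),
        first_purchase_date=("date", "min"),
        last_purchase_date=("date", "max"),
        total_tablets=("tablets", "sum"),
        total_packages=("n_packages", "sum"),
    )
    included = active[active["exclusion_reason"] == REASON_NONE]
    inc = included.groupby("person_id", sort=True).agg(
        numerator_tablets=("effective_tablets", "sum"),
        denominator_days=("interval_days", "sum"),
        n_included=("date", "size"),
    )
    per = per.join(inc, how="left")
    per[["numerator_tablets", "denominator_days"]] = per[
        ["numerator_tablets", "denominator_days"]
    ].fillna(0.0)
    per["n_included"] = per["n_included"].fillna(0).astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        per["mpr"] = np.where(
            per["denominator_days"] > 0,
            (per["numerator_tablets"] / ruleset.daily_dose) / per["denominator_days"],
            np.nan,
        )
    per["span_days"] = (per["last_purchase_date"] - per["first_purchase_date"]).dt.days

    reason = np.full(len(per), REASON_NONE, dtype=object)
    span_low = per["span_days"].to_numpy() < ruleset.eligibility_min_days
    too_few = per["n_included"].to_numpy() < 2
    reason[too_few] = "too_few_purchases"
    reason[span_low] = "span_below_min"  # span checked first in reason precedence
    if ruleset.dialect == "estbb":
        few_tabs = (per["total_tablets"].to_numpy() < ruleset.estbb_min_tablets) & (
            reason == REASON_NONE
        )
        reason[few_tabs] = "below_min_tablets"
    over_cap = (reason == REASON_NONE) & (per["mpr"].to_numpy() > ruleset.mpr_cap)
    reason[over_cap] = "mpr_above_cap"

    per["adherence_excluded_reason"] = reason
    per["adherence_eligible"] = reason == REASON_NONE
    per["adherence"] = np.where(per["adherence_eligible"], per["mpr"], np.nan)
    per["treatment_length_years"] = per["span_days"] / 365.25
    return per.reset_index()


def reconstruct(purchases: pd.DataFrame, ruleset: RuleSet) -> pd.DataFrame:
    """Full purchase-level reconstruction: prepare, flag breaks, truncate switches."""
    return truncate_switches(flag_breaks(prepare_purchases(purchases, ruleset), ruleset), ruleset)


# ---------------------------------------------------------------------------
# single-person API


@dataclass
class Trajectory:
    """Ordered purchase sequence for one person and one medication class."""

    person_id: object
    medication_class: str | None
    frame: pd.DataFrame
    ruleset: RuleSet

    @property
    def purchases(self) -> pd.DataFrame:
        return self.frame

    def included(self) -> pd.DataFrame:
        return self.frame[self.frame["exclusion_reason"] == REASON_NONE]


def build_trajectory(
    purchases: pd.DataFrame, ruleset: RuleSet, medication_class: str | None = None
) -> Trajectory:
    """Build a single-person trajectory (sorted, merged, supply computed)."""
    ids = purchases["person_id"].unique()
    if len(ids) != 1:
        raise ValueError("build_trajectory expects records for exactly one person")
    frame = prepare_purchases(purchases, ruleset)
    if (frame["exclusion_reason"] != REASON_DOSE_DISTRIBUTION).sum() == 0:
        raise ValueError("no purchases left after exclusions")
    return Trajectory(ids[0], medication_class, frame, ruleset)


def detect_breaks(traj: Trajectory, ruleset: RuleSet | None = None) -> Trajectory:
    rs = ruleset or traj.ruleset
    return Trajectory(traj.person_id, traj.medication_class, flag_breaks(traj.frame, rs), rs)


def truncate_switch_overlap(traj: Trajectory, ruleset: RuleSet | None = None) -> Trajectory:
    rs = ruleset or traj.ruleset
    return Trajectory(traj.person_id, traj.medication_class, truncate_switches(traj.frame, rs), rs)


def compute_mpr(traj: Trajectory, ruleset: RuleSet | None = None):
    """Compute (mpr, eligible, reason) for a reconstructed single trajectory.

    Ineligibility (too few purchases, short span, tablet minimum, cap) is a
    regular return value, not an exception.
    """
    rs = ruleset or traj.ruleset
    row = summarize_mpr(traj.frame, rs).iloc[0]
    return float(row["mpr"]), bool(row["adherence_eligible"]), str(row["adherence_excluded_reason"])
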