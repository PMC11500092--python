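"""Day-by-day tablet-ledger reference implementation of the MPR.

This module recomputes adherence by literally walking the calendar one day at
a time, keeping a tablet stock, instead of the interval arithmetic used by
:mod:`adherekit.trajectories`.  It exists as an independent cross-check: the
two routes must agree exactly (inclusion/exclusion flags identical, MPR equal
to within 1e-12) on any trajectory, and the test suite asserts this over
generated cohorts spanning all behavioral archetypes.

Semantics are day-resolution: a day is tablet-covered when at least one daily
dose remains in the stock purchased at the opening purchase of the current
interval.  This matches the interval arithmetic whenever per-purchase supply
is a whole number of days (integer tablets with the default one-tablet daily
dose); fractional supplies would differ at the one-day level and are not used
by the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rules import RuleSet


@dataclass
class LedgerResult:
    exclusion_reasons: list[str]
    effective_tablets: list[float]
    numerator_tablets: float
    observation_days: int
    mpr: float


def replay_ledger(purchases: pd.DataFrame, ruleset: RuleSet) -> LedgerResult:
    """Replay one person's purchases through a daily tablet ledger.

    ``purchases``: frame with columns ``date, atc, tablets`` (and optionally
    ``dose_distribution``), any order; same-day same-formulation rows are
    summed, same-day ties ordered by ATC code.
    """
    df = purchases.copy()
    if "dose_distribution" not in df.columns:
        df["dose_distribution"] = 0
    df["date"] = pd.to_datetime(df["date"])
    dose_rows = df[df["dose_distribution"] != 0]
    df = df[df["dose_distribution"] == 0]
    df = (
        df.groupby(["date", "atc"], as_index=False)["tablets"].sum()
        .sort_values(["date", "atc"], kind="mergesort")
        .reset_index(drop=True)
    )
    n = len(df)
    dates = df["date"].to_numpy(dtype="datetime64[D]").astype(int)
    tablets = df["tablets"].to_numpy(dtype=float)
    atcs = df["atc"].to_list()
    dose = ruleset.daily_dose

    reasons = ["none"] * n
    effective = [float(t) for t in tablets]
    if n:
        reasons[-1] = "last_purchase"

    for i in range(n - 1):
        interval = dates[i + 1] - dates[i]
        # walk the interval day by day, consuming from this purchase's stock
        stock = tablets[i]
        tablet_free = 0
        day = 0
        while day < interval:
            if stock >= dose:
                stock -= dose
            else:
                tablet_free += 1
            day += 1
        if ruleset.apply_break_exclusion and tablet_free >= ruleset.break_threshold_days:
            reasons[i] = "break"
        if atcs[i + 1] != atcs[i] and stock > 0:
            # switching formulation with supply left over: discard the leftovers
            effective[i] = tablets[i] - stock

    numerator = 0.0
    obs_days = 0
    for i in range(n - 1):
        if reasons[i] != "none":
            continue
        numerator += effective[i]
        d = dates[i]
        while d < dates[i + 1]:  # count observation days one at a time
            obs_days += 1
            d += 1
    mpr = (numerator / dose) / obs_days if obs_days > 0 else float("nan")

    # dose-distribution rows are excluded wholesale
    full_reasons = reasons + ["dose_distribution"] * len(dose_rows)
    return LedgerResult(full_reasons[: n + len(dose_rows)], effective, numerator, obs_days, mpr)


def ledger_mpr(purchases: pd.DataFrame, ruleset: RuleSet) -> float:
    """Convenience wrapper returning only the day-by-day MPR."""
    return replay_ledger(purchases, ruleset).mpr
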