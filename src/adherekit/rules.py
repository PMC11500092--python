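"""Phenotyping rule sets (Finnish and Estonian register dialects).

A :class:`RuleSet` bundles every threshold entering the adherence (medication
possession ratio, MPR) and persistence phenotypes:

* ``break_threshold_days`` — a refill gap leaving at least this many
  tablet-free days is a treatment break; in the ``finregistry`` dialect the
  purchase opening the break is excluded from the MPR (numerator and its
  interval), in the ``estbb`` dialect all gaps count as true breaks and stay
  in the denominator.
* ``mpr_cap`` — individuals with MPR above this value are treated as
  stockpilers/overbuyers and excluded from the adherence analysis (MPR equal
  to the cap is retained).
* ``eligibility_min_days`` — minimum first-to-last purchase span for the
  adherence analysis ("at least one year of purchases").
* ``censor_buffer_days`` — an early discontinuation (single purchase) only
  counts as non-persistence when observed at least this long before the end
  of follow-up, to avoid right-censoring bias.
* Estonian extras: a minimum of ``estbb_min_tablets`` total tablets for the
  adherence analysis, and a single discontinuation purchase must contain
  fewer than ``estbb_nonpersist_max_packages`` packages and fewer than
  ``estbb_nonpersist_max_tablets`` tablets, be dated before
  ``estbb_registry_cutoff`` and at least ``estbb_death_buffer_days`` before
  death.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

DIALECTS = ("finregistry", "estbb")


@dataclass(frozen=True)
class RuleSet:
    dialect: str = "finregistry"
    daily_dose: float = 1.0
    break_threshold_days: int = 150
    mpr_cap: float = 1.1
    eligibility_min_days: int = 365
    censor_buffer_days: int = 730
    estbb_min_tablets: int = 150
    estbb_nonpersist_max_packages: int = 3
    estbb_nonpersist_max_tablets: int = 100
    apply_break_exclusion: bool = True
    registry_end: date = field(default_factory=lambda: date(2020, 1, 1))
    estbb_registry_cutoff: date = field(default_factory=lambda: date(2022, 1, 1))
    estbb_death_buffer_days: int = 365
    sensitivity_censor_days: int = 365

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect: {self.dialect!r}")
        if self.daily_dose <= 0:
            raise ValueError("daily_dose must be positive")
        for name in (
            "break_threshold_days",
            "eligibility_min_days",
            "censor_buffer_days",
            "estbb_min_tablets",
            "sensitivity_censor_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mpr_cap <= 1:
            raise ValueError("mpr_cap must exceed 1")

    def with_(self, **kwargs) -> "RuleSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def finregistry_rules(**overrides) -> RuleSet:
    """Finnish-register dialect: break exclusion on, 2-year censor buffer."""
    return RuleSet(dialect="finregistry", apply_break_exclusion=True, **overrides)


def estbb_rules(**overrides) -> RuleSet:
    """Estonian-biobank dialect: gaps kept in the denominator, tablet minima."""
    return RuleSet(dialect="estbb", apply_break_exclusion=False, **overrides)


def rules_for_dialect(dialect: str, **overrides) -> RuleSet:
    if dialect == "finregistry":
        return finregistry_rules(**overrides)
    if dialect == "estbb":
        return estbb_rules(**overrides)
    raise ValueError(f"unknown dialect: {dialect!r}")
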