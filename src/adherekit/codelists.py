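"""Medication-class and diagnosis code lists.

Five medication classes are tracked, identified by WHO ATC code prefixes:

====================  =========================================
class                 ATC codes
====================  =========================================
statins               C10AA*
bp                    C02*, C03*, C08*, C09*
antiplatelets         B01AC04, B01AC30
doac                  B01AF01, B01AF02, B01AF03, B01AE07
breast_cancer         L02BA01, L02BG03, L02BG04, L02BG06
====================  =========================================

Secondary-prevention ICD-10 code lists (the diagnoses that mark a treatment
start as secondary rather than primary prevention) are shipped as a plain-text
table ``data/secondary_prevention.csv`` with columns ``class,icd10_prefix``;
prefixes are dot-stripped and ranges (e.g. I60-I69) are pre-expanded to
three-character prefixes.
"""

from __future__ import annotations

import csv
from importlib import resources

MEDICATION_CLASSES = ("statins", "bp", "antiplatelets", "doac", "breast_cancer")

#: ATC prefixes defining purchase membership per class.
ATC_CLASS_PREFIXES: dict[str, tuple[str, ...]] = {
    "statins": ("C10AA",),
    "bp": ("C02", "C03", "C08", "C09"),
    "antiplatelets": ("B01AC04", "B01AC30"),
    "doac": ("B01AF01", "B01AF02", "B01AF03", "B01AE07"),
    "breast_cancer": ("L02BA01", "L02BG03", "L02BG04", "L02BG06"),
}

#: Concrete 7-character ATC codes used by the synthetic generator.
ATC_CLASS_MEMBERS: dict[str, tuple[str, ...]] = {
    "statins": ("C10AA01", "C10AA05", "C10AA07"),
    "bp": ("C02AC01", "C03CA01", "C08CA01", "C09AA05"),
    "antiplatelets": ("B01AC04", "B01AC30"),
    "doac": ("B01AF01", "B01AF02", "B01AF03", "B01AE07"),
    "breast_cancer": ("L02BA01", "L02BG03", "L02BG04", "L02BG06"),
}

#: Classes with a defined secondary-prevention concept.  BP medications have
#: none (too broad a class); breast cancer and DOAC cohorts are secondary
#: prevention by inclusion.
SECONDARY_PREVENTION_DEFINED = ("statins", "antiplatelets", "breast_cancer", "doac")

#: Cohort-prerequisite diagnoses: a qualifying code must precede the first
#: purchase for the person to enter the cohort at all.
COHORT_PREREQUISITE_CLASSES = ("breast_cancer", "doac")


def normalize_icd10(code: str) -> str:
    """Normalize an ICD-10 code for prefix matching (uppercase, no dot)."""
    return str(code).strip().upper().replace(".", "")


def load_secondary_prevention_codelist() -> dict[str, tuple[str, ...]]:
    """Load the secondary-prevention ICD-10 prefix table shipped with the package.

    Returns
    -------
    dict mapping medication class to a tuple of dot-stripped ICD-10 prefixes.
    """
    out: dict[str, list[str]] = {}
    ref = resources.files("adherekit").joinpath("data/secondary_prevention.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["class"], []).append(normalize_icd10(row["icd10_prefix"]))
    return {k: tuple(v) for k, v in out.items()}


def atc_in_class(atc: str, medication_class: str) -> bool:
    """Whether an ATC code belongs to the given medication class."""
    try:
        prefixes = ATC_CLASS_PREFIXES[medication_class]
    except KeyError:
        raise ValueError(f"unknown medication class: {medication_class!r}") from None
    atc = str(atc).strip().upper()
    return atc.startswith(prefixes)


def matches_any_prefix(code: str, prefixes) -> bool:
    """Prefix-match a normalized ICD-10 code against a prefix collection."""
    code = normalize_icd10(code)
    return any(code.startswith(p) for p in prefixes)
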