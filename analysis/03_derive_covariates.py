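"""Derive the eight baseline risk factors for the phenotyped statin cohort.

Joins the person, diagnosis and purchase registers at each person's
treatment initiation to produce: sex, age at initiation, secondary
prevention (qualifying cardiovascular ICD-10 code before the first statin
purchase), Charlson comorbidity index, education years, living area, mother
tongue, social assistance and polytherapy — in both the dichotomized and the
standardized continuous encodings.  Writes results/covariates/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from adherekit.covariates import build_covariates, encode_covariates
from adherekit.registers import read_register

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--register", type=Path, default=ROOT / "results" / "register")
    parser.add_argument(
        "--phenotypes", type=Path,
        default=ROOT / "results" / "phenotypes" / "phenotypes_finregistry.csv",
    )
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "covariates")
    args = parser.parse_args()

    tables = read_register(args.register)
    phen = pd.read_csv(args.phenotypes, parse_dates=["first_purchase_date"])
    raw = build_covariates(
        tables["person"], tables["diagnosis"], tables["purchase"], phen, "statins"
    )
    args.out.mkdir(parents=True, exist_ok=True)
    for mode in ("dichotomized", "continuous"):
        encoded, n_dropped = encode_covariates(raw, mode=mode)
        encoded.to_csv(args.out / f"covariates_{mode}.csv", index=False)
        print(f"[{mode}] {len(encoded)} rows ({n_dropped} incomplete dropped)")

    print("\ncovariate snapshot (dichotomized):")
    enc, _ = encode_covariates(raw, mode="dichotomized")
    cols = ["age_gt_60", "cci_gt_5", "university_or_higher", "secondary_prevention",
            "social_assistance", "language_fi_sv", "urban"]
    print(enc[cols].mean(numeric_only=True).round(3).to_string())


if __name__ == "__main__":
    main()
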