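"""Reading and writing the delimited-text register schema.

Four UTF-8 CSV files with ISO-8601 dates:

* ``purchase.csv`` — person_id, date, atc, n_packages, tablets_per_package,
  dose_distribution (0/1)
* ``diagnosis.csv`` — person_id, date, icd10
* ``person.csv`` — person_id, sex, birth_date, death_date, emigration_date,
  language_fi_sv, education_years, social_assistance, urban
* ``groundtruth.csv`` — person_id, archetype, true_rate, covariates...
  (only present for synthetic cohorts)

Round-trip identity holds to day precision on dates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

PURCHASE_COLUMNS = ("person_id", "date", "atc", "n_packages", "tablets_per_package", "dose_distribution")
DIAGNOSIS_COLUMNS = ("person_id", "date", "icd10")
PERSON_COLUMNS = (
    "person_id", "sex", "birth_date", "death_date", "emigration_date",
    "language_fi_sv", "education_years", "social_assistance", "urban",
)

_DATE_COLUMNS = {
    "purchase": ["date"],
    "diagnosis": ["date"],
    "person": ["birth_date", "death_date", "emigration_date"],
    "groundtruth": [],
}
_REQUIRED = {
    "purchase": PURCHASE_COLUMNS,
    "diagnosis": DIAGNOSIS_COLUMNS,
    "person": PERSON_COLUMNS,
}
_QUANTITY_COLUMNS = {"purchase": ("n_packages", "tablets_per_package")}


def _validate(name: str, df: pd.DataFrame) -> None:
    required = _REQUIRED.get(name, ())
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing required columns: {missing}")
    for col in _QUANTITY_COLUMNS.get(name, ()):
        if (pd.to_numeric(df[col]) < 0).any():
            raise ValueError(f"{name}.{col} contains negative quantities")
    for col in _DATE_COLUMNS.get(name, []):
        if col in df.columns and len(df):
            parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                raise ValueError(f"{name}.{col} contains unparseable dates")


def write_register(tables: dict[str, pd.DataFrame], directory) -> dict[str, Path]:
    """Write register tables (keys among purchase/diagnosis/person/groundtruth)
    as CSV with ISO dates; returns the written file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        _validate(name, df)
        out = df.copy()
        for col in _DATE_COLUMNS.get(name, []):
            if col in out.columns:
                out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_register(directory) -> dict[str, pd.DataFrame]:
    """Read all register tables present in a directory, parsing dates to day
    precision and validating the schema."""
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name in ("purchase", "diagnosis", "person", "groundtruth"):
        path = directory / f"{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path, dtype={"person_id": str, "icd10": str, "atc": str})
        _validate(name, df)
        for col in _DATE_COLUMNS.get(name, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col], format="ISO8601").astype("datetime64[ns]")
        tables[name] = df
    if not tables:
        raise FileNotFoundError(f"no register tables found in {directory}")
    return tables
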