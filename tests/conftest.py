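"""Shared fixtures: compact purchase-frame builders and rule sets."""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd
import pytest

from adherekit.rules import estbb_rules, finregistry_rules

START = date(2010, 1, 1)


def purchases_from(entries, person_id="p1", start=START):
    """Build a purchase frame from (day_offset, tablets, atc[, dose_flag]) tuples."""
    rows = []
    for entry in entries:
        day, tablets, atc = entry[:3]
        flag = entry[3] if len(entry) > 3 else 0
        rows.append(
            {
                "person_id": person_id,
                "date": pd.Timestamp(start + timedelta(days=int(day))),
                "atc": atc,
                "tablets": float(tablets),
                "n_packages": 1,
                "tablets_per_package": tablets,
                "dose_distribution": flag,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def fin_rules():
    return finregistry_rules()


@pytest.fixture
def est_rules():
    return estbb_rules()
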