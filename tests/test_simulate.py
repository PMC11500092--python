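"""Synthetic register generator: determinism, archetype fidelity, diagnosis
burden, and register round-trips."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from adherekit.charlson import CHARLSON_WEIGHTS, HIERARCHY, QUAN_ICD10, cci_by_person
from adherekit.phenotypes import build_phenotypes
from adherekit.registers import read_register, write_register
from adherekit.rules import finregistry_rules
from adherekit.simulate import CovariateEffect, SimulationConfig, simulate_cohort, simulate_diagnoses
from adherekit.trajectories import reconstruct, summarize_mpr


class TestConfigValidation:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig(n_persons=10)

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="unknown archetype"):
            SimulationConfig(n_persons=10, seed=1, archetype_mix={"couch_potato": 1.0})

    def test_non_summing_mix_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(n_persons=10, seed=1, archetype_mix={"regular": 0.5})

    def test_effect_without_prevalence_rejected(self):
        with pytest.raises(ValueError, match="no prevalence"):
            SimulationConfig(
                n_persons=10, seed=1,
                covariate_effects={"left_handed": CovariateEffect(-0.01, 0.0)},
                covariate_prevalences={"urban": 0.5},
            )

    def test_invalid_study_window_rejected(self):
        with pytest.raises(ValueError, match="study_start"):
            SimulationConfig(
                n_persons=10, seed=1, study_start=date(2020, 1, 1), study_end=date(2010, 1, 1)
            )


class TestDeterminism:
    def test_same_seed_byte_identical_tables(self):
        cfg = dict(n_persons=150, seed=42, dose_distribution_fraction=0.1)
        out1 = simulate_cohort(SimulationConfig(**cfg))
        out2 = simulate_cohort(SimulationConfig(**cfg))
        for a, b in zip(out1[:3], out2[:3]):
            assert a.to_csv(index=False) == b.to_csv(index=False)
        assert out1[3].table.to_csv(index=False) == out2[3].table.to_csv(index=False)

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(n_persons=150, seed=1))[0]
        b = simulate_cohort(SimulationConfig(n_persons=150, seed=2))[0]
        assert not a.equals(b)


class TestArchetypes:
    def test_pure_early_discontinuer_mix(self):
        cfg = SimulationConfig(
            n_persons=100, seed=9, archetype_mix={"early_discontinuer": 1.0}
        )
        purchases, _, _, truth = simulate_cohort(cfg)
        counts = purchases.groupby("person_id").size()
        assert len(counts) == 100
        assert (counts == 1).all()
        assert (truth.table["archetype"] == "early_discontinuer").all()

    @pytest.mark.parametrize(
        "archetype, check",
        [
            ("stockpiler", "mpr_above_cap"),
            ("break_taker", "break_excluded"),
            ("regular", "eligible"),
            ("switcher", "switch_truncated"),
            ("short_course", "stops_within_year"),
        ],
    )
    def test_archetype_fidelity_at_least_95_percent(self, archetype, check):
        """Each pure-archetype cohort lands in its intended phenotype category."""
        cfg = SimulationConfig(n_persons=400, seed=13, archetype_mix={archetype: 1.0})
        purchases, _, persons, _ = simulate_cohort(cfg)
        rules = finregistry_rules(registry_end=cfg.study_end)
        frame = reconstruct(purchases, rules)
        summary = summarize_mpr(frame, rules)
        if check == "mpr_above_cap":
            rate = (summary["adherence_excluded_reason"] == "mpr_above_cap").mean()
        elif check == "break_excluded":
            has_break = frame[frame["exclusion_reason"] == "break"]["person_id"].unique()
            rate = summary["person_id"].isin(has_break).mean()
        elif check == "eligible":
            rate = summary["adherence_eligible"].mean()
        elif check == "switch_truncated":
            truncated = frame[frame["effective_tablets"] < frame["tablets"]]["person_id"].unique()
            rate = summary["person_id"].isin(truncated).mean()
        else:  # short_course
            rate = (
                (summary["n_purchases"].between(2, 3)) & (summary["span_days"] < 365)
            ).mean()
        assert rate >= 0.95, f"{archetype}: {rate:.3f}"

    def test_purchases_within_study_window(self):
        cfg = SimulationConfig(n_persons=300, seed=17)
        purchases, _, _, _ = simulate_cohort(cfg)
        assert purchases["date"].min() >= pd.Timestamp(cfg.study_start)
        assert purchases["date"].max() <= pd.Timestamp(cfg.study_end)


class TestDiagnoses:
    def test_zero_fraction_no_qualifying_codes(self):
        cfg = SimulationConfig(
            n_persons=200, seed=21, secondary_prevention_fraction=0.0, cci_burden=0.0
        )
        _, diagnoses, _, _ = simulate_cohort(cfg)
        assert diagnoses.empty

    def test_full_fraction_everyone_qualified_before_first_purchase(self):
        cfg = SimulationConfig(
            n_persons=200, seed=22, secondary_prevention_fraction=1.0, cci_burden=0.0
        )
        purchases, diagnoses, _, _ = simulate_cohort(cfg)
        statin_codes = {"I20.0", "I21", "I22", "I63", "I70"}
        assert set(diagnoses["icd10"].unique()) <= statin_codes
        first = purchases.groupby("person_id")["date"].min()
        merged = diagnoses.merge(first.rename("first"), left_on="person_id", right_index=True)
        assert (merged["date"] < merged["first"]).all()
        assert set(diagnoses["person_id"]) == set(purchases["person_id"])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            SimulationConfig(n_persons=10, seed=1, secondary_prevention_fraction=1.5)

    def test_cci_burden_matches_monte_carlo_expectation(self):
        """Mean computed CCI equals the Monte-Carlo expectation of the sampling
        scheme (Poisson number of distinct conditions, uniform over the 17)."""
        burden = 1.03
        cfg = SimulationConfig(
            n_persons=5000, seed=23, secondary_prevention_fraction=0.0, cci_burden=burden
        )
        purchases, diagnoses, _, _ = simulate_cohort(cfg)
        first = purchases.groupby("person_id")["date"].min()
        cci = cci_by_person(diagnoses, first)

        # independent Monte-Carlo oracle of the same sampling scheme
        rng = np.random.default_rng(99)
        conds = np.array(list(QUAN_ICD10))
        draws = []
        for k in rng.poisson(burden, 200_000):
            chosen = set(rng.choice(conds, size=min(k, len(conds)), replace=False)) if k else set()
            for severe, mild in HIERARCHY.items():
                if severe in chosen:
                    chosen.discard(mild)
            draws.append(sum(CHARLSON_WEIGHTS[c] for c in chosen))
        draws = np.asarray(draws)
        se = np.sqrt(cci.var() / len(cci) + draws.var() / len(draws))
        assert abs(cci.mean() - draws.mean()) < 3 * se


class TestRegisterRoundTrip:
    def test_simulated_cohort_round_trips(self, tmp_path):
        cfg = SimulationConfig(n_persons=200, seed=31, death_fraction=0.1)
        purchases, diagnoses, persons, truth = simulate_cohort(cfg)
        tables = {
            "purchase": purchases,
            "diagnosis": diagnoses,
            "person": persons,
            "groundtruth": truth.table,
        }
        write_register(tables, tmp_path)
        back = read_register(tmp_path)
        for name, original in tables.items():
            pd.testing.assert_frame_equal(
                back[name].reset_index(drop=True),
                original.reset_index(drop=True),
                check_dtype=False,
            )

    def test_empty_purchase_table_round_trips(self, tmp_path):
        empty = pd.DataFrame(
            columns=[
                "person_id", "date", "atc", "n_packages", "tablets_per_package",
                "dose_distribution",
            ]
        )
        write_register({"purchase": empty}, tmp_path)
        back = read_register(tmp_path)["purchase"]
        assert back.empty
        assert list(back.columns) == list(empty.columns)

    def test_three_rows_three_lines(self, tmp_path):
        purchases = pd.DataFrame(
            {
                "person_id": ["a", "a", "b"],
                "date": pd.to_datetime(["2010-01-01", "2010-04-01", "2011-01-01"]),
                "atc": ["C10AA01"] * 3,
                "n_packages": [1, 1, 2],
                "tablets_per_package": [100, 100, 50],
                "dose_distribution": [0, 0, 0],
            }
        )
        paths = write_register({"purchase": purchases}, tmp_path)
        lines = paths["purchase"].read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 rows

    def test_missing_column_rejected(self, tmp_path):
        bad = pd.DataFrame({"person_id": ["a"], "date": ["2010-01-01"]})
        with pytest.raises(ValueError, match="missing required columns"):
            write_register({"purchase": bad}, tmp_path)

    def test_negative_quantities_rejected(self, tmp_path):
        bad = pd.DataFrame(
            {
                "person_id": ["a"],
                "date": ["2010-01-01"],
                "atc": ["C10AA01"],
                "n_packages": [-1],
                "tablets_per_package": [100],
                "dose_distribution": [0],
            }
        )
        with pytest.raises(ValueError, match="negative"):
            write_register({"purchase": bad}, tmp_path)

    def test_unparseable_dates_rejected(self, tmp_path):
        (tmp_path / "purchase.csv").write_text(
            "person_id,date,atc,n_packages,tablets_per_package,dose_distribution\n"
            "a,not-a-date,C10AA01,1,100,0\n"
        )
        with pytest.raises(ValueError, match="unparseable"):
            read_register(tmp_path)
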