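"""End-to-end pipeline: simulate -> phenotype -> covariates -> associate.

A single seeded run produces the full artifact set under an output
directory — register CSVs, phenotypes, attrition audit, covariates,
association results, a cohort summary table (class size, total purchases,
proportion persistent, mean (SD) adherence, mean treatment length, proportion
of good adherers) and a ``manifest.json`` recording the config hash, seed,
per-stage row counts and wall times.  Attrition reconciles at every stage:
rows in equal rows out plus the per-reason exclusion counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import ModelSpec, fit_adherence, fit_persistence, results_to_frame
from .covariates import build_covariates, encode_covariates
from .phenotypes import NON_PERSISTENT, PERSISTENT, build_phenotypes
from .registers import read_register, write_register
from .rules import RuleSet, rules_for_dialect
from .simulate import CovariateEffect, SimulationConfig, simulate_cohort

DEFAULT_COVARIATE_TERMS = ("social_assistance", "language_fi_sv", "urban")


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping (any parameter change changes it)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in cfg:
        raise ValueError("config must provide a seed")
    return cfg


def simulation_config_from_dict(cfg: dict) -> SimulationConfig:
    sim = dict(cfg.get("simulation", {}))
    sim.setdefault("n_persons", cfg.get("n_persons", 1000))
    sim["seed"] = cfg["seed"]
    if "medication_class" in cfg:
        sim.setdefault("medication_class", cfg["medication_class"])
    effects = {
        name: CovariateEffect(**vals) for name, vals in sim.pop("covariate_effects", {}).items()
    }
    for key in ("study_start", "study_end", "initiation_latest"):
        if key in sim and isinstance(sim[key], str):
            sim[key] = date.fromisoformat(sim[key])
    return SimulationConfig(covariate_effects=effects, **sim)


def ruleset_from_dict(cfg: dict) -> RuleSet:
    rules = dict(cfg.get("rules", {}))
    dialect = rules.pop("dialect", cfg.get("dialect", "finregistry"))
    for key in ("registry_end", "estbb_registry_cutoff"):
        if key in rules and isinstance(rules[key], str):
            rules[key] = date.fromisoformat(rules[key])
    return rules_for_dialect(dialect, **rules)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)
    stage_rows: dict[str, dict] = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    wall_time_s: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def reconciles(self) -> bool:
        """Every audited stage satisfies rows_in == rows_out + sum(excluded)."""
        return all(
            s["rows_in"] == s["rows_out"] + sum(s["excluded"].values())
            for s in self.exclusions
        )


def summarize_cohort(phenotypes: pd.DataFrame, purchases: pd.DataFrame) -> pd.DataFrame:
    """One-row summary of a phenotyped cohort.

    Adherence statistics (mean, sample SD, treatment length, proportion of
    good adherers — adherence strictly greater than 0.8) are computed over
    the adherence-eligible set only; the cohort size counts the individuals
    entering either analysis (adherence-eligible plus early discontinuers).
    """
    if phenotypes.empty:
        raise ValueError("empty cohort")
    eligible = phenotypes[phenotypes["adherence_eligible"]]
    statuses = phenotypes["persistence_primary"]
    n_persistent = int((statuses == PERSISTENT).sum())
    n_nonpersistent = int((statuses == NON_PERSISTENT).sum())
    analyzed = phenotypes[
        phenotypes["adherence_eligible"] | (statuses == NON_PERSISTENT)
    ]
    in_cohort = purchases["person_id"].isin(analyzed["person_id"])
    denom = n_persistent + n_nonpersistent
    return pd.DataFrame(
        [
            {
                "medication_class": phenotypes["medication_class"].iloc[0],
                "n_individuals": int(len(analyzed)),
                "total_purchases": int(in_cohort.sum()),
                "proportion_persistent": (n_persistent / denom) if denom else np.nan,
                "mean_adherence": float(eligible["adherence"].mean()),
                "sd_adherence": float(eligible["adherence"].std(ddof=1)),
                "mean_treatment_length_years": float(
                    eligible["treatment_length_years"].mean()
                ),
                "proportion_good_adherers": float((eligible["adherence"] > 0.8).mean()),
            }
        ]
    )


def adherence_histogram(phenotypes: pd.DataFrame, n_bins: int = 22) -> pd.DataFrame:
    """Adherence distribution of the eligible set as plain-text bin counts."""
    vals = phenotypes.loc[phenotypes["adherence_eligible"], "adherence"].to_numpy()
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.1))
    return pd.DataFrame(
        {"bin_low": edges[:-1].round(3), "bin_high": edges[1:].round(3), "count": counts}
    )


def run_pipeline(config: dict | str | Path, out_dir) -> RunManifest:
    """Execute the full seeded pipeline; returns the reconciled run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config), seed=int(config["seed"]), version=__version__
    )

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest.wall_time_s[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Timer()

    with _stage("simulate"):
        sim_cfg = simulation_config_from_dict(config)
        purchases, diagnoses, persons, truth = simulate_cohort(sim_cfg)
        register_dir = out / "register"
        paths = write_register(
            {
                "purchase": purchases,
                "diagnosis": diagnoses,
                "person": persons,
                "groundtruth": truth.table,
            },
            register_dir,
        )
        manifest.files.update({k: str(v) for k, v in paths.items()})
        manifest.stage_rows["simulate"] = {
            "persons": len(persons),
            "purchases": len(purchases),
            "diagnoses": len(diagnoses),
        }

    with _stage("phenotype"):
        ruleset = ruleset_from_dict(config)
        ruleset = ruleset.with_(
            daily_dose=sim_cfg.daily_dose, registry_end=sim_cfg.study_end
        )
        phenotypes, audit = build_phenotypes(
            purchases, persons, diagnoses, sim_cfg.medication_class, ruleset
        )
        phenotypes_out = phenotypes.copy()
        phenotypes_out["first_purchase_date"] = phenotypes_out["first_purchase_date"].dt.strftime(
            "%Y-%m-%d"
        )
        phenotypes_out.to_csv(out / "phenotypes.csv", index=False)
        audit.to_frame().to_csv(out / "exclusions.csv", index=False)
        manifest.files["phenotypes"] = str(out / "phenotypes.csv")
        manifest.files["exclusions"] = str(out / "exclusions.csv")
        manifest.exclusions = audit.stages
        manifest.stage_rows["phenotype"] = {"persons": len(phenotypes)}

    with _stage("covariates"):
        raw = build_covariates(
            persons, diagnoses, purchases, phenotypes, sim_cfg.medication_class
        )
        encoding = config.get("encoding", "dichotomized")
        encoded, n_dropped = encode_covariates(raw, mode=encoding)
        encoded.to_csv(out / "covariates.csv", index=False)
        manifest.files["covariates"] = str(out / "covariates.csv")
        manifest.stage_rows["covariates"] = {
            "persons": len(encoded),
            "dropped_incomplete": n_dropped,
        }

    with _stage("associate"):
        data = phenotypes.merge(encoded, on="person_id")
        terms = list(config.get("covariate_terms", DEFAULT_COVARIATE_TERMS))
        results = []
        if sim_cfg.medication_class != "antiplatelets":
            spec_p = ModelSpec(
                outcome="persistence_primary",
                covariates=terms,
                encoding=encoding,
                medication_class=sim_cfg.medication_class,
            )
            statuses = data["persistence_primary"]
            if {PERSISTENT, NON_PERSISTENT} <= set(statuses.unique()):
                results += fit_persistence(spec_p, data)
        spec_a = ModelSpec(
            outcome="adherence",
            covariates=terms,
            encoding=encoding,
            medication_class=sim_cfg.medication_class,
        )
        results += fit_adherence(spec_a, data)
        results_to_frame(results).to_csv(out / "associations.csv", index=False)
        manifest.files["associations"] = str(out / "associations.csv")
        manifest.stage_rows["associate"] = {"terms": len(results)}

    with _stage("summarize"):
        summary = summarize_cohort(phenotypes, purchases)
        summary.to_csv(out / "summary.csv", index=False)
        adherence_histogram(phenotypes).to_csv(out / "adherence_histogram.csv", index=False)
        manifest.files["summary"] = str(out / "summary.csv")
        manifest.files["adherence_histogram"] = str(out / "adherence_histogram.csv")

    if not manifest.reconciles():
        raise RuntimeError("attrition tallies do not reconcile")
    for path in manifest.files.values():
        if not Path(path).exists():
            raise RuntimeError(f"declared output missing: {path}")
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
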