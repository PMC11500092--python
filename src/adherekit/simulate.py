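"""Synthetic purchase / diagnosis / person registers with known ground truth.

The generator emulates the statistical structure of a national pharmacy
purchase register: per-person refill trajectories for one medication class,
drawn from a mix of behavioral archetypes:

* ``regular`` — refills near supply exhaustion with day-level jitter; the
  refill cadence encodes the person's underlying adherence, so the MPR
  pipeline is exercised mechanistically rather than receiving a label.
* ``early_discontinuer`` — exactly one purchase.
* ``short_course`` — two or three purchases, stopping within a year.
* ``break_taker`` — regular refills with at least one gap leaving >= 150
  tablet-free days (a treatment break).
* ``stockpiler`` — refills faster than consumption, pushing MPR above 1.1.
* ``switcher`` — at least one formulation change arriving before the
  previous supply is exhausted (overlapping supply).

Adherence effects of covariates are injected by shifting the person's target
MPR (and hence the refill delay relative to supply exhaustion); persistence
effects shift the log-odds of the early-discontinuer archetype.  Right
censoring comes from death/emigration dates for a small fraction of persons
and from the registry end for everyone else.

Everything is a deterministic function of the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .charlson import CHARLSON_WEIGHTS, QUAN_ICD10
from .codelists import ATC_CLASS_MEMBERS, MEDICATION_CLASSES

ARCHETYPES = (
    "regular",
    "early_discontinuer",
    "break_taker",
    "stockpiler",
    "switcher",
    "short_course",
)

#: One representative ICD-10 code per Charlson condition, used for comorbidity burden.
_CHARLSON_SAMPLE_CODES = {cond: prefixes[0] for cond, prefixes in QUAN_ICD10.items()}

#: Representative qualifying (secondary-prevention) codes per class.
_QUALIFYING_CODES = {
    "statins": ("I21", "I20.0", "I63", "I70"),
    "antiplatelets": ("I21", "I61", "G45"),
    "breast_cancer": ("C50",),
    "doac": ("I48", "I26", "I80", "I87.1"),
}


@dataclass
class CovariateEffect:
    """Injected effect of one covariate: absolute MPR shift and persistence log-odds."""

    adherence_effect: float = 0.0
    persistence_logodds_effect: float = 0.0


@dataclass
class SimulationConfig:
    n_persons: int
    seed: int | None = None
    medication_class: str = "statins"
    study_start: date = field(default_factory=lambda: date(2010, 1, 1))
    study_end: date = field(default_factory=lambda: date(2020, 1, 1))
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "regular": 0.80,
            "early_discontinuer": 0.05,
            "break_taker": 0.06,
            "stockpiler": 0.03,
            "switcher": 0.04,
            "short_course": 0.02,
        }
    )
    refill_interval_mean_days: float = 110.0
    refill_jitter_sd_days: float = 10.0
    package_sizes: list[int] = field(default_factory=lambda: [100])
    daily_dose: float = 1.0
    covariate_effects: dict[str, CovariateEffect] = field(default_factory=dict)
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "social_assistance": 0.10,
            "language_fi_sv": 0.95,
            "urban": 0.70,
        }
    )
    #: person-level SD of the target MPR around its covariate-determined mean
    adherence_person_sd: float = 0.06
    death_fraction: float = 0.03
    emigration_fraction: float = 0.01
    #: latest initiation date; None = 3 years before study end
    initiation_latest: date | None = None
    secondary_prevention_fraction: float = 0.3
    #: Poisson mean number of distinct Charlson conditions per person
    cci_burden: float = 0.5
    dose_distribution_fraction: float = 0.0
    age_min: float = 30.0
    age_max: float = 80.0
    female_fraction: float | None = None  # default 0.5; 0.95 for breast cancer

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (reproducibility)")
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if self.medication_class not in MEDICATION_CLASSES:
            raise ValueError(f"unknown medication class: {self.medication_class!r}")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype names: {sorted(unknown)}")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix probabilities sum to {total}, not 1")
        missing = set(self.covariate_effects) - set(self.covariate_prevalences)
        if missing:
            raise ValueError(
                f"covariates with effects but no prevalence: {sorted(missing)}"
            )
        if not 0 <= self.secondary_prevention_fraction <= 1:
            raise ValueError("secondary_prevention_fraction must be in [0, 1]")
        if not 0 <= self.dose_distribution_fraction <= 1:
            raise ValueError("dose_distribution_fraction must be in [0, 1]")
        if any(s <= 0 for s in self.package_sizes):
            raise ValueError("package sizes must be positive")
        if self.daily_dose <= 0 or self.refill_interval_mean_days <= 0:
            raise ValueError("daily_dose and refill_interval_mean_days must be positive")
        if not 0 < self.base_mpr < 1:
            raise ValueError(
                "mean refill interval must exceed the mean supply (regular refillers "
                "cannot systematically refill early; use the stockpiler archetype)"
            )
        if self.adherence_person_sd <= 0:
            raise ValueError("adherence_person_sd must be positive")
        if self.refill_jitter_sd_days < 0:
            raise ValueError("refill_jitter_sd_days must be non-negative")

    @property
    def base_mpr(self) -> float:
        """Target MPR of an effect-free regular refiller (supply / mean interval)."""
        mean_supply = float(np.mean(self.package_sizes)) / self.daily_dose
        return mean_supply / self.refill_interval_mean_days


@dataclass
class GroundTruth:
    """Per-person generative truth: archetype, cadence rate, covariates, effects."""

    table: pd.DataFrame
    effects: dict[str, CovariateEffect]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _draw_archetypes(cfg: SimulationConfig, rng, X: pd.DataFrame) -> np.ndarray:
    """Archetype per person; covariate persistence effects shift the
    early-discontinuer odds, the remaining mix is unchanged conditionally."""
    n = cfg.n_persons
    p_ed0 = cfg.archetype_mix.get("early_discontinuer", 0.0)
    pers_effects = {
        name: eff.persistence_logodds_effect
        for name, eff in cfg.covariate_effects.items()
        if eff.persistence_logodds_effect != 0.0
    }
    if 0.0 < p_ed0 < 1.0 and pers_effects:
        # log-odds of persistence go up by the effect => early-discontinuation
        # log-odds go down by it
        eta = _logit(p_ed0) - sum(
            eff * X[name].to_numpy(float) for name, eff in pers_effects.items()
        )
        p_ed = 1.0 / (1.0 + np.exp(-eta))
    else:
        p_ed = np.full(n, p_ed0)

    others = [(a, p) for a, p in cfg.archetype_mix.items() if a != "early_discontinuer" and p > 0]
    arch = np.full(n, "early_discontinuer", dtype=object)
    is_ed = rng.random(n) < p_ed
    if others:
        names = [a for a, _ in others]
        probs = np.array([p for _, p in others], float)
        probs = probs / probs.sum()
        arch[~is_ed] = rng.choice(names, size=int((~is_ed).sum()), p=probs)
    return arch


def simulate_cohort(config: SimulationConfig):
    """Generate (purchase table, diagnosis table, person table, GroundTruth)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    start = np.datetime64(cfg.study_start, "D")
    end = np.datetime64(cfg.study_end, "D")
    horizon = int((end - start).astype(int))

    person_id = np.array([f"P{i:07d}" for i in range(n)])

    female_frac = cfg.female_fraction
    if female_frac is None:
        female_frac = 0.95 if cfg.medication_class == "breast_cancer" else 0.5
    sex = np.where(rng.random(n) < female_frac, "female", "male")
    age_at_start = rng.uniform(cfg.age_min, cfg.age_max, n)
    birth_offset = -(age_at_start * 365.25).astype(int)
    birth_date = start + birth_offset.astype("timedelta64[D]")

    X = pd.DataFrame(index=np.arange(n))
    for name, prev in cfg.covariate_prevalences.items():
        X[name] = (rng.random(n) < prev).astype(int)
    education_years = np.clip(rng.normal(13.0, 3.0, n), 6.0, 22.0).round(1)

    # censoring: death / emigration for small fractions
    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    emigration_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    dies = rng.random(n) < cfg.death_fraction
    death_date[dies] = start + rng.integers(365, max(horizon, 366), dies.sum()).astype(
        "timedelta64[D]"
    )
    emigrates = (rng.random(n) < cfg.emigration_fraction) & ~dies
    emigration_date[emigrates] = start + rng.integers(
        365, max(horizon, 366), emigrates.sum()
    ).astype("timedelta64[D]")
    eof = np.minimum(
        np.where(np.isnat(death_date), end, death_date),
        np.where(np.isnat(emigration_date), end, emigration_date),
    ).astype("datetime64[D]")

    # Target MPR per person: left-skewed below a hard ceiling of 1, matching
    # observed MPR distributions (a mode near full possession with a tail of
    # late refillers).  A regular refiller can at most refill on schedule —
    # systematically early refilling is the stockpiler archetype — so the
    # person-level lateness is Gamma-distributed with mean (1 - base_mpr) and
    # SD adherence_person_sd.  Keeping the distribution clear of the 1.1
    # analysis cap makes injected covariate effects identifiable without
    # boundary-selection bias.
    lateness_mean = 1.0 - cfg.base_mpr
    shape = (lateness_mean / cfg.adherence_person_sd) ** 2
    m = 1.0 - rng.gamma(shape, lateness_mean / shape, n)
    for name, eff in cfg.covariate_effects.items():
        m = m + eff.adherence_effect * X[name].to_numpy(float)
    m = np.maximum(m, 0.2)

    archetype = _draw_archetypes(cfg, rng, X)

    # purchase cadence rate: stockpilers buy faster than they consume
    rate = m.copy()
    stock = archetype == "stockpiler"
    rate[stock] = rng.uniform(1.25, 1.6, stock.sum())

    init_latest = (
        np.datetime64(cfg.initiation_latest, "D")
        if cfg.initiation_latest is not None
        else end - np.timedelta64(3 * 365, "D")
    )
    if init_latest <= start:
        raise ValueError("initiation window is empty; move initiation_latest after study_start")
    t0 = rng.integers(0, int((init_latest - start).astype(int)) + 1, n)
    # nobody initiates after their own end of follow-up
    t0 = np.minimum(t0, (eof - start).astype(int) - 1)

    # column budget: enough purchases to cover the longest possible follow-up
    # at the fastest cadence
    min_supply = min(cfg.package_sizes) / cfg.daily_dose
    k_max = int(np.ceil(horizon * 1.7 / min_supply)) + 4

    sizes = rng.choice(np.asarray(cfg.package_sizes, float), size=(n, k_max))
    tablets = sizes  # one package per purchase
    supply = tablets / cfg.daily_dose
    intervals = supply / rate[:, None] + rng.normal(0.0, cfg.refill_jitter_sd_days, (n, k_max))
    intervals = np.maximum(np.rint(intervals), 1.0)

    rows = np.arange(n)
    # break takers: one guaranteed long gap (>= threshold tablet-free days)
    bt = np.flatnonzero(archetype == "break_taker")
    if bt.size:
        jcol = rng.integers(1, 5, bt.size)
        intervals[bt, jcol] = (
            supply[bt, jcol] + 150 + np.rint(rng.exponential(60.0, bt.size))
        )

    # switchers: one early refill (overlapping supply) at the switch point
    sw = np.flatnonzero(archetype == "switcher")
    switch_col = np.full(n, -1)
    if sw.size:
        scol = rng.integers(1, 4, sw.size)
        switch_col[sw] = scol
        intervals[sw, scol - 1] = np.maximum(
            np.rint(rng.uniform(0.3, 0.8, sw.size) * supply[sw, scol - 1]), 1.0
        )

    # short courses: clamp intervals so 2-3 purchases stay within a year
    sc = archetype == "short_course"
    intervals[sc] = np.minimum(intervals[sc], 115.0)

    # purchase dates: cumulative intervals from initiation
    offsets = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(intervals, axis=1)[:, :-1]], axis=1
    )
    dates = start + (t0[:, None] + offsets).astype("timedelta64[D]")

    n_limit = np.full(n, k_max)
    n_limit[archetype == "early_discontinuer"] = 1
    n_limit[sc] = rng.integers(2, 4, int(sc.sum()))
    col = np.arange(k_max)[None, :]
    keep = (col < n_limit[:, None]) & (dates <= eof[:, None])
    keep[:, 0] = dates[:, 0] <= eof  # first purchase always within follow-up

    # formulations: one ATC per person; switchers change at the switch column
    members = np.asarray(ATC_CLASS_MEMBERS[cfg.medication_class])
    base_idx = rng.integers(0, len(members), n)
    alt_shift = rng.integers(1, len(members), n) if len(members) > 1 else np.zeros(n, int)
    alt_idx = (base_idx + alt_shift) % len(members)
    atc_matrix = np.broadcast_to(members[base_idx][:, None], (n, k_max)).copy()
    if sw.size and len(members) > 1:
        after_switch = col >= switch_col[:, None]
        atc_matrix[sw] = np.where(
            after_switch[sw], members[alt_idx[sw]][:, None], members[base_idx[sw]][:, None]
        )

    ii, jj = np.nonzero(keep)
    purchases = pd.DataFrame(
        {
            "person_id": person_id[ii],
            "date": pd.to_datetime(dates[ii, jj]),
            "atc": atc_matrix[ii, jj],
            "n_packages": 1,
            "tablets_per_package": tablets[ii, jj].astype(int),
            "dose_distribution": 0,
        }
    )

    # optional dose-distribution micro-purchases (biweekly, flagged)
    if cfg.dose_distribution_fraction > 0:
        dd = np.flatnonzero(rng.random(n) < cfg.dose_distribution_fraction)
        extra = []
        step = np.timedelta64(14, "D")
        dd_tabs = max(int(round(14 * cfg.daily_dose)), 1)
        for i in dd:
            d = dates[i, 0] + step
            while d <= eof[i] and d <= dates[i, : n_limit[i]].max():
                extra.append((person_id[i], pd.Timestamp(d), atc_matrix[i, 0], 1, dd_tabs, 1))
                d += step
        if extra:
            purchases = pd.concat(
                [purchases, pd.DataFrame(extra, columns=purchases.columns)], ignore_index=True
            )

    purchases = purchases.sort_values(["person_id", "date", "atc"], kind="mergesort").reset_index(
        drop=True
    )

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_date": pd.to_datetime(birth_date).astype("datetime64[ns]"),
            "death_date": pd.to_datetime(death_date).astype("datetime64[ns]"),
            "emigration_date": pd.to_datetime(emigration_date).astype("datetime64[ns]"),
            "language_fi_sv": X.get("language_fi_sv", pd.Series(1, index=X.index)).astype(int),
            "education_years": education_years,
            "social_assistance": X.get("social_assistance", pd.Series(0, index=X.index)).astype(
                int
            ),
            "urban": X.get("urban", pd.Series(1, index=X.index)).astype(int),
        }
    )

    first_purchase = pd.Series(pd.to_datetime(dates[:, 0]), index=person_id)
    diagnoses = simulate_diagnoses(persons, cfg, first_purchase=first_purchase, rng=rng)

    gt = pd.DataFrame(
        {
            "person_id": person_id,
            "archetype": archetype,
            "true_rate": rate * cfg.daily_dose,
            "target_mpr": m,
        }
    )
    for name in cfg.covariate_prevalences:
        gt[name] = X[name].to_numpy()
    ground_truth = GroundTruth(table=gt, effects=dict(cfg.covariate_effects))
    return purchases, diagnoses, persons, ground_truth


def simulate_diagnoses(
    persons: pd.DataFrame,
    config: SimulationConfig,
    first_purchase: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Diagnosis register: secondary-prevention events and Charlson burden.

    A ``secondary_prevention_fraction`` of persons receive one class-relevant
    qualifying code dated before their first purchase, and everyone receives
    a Poisson(``cci_burden``) number of distinct Charlson conditions (one
    representative code each), also dated before the first purchase.
    """
    cfg = config
    if not 0 <= cfg.secondary_prevention_fraction <= 1:
        raise ValueError("secondary_prevention_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1 if cfg.seed is not None else None)
    ids = persons["person_id"].to_numpy()
    n = len(ids)
    if first_purchase is None:
        anchor = np.full(n, np.datetime64(cfg.study_start, "D") + np.timedelta64(365, "D"))
        anchor = pd.Series(pd.to_datetime(anchor), index=ids)
    else:
        anchor = first_purchase.reindex(ids)

    rows: list[tuple] = []
    qualifying = _QUALIFYING_CODES.get(cfg.medication_class, ())
    if qualifying and cfg.secondary_prevention_fraction > 0:
        has_event = rng.random(n) < cfg.secondary_prevention_fraction
        codes = rng.choice(np.asarray(qualifying), size=n)
        lags = rng.integers(30, 1500, n)
        for i in np.flatnonzero(has_event):
            rows.append((ids[i], anchor.iloc[i] - pd.Timedelta(days=int(lags[i])), codes[i]))

    conds = np.asarray(list(_CHARLSON_SAMPLE_CODES))
    k = rng.poisson(cfg.cci_burden, n)
    for i in np.flatnonzero(k > 0):
        chosen = rng.choice(conds, size=min(int(k[i]), len(conds)), replace=False)
        for cond in chosen:
            lag = int(rng.integers(100, 3000))
            rows.append((ids[i], anchor.iloc[i] - pd.Timedelta(days=lag), _CHARLSON_SAMPLE_CODES[cond]))

    dx = pd.DataFrame(rows, columns=["person_id", "date", "icd10"])
    return dx.sort_values(["person_id", "date", "icd10"], kind="mergesort").reset_index(drop=True)
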