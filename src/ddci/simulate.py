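"""Synthetic administrative-claims cohort generator.

Emulates the statistical structure the pipeline assumes, so that every
stage can be exercised and tested without access to real claims:

* baseline drug-exposure indicators drawn independently per class at the
  published training-cohort prevalences,
* per-person death times from an exponential proportional-hazards model,
  ``hazard = baseline_hazard · exp(Σ βk·flagk + β_age·(age − 60))`` with
  the published class coefficients as defaults,
* censoring by migration (exponential) and by the prediction horizon,
* prescription rows constructed so that each true flag satisfies — and
  each false flag fails — the corresponding drug-class rule, with
  dispensing dates uniform over the baseline year,
* unplanned follow-up admissions as a Poisson process whose rate grows
  geometrically with the generative risk class, plus baseline-year
  admissions carrying Charlson-mappable ICD-9 diagnoses so that the CCI
  comparator has signal.

The generator writes the same three CSV tables the loader reads, plus
``truth.csv`` holding the generative flags, score and times.  Identical
seeds produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .data_model import DAYS_PER_YEAR, Cohort, LoadReport, write_cohort
from .reference import DRUG_CLASSES, REFERENCE_COEFFICIENTS, REFERENCE_PREVALENCES
from .rules import DrugClassRule, default_rule_table
from .scoring import MAX_RISK_CLASS

#: Representative full ATC code emitted for each drug class (chosen so that
#: a code emitted for one class never satisfies another class's rule).
CLASS_ATC_CODES: dict[str, str] = {
    "Antiarrhythmics": "C01BD01",
    "Immunosuppressants": "L04AX03",
    "Platelet aggregation inhibitors": "B01AC06",
    "Parenteral anticoagulants": "B01AB05",
    "Oral anticoagulants": "B01AA03",
    "Antineoplastic agents": "L01BA01",
    "Inhaled bronchodilators": "R03AC02",
    "Drugs for arterial hypertension": "C08CA01",
    "Antihyperglycemic therapy": "A10BA02",
    "Drugs for acid related disorders": "A02BC01",
    "Lipid modifying agents": "C10AA01",
    "Nonsteroidal anti-inflammatory drugs": "M01AB05",
    "Systemic corticosteroids": "H02AB06",
    "Opioids": "N02AA01",
    "Anti-Parkinson drugs": "N04BA02",
    "Antipsychotics": "N05AH04",
    "Anti-dementia drugs": "N06AX11",
    "Antidepressants": "N06DA02",
}

#: Agents used for the two branches of the hypertensive-heart-disease
#: combination rule (loop diuretic + aldosterone antagonist; digoxin).
HHD_COMBO_AGENTS = ("C03CA01", "C03DA01")
HHD_DIGOXIN = "C01AA05"

#: ICD-9-CM codes for synthetic baseline admissions: a few Charlson
#: conditions plus non-Charlson filler diagnoses.
CHARLSON_ICD9_POOL = ("410.1", "428.0", "250.01", "496", "585", "153.4", "290.0")
FILLER_ICD9_POOL = ("401.9", "780.2", "724.2", "786.50", "599.0")


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the published development-cohort conditions: the 19
    class prevalences and Cox coefficients, age ~ normal(60.17, 13.57)
    truncated at 40, 46.29% male, a 7-year horizon, and a baseline hazard
    of 0.0059/y solved so that expected 7-year cumulative mortality matches
    the published 10.67%.  Admission intensities follow the published
    readmission-rate gradient (base 0.10/y, ×1.17 per risk class).
    """

    n_persons: int = 10_000
    seed: int = 0
    exposure_prevalences: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(REFERENCE_PREVALENCES)
    )
    true_coefficients: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(REFERENCE_COEFFICIENTS)
    )
    baseline_hazard: float = 0.0059  # per year, zero-exposure age-60 stratum
    beta_age: float = 0.08  # log-hazard per year of age
    horizon_years: float = 7.0
    migration_rate: float = 0.005  # per year
    admission_rate_base: float = 0.10  # unplanned admissions/y, class 0
    admission_rate_per_class: float = 1.17  # multiplicative step per class
    baseline_admission_prob: float = 0.125
    age_mean: float = 60.17
    age_sd: float = 13.57
    age_min: float = 40.0
    male_fraction: float = 0.4629
    index_date: dt.date = dt.date(2004, 1, 1)
    noise_prob: float = 0.05  # sub-threshold prescriptions per negative class
    exposure_correlation: float = 0.0  # Gaussian-copula correlation, off by default

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for cls, p in self.exposure_prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {cls} outside [0, 1]")
        for name in ("baseline_hazard", "migration_rate", "admission_rate_base"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic sub-stream: one generator per output table."""
    return np.random.default_rng([seed, stream])


def _draw_flags(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = list(config.exposure_prevalences)
    p = np.array([config.exposure_prevalences[c] for c in classes])
    n, k = config.n_persons, len(classes)
    if config.exposure_correlation > 0:
        # Gaussian copula: equicorrelated latent normals, per-class thresholds
        rho = config.exposure_correlation
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, k))
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        from scipy.stats import norm

        flags = z < norm.ppf(p)[None, :]
    else:
        flags = rng.random((n, k)) < p[None, :]
    ids = [f"P{i:07d}" for i in range(n)]
    return pd.DataFrame(flags, index=pd.Index(ids, name="person_id"), columns=classes)


def _emit_prescriptions(
    flags: pd.DataFrame,
    rules: dict[str, DrugClassRule],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Prescription rows satisfying true flags and failing false ones."""
    index = pd.Timestamp(config.index_date)
    pid_col: list[str] = []
    atc_col: list[str] = []
    day_col: list[int] = []  # days before index, 1..365
    pkg_col: list[int] = []

    ids = flags.index.to_numpy()
    for cls in flags.columns:
        rule = rules[cls]
        pos = ids[flags[cls].to_numpy()]
        neg = ids[~flags[cls].to_numpy()]
        if rule.combination_logic is not None:
            logic = rule.combination_logic
            # branch split: ~60% two distinct agents, 40% repeated digoxin
            branch_a = rng.random(len(pos)) < 0.6
            d1 = rng.integers(1, 366 - logic.window_days, len(pos))
            gap = rng.integers(0, logic.window_days + 1, len(pos))
            for pid, a, day1, g in zip(pos, branch_a, d1, gap):
                codes = HHD_COMBO_AGENTS if a else (HHD_DIGOXIN, HHD_DIGOXIN)
                pid_col += [pid, pid]
                atc_col += list(codes)
                day_col += [int(day1), int(day1 + g)]
                pkg_col += [1, 1]
            # negatives occasionally get a single agent (never a combination)
            lone = neg[rng.random(len(neg)) < config.noise_prob]
            pid_col += list(lone)
            atc_col += [HHD_COMBO_AGENTS[0]] * len(lone)
            day_col += list(rng.integers(1, 366, len(lone)))
            pkg_col += [1] * len(lone)
            continue

        code = CLASS_ATC_CODES[cls]
        need = rule.min_packages
        # positives: `need` packages split over 1..need dispensations
        n_rows = rng.integers(1, need + 1, len(pos))
        for pid, k in zip(pos, n_rows):
            days = rng.integers(1, rule.window_days + 1, k)
            per_row = np.full(k, need // k)
            per_row[: need - per_row.sum()] += 1
            keep = per_row > 0
            pid_col += [pid] * int(keep.sum())
            atc_col += [code] * int(keep.sum())
            day_col += list(days[keep])
            pkg_col += list(per_row[keep])
        # negatives: sub-threshold noise (impossible when threshold is 1)
        if need > 1:
            noisy = neg[rng.random(len(neg)) < config.noise_prob]
            pid_col += list(noisy)
            atc_col += [code] * len(noisy)
            day_col += list(rng.integers(1, rule.window_days + 1, len(noisy)))
            pkg_col += [need - 1] * len(noisy)
    # tramadol rows: excluded from the opioid class by definition
    opioid_rule = rules.get("Opioids")
    if opioid_rule is not None and opioid_rule.exclude_atc:
        ids_all = flags.index.to_numpy()
        tram = ids_all[rng.random(len(ids_all)) < config.noise_prob / 2]
        pid_col += list(tram)
        atc_col += [opioid_rule.exclude_atc[-1]] * len(tram)
        day_col += list(rng.integers(1, 366, len(tram)))
        pkg_col += [3] * len(tram)

    rx = pd.DataFrame(
        {
            "person_id": pid_col,
            "atc_code": atc_col,
            "dispense_date": index - pd.to_timedelta(day_col, unit="D"),
            "packages": pkg_col,
        }
    )
    return rx.sort_values(["person_id", "dispense_date", "atc_code"]).reset_index(drop=True)


def _emit_hospitalizations(
    flags: pd.DataFrame,
    risk_class: np.ndarray,
    followup_years: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Baseline admissions (with Charlson-mappable codes) + follow-up
    unplanned admissions from a class-graded Poisson process."""
    index = pd.Timestamp(config.index_date)
    rows: list[tuple] = []
    ids = flags.index.to_numpy()

    # baseline year: feeds the CCI comparator
    has_base = rng.random(len(ids)) < config.baseline_admission_prob
    for pid in ids[has_base]:
        adm_day = int(rng.integers(1, 360))
        los = 1 + int(rng.poisson(5))
        n_diag = 1 + int(rng.integers(0, 3))
        diags = []
        for j in range(n_diag):
            pool = CHARLSON_ICD9_POOL if rng.random() < 0.5 else FILLER_ICD9_POOL
            diags.append(pool[int(rng.integers(0, len(pool)))])
        rows.append(
            (pid, index - pd.Timedelta(days=adm_day), index - pd.Timedelta(days=max(adm_day - los, 1)),
             int(rng.random() < 0.7), ";".join(dict.fromkeys(diags)), 0)
        )

    # follow-up: Poisson process, rate graded by generative risk class
    rate = config.admission_rate_base * config.admission_rate_per_class ** risk_class
    n_adm = rng.poisson(rate * followup_years)
    for pid, k, fu in zip(ids, n_adm, followup_years):
        if k == 0:
            continue
        times = np.sort(rng.random(k)) * fu
        for t in times:
            adm = index + pd.Timedelta(days=int(t * DAYS_PER_YEAR))
            los = 1 + int(rng.poisson(4))
            diag = FILLER_ICD9_POOL[int(rng.integers(0, len(FILLER_ICD9_POOL)))]
            rows.append((pid, adm, adm + pd.Timedelta(days=los), 1, diag, 0))

    hosp = pd.DataFrame(
        rows,
        columns=[
            "person_id", "admission_date", "discharge_date", "unplanned",
            "diagnoses", "in_hospital_death",
        ],
    )
    return hosp.sort_values(["person_id", "admission_date"]).reset_index(drop=True)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort in memory; returns (cohort, truth table).

    The truth table records, per person, the generative exposure flags, raw
    score and risk class (published weights), the uncensored death time,
    and the realised follow-up time and event indicator.
    """
    from .scoring import WeightTable, score_cohort

    rules = {r.name: r for r in default_rule_table()}
    index = pd.Timestamp(config.index_date)

    rng_person = _rng(config.seed, 0)
    flags = _draw_flags(config, rng_person)
    n = config.n_persons
    ids = flags.index

    a = (config.age_min - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n,
                        random_state=rng_person)
    male = rng_person.random(n) < config.male_fraction

    beta = np.array([config.true_coefficients.get(c, 0.0) for c in flags.columns])
    lp = flags.to_numpy(dtype=float) @ beta + config.beta_age * (age - 60.0)
    hazard = config.baseline_hazard * np.exp(lp)
    death_t = rng_person.exponential(1.0 / np.maximum(hazard, 1e-12))
    migr_t = (
        rng_person.exponential(1.0 / config.migration_rate, n)
        if config.migration_rate > 0
        else np.full(n, np.inf)
    )
    followup = np.minimum(np.minimum(death_t, migr_t), config.horizon_years)
    event = death_t <= np.minimum(migr_t, config.horizon_years)

    # dates in whole days (minimum 1 day of follow-up)
    death_days = np.maximum(1, np.round(death_t * DAYS_PER_YEAR)).astype(int)
    migr_days = np.where(
        np.isfinite(migr_t), np.maximum(1, np.round(migr_t * DAYS_PER_YEAR)), -1
    ).astype(int)
    horizon_days = int(round(config.horizon_years * DAYS_PER_YEAR))
    birth_days = (age * DAYS_PER_YEAR).astype(int) + 1

    persons = pd.DataFrame(
        {
            "sex": np.where(male, "M", "F"),
            "birth_date": index - pd.to_timedelta(birth_days, unit="D"),
            "index_date": index,
            "death_date": pd.Series(
                [
                    index + pd.Timedelta(days=int(d)) if d <= min(m if m > 0 else 10**9, horizon_days) else pd.NaT
                    for d, m in zip(death_days, migr_days)
                ],
                index=ids,
            ),
            "migration_date": pd.Series(
                [
                    index + pd.Timedelta(days=int(m)) if 0 < m < min(d, horizon_days + 1) else pd.NaT
                    for d, m in zip(death_days, migr_days)
                ],
                index=ids,
            ),
        },
        index=ids,
    )

    scores = score_cohort(flags, WeightTable.reference())
    risk_class = scores["risk_class"].to_numpy()

    rx = _emit_prescriptions(flags, rules, config, _rng(config.seed, 1))
    hosp = _emit_hospitalizations(
        flags, risk_class, followup, config, _rng(config.seed, 2)
    )
    hosp_typed = hosp.copy()
    hosp_typed["diagnoses"] = hosp_typed["diagnoses"].str.split(";").map(tuple)
    hosp_typed["unplanned"] = hosp_typed["unplanned"].astype(bool)
    hosp_typed["in_hospital_death"] = hosp_typed["in_hospital_death"].astype(bool)

    truth = flags.astype(int).copy()
    truth["age"] = np.round(age, 3)
    truth["male"] = male.astype(int)
    truth["raw_score"] = scores["raw_score"]
    truth["risk_class"] = scores["risk_class"]
    truth["death_time_years"] = np.round(death_t, 6)
    truth["followup_years"] = np.round(followup, 6)
    truth["event"] = event.astype(int)

    cohort = Cohort(persons, rx, hosp_typed, LoadReport())
    return cohort, truth


def simulate(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write persons/prescriptions/hospitalizations
    CSVs plus truth.csv to ``out_dir``; deterministic given the seed."""
    cohort, truth = simulate_cohort(config)
    out_dir = Path(out_dir)
    paths = write_cohort(cohort, out_dir)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path)
    paths["truth"] = truth_path
    return paths


def make_worked_fixture() -> tuple[Cohort, pd.DataFrame]:
    """Tiny hand-built cohort covering every rule branch.

    Includes a 3-package antiarrhythmic case and its 2-package negative,
    the 2-package antihyperglycemic threshold, the C07AB09 exclusion, a
    tramadol-only opioid negative, both branches (and a too-far-apart
    negative) of the 45-day hypertensive-heart rule, window-edge cases, a
    negative-score person (statin + immunosuppressant) and a top-class
    person.  Returns (cohort, expected) where ``expected`` holds the
    intended flags/scores for the documented persons.
    """
    index = pd.Timestamp("2004-01-01")

    def d(days_before: int) -> pd.Timestamp:
        return index - pd.Timedelta(days=days_before)

    people = []  # person_id, sex, age_years, death_days, migration_days
    rx_rows = []  # person_id, atc, days_before_index, packages
    hosp_rows = []

    def add_person(pid, sex="F", age=70, death_days=None, migration_days=None):
        people.append((pid, sex, age, death_days, migration_days))

    add_person("W01")  # antiarrhythmics positive: 3 packages spread over year
    rx_rows += [("W01", "C01BD01", 300, 1), ("W01", "C01BD01", 150, 1), ("W01", "C01BD01", 30, 1)]
    add_person("W02")  # 2 packages -> negative
    rx_rows += [("W02", "C01BD01", 200, 2)]
    add_person("W03")  # antihyperglycemic: threshold 2
    rx_rows += [("W03", "A10BA02", 100, 2)]
    add_person("W04")  # excluded beta-blocker: arterial hypertension negative
    rx_rows += [("W04", "C07AB09", 90, 3)]
    add_person("W05")  # included beta-blocker: arterial hypertension positive
    rx_rows += [("W05", "C07AB03", 90, 3)]
    add_person("W06")  # tramadol only -> opioids negative
    rx_rows += [("W06", "N02AX02", 60, 3)]
    add_person("W07")  # morphine -> opioids positive
    rx_rows += [("W07", "N02AA01", 60, 3)]
    add_person("W08")  # hypertensive heart, branch a: two agents 10 d apart
    rx_rows += [("W08", "C03CA01", 100, 1), ("W08", "C03DA01", 90, 1)]
    add_person("W09")  # branch b: digoxin twice, 30 d apart
    rx_rows += [("W09", "C01AA05", 200, 1), ("W09", "C01AA05", 170, 1)]
    add_person("W10")  # agents 60 d apart -> negative
    rx_rows += [("W10", "C03CA01", 160, 1), ("W10", "C03DA01", 100, 1)]
    add_person("W11")  # statin + immunosuppressant -> score -3, class 0
    rx_rows += [("W11", "C10AA01", 120, 3), ("W11", "L04AX03", 140, 3)]
    add_person("W12")  # opioids+anti-Parkinson+antineoplastic: 6+4+3 = 13 -> class 11
    rx_rows += [("W12", "N02AA01", 50, 3), ("W12", "N04BA02", 80, 1), ("W12", "L01BA01", 110, 3)]
    add_person("W13")  # no prescriptions
    add_person("W14")  # window edge: exactly 365 d before index counts
    rx_rows += [("W14", "C01BD01", 365, 3)]
    add_person("W15")  # dispensed on index date: never counts
    rx_rows += [("W15", "C01BD01", 0, 3)]
    # survival / CCI material
    add_person("W16", death_days=731)  # dies at ~2 years
    hosp_rows.append(("W16", 120, 114, 1, "410.11", 0))  # MI -> CCI 1
    add_person("W17", migration_days=1132, death_days=1278)  # migrates before death
    hosp_rows.append(("W17", 200, 195, 1, "250.01;428.0", 0))  # diabetes+CHF -> CCI 2

    persons = pd.DataFrame(
        {
            "person_id": [p[0] for p in people],
            "sex": [p[1] for p in people],
            "birth_date": [index - pd.Timedelta(days=int(p[2] * DAYS_PER_YEAR) + 1) for p in people],
            "index_date": index,
            "death_date": [index + pd.Timedelta(days=p[3]) if p[3] else pd.NaT for p in people],
            "migration_date": [index + pd.Timedelta(days=p[4]) if p[4] else pd.NaT for p in people],
        }
    ).set_index("person_id")

    rx = pd.DataFrame(
        {
            "person_id": [r[0] for r in rx_rows],
            "atc_code": [r[1] for r in rx_rows],
            "dispense_date": [d(r[2]) for r in rx_rows],
            "packages": [r[3] for r in rx_rows],
        }
    )
    hosp = pd.DataFrame(
        {
            "person_id": [h[0] for h in hosp_rows],
            "admission_date": [d(h[1]) for h in hosp_rows],
            "discharge_date": [d(h[2]) for h in hosp_rows],
            "unplanned": [bool(h[3]) for h in hosp_rows],
            "diagnoses": [tuple(h[4].split(";")) for h in hosp_rows],
            "in_hospital_death": [bool(h[5]) for h in hosp_rows],
        }
    )

    expected = pd.DataFrame(
        [
            ("W01", "Antiarrhythmics", True),
            ("W02", "Antiarrhythmics", False),
            ("W03", "Antihyperglycemic therapy", True),
            ("W04", "Drugs for arterial hypertension", False),
            ("W05", "Drugs for arterial hypertension", True),
            ("W06", "Opioids", False),
            ("W07", "Opioids", True),
            ("W08", "Drugs for hypertensive heart disease", True),
            ("W09", "Drugs for hypertensive heart disease", True),
            ("W10", "Drugs for hypertensive heart disease", False),
            ("W14", "Antiarrhythmics", True),
            ("W15", "Antiarrhythmics", False),
        ],
        columns=["person_id", "drug_class", "flag"],
    )
    return Cohort(persons, rx, hosp, LoadReport()), expected
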