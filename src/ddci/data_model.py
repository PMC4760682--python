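"""Claims-data domain model: persons, prescriptions, hospital discharges.

The pipeline consumes three flat tables, mirroring the structure of the
administrative sources the index was built from (civil registry, community
pharmacy claims, hospital discharge abstracts):

``persons.csv``
    person_id, sex (M/F), birth_date, index_date, death_date, migration_date
``prescriptions.csv``
    person_id, atc_code, dispense_date, packages
``hospitalizations.csv``
    person_id, admission_date, discharge_date, unplanned (0/1),
    diagnoses (ICD-9-CM codes joined by ';', primary first, at most 6),
    in_hospital_death (0/1)

One dialect only: comma-separated, ISO-8601 dates, mandatory header row.
Date arithmetic is done in days; years are days / 365.25.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import re
from pathlib import Path

import numpy as np
import pandas as pd

#: Days-per-year convention used for every date difference in the package.
DAYS_PER_YEAR = 365.25

#: Default prediction horizon in years.
DEFAULT_HORIZON_YEARS = 7.0

_ATC_RE = re.compile(r"^[A-Z]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$")

PERSON_COLUMNS = ["person_id", "sex", "birth_date", "index_date", "death_date", "migration_date"]
PRESCRIPTION_COLUMNS = ["person_id", "atc_code", "dispense_date", "packages"]
HOSPITALIZATION_COLUMNS = [
    "person_id",
    "admission_date",
    "discharge_date",
    "unplanned",
    "diagnoses",
    "in_hospital_death",
]


class CohortLoadError(RuntimeError):
    """Fatal cohort-loading problem (missing file or wrong header)."""


@dataclasses.dataclass(frozen=True)
class Person:
    person_id: str
    sex: str  # "M" or "F"
    birth_date: dt.date
    index_date: dt.date
    death_date: dt.date | None = None
    migration_date: dt.date | None = None

    def age_at_index(self) -> int:
        """Completed years of age on the index date."""
        years = (self.index_date - self.birth_date).days / DAYS_PER_YEAR
        return int(np.floor(years))


@dataclasses.dataclass(frozen=True)
class PrescriptionRecord:
    person_id: str
    atc_code: str
    dispense_date: dt.date
    packages: int


@dataclasses.dataclass(frozen=True)
class HospitalizationRecord:
    person_id: str
    admission_date: dt.date
    discharge_date: dt.date
    unplanned: bool
    diagnoses: tuple[str, ...]  # primary first, 1..6 ICD-9-CM codes
    in_hospital_death: bool = False


@dataclasses.dataclass(frozen=True)
class SurvivalRecord:
    person_id: str
    time: float  # years from index date
    event: bool  # death observed within follow-up


@dataclasses.dataclass
class LoadReport:
    """Row counts and per-row rejections collected while reading a cohort."""

    read: dict[str, int] = dataclasses.field(default_factory=dict)
    accepted: dict[str, int] = dataclasses.field(default_factory=dict)
    rejections: list[tuple[str, int, str]] = dataclasses.field(default_factory=list)

    def reject(self, table: str, row: int, reason: str) -> None:
        self.rejections.append((table, row, reason))

    def n_rejected(self, table: str | None = None) -> int:
        if table is None:
            return len(self.rejections)
        return sum(1 for t, _, _ in self.rejections if t == table)

    def to_text(self) -> str:
        lines = ["cohort load report"]
        for table in sorted(self.read):
            lines.append(
                f"  {table}: read {self.read[table]}, accepted {self.accepted[table]}, "
                f"rejected {self.read[table] - self.accepted[table]}"
            )
        for table, row, reason in self.rejections:
            lines.append(f"  reject {table} row {row}: {reason}")
        return "\n".join(lines)


@dataclasses.dataclass
class Cohort:
    """Validated claims cohort: three tables keyed by person_id.

    ``persons`` is indexed by ``person_id``; date columns are pandas
    datetime64 (NaT where absent).  ``prescriptions`` and
    ``hospitalizations`` keep one row per record.
    """

    persons: pd.DataFrame
    prescriptions: pd.DataFrame
    hospitalizations: pd.DataFrame
    report: LoadReport = dataclasses.field(default_factory=LoadReport)

    @property
    def person_ids(self) -> pd.Index:
        return self.persons.index

    def prescriptions_for(self, person_id: str) -> list[PrescriptionRecord]:
        sub = self.prescriptions[self.prescriptions["person_id"] == person_id]
        return [
            PrescriptionRecord(r.person_id, r.atc_code, r.dispense_date.date(), int(r.packages))
            for r in sub.itertuples()
        ]

    def hospitalizations_for(self, person_id: str) -> list[HospitalizationRecord]:
        sub = self.hospitalizations[self.hospitalizations["person_id"] == person_id]
        return [
            HospitalizationRecord(
                r.person_id,
                r.admission_date.date(),
                r.discharge_date.date(),
                bool(r.unplanned),
                tuple(r.diagnoses),
                bool(r.in_hospital_death),
            )
            for r in sub.itertuples()
        ]

    def person(self, person_id: str) -> Person:
        r = self.persons.loc[person_id]
        return Person(
            person_id=person_id,
            sex=r["sex"],
            birth_date=r["birth_date"].date(),
            index_date=r["index_date"].date(),
            death_date=None if pd.isna(r["death_date"]) else r["death_date"].date(),
            migration_date=None if pd.isna(r["migration_date"]) else r["migration_date"].date(),
        )


def is_valid_atc(code: str) -> bool:
    """Syntactic ATC check: letter, two digits, then letters/digits (1-7 chars)."""
    return bool(_ATC_RE.match(code)) if isinstance(code, str) else False


def _check_header(path: Path, expected: list[str], table: str) -> None:
    if not path.exists():
        raise CohortLoadError(f"{table} file not found: {path}")
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if header != expected:
        raise CohortLoadError(
            f"{table} header mismatch in {path}: expected {expected}, found {header}"
        )


def _parse_dates(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")


def read_cohort(
    persons_path: str | Path,
    prescriptions_path: str | Path,
    hospitalizations_path: str | Path,
    min_age: int = 40,
) -> Cohort:
    """Read and validate the three claims tables.

    Rows violating a type invariant (malformed date, non-positive package
    count, bad ATC syntax, unknown person_id, age below ``min_age`` at
    index, death or migration before the index date, ...) are dropped and
    recorded in the load report.  A missing file or a header mismatch is
    fatal.
    """
    persons_path, prescriptions_path, hospitalizations_path = (
        Path(persons_path),
        Path(prescriptions_path),
        Path(hospitalizations_path),
    )
    _check_header(persons_path, PERSON_COLUMNS, "persons")
    _check_header(prescriptions_path, PRESCRIPTION_COLUMNS, "prescriptions")
    _check_header(hospitalizations_path, HOSPITALIZATION_COLUMNS, "hospitalizations")

    report = LoadReport()

    per = pd.read_csv(persons_path, dtype={"person_id": str, "sex": str})
    report.read["persons"] = len(per)
    for col in ("birth_date", "index_date", "death_date", "migration_date"):
        per[col] = _parse_dates(per[col])
    keep = np.ones(len(per), dtype=bool)

    def _drop(table: str, df: pd.DataFrame, mask: np.ndarray, reason: str) -> None:
        for row in df.index[mask & keep]:
            report.reject(table, int(row), reason)
        keep[np.asarray(mask)] = False

    _drop("persons", per, per["person_id"].isna().to_numpy() | per["person_id"].duplicated().to_numpy(), "missing or duplicate person_id")
    _drop("persons", per, ~per["sex"].isin(["M", "F"]).to_numpy(), "sex not in {M, F}")
    _drop("persons", per, (per["birth_date"].isna() | per["index_date"].isna()).to_numpy(), "malformed date")
    _drop("persons", per, (per["index_date"] <= per["birth_date"]).to_numpy(), "index date not after birth date")
    age = (per["index_date"] - per["birth_date"]).dt.days / DAYS_PER_YEAR
    _drop("persons", per, np.floor(age).to_numpy() < min_age, f"age below {min_age} at index")
    _drop("persons", per, (per["death_date"] < per["index_date"]).to_numpy(), "death before index date")
    _drop("persons", per, (per["migration_date"] < per["index_date"]).to_numpy(), "migration before index date")
    persons = per[keep].set_index("person_id")
    report.accepted["persons"] = len(persons)
    known = set(persons.index)

    rx = pd.read_csv(prescriptions_path, dtype={"person_id": str, "atc_code": str})
    report.read["prescriptions"] = len(rx)
    rx["dispense_date"] = _parse_dates(rx["dispense_date"])
    rx["packages"] = pd.to_numeric(rx["packages"], errors="coerce")
    keep = np.ones(len(rx), dtype=bool)
    _drop("prescriptions", rx, ~rx["person_id"].isin(known).to_numpy(), "unknown person_id")
    _drop("prescriptions", rx, rx["dispense_date"].isna().to_numpy(), "malformed date")
    _drop("prescriptions", rx, ~(rx["packages"] >= 1).to_numpy() | (rx["packages"] % 1 != 0).to_numpy(), "non-positive packages")
    _drop("prescriptions", rx, ~rx["atc_code"].map(is_valid_atc).to_numpy(), "invalid ATC code")
    prescriptions = rx[keep].reset_index(drop=True)
    prescriptions["packages"] = prescriptions["packages"].astype(int)
    report.accepted["prescriptions"] = len(prescriptions)

    hosp = pd.read_csv(hospitalizations_path, dtype={"person_id": str, "diagnoses": str})
    report.read["hospitalizations"] = len(hosp)
    for col in ("admission_date", "discharge_date"):
        hosp[col] = _parse_dates(hosp[col])
    keep = np.ones(len(hosp), dtype=bool)
    _drop("hospitalizations", hosp, ~hosp["person_id"].isin(known).to_numpy(), "unknown person_id")
    _drop("hospitalizations", hosp, (hosp["admission_date"].isna() | hosp["discharge_date"].isna()).to_numpy(), "malformed date")
    _drop("hospitalizations", hosp, (hosp["discharge_date"] < hosp["admission_date"]).to_numpy(), "discharge before admission")
    diag_lists = hosp["diagnoses"].fillna("").str.split(";").map(lambda xs: tuple(x for x in xs if x))
    _drop("hospitalizations", hosp, ~diag_lists.map(lambda xs: 1 <= len(xs) <= 6).to_numpy(), "diagnosis count outside 1..6")
    hospitalizations = hosp[keep].reset_index(drop=True)
    hospitalizations["diagnoses"] = diag_lists[keep].reset_index(drop=True)
    hospitalizations["unplanned"] = hospitalizations["unplanned"].astype(int).astype(bool)
    hospitalizations["in_hospital_death"] = hospitalizations["in_hospital_death"].astype(int).astype(bool)
    report.accepted["hospitalizations"] = len(hospitalizations)

    return Cohort(persons, prescriptions, hospitalizations, report)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables back to canonical CSV; inverse of read_cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "persons": out_dir / "persons.csv",
        "prescriptions": out_dir / "prescriptions.csv",
        "hospitalizations": out_dir / "hospitalizations.csv",
    }
    per = cohort.persons.reset_index()[PERSON_COLUMNS].copy()
    for col in ("birth_date", "index_date", "death_date", "migration_date"):
        per[col] = per[col].dt.strftime("%Y-%m-%d")
    per.to_csv(paths["persons"], index=False)

    rx = cohort.prescriptions[PRESCRIPTION_COLUMNS].copy()
    rx["dispense_date"] = rx["dispense_date"].dt.strftime("%Y-%m-%d")
    rx.to_csv(paths["prescriptions"], index=False)

    hosp = cohort.hospitalizations[HOSPITALIZATION_COLUMNS].copy()
    for col in ("admission_date", "discharge_date"):
        hosp[col] = hosp[col].dt.strftime("%Y-%m-%d")
    hosp["diagnoses"] = hosp["diagnoses"].map(";".join)
    hosp["unplanned"] = hosp["unplanned"].astype(int)
    hosp["in_hospital_death"] = hosp["in_hospital_death"].astype(int)
    hosp.to_csv(paths["hospitalizations"], index=False)
    return paths


def derive_survival(person: Person, horizon_years: float = DEFAULT_HORIZON_YEARS) -> SurvivalRecord:
    """Follow-up time and death indicator for one person.

    time = min(death, migration, horizon) − index, in years; the event is a
    death only when death is the earliest of the three.  Censoring by
    migration or by the end of the prediction horizon yields event=False.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    if person.death_date is not None and person.death_date < person.index_date:
        raise ValueError(f"event precedes index for person {person.person_id}")
    if person.migration_date is not None and person.migration_date < person.index_date:
        raise ValueError(f"migration precedes index for person {person.person_id}")

    death_t = (
        (person.death_date - person.index_date).days / DAYS_PER_YEAR
        if person.death_date is not None
        else np.inf
    )
    migr_t = (
        (person.migration_date - person.index_date).days / DAYS_PER_YEAR
        if person.migration_date is not None
        else np.inf
    )
    time = min(death_t, migr_t, horizon_years)
    event = death_t <= min(migr_t, horizon_years) and np.isfinite(death_t)
    return SurvivalRecord(person.person_id, float(time), bool(event))


def derive_survival_frame(
    persons: pd.DataFrame, horizon_years: float = DEFAULT_HORIZON_YEARS
) -> pd.DataFrame:
    """Vectorised derive_survival over the persons table.

    Returns a DataFrame indexed like ``persons`` with float ``time`` (years)
    and boolean ``event`` columns.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    death_t = (persons["death_date"] - persons["index_date"]).dt.days / DAYS_PER_YEAR
    migr_t = (persons["migration_date"] - persons["index_date"]).dt.days / DAYS_PER_YEAR
    if (death_t < 0).any() or (migr_t < 0).any():
        raise ValueError("event precedes index for at least one person")
    death_t = death_t.fillna(np.inf)
    migr_t = migr_t.fillna(np.inf)
    time = np.minimum(np.minimum(death_t, migr_t), horizon_years)
    event = (death_t <= np.minimum(migr_t, horizon_years)) & np.isfinite(death_t)
    return pd.DataFrame({"time": time, "event": event}, index=persons.index)
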