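"""End-to-end orchestration: simulate → exposures → score → derive → evaluate.

Mirrors the development/validation design of the index: the cohort is split
into two random halves, weights are derived on the training half, and the
score built from those weights is evaluated on the validation half
(class-wise hazard ratios, C-index and NRI against an age–sex reference
model, readmission rate ratios).
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    DAYS_PER_YEAR,
    Cohort,
    derive_survival_frame,
    read_cohort,
)
from .derivation import DdciWeightModel, DdciWeightResults
from .evaluation import (
    ModelComparison,
    classwise_hazard_ratios,
    km_estimate,
    readmission_irr,
)
from .rules import default_rule_table, detect_exposures_frame, load_rule_table
from .scoring import WeightTable, compute_cci_frame, score_cohort


@dataclasses.dataclass
class PipelineConfig:
    """Knobs of the full pipeline run."""

    out_dir: Path
    cohort_dir: Path | None = None  # read an existing cohort; otherwise simulate
    n_persons: int = 20_000  # used only when simulating
    seed: int = 0
    split_fraction: float = 0.5
    split_seed: int = 1
    horizon_years: float = 7.0
    rules_path: Path | None = None
    alpha: float = 0.05
    divisor: float = 0.3
    model: str = "A"  # A: +DDCI vs age/sex; B/C/D: hospitalized-cohort analogues

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.model not in {"A", "B", "C", "D"}:
            raise ValueError("model must be one of A, B, C, D")


def split_cohort(
    person_ids, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Deterministic random partition into training / validation ids."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    ids = pd.Index(person_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(len(ids) * fraction))
    return ids[perm[:n_train]].sort_values(), ids[perm[n_train:]].sort_values()


def _age_sex_frames(persons: pd.DataFrame) -> pd.DataFrame:
    age = (persons["index_date"] - persons["birth_date"]).dt.days / DAYS_PER_YEAR
    return pd.DataFrame(
        {"age": age, "male": (persons["sex"] == "M").astype(float)}, index=persons.index
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write artifacts to ``config.out_dir``.

    Returns a dict with the in-memory results: weight results, score table,
    evaluation report.  Artifacts: weights.yaml, scores.csv, fit_summary.txt,
    report.json, km_class_<k>.csv, log.txt.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.time()

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {stage}: {msg}")

    if config.cohort_dir is not None:
        cohort = read_cohort(
            Path(config.cohort_dir) / "persons.csv",
            Path(config.cohort_dir) / "prescriptions.csv",
            Path(config.cohort_dir) / "hospitalizations.csv",
        )
        log("load", f"{len(cohort.persons)} persons from {config.cohort_dir}")
    else:
        from .simulate import SimulationConfig, simulate_cohort

        cohort, _ = simulate_cohort(
            SimulationConfig(n_persons=config.n_persons, seed=config.seed,
                             horizon_years=config.horizon_years)
        )
        log("simulate", f"{len(cohort.persons)} persons (seed {config.seed})")

    rules = (
        load_rule_table(config.rules_path) if config.rules_path else default_rule_table()
    )
    exposures = detect_exposures_frame(cohort.prescriptions, cohort.persons, rules)
    log("exposures", f"{int(exposures.to_numpy().sum())} positive flags")

    survival = derive_survival_frame(cohort.persons, config.horizon_years)
    agesex = _age_sex_frames(cohort.persons)

    train_ids, valid_ids = split_cohort(
        cohort.person_ids, config.split_fraction, config.split_seed
    )
    log("split", f"{len(train_ids)} training / {len(valid_ids)} validation")

    # -- derive weights on the training half
    model = DdciWeightModel(
        exposures.loc[train_ids],
        survival.loc[train_ids],
        adjustment=agesex.loc[train_ids, ["age"]] - 60.0,
    )
    weight_res: DdciWeightResults = model.fit(divisor=config.divisor, alpha=config.alpha)
    weight_res.weight_table.save(out / "weights.yaml")
    (out / "fit_summary.txt").write_text(weight_res.summary())
    log("derive", f"weights for {len(weight_res.weight_table.weights)} classes; "
                  f"excluded {len(weight_res.excluded)}")

    # -- score everybody with the derived weights
    scores = score_cohort(exposures, weight_res.weight_table)
    scores["cci"] = compute_cci_frame(cohort.hospitalizations, cohort.persons)
    scores.to_csv(out / "scores.csv")
    log("score", f"mean raw score {scores['raw_score'].mean():.3f}")

    # -- evaluate on the validation half
    vsurv = survival.loc[valid_ids]
    vscores = scores.loc[valid_ids]
    vagesex = agesex.loc[valid_ids]

    km = km_estimate(vsurv, vscores["risk_class"])
    for label, tab in km.items():
        tab.to_csv(out / f"km_class_{label}.csv", index=False)

    hr_fit = classwise_hazard_ratios(
        vsurv, vscores["risk_class"], vagesex["age"], vagesex["male"]
    )

    ref = vagesex.copy()
    if config.model == "A":
        aug = ref.assign(ddci=vscores["raw_score"].astype(float))
    elif config.model == "B":
        aug = ref.assign(ddci=vscores["raw_score"].astype(float))
    elif config.model == "C":
        aug = ref.assign(cci=vscores["cci"].astype(float))
    else:  # D: reference already contains CCI, augmentation adds the score
        ref = ref.assign(cci=vscores["cci"].astype(float))
        aug = ref.assign(ddci=vscores["raw_score"].astype(float))
    if config.model in {"B", "C", "D"}:
        # hospitalized sub-cohort analogue: persons with a baseline admission
        hospitalized = valid_ids[_had_baseline_admission(cohort, valid_ids)]
        ref, aug, vsurv = ref.loc[hospitalized], aug.loc[hospitalized], vsurv.loc[hospitalized]
    comparison = ModelComparison(ref, aug, vsurv).fit(horizon=config.horizon_years)
    log("evaluate", f"C {comparison.c_reference.c_index:.3f} -> "
                    f"{comparison.c_augmented.c_index:.3f}, NRI {comparison.nri_result.nri:.3f}")

    # -- readmissions among persons with a first unplanned admission
    readm = _readmission_table(cohort, vsurv.index, vscores, vagesex)
    irr_tab = None
    if readm is not None and (readm["cls"] == 0).any():
        irr_tab = readmission_irr(
            readm["count"], readm["py"], readm["cls"], readm["age"], readm["male"]
        )
        irr_tab.to_csv(out / "readmission_irr.csv")
        log("readmission", f"{len(readm)} persons with a first unplanned admission")

    report = {
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in dataclasses.asdict(config).items()
        },
        "n_train": len(train_ids),
        "n_validation": len(valid_ids),
        "weights": weight_res.weight_table.weights,
        "excluded_classes": weight_res.excluded,
        "c_reference": comparison.c_reference.c_index,
        "c_augmented": comparison.c_augmented.c_index,
        "nri": comparison.nri_result.nri,
        "nri_event_component": comparison.nri_result.event_component,
        "nri_nonevent_component": comparison.nri_result.nonevent_component,
        "classwise_hr": {
            name: float(row["hazard_ratio"])
            for name, row in hr_fit.table.iterrows()
            if name.startswith("class_")
        },
        "readmission_irr": (
            {str(k): float(v) for k, v in irr_tab["irr"].items()} if irr_tab is not None else None
        ),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "weight_results": weight_res,
        "scores": scores,
        "comparison": comparison,
        "classwise_hr": hr_fit,
        "readmission_irr": irr_tab,
        "report": report,
    }


def _had_baseline_admission(cohort: Cohort, ids: pd.Index) -> pd.Series:
    """Boolean per person: any admission in the year before index."""
    hosp = cohort.hospitalizations.merge(
        cohort.persons[["index_date"]], left_on="person_id", right_index=True
    )
    days = (hosp["index_date"] - hosp["admission_date"]).dt.days
    base_ids = set(hosp.loc[(days > 0) & (days <= 365), "person_id"])
    return pd.Series([i in base_ids for i in ids], index=ids)


def _readmission_table(
    cohort: Cohort, ids: pd.Index, scores: pd.DataFrame, agesex: pd.DataFrame
) -> pd.DataFrame | None:
    """Readmission counts and person-years after the first unplanned
    admission following the index date.

    Exposure time runs from the first unplanned discharge to death,
    migration or the study end; every later admission counts.
    """
    hosp = cohort.hospitalizations
    hosp = hosp[hosp["person_id"].isin(ids) & hosp["unplanned"]]
    if len(hosp) == 0:
        return None
    hosp = hosp.merge(cohort.persons[["index_date"]], left_on="person_id", right_index=True)
    hosp = hosp[hosp["admission_date"] >= hosp["index_date"]]
    if len(hosp) == 0:
        return None

    first = hosp.sort_values("admission_date").groupby("person_id").first()
    persons = cohort.persons.loc[first.index]
    end = persons[["death_date", "migration_date"]].min(axis=1)
    study_end = persons["index_date"] + pd.to_timedelta(
        int(7 * DAYS_PER_YEAR), unit="D"
    )
    end = end.fillna(study_end).clip(upper=study_end)
    py = (end - first["discharge_date"]).dt.days / DAYS_PER_YEAR
    py = py.clip(lower=0)

    later = hosp.merge(
        first[["discharge_date"]].rename(columns={"discharge_date": "first_discharge"}),
        left_on="person_id",
        right_index=True,
    )
    counts = (
        later[later["admission_date"] > later["first_discharge"]]
        .groupby("person_id")
        .size()
        .reindex(first.index, fill_value=0)
    )
    keep = py > 0
    return pd.DataFrame(
        {
            "count": counts[keep],
            "py": py[keep],
            "cls": scores.loc[keep[keep].index, "risk_class"],
            "age": agesex.loc[keep[keep].index, "age"],
            "male": agesex.loc[keep[keep].index, "male"],
        }
    )
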