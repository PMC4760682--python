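"""Score computation: DDCI from exposure flags, risk classes, and the CCI.

The DDCI raw score is the algebraic sum of integer drug-class weights over
the exposure flags a person carries.  With the published weights it ranges
from −3 (statin + immunosuppressant only) upward; because low scores are
sparse and high scores rare, raw scores are folded into 12 risk classes:
everything ≤ 0 becomes class 0, scores 1–10 map to classes 1–10, and 11+
becomes class 11.

The Charlson Comorbidity Index (CCI) comparator is computed from baseline
hospital-discharge diagnoses with a bundled Deyo-style ICD-9-CM mapping
(original Charlson weights); persons without a baseline admission score 0.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import HospitalizationRecord
from .reference import DRUG_CLASSES, REFERENCE_WEIGHTS
from .rules import ExposureProfile

#: Number of risk classes after folding (0 .. MAX_RISK_CLASS).
MAX_RISK_CLASS = 11


@dataclasses.dataclass(frozen=True)
class WeightTable:
    """Integer weight per drug class."""

    weights: dict[str, int]

    @classmethod
    def reference(cls) -> "WeightTable":
        """The published weight column."""
        return cls(dict(REFERENCE_WEIGHTS))

    def min_score(self) -> int:
        return sum(w for w in self.weights.values() if w < 0)

    def max_score(self) -> int:
        return sum(w for w in self.weights.values() if w > 0)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"weights": self.weights}, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "WeightTable":
        return cls({k: int(v) for k, v in yaml.safe_load(Path(path).read_text())["weights"].items()})


@dataclasses.dataclass(frozen=True)
class DdciResult:
    person_id: str
    raw_score: int
    risk_class: int


def compute_ddci(profile: ExposureProfile, weights: WeightTable | None = None) -> int:
    """Raw DDCI: algebraic sum of weights over the true exposure flags."""
    if weights is None:
        weights = WeightTable.reference()
    missing = set(profile.flags) - set(weights.weights)
    if missing:
        raise KeyError(f"unweighted class: {sorted(missing)}")
    return sum(weights.weights[name] for name, on in profile.flags.items() if on)


def assign_class(raw_score: int) -> int:
    """Fold a raw score into the 12 risk classes (0 = lowest, 11 = top)."""
    return int(np.clip(raw_score, 0, MAX_RISK_CLASS))


def score_cohort(
    exposures: pd.DataFrame, weights: WeightTable | None = None
) -> pd.DataFrame:
    """Raw score and risk class per person from a boolean exposure frame.

    ``exposures``: persons × drug-class boolean DataFrame (as produced by
    :func:`ddci.rules.detect_exposures_frame`).
    """
    if weights is None:
        weights = WeightTable.reference()
    missing = set(exposures.columns) - set(weights.weights)
    if missing:
        raise KeyError(f"unweighted class: {sorted(missing)}")
    w = np.array([weights.weights[c] for c in exposures.columns])
    raw = exposures.to_numpy(dtype=int) @ w
    return pd.DataFrame(
        {"raw_score": raw, "risk_class": np.clip(raw, 0, MAX_RISK_CLASS)},
        index=exposures.index,
    )


def enumerate_scores(weights: WeightTable | None = None) -> np.ndarray:
    """Raw score of every one of the 2^19 exposure-flag combinations.

    Brute-force enumeration used to characterise the attainable score
    range; returns an array of length 2**n_classes.
    """
    if weights is None:
        weights = WeightTable.reference()
    w = np.array([weights.weights[c] for c in weights.weights], dtype=np.int64)
    n = len(w)
    combos = (np.arange(2**n, dtype=np.int64)[:, None] >> np.arange(n)) & 1
    return combos @ w


# -- Charlson comparator ----------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CharlsonCondition:
    name: str
    weight: int
    prefixes: tuple[str, ...]
    superseded_by: str | None = None


def load_charlson_mapping(path: str | Path | None = None) -> list[CharlsonCondition]:
    """Load the ICD-9-CM condition mapping (bundled Deyo-style default)."""
    if path is None:
        text = (
            importlib.resources.files("ddci").joinpath("data/charlson_icd9.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [
        CharlsonCondition(
            name=c["name"],
            weight=int(c["weight"]),
            prefixes=tuple(str(p) for p in c["prefixes"]),
            superseded_by=c.get("superseded_by"),
        )
        for c in raw["conditions"]
    ]


def _normalise_icd9(code: str) -> str:
    return code.replace(".", "").strip().upper()


def _conditions_from_codes(
    codes: set[str], mapping: list[CharlsonCondition]
) -> set[str]:
    present = {
        cond.name
        for cond in mapping
        if any(code.startswith(p) for code in codes for p in cond.prefixes)
    }
    # hierarchy: drop the milder condition when its severe form is present
    for cond in mapping:
        if cond.superseded_by and cond.superseded_by in present:
            present.discard(cond.name)
    return present


def compute_cci(
    hospitalizations: list[HospitalizationRecord],
    mapping: list[CharlsonCondition] | None = None,
) -> int:
    """Charlson score from one person's baseline hospital discharges.

    Scans primary and secondary diagnoses of every record against the
    condition mapping and sums the condition weights (each condition counts
    once).  An empty record list scores 0.
    """
    if mapping is None:
        mapping = load_charlson_mapping()
    codes = {_normalise_icd9(d) for h in hospitalizations for d in h.diagnoses}
    present = _conditions_from_codes(codes, mapping)
    by_name = {c.name: c.weight for c in mapping}
    return sum(by_name[name] for name in present)


def compute_cci_frame(
    hospitalizations: pd.DataFrame,
    persons: pd.DataFrame,
    mapping: list[CharlsonCondition] | None = None,
    window_days: int = 365,
) -> pd.Series:
    """Charlson score per person from baseline-window admissions.

    Admissions whose admission date falls in the half-open window
    ``[index − window_days, index)`` contribute; persons without any such
    admission score 0.
    """
    if mapping is None:
        mapping = load_charlson_mapping()
    by_name = {c.name: c.weight for c in mapping}
    out = pd.Series(0, index=persons.index, name="cci")
    if len(hospitalizations) == 0:
        return out
    hosp = hospitalizations.merge(
        persons[["index_date"]], left_on="person_id", right_index=True, how="inner"
    )
    days_before = (hosp["index_date"] - hosp["admission_date"]).dt.days
    hosp = hosp[(days_before > 0) & (days_before <= window_days)]
    for pid, grp in hosp.groupby("person_id"):
        codes = {_normalise_icd9(d) for diags in grp["diagnoses"] for d in diags}
        present = _conditions_from_codes(codes, mapping)
        out.loc[pid] = sum(by_name[name] for name in present)
    return out


def profile_from_row(person_id: str, row: pd.Series) -> ExposureProfile:
    """ExposureProfile from one row of a boolean exposure frame."""
    return ExposureProfile(person_id, {c: bool(row[c]) for c in DRUG_CLASSES})
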