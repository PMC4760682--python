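"""Rule engine: baseline prescriptions → 19 drug-class exposure flags.

Each drug class is defined by a rule over dispensing records — a
prescription pattern indicative of a chronic disease (PPCD): a set of ATC
prefixes, a minimum total package count, and a look-back window.  The
baseline window is the half-open year before the index date,
``[index − 365 d, index)``: a package dispensed exactly 365 days before the
index date counts, one dispensed on the index date does not.

"Packages" sums the per-dispensation package quantities (Italian pharmacy
claims record packages per dispensation), not distinct prescription rows.

One class — drugs for hypertensive heart disease — uses a combination rule
instead of a package threshold: the flag is raised when, within any sliding
45-day window inside the baseline year, either prescriptions from at least
two distinct entries of a listed agent set occur, or at least two
prescriptions of digoxin (C01AA05) occur.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import PrescriptionRecord
from .reference import DRUG_CLASSES

#: Default look-back window (days) for the package-count rules.
DEFAULT_WINDOW_DAYS = 365

#: ATC exclusions implementing "other than codeine and tramadol" for the
#: opioid class: codeine combinations and tramadol (plain and combined).
OPIOID_EXCLUSIONS = ("N02AA59", "N02AA79", "N02AX02", "N02AX52")

#: Agent set of the hypertensive-heart-disease combination rule.
HHD_COMBINATION_ATC = ("C01AA05", "C03CA01", "C03DA01", "C07AG02", "C07AB07", "C07AB03", "C09")
HHD_REPEAT_ATC = "C01AA05"
HHD_WINDOW_DAYS = 45


@dataclasses.dataclass(frozen=True)
class CombinationLogic:
    """Sliding-window combination rule (hypertensive heart disease).

    True iff, within any ``window_days``-day span inside the baseline year,
    (a) prescriptions matching ≥2 distinct members of ``combo_atc`` occur,
    or (b) ≥ ``min_repeat`` prescription rows of ``repeat_atc`` occur.
    """

    combo_atc: tuple[str, ...] = HHD_COMBINATION_ATC
    repeat_atc: str = HHD_REPEAT_ATC
    min_repeat: int = 2
    window_days: int = HHD_WINDOW_DAYS


@dataclasses.dataclass(frozen=True)
class DrugClassRule:
    """One drug-class definition: ATC prefixes + threshold + window."""

    name: str
    include_atc: tuple[str, ...]
    exclude_atc: tuple[str, ...] = ()
    min_packages: int = 3
    window_days: int = DEFAULT_WINDOW_DAYS
    combination_logic: CombinationLogic | None = None

    def __post_init__(self) -> None:
        if not self.include_atc:
            raise ValueError(f"rule {self.name}: include_atc must be non-empty")
        for exc in self.exclude_atc:
            if not any(exc.startswith(inc) for inc in self.include_atc):
                raise ValueError(
                    f"rule {self.name}: exclusion {exc} extends no include prefix"
                )


@dataclasses.dataclass(frozen=True)
class ExposureProfile:
    """The 19 baseline exposure flags for one person."""

    person_id: str
    flags: dict[str, bool]


def default_rule_table(standard_neuro_atc: bool = False) -> list[DrugClassRule]:
    """The 19 published drug-class definitions.

    The published table maps anti-dementia drugs to N06A and antidepressants
    to N06D — the reverse of the standard ATC assignment (N06A =
    antidepressants, N06D = anti-dementia).  The default follows the
    published table verbatim; ``standard_neuro_atc=True`` restores standard
    ATC semantics for those two classes.
    """
    dementia_atc, depress_atc = ("N06D", "N06A") if standard_neuro_atc else ("N06A", "N06D")
    return [
        DrugClassRule("Antiarrhythmics", ("C01B",)),
        DrugClassRule("Immunosuppressants", ("L04",)),
        DrugClassRule("Platelet aggregation inhibitors", ("B01AC",)),
        DrugClassRule("Parenteral anticoagulants", ("B01AB", "B01AX")),
        DrugClassRule("Oral anticoagulants", ("B01AA",)),
        DrugClassRule("Antineoplastic agents", ("L01",)),
        DrugClassRule("Inhaled bronchodilators", ("R03A", "R03BB", "R03DA")),
        DrugClassRule(
            "Drugs for arterial hypertension",
            (
                "C02A", "C02C", "C02LA", "C02LB", "C03A", "C03BA", "C03EA01",
                "C07AA", "C07AB", "C07AG", "C07BB", "C07C", "C08",
                "C09AA", "C09BA", "C09CA", "C09DA",
            ),
            exclude_atc=("C07AB09",),
        ),
        DrugClassRule("Antihyperglycemic therapy", ("A10",), min_packages=2),
        DrugClassRule(
            "Drugs for hypertensive heart disease",
            HHD_COMBINATION_ATC,
            combination_logic=CombinationLogic(),
        ),
        DrugClassRule("Drugs for acid related disorders", ("A02",)),
        DrugClassRule("Lipid modifying agents", ("C10",)),
        DrugClassRule("Nonsteroidal anti-inflammatory drugs", ("M01",)),
        DrugClassRule("Systemic corticosteroids", ("H02AB",)),
        DrugClassRule("Opioids", ("N02A",), exclude_atc=OPIOID_EXCLUSIONS),
        DrugClassRule("Anti-Parkinson drugs", ("N04",), min_packages=1),
        DrugClassRule("Antipsychotics", ("N05A",), min_packages=1),
        DrugClassRule("Anti-dementia drugs", (dementia_atc,), min_packages=1),
        DrugClassRule("Antidepressants", (depress_atc,), min_packages=1),
    ]


def match_atc(atc_code: str, rule: DrugClassRule) -> bool:
    """True iff the code starts with an include prefix and no exclude prefix."""
    return any(atc_code.startswith(p) for p in rule.include_atc) and not any(
        atc_code.startswith(p) for p in rule.exclude_atc
    )


def _combination_flag(dates: np.ndarray, entries: np.ndarray, logic: CombinationLogic) -> bool:
    """Evaluate the sliding-window combination rule.

    ``dates``: integer day offsets of matching prescriptions; ``entries``:
    index of the agent-set member each prescription matches (longest-prefix
    match).  Two prescriptions are "within" the window when their dates
    differ by at most ``window_days``.
    """
    if len(dates) < 2:
        return False
    order = np.argsort(dates, kind="stable")
    dates = dates[order]
    entries = entries[order]
    repeat_idx = logic.combo_atc.index(logic.repeat_atc) if logic.repeat_atc in logic.combo_atc else -1
    j = 0
    for i in range(len(dates)):
        while dates[i] - dates[j] > logic.window_days:
            j += 1
        window = entries[j : i + 1]
        if len(np.unique(window)) >= 2:
            return True
        if repeat_idx >= 0 and int(np.sum(window == repeat_idx)) >= logic.min_repeat:
            return True
    return False


def _entry_index(code: str, combo_atc: tuple[str, ...]) -> int:
    """Longest-prefix member of the agent set matched by ``code`` (-1: none)."""
    best, best_len = -1, -1
    for k, prefix in enumerate(combo_atc):
        if code.startswith(prefix) and len(prefix) > best_len:
            best, best_len = k, len(prefix)
    return best


def detect_exposures(
    prescriptions: list[PrescriptionRecord],
    rules: list[DrugClassRule],
    index_date: dt.date,
) -> ExposureProfile:
    """Exposure flags for one person from their prescription history.

    Only dispensations in the half-open baseline window
    ``[index − window_days, index)`` count.
    """
    person_ids = {p.person_id for p in prescriptions}
    if len(person_ids) > 1:
        raise ValueError(f"prescriptions span several persons: {sorted(person_ids)}")
    person_id = person_ids.pop() if person_ids else ""

    flags: dict[str, bool] = {}
    for rule in rules:
        in_window = [
            p
            for p in prescriptions
            if 0 < (index_date - p.dispense_date).days <= rule.window_days
            and match_atc(p.atc_code, rule)
        ]
        if rule.combination_logic is None:
            flags[rule.name] = sum(p.packages for p in in_window) >= rule.min_packages
        else:
            logic = rule.combination_logic
            dates = np.array([(p.dispense_date - index_date).days for p in in_window])
            entries = np.array([_entry_index(p.atc_code, logic.combo_atc) for p in in_window], dtype=int)
            ok = entries >= 0
            flags[rule.name] = _combination_flag(dates[ok], entries[ok], logic)
    return ExposureProfile(person_id, flags)


def detect_exposures_frame(
    prescriptions: pd.DataFrame,
    persons: pd.DataFrame,
    rules: list[DrugClassRule] | None = None,
) -> pd.DataFrame:
    """Vectorised exposure detection for a whole cohort.

    Parameters
    ----------
    prescriptions
        Cohort prescriptions table (person_id, atc_code, dispense_date,
        packages).
    persons
        Persons table indexed by person_id with an ``index_date`` column.
    rules
        Rule table; defaults to the published definitions.

    Returns
    -------
    Boolean DataFrame indexed like ``persons``, one column per drug class.
    """
    if rules is None:
        rules = default_rule_table()
    out = pd.DataFrame(False, index=persons.index, columns=[r.name for r in rules])
    if len(prescriptions) == 0:
        return out

    rx = prescriptions.merge(
        persons[["index_date"]], left_on="person_id", right_index=True, how="inner"
    )
    day_before_index = (rx["index_date"] - rx["dispense_date"]).dt.days.to_numpy()
    codes = rx["atc_code"].to_numpy(dtype=str)

    for rule in rules:
        match = np.zeros(len(rx), dtype=bool)
        for prefix in rule.include_atc:
            match |= np.char.startswith(codes, prefix)
        for prefix in rule.exclude_atc:
            match &= ~np.char.startswith(codes, prefix)
        match &= (day_before_index > 0) & (day_before_index <= rule.window_days)
        sub = rx[match]
        if rule.combination_logic is None:
            totals = sub.groupby("person_id")["packages"].sum()
            hit = totals[totals >= rule.min_packages].index
            out.loc[out.index.isin(hit), rule.name] = True
        else:
            logic = rule.combination_logic
            entry = np.array([_entry_index(c, logic.combo_atc) for c in sub["atc_code"]], dtype=int)
            sub = sub.assign(
                _entry=entry, _day=(sub["dispense_date"] - sub["index_date"]).dt.days
            )
            sub = sub[sub["_entry"] >= 0]
            for pid, grp in sub.groupby("person_id"):
                if _combination_flag(
                    grp["_day"].to_numpy(), grp["_entry"].to_numpy(), logic
                ):
                    out.loc[pid, rule.name] = True
    return out


# -- rule-table configuration round trip -----------------------------------

def save_rule_table(rules: list[DrugClassRule], path: str | Path) -> None:
    """Write a rule table to YAML (one block per class)."""
    blocks = []
    for r in rules:
        block: dict = {
            "name": r.name,
            "include_atc": list(r.include_atc),
            "exclude_atc": list(r.exclude_atc),
            "min_packages": r.min_packages,
            "window_days": r.window_days,
        }
        if r.combination_logic is not None:
            c = r.combination_logic
            block["combination_logic"] = {
                "combo_atc": list(c.combo_atc),
                "repeat_atc": c.repeat_atc,
                "min_repeat": c.min_repeat,
                "window_days": c.window_days,
            }
        blocks.append(block)
    Path(path).write_text(yaml.safe_dump({"drug_classes": blocks}, sort_keys=False))


def load_rule_table(path: str | Path) -> list[DrugClassRule]:
    """Read a rule table from YAML written by :func:`save_rule_table`."""
    raw = yaml.safe_load(Path(path).read_text())
    rules = []
    for block in raw["drug_classes"]:
        logic = None
        if "combination_logic" in block:
            c = block["combination_logic"]
            logic = CombinationLogic(
                combo_atc=tuple(c["combo_atc"]),
                repeat_atc=c["repeat_atc"],
                min_repeat=int(c["min_repeat"]),
                window_days=int(c["window_days"]),
            )
        rules.append(
            DrugClassRule(
                name=block["name"],
                include_atc=tuple(block["include_atc"]),
                exclude_atc=tuple(block.get("exclude_atc", ())),
                min_packages=int(block.get("min_packages", 3)),
                window_days=int(block.get("window_days", DEFAULT_WINDOW_DAYS)),
                combination_logic=logic,
            )
        )
    return rules


def rule_names(rules: list[DrugClassRule] | None = None) -> list[str]:
    return [r.name for r in rules] if rules is not None else list(DRUG_CLASSES)
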