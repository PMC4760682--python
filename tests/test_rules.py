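"""Exposure rule engine: ATC matching, windows, and the combination rule."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddci.data_model import PrescriptionRecord
from ddci.reference import DRUG_CLASSES
from ddci.rules import (
    default_rule_table,
    detect_exposures,
    detect_exposures_frame,
    load_rule_table,
    match_atc,
    save_rule_table,
)

INDEX = dt.date(2004, 1, 1)
RULES = default_rule_table()
BY_NAME = {r.name: r for r in RULES}


def rx(atc, days_before, packages=1, pid="p"):
    return PrescriptionRecord(pid, atc, INDEX - dt.timedelta(days=days_before), packages)


class TestRuleTable:
    def test_nineteen_classes_in_canonical_order(self):
        assert [r.name for r in RULES] == list(DRUG_CLASSES)

    @pytest.mark.parametrize(
        "name, includes, min_packages",
        [
            ("Antiarrhythmics", ("C01B",), 3),
            ("Antihyperglycemic therapy", ("A10",), 2),
            ("Anti-Parkinson drugs", ("N04",), 1),
            ("Antipsychotics", ("N05A",), 1),
            ("Systemic corticosteroids", ("H02AB",), 3),
        ],
    )
    def test_published_definitions(self, name, includes, min_packages):
        rule = BY_NAME[name]
        assert rule.include_atc == includes
        assert rule.min_packages == min_packages
        assert rule.window_days == 365

    def test_opioid_exclusions_cover_codeine_and_tramadol(self):
        assert set(BY_NAME["Opioids"].exclude_atc) == {"N02AA59", "N02AA79", "N02AX02", "N02AX52"}

    def test_neuro_class_swap_switch(self):
        printed = {r.name: r.include_atc for r in default_rule_table()}
        standard = {r.name: r.include_atc for r in default_rule_table(standard_neuro_atc=True)}
        assert printed["Anti-dementia drugs"] == ("N06A",)
        assert printed["Antidepressants"] == ("N06D",)
        assert standard["Anti-dementia drugs"] == ("N06D",)
        assert standard["Antidepressants"] == ("N06A",)

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        save_rule_table(RULES, path)
        assert load_rule_table(path) == RULES


class TestMatchAtc:
    @pytest.mark.parametrize(
        "code, rule_name, expected",
        [
            ("C07AB03", "Drugs for arterial hypertension", True),
            ("C07AB09", "Drugs for arterial hypertension", False),
            ("C01BA01", "Antiarrhythmics", True),
            ("C01AA05", "Antiarrhythmics", False),
            ("N02AA01", "Opioids", True),
            ("N02AX02", "Opioids", False),  # tramadol
            ("N02AA59", "Opioids", False),  # codeine combination
        ],
    )
    def test_prefix_and_exclusion_semantics(self, code, rule_name, expected):
        assert match_atc(code, BY_NAME[rule_name]) is expected


class TestDetectExposures:
    def test_three_packages_flag_antiarrhythmics(self):
        prof = detect_exposures([rx("C01BD01", 300), rx("C01BD01", 150), rx("C01BD01", 30)], RULES, INDEX)
        assert prof.flags["Antiarrhythmics"]

    def test_per_rule_thresholds(self):
        prof = detect_exposures([rx("C01BD01", 100, 2)], RULES, INDEX)
        assert not prof.flags["Antiarrhythmics"]
        prof = detect_exposures([rx("A10BA02", 100, 2)], RULES, INDEX)
        assert prof.flags["Antihyperglycemic therapy"]

    def test_no_prescriptions_all_flags_false(self):
        prof = detect_exposures([], RULES, INDEX)
        assert len(prof.flags) == 19 and not any(prof.flags.values())

    def test_window_is_half_open(self):
        assert detect_exposures([rx("C01BD01", 365, 3)], RULES, INDEX).flags["Antiarrhythmics"]
        assert not detect_exposures([rx("C01BD01", 0, 3)], RULES, INDEX).flags["Antiarrhythmics"]
        assert not detect_exposures([rx("C01BD01", 366, 3)], RULES, INDEX).flags["Antiarrhythmics"]

    def test_combination_rule_branches(self):
        hhd = "Drugs for hypertensive heart disease"
        two_agents = [rx("C03CA01", 100), rx("C03DA01", 90)]
        assert detect_exposures(two_agents, RULES, INDEX).flags[hhd]
        far_apart = [rx("C03CA01", 160), rx("C03DA01", 100)]
        assert not detect_exposures(far_apart, RULES, INDEX).flags[hhd]
        digoxin_twice = [rx("C01AA05", 200), rx("C01AA05", 170)]
        assert detect_exposures(digoxin_twice, RULES, INDEX).flags[hhd]
        digoxin_once = [rx("C01AA05", 200)]
        assert not detect_exposures(digoxin_once, RULES, INDEX).flags[hhd]

    def test_c09_counts_as_single_combination_entry(self):
        # two prescriptions inside one C09 subgroup are one agent, not two
        hhd = "Drugs for hypertensive heart disease"
        prof = detect_exposures([rx("C09AA02", 100), rx("C09AA05", 95)], RULES, INDEX)
        assert not prof.flags[hhd]
        prof = detect_exposures([rx("C09AA02", 100), rx("C01AA05", 95)], RULES, INDEX)
        assert prof.flags[hhd]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["C01BD01", "A10BA02", "N02AA01", "C03CA01", "C01AA05", "M01AB05"]),
                st.integers(min_value=1, max_value=400),
                st.integers(min_value=1, max_value=3),
            ),
            max_size=8,
        ),
        st.tuples(
            st.sampled_from(["C01BD01", "A10BA02", "C03DA01", "C01AA05"]),
            st.integers(min_value=1, max_value=365),
        ),
    )
    def test_monotone_in_prescriptions(self, base, extra):
        """Adding a prescription never turns a flag from true to false."""
        before = detect_exposures([rx(a, d, k) for a, d, k in base], RULES, INDEX).flags
        after = detect_exposures(
            [rx(a, d, k) for a, d, k in base] + [rx(extra[0], extra[1])], RULES, INDEX
        ).flags
        for name in before:
            assert after[name] >= before[name]


def _brute_force_flags(prescriptions, rules, index_date):
    """Independent re-scan: per-rule loops, pairwise combination check."""
    flags = {}
    for rule in rules:
        window = [
            p
            for p in prescriptions
            if 0 < (index_date - p.dispense_date).days <= rule.window_days
            and any(p.atc_code.startswith(i) for i in rule.include_atc)
            and not any(p.atc_code.startswith(e) for e in rule.exclude_atc)
        ]
        if rule.combination_logic is None:
            flags[rule.name] = sum(p.packages for p in window) >= rule.min_packages
            continue
        logic = rule.combination_logic
        hit = False
        for i, a in enumerate(window):
            for b in window[i + 1 :]:
                if abs((a.dispense_date - b.dispense_date).days) > logic.window_days:
                    continue
                ent_a = max((p for p in logic.combo_atc if a.atc_code.startswith(p)), key=len, default=None)
                ent_b = max((p for p in logic.combo_atc if b.atc_code.startswith(p)), key=len, default=None)
                if ent_a and ent_b and ent_a != ent_b:
                    hit = True
                if (
                    a.atc_code.startswith(logic.repeat_atc)
                    and b.atc_code.startswith(logic.repeat_atc)
                ):
                    hit = True
        flags[rule.name] = hit
    return flags


def test_frame_detector_matches_brute_force_scan():
    """Vectorised detection equals an exhaustive (rule, person, window) scan."""
    rng = np.random.default_rng(2024)
    codes = [
        "C01BD01", "A10BA02", "N02AA01", "N02AX02", "C03CA01", "C03DA01",
        "C01AA05", "C09AA02", "M01AB05", "C10AA01", "N04BA02", "C07AB03",
        "C07AB09", "H02AB06", "B01AC06",
    ]
    persons = pd.DataFrame(
        {"index_date": pd.Timestamp("2004-01-01")},
        index=pd.Index([f"r{i:03d}" for i in range(200)], name="person_id"),
    )
    rows = []
    for pid in persons.index:
        for _ in range(rng.integers(0, 8)):
            rows.append(
                (
                    pid,
                    codes[rng.integers(0, len(codes))],
                    pd.Timestamp("2004-01-01") - pd.Timedelta(days=int(rng.integers(0, 400))),
                    int(rng.integers(1, 4)),
                )
            )
    rx_frame = pd.DataFrame(rows, columns=["person_id", "atc_code", "dispense_date", "packages"])
    frame_flags = detect_exposures_frame(rx_frame, persons, RULES)
    for pid in persons.index:
        recs = [
            PrescriptionRecord(r.person_id, r.atc_code, r.dispense_date.date(), r.packages)
            for r in rx_frame[rx_frame["person_id"] == pid].itertuples()
        ]
        expected = _brute_force_flags(recs, RULES, dt.date(2004, 1, 1))
        got = frame_flags.loc[pid].to_dict()
        assert got == expected, pid
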