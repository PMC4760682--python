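"""Discrimination, reclassification and rate-model battery."""

import numpy as np
import pandas as pd
import pytest

from ddci.evaluation import (
    ModelComparison,
    classwise_hazard_ratios,
    harrell_c,
    km_estimate,
    nri,
    readmission_irr,
)


def _surv(time, event):
    return pd.DataFrame({"time": np.asarray(time, float), "event": np.asarray(event, bool)})


class TestKaplanMeier:
    def test_two_deaths_closed_form(self):
        km = km_estimate(_surv([1.0, 2.0], [1, 1]))[0]
        s = km.set_index("time")["survival"]
        assert s[1.0] == pytest.approx(0.5)
        assert s[2.0] == pytest.approx(0.0)

    def test_censoring_after_last_event_leaves_curve(self):
        a = km_estimate(_surv([1.0, 2.0], [1, 1]))[0].set_index("time")["survival"]
        b = km_estimate(_surv([1.0, 2.0, 3.0], [1, 1, 0]))[0].set_index("time")["survival"]
        assert b[1.0] == pytest.approx(2 / 3)  # risk set grows, curve differs before
        assert b[2.0] == pytest.approx(1 / 3)
        assert b.iloc[-1] == pytest.approx(b[2.0])  # censoring adds no drop

    def test_matches_product_limit_oracle(self):
        """100-person random fixture vs a direct product over risk sets."""
        rng = np.random.default_rng(7)
        time = np.round(rng.exponential(3, 100), 2).clip(0.01, 7)
        event = rng.random(100) < 0.6
        km = km_estimate(_surv(time, event))[0]
        for t in np.unique(time[event]):
            s = 1.0
            for td in sorted(np.unique(time[event & (time <= t)])):
                d = np.sum((time == td) & event)
                n_risk = np.sum(time >= td)
                s *= 1 - d / n_risk
            got = km[km["time"] == t]["survival"].iloc[0]
            assert got == pytest.approx(s)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(11)
        time = np.round(rng.exponential(2, 80), 3)
        km = km_estimate(_surv(time, np.ones(80)))[0]
        for _, row in km.iloc[1:].iterrows():
            assert row["survival"] == pytest.approx(np.mean(time > row["time"]))


def _brute_force_c(score, time, event):
    """O(n²) pair enumeration with explicit usability rules."""
    num = den = 0.0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = event[i] and (time[i] < time[j] or (time[i] == time[j] and not event[j]))
            if not usable:
                continue
            den += 1
            if score[i] > score[j]:
                num += 1
            elif score[i] == score[j]:
                num += 0.5
    return num / den, int(den)


class TestHarrellC:
    def test_perfect_ranking_gives_one(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrell_c(-time, _surv(time, [1, 1, 1, 1])).c_index == 1.0

    def test_random_score_near_half(self):
        rng = np.random.default_rng(5)
        n = 600
        time = rng.exponential(3, n).clip(max=7)
        event = time < 7
        res = harrell_c(rng.random(n), _surv(time, event))
        assert res.c_index == pytest.approx(0.5, abs=0.05)
        assert res.ci[0] < 0.5 < res.ci[1]

    def test_equals_pair_enumeration_oracle(self):
        """50-person censored fixture: exact agreement with brute force."""
        rng = np.random.default_rng(17)
        n = 50
        time = np.round(rng.exponential(3, n), 1).clip(0.1, 7)
        event = rng.random(n) < 0.6
        score = np.round(rng.random(n), 2)
        res = harrell_c(score, _surv(time, event))
        c_oracle, n_pairs = _brute_force_c(score, time, event)
        assert res.c_index == pytest.approx(c_oracle, abs=1e-12)
        assert res.n_pairs == n_pairs

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(23)
        n = 300
        time = rng.exponential(3, n).clip(max=7)
        event = time < 7
        score = rng.random(n) + 0.3 * (7 - time)
        res = harrell_c(score, _surv(time, event))
        assert res.c_index == pytest.approx(
            concordance_index(time, -score, event), abs=1e-10
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(31)
        n = 120
        time = rng.exponential(3, n).clip(max=7)
        event = time < 7
        score = rng.normal(size=n)
        surv = _surv(time, event)
        a = harrell_c(score, surv).c_index
        b = harrell_c(np.exp(2 * score) + 5, surv).c_index
        assert a == pytest.approx(b, abs=1e-12)

    def test_bootstrap_ci_available(self):
        rng = np.random.default_rng(41)
        time = rng.exponential(3, 60).clip(max=7)
        event = time < 7
        res = harrell_c(rng.random(60), _surv(time, event), ci_method="bootstrap", n_boot=50)
        assert res.ci[0] <= res.c_index <= res.ci[1]

    def test_no_usable_pairs_is_error(self):
        with pytest.raises(ValueError, match="usable"):
            harrell_c([1.0, 2.0], _surv([1.0, 2.0], [0, 0]))


class TestNri:
    def test_maximum_reclassification(self):
        ref = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.9, 0.8, 0.1, 0.2])
        event = np.array([True, True, False, False])
        res = nri(ref, new, event)
        assert (res.nri, res.event_component, res.nonevent_component) == (2.0, 1.0, 1.0)

    def test_identity_gives_zero(self):
        r = np.array([0.1, 0.5, 0.9, 0.4])
        res = nri(r, r, np.array([True, False, True, False]))
        assert res.nri == 0.0

    def test_counting_oracle_forty_persons(self):
        rng = np.random.default_rng(13)
        n = 40
        ref = rng.random(n)
        new = rng.random(n)
        event = rng.random(n) < 0.4
        res = nri(ref, new, event)
        up_e = sum(1 for i in range(n) if event[i] and new[i] > ref[i])
        dn_e = sum(1 for i in range(n) if event[i] and new[i] < ref[i])
        up_ne = sum(1 for i in range(n) if not event[i] and new[i] > ref[i])
        dn_ne = sum(1 for i in range(n) if not event[i] and new[i] < ref[i])
        n_e, n_ne = int(event.sum()), int((~event).sum())
        assert res.event_component == pytest.approx((up_e - dn_e) / n_e)
        assert res.nonevent_component == pytest.approx((dn_ne - up_ne) / n_ne)
        assert res.nri == pytest.approx(res.event_component + res.nonevent_component)

    def test_antisymmetric_and_bounded(self):
        rng = np.random.default_rng(29)
        ref, new = rng.random(60), rng.random(60)
        event = rng.random(60) < 0.5
        a, b = nri(ref, new, event), nri(new, ref, event)
        assert a.nri == pytest.approx(-b.nri)
        assert -1 <= a.event_component <= 1 and -1 <= a.nonevent_component <= 1
        assert -2 <= a.nri <= 2

    def test_requires_both_outcomes(self):
        with pytest.raises(ValueError, match="events"):
            nri([0.1], [0.2], [True])


class TestReadmissionIrr:
    def test_irr_equals_crude_rate_ratio(self):
        """Single binary class, no covariates: model IRR = ratio of rates."""
        counts = pd.Series([1, 2, 0, 3, 2, 4, 1, 5])
        py = pd.Series([2.0, 3.0, 1.0, 4.0, 2.0, 3.0, 1.0, 4.0])
        cls = pd.Series([0, 0, 0, 0, 1, 1, 1, 1])
        tab = readmission_irr(counts, py, cls)
        crude = (counts[cls == 1].sum() / py[cls == 1].sum()) / (
            counts[cls == 0].sum() / py[cls == 0].sum()
        )
        assert tab.loc[1, "irr"] == pytest.approx(crude, rel=1e-6)
        assert tab.loc[0, "irr"] == 1.0

    def test_equal_rates_give_unit_irr(self):
        counts = pd.Series([2, 4, 1, 2])
        py = pd.Series([2.0, 4.0, 1.0, 2.0])
        cls = pd.Series([0, 0, 1, 1])
        tab = readmission_irr(counts, py, cls)
        assert tab.loc[1, "irr"] == pytest.approx(1.0, rel=1e-6)

    def test_recovers_simulated_rate_multipliers(self):
        rng = np.random.default_rng(8)
        n = 3000
        cls = rng.integers(0, 3, n)
        mult = np.array([1.0, 1.4, 1.9])[cls]
        py = rng.uniform(1, 7, n)
        counts = rng.poisson(0.5 * mult * py)
        tab = readmission_irr(pd.Series(counts), pd.Series(py), pd.Series(cls))
        for c, true in [(1, 1.4), (2, 1.9)]:
            assert tab.loc[c, "ci_low"] < true < tab.loc[c, "ci_high"]

    def test_empty_reference_class_is_error(self):
        with pytest.raises(ValueError, match="class 0"):
            readmission_irr(pd.Series([1]), pd.Series([1.0]), pd.Series([2]))


class TestClasswiseHazardRatios:
    def test_recovers_proportional_hazard(self):
        rng = np.random.default_rng(19)
        n = 4000
        cls = rng.integers(0, 2, n)
        age = rng.uniform(40, 90, n)
        male = rng.random(n) < 0.5
        hazard = 0.05 * np.exp(np.log(2.0) * cls)
        time = rng.exponential(1 / hazard).clip(max=7)
        event = time < 7
        fit = classwise_hazard_ratios(_surv(time, event), pd.Series(cls), pd.Series(age), pd.Series(male))
        row = fit.table.loc["class_1"]
        assert row["ci_low"] < 2.0 < row["ci_high"]

    def test_null_effect_hr_near_one(self):
        rng = np.random.default_rng(37)
        n = 3000
        cls = rng.integers(0, 3, n)
        time = rng.exponential(8, n).clip(max=7)
        event = time < 7
        fit = classwise_hazard_ratios(
            _surv(time, event), pd.Series(cls),
            pd.Series(rng.uniform(40, 90, n)), pd.Series(rng.random(n) < 0.5),
        )
        for c in (1, 2):
            row = fit.table.loc[f"class_{c}"]
            assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError, match="class 0"):
            classwise_hazard_ratios(
                _surv([1.0, 2.0], [1, 1]), pd.Series([1, 2]),
                pd.Series([50.0, 60.0]), pd.Series([0, 1]),
            )


class TestModelComparison:
    @staticmethod
    def _cohort(n=3000, seed=43, beta_extra=0.0):
        rng = np.random.default_rng(seed)
        age = rng.uniform(40, 90, n)
        male = (rng.random(n) < 0.5).astype(float)
        extra = rng.standard_normal(n)
        lp = 0.06 * (age - 60) + 0.2 * male + beta_extra * extra
        time = rng.exponential(1 / (0.01 * np.exp(lp))).clip(max=7)
        event = time < 7
        ref = pd.DataFrame({"age": age, "male": male})
        aug = ref.assign(extra=extra)
        return ref, aug, _surv(time, event), extra

    def test_null_augmentation_changes_nothing(self):
        ref, aug, surv, _ = self._cohort(beta_extra=0.0)
        res = ModelComparison(ref, aug, surv).fit(horizon=7.0)
        assert abs(res.delta_c) < 0.01
        assert res.nri_result.ci[0] < 0 < res.nri_result.ci[1]

    def test_true_signal_raises_concordance(self):
        ref, aug, surv, _ = self._cohort(beta_extra=0.8)
        res = ModelComparison(ref, aug, surv).fit(horizon=7.0)
        assert res.delta_c > 0.02
        assert res.nri_result.nri > 0
        assert res.nri_result.ci[0] > 0

    def test_nri_components_sum(self):
        ref, aug, surv, _ = self._cohort(beta_extra=0.5)
        res = ModelComparison(ref, aug, surv).fit(horizon=7.0)
        r = res.nri_result
        assert r.nri == pytest.approx(r.event_component + r.nonevent_component)

    def test_ipcw_option_runs_and_agrees_in_sign(self):
        ref, aug, surv, _ = self._cohort(beta_extra=0.8)
        plain = ModelComparison(ref, aug, surv).fit(horizon=7.0)
        weighted = ModelComparison(ref, aug, surv).fit(horizon=7.0, ipcw=True)
        assert np.sign(plain.nri_result.nri) == np.sign(weighted.nri_result.nri)

    def test_summary_mentions_both_models(self):
        ref, aug, surv, _ = self._cohort()
        text = ModelComparison(ref, aug, surv).fit(horizon=7.0).summary()
        assert "reference" in text and "augmented" in text and "NRI" in text
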