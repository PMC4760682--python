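"""Validation battery: discrimination, reclassification and rate models.

Implements the evaluation the index is judged by:

* Kaplan–Meier survival curves stratified by risk class,
* class-wise mortality hazard ratios (Cox, adjusted for age and sex),
* Harrell's survival C-index with an asymptotic 95% CI,
* continuous (category-free) Net Reclassification Improvement,
* Poisson incidence-rate-ratio model for hospital readmissions with a
  person-years exposure offset,
* paired model comparison — a reference Cox model (age + sex) against an
  augmented one (+DDCI, +CCI, or both), reporting ΔC and NRI.

Predicted risk at a horizon t is ``1 − S0(t)^exp(lp)`` with the Breslow
baseline survival from the fitted Cox model.
"""

from __future__ import annotations

import dataclasses
import io
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter

from .derivation import CoxFitResult, fit_cox

_Z95 = 1.959963984540054


# -- Kaplan-Meier -----------------------------------------------------------

def km_estimate(
    survival: pd.DataFrame, groups: pd.Series | None = None
) -> dict[object, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns one DataFrame per group label with columns ``time``,
    ``survival`` and ``at_risk``; probabilities start at 1 and are
    non-increasing.
    """
    if groups is None:
        groups = pd.Series(0, index=survival.index)
    out: dict[object, pd.DataFrame] = {}
    for label in sorted(pd.unique(groups)):
        sub = survival[groups == label]
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(int))
        tab = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": kmf.event_table["at_risk"].reindex(
                    kmf.survival_function_.index
                ).to_numpy(),
            }
        )
        out[label] = tab.reset_index(drop=True)
    return out


# -- class-wise hazard ratios ----------------------------------------------

def classwise_hazard_ratios(
    survival: pd.DataFrame,
    classes: pd.Series,
    age: pd.Series,
    sex_male: pd.Series,
) -> CoxFitResult:
    """Cox HR for each risk class vs class 0, adjusted for age and sex.

    Classes absent from the data are omitted (with a warning), as are
    degenerate sparse classes whose indicator makes the information matrix
    singular (complete separation); class 0 must be populated since it is
    the reference.
    """
    from lifelines.exceptions import ConvergenceError

    present = sorted(pd.unique(classes))
    if 0 not in present:
        raise ValueError("reference class 0 is empty")
    dummies = [c for c in present if c != 0]
    while True:
        design = pd.DataFrame(index=survival.index)
        for c in dummies:
            design[f"class_{c}"] = (classes == c).astype(float)
        design["age"] = age.astype(float)
        design["male"] = sex_male.astype(float)
        try:
            return fit_cox(design, survival)
        except (ConvergenceError, np.linalg.LinAlgError):
            if not dummies:
                raise
            sizes = {c: int((classes == c).sum()) for c in dummies}
            drop = min(sizes, key=sizes.get)
            warnings.warn(
                f"risk class {drop} (n={sizes[drop]}) dropped: singular fit"
            )
            dummies.remove(drop)


# -- Harrell's C ------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    ci: tuple[float, float]
    n_pairs: int  # usable (comparable) pairs
    n_concordant: float  # concordant + 0.5 per score tie


def _pair_counts(score: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Blockwise O(n²) usable/concordant pair counts plus per-subject sums.

    A pair is usable when the shorter observed time is an event and the
    times differ, or the times are equal and exactly one is an event (the
    censored subject is then known to survive longer).  Within a usable
    pair the higher score should belong to the earlier failure; equal
    scores earn 0.5.
    """
    n = len(score)
    usable_i = np.zeros(n)
    conc_i = np.zeros(n)
    block = 1024
    for start in range(0, n, block):
        sl = slice(start, min(start + block, n))
        t_i, e_i, s_i = time[sl, None], event[sl, None], score[sl, None]
        # i is the (potential) earlier failure in pairs (i, j)
        usable = (e_i == 1) & (
            (t_i < time[None, :]) | ((t_i == time[None, :]) & (event[None, :] == 0))
        )
        usable[np.arange(sl.stop - sl.start), np.arange(sl.start, sl.stop)] = False
        win = usable & (s_i > score[None, :])
        tie = usable & (s_i == score[None, :])
        usable_i[sl] += usable.sum(axis=1)
        conc_i[sl] += win.sum(axis=1) + 0.5 * tie.sum(axis=1)
        # contributions to the later member j of each pair
        usable_i += usable.sum(axis=0)
        conc_i += win.sum(axis=0) + 0.5 * tie.sum(axis=0)
    return usable_i, conc_i


def harrell_c(
    score,
    survival: pd.DataFrame,
    ci_method: str = "jackknife",
    n_boot: int = 200,
    seed: int = 0,
) -> ConcordanceResult:
    """Harrell's concordance index for a risk score under censoring.

    Among usable pairs, the fraction in which the higher score fails first,
    with 0.5 credit for tied scores.  The 95% CI comes from a delete-one
    jackknife linearisation of the pair-ratio statistic (an asymptotic
    variance of the concordance U-statistic); ``ci_method="bootstrap"``
    resamples persons instead (seeded), for small cohorts.
    """
    score = np.asarray(score, dtype=float)
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    usable_i, conc_i = _pair_counts(score, time, event)
    U, W = usable_i.sum(), conc_i.sum()  # each pair counted twice; ratio unaffected
    if U == 0:
        raise ValueError("no usable pairs")
    c = W / U

    if ci_method == "jackknife":
        # pairs involving subject i are counted once in usable_i[i] but twice
        # in the doubled totals (once at each endpoint)
        denom = U - 2 * usable_i
        with np.errstate(invalid="ignore", divide="ignore"):
            c_loo = np.where(denom > 0, (W - 2 * conc_i) / denom, c)
        n = len(score)
        var = (n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)
        se = np.sqrt(var)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(score)
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            u_b, c_b = _pair_counts(score[idx], time[idx], event[idx])
            if u_b.sum() > 0:
                stats.append(c_b.sum() / u_b.sum())
        se = float(np.std(stats, ddof=1))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = max(0.0, c - _Z95 * se), min(1.0, c + _Z95 * se)
    return ConcordanceResult(float(c), (float(lo), float(hi)), int(U // 2), float(W / 2))


# -- continuous NRI ---------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NriResult:
    nri: float
    event_component: float
    nonevent_component: float
    ci: tuple[float, float]
    n_events: int
    n_nonevents: int


def nri(reference_risk, new_risk, event) -> NriResult:
    """Category-free Net Reclassification Improvement.

    event component    = P(new > ref | event) − P(new < ref | event)
    nonevent component = P(new < ref | non-event) − P(new > ref | non-event)
    NRI = sum of the two; each component lies in [−1, 1].  The 95% CI uses
    the standard asymptotic variance of the two net proportions.
    """
    ref = np.asarray(reference_risk, dtype=float)
    new = np.asarray(new_risk, dtype=float)
    ev = np.asarray(event, dtype=bool)
    if len(ref) != len(new) or len(ref) != len(ev):
        raise ValueError("inputs are not aligned")
    n_e, n_ne = int(ev.sum()), int((~ev).sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("NRI needs both events and non-events")

    up_e = float(np.mean(new[ev] > ref[ev]))
    dn_e = float(np.mean(new[ev] < ref[ev]))
    up_ne = float(np.mean(new[~ev] > ref[~ev]))
    dn_ne = float(np.mean(new[~ev] < ref[~ev]))
    event_comp = up_e - dn_e
    nonevent_comp = dn_ne - up_ne
    total = event_comp + nonevent_comp
    var = (up_e + dn_e - event_comp**2) / n_e + (up_ne + dn_ne - nonevent_comp**2) / n_ne
    se = np.sqrt(var)
    return NriResult(
        float(total),
        event_comp,
        nonevent_comp,
        (float(total - _Z95 * se), float(total + _Z95 * se)),
        n_e,
        n_ne,
    )


# -- readmission incidence-rate ratios -------------------------------------

def readmission_irr(
    counts: pd.Series,
    person_years: pd.Series,
    classes: pd.Series,
    age: pd.Series | None = None,
    sex_male: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-class readmission incidence rates and IRRs vs class 0.

    Fits a log-linear Poisson model for readmission counts with
    log(person-years) offset, class indicators and optional age/sex
    adjustment.  Returns one row per observed class with crude ``ir``
    (events / person-years) and model ``irr`` with 95% CI (class 0: 1.0).
    Classes with zero person-years are dropped with a warning.
    """
    df = pd.DataFrame(
        {"counts": counts, "py": person_years, "cls": classes}
    )
    bad = df["py"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} persons with zero person-years")
        df = df[~bad]
    if (df["cls"] == 0).sum() == 0 or df.loc[df["cls"] == 0, "py"].sum() <= 0:
        raise ValueError("reference class 0 has no person-years")

    present = sorted(df["cls"].unique())
    X = pd.DataFrame(index=df.index)
    for c in present:
        if c != 0:
            X[f"class_{c}"] = (df["cls"] == c).astype(float)
    if age is not None:
        X["age"] = age.reindex(df.index).astype(float)
    if sex_male is not None:
        X["male"] = sex_male.reindex(df.index).astype(float)
    X = sm.add_constant(X)
    model = sm.GLM(
        df["counts"].to_numpy(),
        X.to_numpy(),
        family=sm.families.Poisson(),
        offset=np.log(df["py"].to_numpy()),
    )
    res = model.fit()
    params = pd.Series(res.params, index=X.columns)
    ses = pd.Series(res.bse, index=X.columns)

    rows = []
    for c in present:
        ir = df.loc[df["cls"] == c, "counts"].sum() / df.loc[df["cls"] == c, "py"].sum()
        if c == 0:
            rows.append({"risk_class": c, "ir": ir, "irr": 1.0, "ci_low": np.nan, "ci_high": np.nan})
        else:
            b, s = params[f"class_{c}"], ses[f"class_{c}"]
            rows.append(
                {
                    "risk_class": c,
                    "ir": ir,
                    "irr": float(np.exp(b)),
                    "ci_low": float(np.exp(b - _Z95 * s)),
                    "ci_high": float(np.exp(b + _Z95 * s)),
                }
            )
    return pd.DataFrame(rows).set_index("risk_class")


# -- paired model comparison ------------------------------------------------

def _cox_horizon_risk(
    covariates: pd.DataFrame, survival: pd.DataFrame, horizon: float
) -> tuple[np.ndarray, np.ndarray, CoxPHFitter]:
    """Linear predictor and predicted risk 1 − S0(t)^exp(lp) at the horizon."""
    df = covariates.astype(float).copy()
    df["time"] = survival["time"].to_numpy()
    df["event"] = survival["event"].astype(int).to_numpy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    lp = covariates.astype(float).to_numpy() @ cph.params_[covariates.columns].to_numpy()
    surv_at_h = cph.predict_survival_function(
        covariates.astype(float), times=[horizon]
    ).to_numpy()[0]
    risk = 1.0 - surv_at_h
    return lp, risk, cph


@dataclasses.dataclass
class ComparisonResult:
    """Discrimination and reclassification of an augmented model vs a reference.

    ``c_reference`` / ``c_augmented`` are Harrell's C of the two linear
    predictors; ``nri_result`` compares predicted horizon risks, with
    persons censored before the horizon excluded from the NRI (documented
    limitation of the category-free NRI under censoring).
    """

    horizon: float
    c_reference: ConcordanceResult
    c_augmented: ConcordanceResult
    nri_result: NriResult
    n: int
    n_nri: int

    @property
    def delta_c(self) -> float:
        return self.c_augmented.c_index - self.c_reference.c_index

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(f"model comparison at horizon {self.horizon:g} y (n={self.n})\n")
        for label, c in (("reference", self.c_reference), ("augmented", self.c_augmented)):
            buf.write(
                f"  C {label}: {c.c_index:.3f} ({c.ci[0]:.3f}-{c.ci[1]:.3f})\n"
            )
        r = self.nri_result
        buf.write(
            f"  NRI: {r.nri:.3f} ({r.ci[0]:.3f}-{r.ci[1]:.3f}); "
            f"events {r.event_component:.4f}, non-events {r.nonevent_component:.4f} "
            f"(n={self.n_nri})\n"
        )
        return buf.getvalue()


class ModelComparison:
    """Reference Cox model (e.g. age + sex) vs an augmented one (+index).

    statsmodels-style: construct from aligned design frames and survival
    data, then ``fit(horizon)`` to obtain a :class:`ComparisonResult`.

    ``ipcw=True`` weights the NRI proportions by inverse probability of
    censoring (Kaplan–Meier of the censoring distribution); by default
    persons censored before the horizon are simply excluded.
    """

    def __init__(
        self,
        reference_covariates: pd.DataFrame,
        augmented_covariates: pd.DataFrame,
        survival: pd.DataFrame,
    ) -> None:
        if not (len(reference_covariates) == len(augmented_covariates) == len(survival)):
            raise ValueError("covariate frames and survival are not aligned")
        self.reference_covariates = reference_covariates
        self.augmented_covariates = augmented_covariates
        self.survival = survival

    def fit(self, horizon: float = 7.0, ipcw: bool = False) -> ComparisonResult:
        surv = self.survival.copy()
        # truncate follow-up at the horizon for the discrimination analysis
        over = surv["time"] > horizon
        surv.loc[over, "time"] = horizon
        surv.loc[over, "event"] = False

        lp_ref, risk_ref, _ = _cox_horizon_risk(self.reference_covariates, surv, horizon)
        lp_aug, risk_aug, _ = _cox_horizon_risk(self.augmented_covariates, surv, horizon)
        c_ref = harrell_c(lp_ref, surv)
        c_aug = harrell_c(lp_aug, surv)

        known = surv["event"] | (surv["time"] >= horizon)
        if ipcw:
            res_nri = _ipcw_nri(risk_ref, risk_aug, surv, horizon)
        else:
            ev = surv.loc[known, "event"].to_numpy(dtype=bool)
            res_nri = nri(risk_ref[known.to_numpy()], risk_aug[known.to_numpy()], ev)
        return ComparisonResult(
            horizon=horizon,
            c_reference=c_ref,
            c_augmented=c_aug,
            nri_result=res_nri,
            n=len(surv),
            n_nri=int(known.sum()),
        )


def _ipcw_nri(
    risk_ref: np.ndarray, risk_aug: np.ndarray, surv: pd.DataFrame, horizon: float
) -> NriResult:
    """NRI with inverse-probability-of-censoring weights.

    Events before the horizon are weighted by 1/G(t−), non-events known at
    the horizon by 1/G(horizon), with G the KM estimate of the censoring
    survival function.
    """
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=(~event).astype(int))
    G = kmf.survival_function_["KM_estimate"]

    grid = G.index.to_numpy()
    vals = G.to_numpy()

    def g_at(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(grid, t, side="right") - 1
        return np.maximum(np.where(idx >= 0, vals[np.clip(idx, 0, len(vals) - 1)], 1.0), 1e-10)

    is_event = event & (time <= horizon)
    is_nonevent = time >= horizon
    w = np.zeros(len(time))
    w[is_event] = 1.0 / g_at(time[is_event] - 1e-9)
    w[is_nonevent] = 1.0 / g_at(np.full(is_nonevent.sum(), horizon))

    def wmean(mask, cond):
        tot = w[mask].sum()
        return float((w[mask] * cond[mask]).sum() / tot) if tot > 0 else 0.0

    up = risk_aug > risk_ref
    dn = risk_aug < risk_ref
    event_comp = wmean(is_event, up) - wmean(is_event, dn)
    nonevent_comp = wmean(is_nonevent, dn) - wmean(is_nonevent, up)
    total = event_comp + nonevent_comp
    n_e, n_ne = int(is_event.sum()), int(is_nonevent.sum())
    up_e, dn_e = wmean(is_event, up), wmean(is_event, dn)
    up_ne, dn_ne = wmean(is_nonevent, up), wmean(is_nonevent, dn)
    var = (up_e + dn_e - event_comp**2) / max(n_e, 1) + (
        up_ne + dn_ne - nonevent_comp**2
    ) / max(n_ne, 1)
    se = np.sqrt(var)
    return NriResult(
        float(total), event_comp, nonevent_comp,
        (float(total - _Z95 * se), float(total + _Z95 * se)), n_e, n_ne,
    )


def compare_models(
    reference_covariates: pd.DataFrame,
    augmented_covariates: pd.DataFrame,
    survival: pd.DataFrame,
    horizon: float = 7.0,
    ipcw: bool = False,
) -> ComparisonResult:
    """Functional wrapper over :class:`ModelComparison`."""
    return ModelComparison(reference_covariates, augmented_covariates, survival).fit(
        horizon=horizon, ipcw=ipcw
    )
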