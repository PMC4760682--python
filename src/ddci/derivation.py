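"""Weight derivation: Cox regression of mortality on exposure flags.

The integer weights of the index are re-derived from data in three steps:

1. a multivariate Cox proportional-hazards fit of overall mortality on the
   19 drug-class exposure flags (Efron tie handling; optionally with age as
   an adjustment covariate),
2. a significance filter — classes whose Wald test does not reach
   ``alpha`` (default 0.05, two-sided) are excluded from the final model,
3. the Gagne-style conversion ``weight = round(coefficient / 0.3)`` with
   halves rounded away from zero.  Retained classes may legitimately carry
   weight 0; excluded classes are kept in the weight table with weight 0 so
   that downstream scoring sees a complete table, and are listed in the
   results as excluded.

The fit is exposed statsmodels-style: :class:`DdciWeightModel` is built
from data, ``fit()`` returns a :class:`DdciWeightResults` carrying the
coefficient table, the derived weights and a ``summary()``.
"""

from __future__ import annotations

import dataclasses
import io

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .reference import WEIGHT_DIVISOR, weight_from_coefficient
from .scoring import WeightTable

DEFAULT_ALPHA = 0.05


@dataclasses.dataclass
class CoxFitResult:
    """Per-covariate Cox estimates plus fit diagnostics.

    ``table`` has one row per covariate with columns
    ``coef`` (log hazard ratio), ``se``, ``hazard_ratio``, ``ci_low``,
    ``ci_high`` (95%, exp(coef ± 1.96 se)) and ``p`` (two-sided Wald).
    """

    table: pd.DataFrame
    converged: bool
    log_likelihood: float
    n: int
    n_events: int
    dropped: tuple[str, ...] = ()  # constant covariates removed before the fit


def fit_cox(covariates: pd.DataFrame, survival: pd.DataFrame) -> CoxFitResult:
    """Maximise the Cox partial likelihood (Efron ties) by Newton iteration.

    Parameters
    ----------
    covariates
        persons × covariates design frame (booleans are cast to int).
    survival
        aligned frame with ``time`` (years) and ``event`` columns.
    """
    if survival["event"].sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    X = covariates.astype(float)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    df = X.copy()
    df["time"] = survival["time"].to_numpy()
    df["event"] = survival["event"].astype(int).to_numpy()

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")

    z = 1.959963984540054
    table = pd.DataFrame(
        {
            "coef": cph.params_,
            "se": cph.standard_errors_,
            "hazard_ratio": np.exp(cph.params_),
            "ci_low": np.exp(cph.params_ - z * cph.standard_errors_),
            "ci_high": np.exp(cph.params_ + z * cph.standard_errors_),
            "p": cph.summary["p"],
        }
    )
    table.index.name = "covariate"
    return CoxFitResult(
        table=table,
        converged=True,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df["event"].sum()),
        dropped=tuple(constant),
    )


def derive_weights(
    fit: CoxFitResult,
    divisor: float = WEIGHT_DIVISOR,
    alpha: float = DEFAULT_ALPHA,
    exclude_covariates: tuple[str, ...] = (),
) -> tuple[WeightTable, list[str]]:
    """Integer weights from a Cox fit.

    Classes with Wald p ≥ ``alpha`` are excluded from the final model
    (their weight is recorded as 0); the rest get
    ``round(coef / divisor)``, halves away from zero.
    ``exclude_covariates`` names adjustment covariates (e.g. age) that are
    part of the fit but never weighted.

    Returns the weight table and the list of excluded class names.
    """
    weights: dict[str, int] = {}
    excluded: list[str] = []
    for name, row in fit.table.iterrows():
        if name in exclude_covariates:
            continue
        if row["p"] >= alpha:
            weights[name] = 0
            excluded.append(name)
        else:
            weights[name] = weight_from_coefficient(row["coef"], divisor)
    for name in fit.dropped:
        if name not in exclude_covariates:
            weights[name] = 0
            excluded.append(name)
    return WeightTable(weights), excluded


@dataclasses.dataclass
class WeightAgreement:
    """Per-class comparison of a derived weight table with a reference."""

    matches: dict[str, bool]
    derived: dict[str, int]
    reference: dict[str, int]

    @property
    def n_match(self) -> int:
        return sum(self.matches.values())

    @property
    def n_total(self) -> int:
        return len(self.matches)

    @property
    def mismatched(self) -> list[str]:
        return [k for k, ok in self.matches.items() if not ok]

    def to_text(self) -> str:
        lines = [f"weight agreement: {self.n_match}/{self.n_total}"]
        for name in self.mismatched:
            lines.append(
                f"  mismatch {name}: derived {self.derived[name]}, reference {self.reference[name]}"
            )
        return "\n".join(lines)


def compare_weight_tables(derived: WeightTable, reference: WeightTable) -> WeightAgreement:
    """Class-by-class agreement between two weight tables (same key sets)."""
    if set(derived.weights) != set(reference.weights):
        raise ValueError("weight tables have different key sets")
    matches = {k: derived.weights[k] == reference.weights[k] for k in reference.weights}
    return WeightAgreement(matches, dict(derived.weights), dict(reference.weights))


class DdciWeightModel:
    """Cox-based weight derivation model.

    Parameters
    ----------
    exposures
        persons × drug-class boolean frame (baseline flags).
    survival
        aligned frame with ``time`` and ``event``.
    adjustment
        optional frame of adjustment covariates (e.g. centred age) included
        in the fit but never converted to weights.

    Examples
    --------
    >>> model = DdciWeightModel(flags, surv, adjustment=age_frame)
    >>> res = model.fit()
    >>> res.weight_table.weights["Opioids"]
    """

    def __init__(
        self,
        exposures: pd.DataFrame,
        survival: pd.DataFrame,
        adjustment: pd.DataFrame | None = None,
    ) -> None:
        if len(exposures) != len(survival):
            raise ValueError("exposures and survival are not aligned")
        self.exposures = exposures
        self.survival = survival
        self.adjustment = adjustment

    def fit(
        self, divisor: float = WEIGHT_DIVISOR, alpha: float = DEFAULT_ALPHA
    ) -> "DdciWeightResults":
        design = self.exposures.astype(float)
        adj_names: tuple[str, ...] = ()
        if self.adjustment is not None:
            design = pd.concat([design, self.adjustment.astype(float)], axis=1)
            adj_names = tuple(self.adjustment.columns)
        fit = fit_cox(design, self.survival)
        weights, excluded = derive_weights(
            fit, divisor=divisor, alpha=alpha, exclude_covariates=adj_names
        )
        return DdciWeightResults(self, fit, weights, excluded, divisor, alpha)


@dataclasses.dataclass
class DdciWeightResults:
    """Fitted weight-derivation results.

    Attributes
    ----------
    fit
        the underlying :class:`CoxFitResult` (coefficients, SEs, HRs, p).
    weight_table
        derived integer weights (excluded classes carry weight 0).
    excluded
        classes dropped by the significance filter or constant in the data.
    """

    model: DdciWeightModel
    fit: CoxFitResult
    weight_table: WeightTable
    excluded: list[str]
    divisor: float
    alpha: float

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(
            f"DDCI weight derivation  (n={self.fit.n}, events={self.fit.n_events}, "
            f"divisor={self.divisor}, alpha={self.alpha})\n"
        )
        tab = self.fit.table.copy()
        tab["weight"] = [
            self.weight_table.weights.get(name, np.nan) for name in tab.index
        ]
        buf.write(tab.to_string(float_format=lambda v: f"{v:.4f}"))
        if self.excluded:
            buf.write(f"\nexcluded (p >= {self.alpha} or constant): {', '.join(self.excluded)}")
        return buf.getvalue()

    def agreement_with(self, reference: WeightTable) -> WeightAgreement:
        shared = {
            k: self.weight_table.weights.get(k, 0) for k in reference.weights
        }
        return compare_weight_tables(WeightTable(shared), reference)
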