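"""Published reference values for the Drug Derived Complexity Index (DDCI).

The DDCI was developed on a fixed cohort of ~2 million residents aged 40+
of an Italian region, by regressing overall mortality on 19 baseline
drug-exposure indicators in a multivariate Cox proportional-hazards model
and converting each regression coefficient to an integer weight
(``round(coefficient / 0.3)``, halves away from zero).

This module holds the published per-class Cox coefficients, hazard ratios,
integer weights, and the training-cohort exposure prevalences.  They are the
defaults used by the rule engine, the scorer and the synthetic-cohort
generator; every value can be overridden through configuration.
"""

from __future__ import annotations

import math

#: Canonical order of the 19 drug classes of the index.
DRUG_CLASSES: tuple[str, ...] = (
    "Antiarrhythmics",
    "Immunosuppressants",
    "Platelet aggregation inhibitors",
    "Parenteral anticoagulants",
    "Oral anticoagulants",
    "Antineoplastic agents",
    "Inhaled bronchodilators",
    "Drugs for arterial hypertension",
    "Antihyperglycemic therapy",
    "Drugs for hypertensive heart disease",
    "Drugs for acid related disorders",
    "Lipid modifying agents",
    "Nonsteroidal anti-inflammatory drugs",
    "Systemic corticosteroids",
    "Opioids",
    "Anti-Parkinson drugs",
    "Antipsychotics",
    "Anti-dementia drugs",
    "Antidepressants",
)

#: Published Cox log-hazard-ratio per drug class (overall mortality,
#: multivariate fit on the training half of the development cohort).
REFERENCE_COEFFICIENTS: dict[str, float] = {
    "Antiarrhythmics": 0.418,
    "Immunosuppressants": -0.368,
    "Platelet aggregation inhibitors": 0.532,
    "Parenteral anticoagulants": 0.435,
    "Oral anticoagulants": 0.368,
    "Antineoplastic agents": 0.880,
    "Inhaled bronchodilators": 0.739,
    "Drugs for arterial hypertension": 0.390,
    "Antihyperglycemic therapy": 0.530,
    "Drugs for hypertensive heart disease": 0.831,
    "Drugs for acid related disorders": 0.289,
    "Lipid modifying agents": -0.560,
    "Nonsteroidal anti-inflammatory drugs": 0.087,
    "Systemic corticosteroids": 0.464,
    "Opioids": 1.672,
    "Anti-Parkinson drugs": 1.108,
    "Antipsychotics": 0.841,
    "Anti-dementia drugs": 1.130,
    "Antidepressants": 0.087,
}

#: Published hazard ratios (2 decimals) for the same fit.
REFERENCE_HAZARD_RATIOS: dict[str, float] = {
    "Antiarrhythmics": 1.52,
    "Immunosuppressants": 0.69,
    "Platelet aggregation inhibitors": 1.70,
    "Parenteral anticoagulants": 1.55,
    "Oral anticoagulants": 1.45,
    "Antineoplastic agents": 2.41,
    "Inhaled bronchodilators": 2.09,
    "Drugs for arterial hypertension": 1.48,
    "Antihyperglycemic therapy": 1.70,
    "Drugs for hypertensive heart disease": 2.30,
    "Drugs for acid related disorders": 1.34,
    "Lipid modifying agents": 0.57,
    "Nonsteroidal anti-inflammatory drugs": 1.09,
    "Systemic corticosteroids": 1.59,
    "Opioids": 5.32,
    "Anti-Parkinson drugs": 3.03,
    "Antipsychotics": 2.32,
    "Anti-dementia drugs": 3.10,
    "Antidepressants": 1.09,
}

#: Published integer weights (coefficient / 0.3, rounded half away from zero).
REFERENCE_WEIGHTS: dict[str, int] = {
    "Antiarrhythmics": 1,
    "Immunosuppressants": -1,
    "Platelet aggregation inhibitors": 2,
    "Parenteral anticoagulants": 1,
    "Oral anticoagulants": 1,
    "Antineoplastic agents": 3,
    "Inhaled bronchodilators": 2,
    "Drugs for arterial hypertension": 1,
    "Antihyperglycemic therapy": 2,
    "Drugs for hypertensive heart disease": 3,
    "Drugs for acid related disorders": 1,
    "Lipid modifying agents": -2,
    "Nonsteroidal anti-inflammatory drugs": 0,
    "Systemic corticosteroids": 2,
    "Opioids": 6,
    "Anti-Parkinson drugs": 4,
    "Antipsychotics": 3,
    "Anti-dementia drugs": 4,
    "Antidepressants": 0,
}

#: Baseline exposure prevalence per class in the published training cohort
#: (fraction of persons whose dispensing history satisfied the class rule
#: in the year before the index date).
REFERENCE_PREVALENCES: dict[str, float] = {
    "Antiarrhythmics": 0.0103,
    "Immunosuppressants": 0.0019,
    "Platelet aggregation inhibitors": 0.0825,
    "Parenteral anticoagulants": 0.0065,
    "Oral anticoagulants": 0.0104,
    "Antineoplastic agents": 0.0122,
    "Inhaled bronchodilators": 0.0373,
    "Drugs for arterial hypertension": 0.2945,
    "Antihyperglycemic therapy": 0.0790,
    "Drugs for hypertensive heart disease": 0.0512,
    "Drugs for acid related disorders": 0.2028,
    "Lipid modifying agents": 0.0676,
    "Nonsteroidal anti-inflammatory drugs": 0.1795,
    "Systemic corticosteroids": 0.0160,
    "Opioids": 0.0005,
    "Anti-Parkinson drugs": 0.0067,
    "Antipsychotics": 0.0121,
    "Anti-dementia drugs": 0.0021,
    "Antidepressants": 0.0330,
}

#: Divisor of the Gagne-style coefficient-to-weight conversion.
WEIGHT_DIVISOR: float = 0.3


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; the weight rule
    needs the conventional half-up (for positives) / half-down (for
    negatives) behaviour, so it is fixed here once.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def weight_from_coefficient(coefficient: float, divisor: float = WEIGHT_DIVISOR) -> int:
    """Integer weight from a Cox log-hazard-ratio: round(c / divisor)."""
    return round_half_away_from_zero(coefficient / divisor)
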