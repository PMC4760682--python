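"""Drug Derived Complexity Index (DDCI).

A prescription-based comorbidity/complexity score: 19 drug-class exposure
rules evaluated on the year of pharmacy claims before an index date, each
class carrying an integer weight derived from a Cox regression of overall
mortality; the algebraic weight sum stratifies a population into 12 risk
classes.  The package bundles the rule engine, the scorer, Cox-based
weight re-derivation, a Charlson comparator, the discrimination /
reclassification evaluation battery, and a synthetic claims-cohort
generator.
"""

from .data_model import (
    Cohort,
    HospitalizationRecord,
    Person,
    PrescriptionRecord,
    SurvivalRecord,
    derive_survival,
    derive_survival_frame,
    read_cohort,
    write_cohort,
)
from .derivation import (
    CoxFitResult,
    DdciWeightModel,
    DdciWeightResults,
    compare_weight_tables,
    derive_weights,
    fit_cox,
)
from .evaluation import (
    ComparisonResult,
    ModelComparison,
    classwise_hazard_ratios,
    compare_models,
    harrell_c,
    km_estimate,
    nri,
    readmission_irr,
)
from .pipeline import PipelineConfig, run_pipeline, split_cohort
from .reference import (
    DRUG_CLASSES,
    REFERENCE_COEFFICIENTS,
    REFERENCE_HAZARD_RATIOS,
    REFERENCE_PREVALENCES,
    REFERENCE_WEIGHTS,
    weight_from_coefficient,
)
from .rules import (
    DrugClassRule,
    ExposureProfile,
    default_rule_table,
    detect_exposures,
    detect_exposures_frame,
    match_atc,
)
from .scoring import (
    DdciResult,
    WeightTable,
    assign_class,
    compute_cci,
    compute_cci_frame,
    compute_ddci,
    enumerate_scores,
    score_cohort,
)
from .simulate import SimulationConfig, make_worked_fixture, simulate, simulate_cohort

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
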