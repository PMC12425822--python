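"""pherskit: phenotype risk scores from longitudinal diagnosis codes.

Build phecode-based EHR risk scores under a windowed observation /
washout / prediction study design, transfer them across cohorts without
retraining, and evaluate them — alone and against an independent genetic
score — with Cox proportional-hazards models, concordance statistics and
random-effects meta-analysis.  A bundled synthetic multi-cohort generator
provides data with the assumed statistical structure.
"""

from importlib import resources

from .cohort import (
    Cohort,
    DiseaseDefinition,
    StudyDesign,
    apply_eligibility,
    build_cohort,
    build_feature_matrix,
    count_unique_phecodes,
    define_outcomes,
    pooled_vocabulary,
)
from .evaluation import (
    ComparisonResult,
    EffectEstimate,
    auprc,
    compare_effects,
    concordance_index,
    correlation,
    cox_model_cindex,
    fit_cox_per_sd,
    nagelkerke_r2,
    percentile_group_hr,
    residualize_score,
)
from .meta import MetaResult, dersimonian_laird_tau2, forest_table, meta_analyze_cindex, random_effects_meta
from .model import (
    HyperGrid,
    PheRS,
    SplitSpec,
    fit_phers,
    loo_importance,
    rank_coefficients,
    score_cohort,
    small_grid,
    split_cohort,
    transfer_score,
)
from .phecodes import (
    CodeSystem,
    IcdCode,
    Phecode,
    PhecodeMap,
    excluded_phecodes_for_disease,
    load_phecode_map,
    map_diagnoses,
    map_icd_to_phecode,
    mapping_report,
    normalize_icd,
    rollup_to_parent,
)
from .simulate import (
    GeneratorConfig,
    SyntheticDisease,
    disease_definitions,
    generate_carriage,
    generate_cohort_tables,
    generate_diagnosis_stream,
    generate_outcomes,
    generate_population,
    generate_study,
    make_cohort_pair,
    scenario_config,
    simulate_scored_survival,
    synthetic_phecode_map,
)

__version__ = "0.1.0"


def example_phecode_map() -> PhecodeMap:
    """The bundled worked-example phecode map (phewascatalog v1.2 dialect)."""
    path = resources.files("pherskit").joinpath("data/phecode_map_example.csv")
    with resources.as_file(path) as p:
        return load_phecode_map(p)
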