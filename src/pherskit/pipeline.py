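"""End-to-end experiment drivers.

These functions wire the pipeline stages together the way the study design
prescribes: map diagnoses to parent phecodes, build the windowed cohort,
drop disease-excluded predictors, split 50/42.5/7.5, fit the elastic-net
PheRS on the training split, score the untouched test split, residualize
on age and sex (plus PCs when a genetic score is involved) and evaluate
with Cox models, percentile contrasts and c-index comparisons.  They are
used both by the test-suite experiments and by the command-line tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, DiseaseDefinition, StudyDesign, build_cohort
from .evaluation import (
    EffectEstimate,
    compare_effects,
    concordance_index,
    correlation,
    cox_model_cindex,
    fit_cox_per_sd,
    percentile_group_hr,
    residualize_score,
)
from .model import HyperGrid, PheRS, SplitSpec, fit_phers, split_cohort, transfer_score
from .phecodes import PhecodeMap, excluded_phecodes_for_disease
from .simulate import (
    GeneratorConfig,
    SyntheticCohortTables,
    disease_definitions,
    generate_cohort_tables,
    make_cohort_pair,
    synthetic_phecode_map,
)


@dataclass
class TrainedPheRS:
    """A fitted PheRS with its cohort, splits and design matrix."""

    model: PheRS
    cohort: Cohort
    X: pd.DataFrame
    splits: dict[str, np.ndarray]

    def scores(self, part: str = "test") -> pd.Series:
        idx = self.splits[part]
        return pd.Series(self.model.decision_function(self.X.loc[idx]), index=idx, name="phers")


def assemble_cohort(
    tables: SyntheticCohortTables,
    cfg: GeneratorConfig,
    disease: DiseaseDefinition,
    pmap: PhecodeMap | None = None,
    vocabulary=None,
    name: str | None = None,
) -> Cohort:
    """Build an analysis cohort from synthetic per-cohort tables."""
    pmap = pmap or synthetic_phecode_map(cfg)
    return build_cohort(
        name=name or f"cohort{tables.cohort}",
        persons=tables.persons,
        diagnoses=tables.diagnoses,
        pmap=pmap,
        design=cfg.design,
        disease=disease,
        vocabulary=vocabulary,
    )


def train_phers_on_cohort(
    cohort: Cohort,
    disease: DiseaseDefinition,
    pmap: PhecodeMap,
    seed: int = 0,
    grid: HyperGrid | None = None,
    penalty: str = "elastic_net",
) -> TrainedPheRS:
    """Split the cohort and fit a PheRS on its training partition.

    Predictors inside the disease's phecode exclusion range are dropped
    before training; age and sex enter as ordinary predictors.
    """
    excluded = excluded_phecodes_for_disease(disease.disease_phecode, pmap, cohort.vocabulary)
    predictors = [p for p in cohort.vocabulary if p not in excluded]
    X = cohort.design_frame(predictors)
    events = cohort.outcome["event"].to_numpy()
    splits = split_cohort(X.index.to_numpy(), events, SplitSpec(seed=seed))
    y_train = cohort.outcome.loc[splits["train"], "event"]
    model = fit_phers(
        X.loc[splits["train"]], y_train, grid=grid, penalty=penalty, seed=seed,
        disease=disease.name, source_cohort=cohort.name,
    )
    return TrainedPheRS(model=model, cohort=cohort, X=X, splits=splits)


def evaluate_score(
    score: pd.Series,
    cohort: Cohort,
    covariate_cols: tuple[str, ...] = ("age", "sex"),
    label: str = "",
) -> dict[str, EffectEstimate]:
    """Residualize a score on the given covariates and evaluate it.

    Returns the per-SD Cox HR, the top-10%-vs-mid HR and the c-index of the
    residualized score on the supplied persons.
    """
    cov = cohort.covariates.loc[score.index, list(covariate_cols)]
    resid = residualize_score(score, cov)
    outcome = cohort.outcome.loc[score.index]
    return {
        "hr_per_sd": fit_cox_per_sd(resid, outcome, label=label),
        "hr_top10_vs_mid": percentile_group_hr(resid, outcome, label=label),
        "cindex": concordance_index(resid, outcome, label=label),
        "_residual": resid,
    }


def cindex_gain(
    cohort: Cohort,
    test_ids: np.ndarray,
    base_covariates: list[str],
    added: pd.Series,
    added_name: str = "phers",
):
    """c-index of a Cox model with and without an added score, plus the
    one-tailed z test of the increase."""
    outcome = cohort.outcome.loc[test_ids]
    base = cohort.covariates.loc[test_ids, base_covariates]
    c_base = cox_model_cindex(base, outcome, label="baseline")
    full = base.copy()
    full[added_name] = added.loc[test_ids].to_numpy()
    c_full = cox_model_cindex(full, outcome, label=f"baseline+{added_name}")
    comp = compare_effects(c_full, c_base, sidedness="one_tailed")
    return c_base, c_full, comp


# -- experiments -----------------------------------------------------------


def transfer_experiment(
    seed: int,
    grid: HyperGrid | None = None,
    overlap_fraction: float = 0.7,
    cfg: GeneratorConfig | None = None,
) -> dict:
    """Internal vs external PheRS on a synthetic cohort pair.

    Trains one PheRS in the source cohort and one in the target cohort,
    scores the *same* target test set with both (the external model is
    transferred without retraining), and compares the residualized per-SD
    hazard ratios.
    """
    from .simulate import scenario_config

    cfg = cfg or scenario_config("transfer", seed=seed)
    source, target, pair_cfg = make_cohort_pair(cfg, overlap_fraction=overlap_fraction)
    pmap = synthetic_phecode_map(pair_cfg)
    dz = disease_definitions(pair_cfg)[0]
    src = assemble_cohort(source, pair_cfg, dz, pmap, name="source")
    tgt = assemble_cohort(target, pair_cfg, dz, pmap, name="target")

    fit_src = train_phers_on_cohort(src, dz, pmap, seed=seed, grid=grid)
    fit_tgt = train_phers_on_cohort(tgt, dz, pmap, seed=seed, grid=grid)

    test_ids = fit_tgt.splits["test"]
    internal_score = fit_tgt.scores("test")
    external_score = transfer_score(fit_src.model, fit_tgt.X.loc[test_ids])

    internal = evaluate_score(internal_score, tgt, label="internal")
    external = evaluate_score(external_score, tgt, label="external")
    return {
        "internal": internal["hr_per_sd"],
        "external": external["hr_per_sd"],
        "internal_cindex": internal["cindex"],
        "external_cindex": external["cindex"],
        "score_correlation": correlation(
            internal_score, external_score.loc[internal_score.index],
        ),
        "source_model": fit_src.model,
        "target_model": fit_tgt.model,
        "vocabulary_overlap": len(set(src.vocabulary) & set(tgt.vocabulary))
        / max(len(set(src.vocabulary)), 1),
    }


def orthogonality_experiment(
    seed: int,
    grid: HyperGrid | None = None,
    cfg: GeneratorConfig | None = None,
) -> dict:
    """PheRS vs an independent genetic score on one synthetic cohort.

    Measures the partial correlation between the two scores (age, sex and
    ten PCs regressed out) and the c-index gain from adding the PheRS to a
    Cox model with PGS + age + sex.
    """
    from .simulate import scenario_config

    cfg = cfg or scenario_config("orthogonality", seed=seed)
    tables = generate_cohort_tables(cfg, 0)
    pmap = synthetic_phecode_map(cfg)
    dz = disease_definitions(cfg)[0]
    cohort = assemble_cohort(tables, cfg, dz, pmap)
    fit = train_phers_on_cohort(cohort, dz, pmap, seed=seed, grid=grid)

    test_ids = fit.splits["test"]
    phers = fit.scores("test")
    pgs = cohort.covariates.loc[test_ids, "pgs"]
    pc_cols = [f"pc{i}" for i in range(1, 11)]
    covs = cohort.covariates.loc[test_ids, ["age", "sex", *pc_cols]]

    r = correlation(phers, pgs, partial_covariates=covs, label="phers_vs_pgs")
    phers_resid = residualize_score(phers, covs)
    c_base, c_full, comp = cindex_gain(
        cohort, test_ids, ["pgs", "age", "sex"], phers_resid, added_name="phers",
    )
    return {
        "correlation": r,
        "cindex_base": c_base,
        "cindex_with_phers": c_full,
        "cindex_comparison": comp,
        "phers_hr_per_sd": fit_cox_per_sd(phers_resid, cohort.outcome.loc[test_ids]),
        "trained": fit,
    }
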