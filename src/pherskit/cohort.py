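"""Windowed cohort construction from longitudinal diagnosis streams.

The study design splits calendar time into an *observation period* (when
predictor diagnoses are collected), a *washout period* (a buffer during
which nothing is recorded, to limit reverse-causation leakage), and a
*prediction period* that starts at the *baseline* date.  Eligibility, age
and the survival outcome are all assessed at baseline: a person is a case
if their first qualifying diagnosis falls strictly inside the prediction
period, and is otherwise censored at end of follow-up or at the end of
the prediction period, whichever comes first.

Features are binary parent-phecode indicators restricted to the
observation window, filtered to a minimum prevalence (by default 1% in
any cohort of the study set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phecodes import PhecodeMap, map_diagnoses, normalize_icd

DAYS_PER_YEAR = 365.25


class DesignError(ValueError):
    """Study-design misconfiguration or a filter that empties the cohort."""


@dataclass(frozen=True)
class StudyDesign:
    """Observation / washout / prediction windows and age limits.

    All window bounds are closed calendar dates.  Age at baseline is
    computed in whole years.  The default layout is a 10-year observation
    window (1999-2008), a 2-year washout, a 2011-01-01 baseline and an
    8-year prediction period.
    """

    obs_start: pd.Timestamp = pd.Timestamp("1999-01-01")
    obs_end: pd.Timestamp = pd.Timestamp("2008-12-31")
    baseline: pd.Timestamp = pd.Timestamp("2011-01-01")
    pred_end: pd.Timestamp = pd.Timestamp("2018-12-31")
    washout_years: int = 2
    age_min: int = 32
    age_max: int = 70

    def __post_init__(self):
        for name in ("obs_start", "obs_end", "baseline", "pred_end"):
            object.__setattr__(self, name, pd.Timestamp(getattr(self, name)))
        if not (self.obs_start <= self.obs_end < self.baseline < self.pred_end):
            raise DesignError("windows must satisfy obs_start <= obs_end < baseline < pred_end")
        gap_years = (self.baseline - self.obs_end).days / DAYS_PER_YEAR
        if gap_years < self.washout_years - 0.05:
            raise DesignError(
                f"gap between obs_end and baseline ({gap_years:.2f}y) is shorter "
                f"than the washout ({self.washout_years}y)"
            )
        if self.age_min >= self.age_max:
            raise DesignError("age_min must be below age_max")

    @property
    def horizon_years(self) -> float:
        return (self.pred_end - self.baseline).days / DAYS_PER_YEAR


def short_observation_design(**overrides) -> StudyDesign:
    """A 6-year observation preset for cohorts with shorter register coverage."""
    kwargs = dict(obs_start=pd.Timestamp("2003-01-01"))
    kwargs.update(overrides)
    return StudyDesign(**kwargs)


@dataclass(frozen=True)
class DiseaseDefinition:
    """Case definition: ICD prefixes that identify a case, plus metadata.

    ``case_icd_codes`` are matched as normalized prefixes against
    normalized diagnosis codes.  ``disease_phecode`` anchors the
    predictor exclusion range.  ``sex_restriction`` limits the cohort to
    one sex (e.g. prostate cancer: male; breast cancer: female).
    """

    name: str
    case_icd_codes: frozenset[str]
    disease_phecode: str
    sex_restriction: str = "none"  # none | female | male

    def __post_init__(self):
        if not self.case_icd_codes:
            raise DesignError(f"disease {self.name!r} has an empty case code set")
        object.__setattr__(
            self, "case_icd_codes",
            frozenset(normalize_icd(c) for c in self.case_icd_codes),
        )
        if self.sex_restriction not in ("none", "female", "male"):
            raise DesignError(f"invalid sex_restriction {self.sex_restriction!r}")

    def is_case_code(self, code: str) -> bool:
        norm = normalize_icd(code)
        return any(norm.startswith(p) for p in self.case_icd_codes)


@dataclass
class Cohort:
    """Assembled analysis cohort.

    ``features`` is a person x parent-phecode 0/1 matrix over ``vocabulary``;
    ``covariates`` carries age at baseline (whole years), sex (0 = female,
    1 = male), optional pgs / pc1..pc10 and the unique-phecode count;
    ``outcome`` has ``time_years`` (> 0) and ``event`` (0/1).
    All three frames share the person_id index.
    """

    name: str
    persons: pd.DataFrame
    features: pd.DataFrame
    covariates: pd.DataFrame
    outcome: pd.DataFrame
    vocabulary: list[str]
    exclusion_tally: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)

    def design_frame(self, predictors: Sequence[str] | None = None) -> pd.DataFrame:
        """Features plus age/sex columns, the PheRS training design matrix."""
        cols = list(predictors) if predictors is not None else list(self.vocabulary)
        X = self.features.reindex(columns=cols).astype(float)
        X["age"] = self.covariates["age"].astype(float)
        X["sex"] = self.covariates["sex"].astype(float)
        return X


def age_at(birth_date: pd.Series, when: pd.Timestamp) -> pd.Series:
    """Age in whole years at a reference date."""
    birth = pd.to_datetime(birth_date)
    had_birthday = (birth.dt.month < when.month) | (
        (birth.dt.month == when.month) & (birth.dt.day <= when.day)
    )
    return (when.year - birth.dt.year - (~had_birthday).astype(int)).astype(int)


def first_case_dates(diagnoses: pd.DataFrame, disease: DiseaseDefinition) -> pd.Series:
    """First date on which each person carries a case-defining code."""
    norm = diagnoses["code"].map(normalize_icd)
    is_case = norm.map(disease.is_case_code)
    cases = diagnoses.loc[is_case.to_numpy()]
    if cases.empty:
        return pd.Series(dtype="datetime64[ns]", name="first_case_date")
    return (
        pd.to_datetime(cases["date"]).groupby(cases["person_id"]).min()
        .rename("first_case_date")
    )


def apply_eligibility(
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    disease: DiseaseDefinition,
    design: StudyDesign,
    drop_cases_after_pred_end: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter persons to the eligible cohort; return it with an exclusion tally.

    Exclusion reasons are assessed in a fixed order (age, sex restriction,
    lost to follow-up before baseline, prevalent case, case after the
    prediction period) so the tally counts partition the removed persons.
    """
    df = persons.copy()
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["followup_end"] = pd.to_datetime(df["followup_end"])
    df["age_at_baseline"] = age_at(df["birth_date"], design.baseline)
    first_case = first_case_dates(diagnoses, disease)
    df = df.join(first_case, on="person_id") if "person_id" in df.columns else df
    if "first_case_date" not in df.columns:
        df["first_case_date"] = pd.NaT

    tally = {"age": 0, "sex_restriction": 0, "lost_to_followup": 0,
             "prevalent_case": 0, "case_after_prediction_period": 0}
    keep = pd.Series(True, index=df.index)

    bad_age = (df["age_at_baseline"] < design.age_min) | (df["age_at_baseline"] > design.age_max)
    tally["age"] = int(bad_age.sum())
    keep &= ~bad_age

    if disease.sex_restriction != "none":
        bad_sex = keep & (df["sex"] != disease.sex_restriction)
        tally["sex_restriction"] = int(bad_sex.sum())
        keep &= ~bad_sex

    lost = keep & (df["followup_end"] < design.baseline)
    tally["lost_to_followup"] = int(lost.sum())
    keep &= ~lost

    prevalent = keep & df["first_case_date"].notna() & (df["first_case_date"] <= design.baseline)
    tally["prevalent_case"] = int(prevalent.sum())
    keep &= ~prevalent

    if drop_cases_after_pred_end:
        late = keep & df["first_case_date"].notna() & (df["first_case_date"] > design.pred_end)
        tally["case_after_prediction_period"] = int(late.sum())
        keep &= ~late

    out = df.loc[keep].copy()
    if out.empty:
        binding = max(tally, key=tally.get)
        raise DesignError(f"eligibility filtering removed every person (largest filter: {binding})")
    return out, tally


def define_outcomes(
    eligible: pd.DataFrame,
    design: StudyDesign,
) -> pd.DataFrame:
    """(time_years, event) per eligible person.

    Cases: time from baseline to the first case diagnosis inside
    (baseline, pred_end].  Controls: censored at min(followup_end, pred_end).
    Durations are day counts divided by 365.25.
    """
    fc = eligible["first_case_date"]
    if (fc.notna() & (fc <= design.baseline)).any():
        raise DesignError("prevalent case reached outcome definition; run apply_eligibility first")
    event = (fc.notna() & (fc <= design.pred_end)).astype(int)
    end = pd.to_datetime(eligible["followup_end"]).clip(upper=design.pred_end)
    end_date = fc.where(event.astype(bool), end)
    time_years = (end_date - design.baseline).dt.days / DAYS_PER_YEAR
    if (time_years <= 0).any():
        raise DesignError("non-positive survival time; check followup_end >= baseline")
    out = pd.DataFrame({"time_years": time_years, "event": event})
    out.index = eligible["person_id"].to_numpy() if "person_id" in eligible.columns else eligible.index
    return out


def phecode_prevalences(
    persons: pd.DataFrame,
    mapped_diagnoses: pd.DataFrame,
    design: StudyDesign,
) -> pd.Series:
    """Observation-window prevalence of each parent phecode in a person set."""
    carriage = _observation_carriage(persons, mapped_diagnoses, design)
    n = len(persons)
    return carriage.groupby("parent")["person_id"].nunique() / n


def pooled_vocabulary(
    prevalences: Mapping[str, pd.Series],
    min_prevalence: float = 0.01,
) -> list[str]:
    """Parent phecodes reaching ``min_prevalence`` in at least one cohort."""
    vocab: set[str] = set()
    for prev in prevalences.values():
        vocab |= set(prev.index[prev >= min_prevalence])
    return sorted(vocab)


def _observation_carriage(persons, mapped_diagnoses, design) -> pd.DataFrame:
    ids = set(persons["person_id"])
    d = mapped_diagnoses
    dates = pd.to_datetime(d["date"])
    in_window = (dates >= design.obs_start) & (dates <= design.obs_end)
    return d.loc[in_window & d["person_id"].isin(ids), ["person_id", "parent"]]


def build_feature_matrix(
    persons: pd.DataFrame,
    mapped_diagnoses: pd.DataFrame,
    design: StudyDesign,
    min_prevalence: float = 0.01,
    vocabulary: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary person x parent-phecode matrix over the observation window.

    A cell is 1 iff the person has at least one diagnosis with that parent
    phecode dated inside [obs_start, obs_end]; washout- and
    prediction-period records never contribute.  When ``vocabulary`` is not
    supplied, it is the set of parents reaching ``min_prevalence`` in this
    person set (for multi-cohort studies, compute the pooled vocabulary with
    :func:`pooled_vocabulary` and pass it in).
    """
    carriage = _observation_carriage(persons, mapped_diagnoses, design)
    mat = (
        carriage.assign(v=1)
        .pivot_table(index="person_id", columns="parent", values="v", aggfunc="max", fill_value=0)
    )
    mat = mat.reindex(index=persons["person_id"], fill_value=0)
    if vocabulary is None:
        prev = mat.mean(axis=0)
        vocabulary = sorted(prev.index[prev >= min_prevalence])
    if len(vocabulary) == 0:
        raise DesignError("empty predictor vocabulary: no phecode reaches the prevalence threshold")
    mat = mat.reindex(columns=list(vocabulary), fill_value=0).astype("int8")
    mat.index.name = "person_id"
    return mat


def count_unique_phecodes(features: pd.DataFrame) -> pd.Series:
    """Number of distinct parent phecodes per person (pre-exclusion row sum)."""
    return features.sum(axis=1).astype(int).rename("n_unique_phecodes")


def build_cohort(
    name: str,
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    pmap: PhecodeMap,
    design: StudyDesign,
    disease: DiseaseDefinition,
    min_prevalence: float = 0.01,
    vocabulary: Sequence[str] | None = None,
    drop_cases_after_pred_end: bool = True,
) -> Cohort:
    """End-to-end cohort assembly: eligibility, outcome, features, covariates."""
    eligible, tally = apply_eligibility(
        persons, diagnoses, disease, design,
        drop_cases_after_pred_end=drop_cases_after_pred_end,
    )
    outcome = define_outcomes(eligible, design)
    mapped = map_diagnoses(diagnoses, pmap)
    features = build_feature_matrix(
        eligible, mapped, design,
        min_prevalence=min_prevalence, vocabulary=vocabulary,
    )
    cov = pd.DataFrame(index=features.index)
    eligible_idx = eligible.set_index("person_id")
    cov["age"] = eligible_idx["age_at_baseline"]
    cov["sex"] = (eligible_idx["sex"] == "male").astype(int)
    for col in ["pgs"] + [f"pc{i}" for i in range(1, 11)]:
        if col in eligible_idx.columns:
            cov[col] = eligible_idx[col].astype(float)
    cov["n_unique_phecodes"] = count_unique_phecodes(features)
    return Cohort(
        name=name,
        persons=eligible,
        features=features,
        covariates=cov,
        outcome=outcome.reindex(features.index),
        vocabulary=list(features.columns),
        exclusion_tally=tally,
    )
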