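"""Synthetic multi-cohort longitudinal EHR generator.

Emulates the statistical structure the PheRS pipeline assumes, so every
stage — mapping, windowed cohort construction, model training, transfer,
evaluation and meta-analysis — runs without access-protected data:

* persons with uniform ages (32-70 at baseline), Bernoulli(0.5) sex, a
  standard-normal genetic score (PGS) independent of the diagnosis
  channel, and ten standard-normal nuisance PCs;
* parent-phecode *carriage* from a logistic latent-factor model
  (logit prevalence = phecode base + cohort shift + loadings x factors +
  age and sex terms) inducing correlated comorbidities and
  cohort-specific prevalence shifts;
* carried phecodes emitted as 1-5 dated ICD-10-style records inside the
  observation window through cohort-specific *dialect maps* (parent-level
  spellings, child-level spellings or cohort-unique codes), plus
  distractor records in the washout/prediction windows to expose any
  feature leakage;
* proportional-hazards disease onset: liability = gamma x carriage +
  age + sex + PGS terms, exponential onset times, administrative
  censoring at the prediction horizon and random early censoring, and a
  configurable rate of prevalent (pre-baseline) cases to exercise the
  eligibility filters.

The generative truth (liabilities, causal effects) is returned alongside
the tables for parameter-recovery tests; the pipeline itself never sees it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import DiseaseDefinition, StudyDesign
from .phecodes import PhecodeMap, load_phecode_map

BASELINE = pd.Timestamp("2011-01-01")


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticDisease:
    """Generative definition of one synthetic disease."""

    name: str
    phecode: str            # disease phecode anchoring the exclusion range
    icd_code: str           # case-defining ICD spelling
    causal_parents: tuple[str, ...]
    gamma: float = 0.8      # log-HR per carried causal phecode
    age_effect: float = 0.03   # per year of age, centered
    sex_effect: float = 0.3    # male vs female
    pgs_effect: float = 0.0    # log-HR per SD of the PGS channel
    baseline_hazard: float = 0.01   # events / person-year at mean liability
    prevalent_rate: float = 0.03    # fraction with a pre-baseline diagnosis

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise GeneratorError("baseline hazard must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    The defaults are the "small" scenario: 3 cohorts x 5,000 persons,
    60 parent phecodes, 3 comorbidity factors and 2 diseases, sized to run
    the full pipeline in minutes.
    """

    seed: int = 0
    n_cohorts: int = 3
    n_persons: int = 5_000
    n_phecodes: int = 60
    n_factors: int = 3
    loading_scale: float = 0.8
    prevalence_range: tuple[float, float] = (0.02, 0.25)
    prevalence_shift_sd: float = 0.5   # per-cohort logit shifts (coding practice)
    carriage_age_effect: float = 0.02  # logit per year of age, centered at 51
    carriage_sex_effect: float = 0.1
    age_range: tuple[int, int] = (32, 70)
    censoring_rate: float = 0.1
    distractor_rate: float = 0.3
    late_case_window_years: float = 1.0
    suppressed_parents: Mapping[int, frozenset[str]] = field(default_factory=dict)
    diseases: tuple[SyntheticDisease, ...] = ()
    design: StudyDesign = field(default_factory=StudyDesign)

    def __post_init__(self):
        lo, hi = self.prevalence_range
        if not (0 < lo <= hi < 1):
            raise GeneratorError("prevalence range must lie in (0, 1)")
        if not self.diseases:
            object.__setattr__(self, "diseases", default_diseases(self))
        for dz in self.diseases:
            missing = set(dz.causal_parents) - set(self.parents)
            if missing:
                raise GeneratorError(f"causal parents outside the phecode universe: {missing}")

    @property
    def parents(self) -> list[str]:
        return [str(101 + j) for j in range(self.n_phecodes)]

    @property
    def excluded_parents(self) -> list[str]:
        """The last two parents sit inside every disease's exclusion range."""
        return self.parents[-2:]


def default_diseases(cfg: GeneratorConfig, n_diseases: int = 2) -> tuple[SyntheticDisease, ...]:
    """Two diseases with disjoint causal phecode sets (never the excluded parents)."""
    rng = np.random.default_rng([cfg.seed, 901])
    eligible = [p for p in cfg.parents if p not in cfg.excluded_parents]
    picks = rng.choice(len(eligible), size=min(10, len(eligible)), replace=False)
    half = len(picks) // n_diseases
    out = []
    for d in range(n_diseases):
        causal = tuple(eligible[i] for i in sorted(picks[d * half:(d + 1) * half]))
        out.append(SyntheticDisease(
            name=f"disease_{d + 1}",
            phecode=f"9{d + 1:02d}.1",
            icd_code=f"DZ{d + 1:02d}",
            causal_parents=causal,
            gamma=0.5,
        ))
    return tuple(out)


# -- dialect maps and the synthetic phecode map ----------------------------


def dialect_spellings(cfg: GeneratorConfig, cohort: int) -> dict[str, list[str]]:
    """ICD spellings each cohort uses per parent phecode.

    Style rotates with the cohort index: parent-level codes, child-level
    codes, or a mix of the shared parent code and a cohort-unique code.
    Explicit tables (not stochastic) so vocabulary overlap is exact.
    """
    style = cohort % 3
    out: dict[str, list[str]] = {}
    for p in cfg.parents:
        if style == 0:
            out[p] = [f"P{p}", f"P{p}X"]  # the X variant needs truncation to map
        elif style == 1:
            out[p] = [f"C{p}1", f"C{p}2"]
        else:
            out[p] = [f"P{p}", f"U{cohort}{p}"]
    return out


def map_dataframe(cfg: GeneratorConfig) -> pd.DataFrame:
    """The synthetic phecode map as a phewascatalog-v1.2-style table."""
    rows = []
    for p in cfg.parents:
        rows.append({"icd": f"P{p}", "phecode": p, "exclude_range": ""})
        rows.append({"icd": f"C{p}1", "phecode": f"{p}.1", "exclude_range": ""})
        rows.append({"icd": f"C{p}2", "phecode": f"{p}.2", "exclude_range": ""})
        for c in range(cfg.n_cohorts):
            if c % 3 == 2:
                rows.append({"icd": f"U{c}{p}", "phecode": f"{p}.3", "exclude_range": ""})
    lo, hi = cfg.excluded_parents
    excl = f"{lo}-{float(hi) + 0.99:.2f}"
    for dz in cfg.diseases:
        rows.append({"icd": dz.icd_code, "phecode": dz.phecode, "exclude_range": excl})
    return pd.DataFrame(rows)


def synthetic_phecode_map(cfg: GeneratorConfig) -> PhecodeMap:
    buf = io.StringIO()
    map_dataframe(cfg).to_csv(buf, index=False)
    buf.seek(0)
    return load_phecode_map(buf)


def disease_definitions(cfg: GeneratorConfig) -> list[DiseaseDefinition]:
    return [
        DiseaseDefinition(name=dz.name, case_icd_codes=frozenset({dz.icd_code}),
                          disease_phecode=dz.phecode)
        for dz in cfg.diseases
    ]


# -- structural parameters (deterministic in cfg.seed) ---------------------


def _structure(cfg: GeneratorConfig):
    rng = np.random.default_rng([cfg.seed, 11])
    lo, hi = cfg.prevalence_range
    logit = lambda p: np.log(p / (1 - p))
    base = rng.uniform(logit(lo), logit(hi), size=cfg.n_phecodes)
    loadings = rng.normal(0.0, cfg.loading_scale, size=(cfg.n_phecodes, cfg.n_factors))
    shifts = rng.normal(0.0, cfg.prevalence_shift_sd, size=(cfg.n_cohorts, cfg.n_phecodes))
    return base, loadings, shifts


# -- operations ------------------------------------------------------------


def generate_population(cfg: GeneratorConfig, cohort: int = 0) -> pd.DataFrame:
    """Person table for one cohort: demographics, follow-up, PGS and PCs."""
    import warnings

    if cfg.n_persons < 100:
        warnings.warn("n_persons < 100: downstream model fits will be unstable")
    rng = np.random.default_rng([cfg.seed, 23, cohort])
    n = cfg.n_persons
    design = cfg.design
    age = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n)
    birth_offset = rng.integers(0, 330, size=n)
    birth = pd.to_datetime({
        "year": design.baseline.year - age, "month": 1, "day": 1,
    }) - pd.to_timedelta(birth_offset, unit="D")
    followup_end = np.full(n, design.pred_end, dtype="datetime64[ns]")
    early = rng.random(n) < cfg.censoring_rate
    horizon_days = (design.pred_end - design.baseline).days
    early_days = rng.integers(30, horizon_days, size=n)
    followup_end[early] = (design.baseline + pd.to_timedelta(early_days, unit="D")).to_numpy()[early]
    df = pd.DataFrame({
        "person_id": [f"c{cohort}_{i}" for i in range(n)],
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "birth_date": birth,
        "followup_end": followup_end,
        "pgs": rng.normal(size=n),
    })
    for i in range(1, 11):
        df[f"pc{i}"] = rng.normal(size=n)
    df["_age"] = age  # convenience; the pipeline recomputes from birth_date
    df["_factors"] = list(rng.normal(size=(n, cfg.n_factors)))
    return df


def generate_carriage(cfg: GeneratorConfig, persons: pd.DataFrame, cohort: int = 0) -> pd.DataFrame:
    """Binary parent-phecode carriage from the logistic factor model."""
    rng = np.random.default_rng([cfg.seed, 37, cohort])
    base, loadings, shifts = _structure(cfg)
    F = np.stack(persons["_factors"].to_numpy())
    age = persons["_age"].to_numpy()
    sex = (persons["sex"] == "male").to_numpy().astype(float)
    logits = (
        base[None, :]
        + shifts[cohort][None, :]
        + F @ loadings.T
        + cfg.carriage_age_effect * (age - 51.0)[:, None]
        + cfg.carriage_sex_effect * sex[:, None]
    )
    suppressed = cfg.suppressed_parents.get(cohort, frozenset())
    parents = cfg.parents
    prob = 1.0 / (1.0 + np.exp(-logits))
    for j, p in enumerate(parents):
        if p in suppressed:
            prob[:, j] = 0.0
    X = (rng.random(prob.shape) < prob).astype(np.int8)
    return pd.DataFrame(X, index=persons["person_id"].to_numpy(), columns=parents)


def generate_outcomes(
    cfg: GeneratorConfig,
    persons: pd.DataFrame,
    carriage: pd.DataFrame,
    disease: SyntheticDisease,
    cohort: int = 0,
) -> pd.DataFrame:
    """Proportional-hazards onset per person for one disease.

    Returns the generative truth: liability, exponential onset time (years
    from baseline; inf = never), prevalent-case flag.  Liability is centered
    so the baseline hazard applies at the cohort mean.
    """
    rng = np.random.default_rng([cfg.seed, 53, cohort, _disease_salt(disease)])
    age = persons["_age"].to_numpy().astype(float)
    sex = (persons["sex"] == "male").to_numpy().astype(float)
    pgs = persons["pgs"].to_numpy()
    gamma = pd.Series(0.0, index=carriage.columns)
    gamma.loc[list(disease.causal_parents)] = disease.gamma
    liability = (
        carriage.to_numpy() @ gamma.to_numpy()
        + disease.age_effect * (age - 51.0)
        + disease.sex_effect * sex
        + disease.pgs_effect * pgs
    )
    centered = liability - liability.mean()
    hazard = disease.baseline_hazard * np.exp(centered)
    onset = rng.exponential(1.0 / hazard)
    prevalent = rng.random(len(persons)) < disease.prevalent_rate
    return pd.DataFrame({
        "person_id": persons["person_id"].to_numpy(),
        "liability": liability,
        "onset_years": onset,
        "prevalent": prevalent,
    })


def _disease_salt(disease: SyntheticDisease) -> int:
    return sum(ord(ch) for ch in disease.name) % (2**16)


def generate_diagnosis_stream(
    cfg: GeneratorConfig,
    persons: pd.DataFrame,
    carriage: pd.DataFrame,
    outcomes: Mapping[str, pd.DataFrame],
    cohort: int = 0,
) -> pd.DataFrame:
    """Long diagnosis table: predictor records, distractors and case codes.

    Predictor records (1-5 per carried phecode) land in the observation
    window using the cohort dialect; distractor records land in the washout
    and prediction windows; disease case codes are dated at onset (or
    pre-baseline for prevalent cases).
    """
    rng = np.random.default_rng([cfg.seed, 71, cohort])
    design = cfg.design
    spell = dialect_spellings(cfg, cohort)
    for p in carriage.columns:
        if p not in spell:
            raise GeneratorError(f"dialect map missing phecode {p}")
    obs_days = (design.obs_end - design.obs_start).days

    pid_arr = carriage.index.to_numpy()
    rows_p, rows_d, rows_c = [], [], []

    pi, ji = np.nonzero(carriage.to_numpy())
    counts = rng.integers(1, 6, size=len(pi))
    rep_p = np.repeat(pi, counts)
    rep_j = np.repeat(ji, counts)
    dates = design.obs_start + pd.to_timedelta(rng.integers(0, obs_days + 1, size=len(rep_p)), unit="D")
    spell_arr = np.array([spell[p] for p in carriage.columns], dtype=object)
    which = rng.integers(0, 2, size=len(rep_p))
    codes = np.array([spell_arr[j][w % len(spell_arr[j])] for j, w in zip(rep_j, which)], dtype=object)
    rows_p.append(pd.DataFrame({
        "person_id": pid_arr[rep_p], "date": dates, "code_system": "ICD10",
        "code": codes, "source": "observation",
    }))

    # distractors: records dated in the washout / prediction windows only
    n = len(pid_arr)
    has_distractor = rng.random(n) < cfg.distractor_rate
    d_idx = np.flatnonzero(has_distractor)
    if len(d_idx):
        washout_days = (design.baseline - design.obs_end).days - 1
        pred_days = (design.pred_end - design.baseline).days
        in_washout = rng.random(len(d_idx)) < 0.5
        offs_w = rng.integers(1, washout_days + 1, size=len(d_idx))
        offs_p = rng.integers(1, pred_days + 1, size=len(d_idx))
        d_dates = np.where(
            in_washout,
            (design.obs_end + pd.to_timedelta(offs_w, unit="D")).to_numpy(),
            (design.baseline + pd.to_timedelta(offs_p, unit="D")).to_numpy(),
        )
        d_parents = rng.integers(0, cfg.n_phecodes, size=len(d_idx))
        d_codes = np.array([spell_arr[j][0] for j in d_parents], dtype=object)
        rows_d.append(pd.DataFrame({
            "person_id": pid_arr[d_idx], "date": d_dates, "code_system": "ICD10",
            "code": d_codes, "source": "distractor",
        }))

    horizon = design.horizon_years
    for dz in cfg.diseases:
        out = outcomes[dz.name].set_index("person_id").reindex(pid_arr)
        followup_years = (
            (pd.to_datetime(persons.set_index("person_id")["followup_end"]).reindex(pid_arr)
             - design.baseline).dt.days / 365.25
        ).to_numpy()
        onset = out["onset_years"].to_numpy()
        recordable = onset <= np.minimum(followup_years, horizon + cfg.late_case_window_years)
        prevalent = out["prevalent"].to_numpy()
        max_years = horizon + cfg.late_case_window_years  # later onsets are never emitted
        onset_dates = design.baseline + pd.to_timedelta(
            np.ceil(np.clip(onset, 0.0027, max_years) * 365.25), unit="D"
        )
        prev_dates = design.obs_start + pd.to_timedelta(
            rng.integers(0, obs_days + 1, size=len(pid_arr)), unit="D"
        )
        emit = recordable | prevalent
        case_dates = np.where(prevalent, prev_dates.to_numpy(), onset_dates.to_numpy())
        rows_c.append(pd.DataFrame({
            "person_id": pid_arr[emit], "date": case_dates[emit], "code_system": "ICD10",
            "code": dz.icd_code, "source": "case",
        }))

    df = pd.concat(rows_p + rows_d + rows_c, ignore_index=True)
    df["date"] = pd.to_datetime(df["date"])
    return df.sort_values(["person_id", "date"], kind="stable").reset_index(drop=True)


@dataclass
class SyntheticCohortTables:
    """Everything the pipeline ingests for one cohort, plus the truth."""

    cohort: int
    persons: pd.DataFrame        # pipeline input (truth columns stripped)
    diagnoses: pd.DataFrame
    truth_liability: dict[str, pd.Series]     # disease -> per-person liability
    truth_carriage: pd.DataFrame
    truth_effects: dict[str, pd.Series]       # disease -> gamma per parent


def generate_cohort_tables(cfg: GeneratorConfig, cohort: int = 0) -> SyntheticCohortTables:
    """Generate one cohort end to end (population, carriage, outcomes, stream)."""
    persons = generate_population(cfg, cohort)
    carriage = generate_carriage(cfg, persons, cohort)
    outcomes = {dz.name: generate_outcomes(cfg, persons, carriage, dz, cohort)
                for dz in cfg.diseases}
    diagnoses = generate_diagnosis_stream(cfg, persons, carriage, outcomes, cohort)
    truth_liab = {
        name: pd.Series(df["liability"].to_numpy(), index=df["person_id"].to_numpy())
        for name, df in outcomes.items()
    }
    effects = {}
    for dz in cfg.diseases:
        g = pd.Series(0.0, index=carriage.columns)
        g.loc[list(dz.causal_parents)] = dz.gamma
        effects[dz.name] = g
    public = persons.drop(columns=["_age", "_factors"])
    return SyntheticCohortTables(
        cohort=cohort, persons=public, diagnoses=diagnoses,
        truth_liability=truth_liab, truth_carriage=carriage, truth_effects=effects,
    )


def generate_study(cfg: GeneratorConfig) -> list[SyntheticCohortTables]:
    """All cohorts of the configured study set."""
    return [generate_cohort_tables(cfg, c) for c in range(cfg.n_cohorts)]


def make_cohort_pair(
    cfg: GeneratorConfig,
    overlap_fraction: float = 0.7,
) -> tuple[SyntheticCohortTables, SyntheticCohortTables, GeneratorConfig]:
    """A source/target cohort pair sharing disease effects.

    The two cohorts use different coding dialects and base-prevalence
    shifts; additionally, a seeded random (1 - overlap_fraction) share of
    the phecode universe is suppressed (prevalence exactly 0), half of it
    in the source and half in the target, so each cohort also has codes
    the other never records — the mechanism that penalizes a transferred
    model relative to an internally trained one — while the shared
    vocabulary is exactly ``overlap_fraction`` of the universe.
    """
    rng = np.random.default_rng([cfg.seed, 97])
    parents = cfg.parents
    n_drop = int(round((1.0 - overlap_fraction) * len(parents)))
    dropped = rng.choice(parents, size=n_drop, replace=False).tolist()
    half = n_drop // 2
    pair_cfg = replace(
        cfg,
        n_cohorts=max(cfg.n_cohorts, 2),
        suppressed_parents={0: frozenset(dropped[:half]),
                            1: frozenset(dropped[half:])},
    )
    source = generate_cohort_tables(pair_cfg, 0)
    target = generate_cohort_tables(pair_cfg, 1)
    return source, target, pair_cfg


def simulate_scored_survival(
    n: int,
    hr_per_sd: float,
    seed: int,
    baseline_hazard: float = 0.02,
    horizon_years: float = 8.0,
    censoring_rate: float = 0.1,
) -> pd.DataFrame:
    """A standard-normal score with a known per-SD hazard ratio.

    Onset times are exponential with hazard = baseline * HR^score;
    administrative censoring at the horizon plus random early censoring.
    Used for Cox coverage and null-calibration experiments.
    """
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    hazard = baseline_hazard * np.exp(np.log(hr_per_sd) * score)
    onset = rng.exponential(1.0 / hazard)
    censor = np.full(n, horizon_years)
    early = rng.random(n) < censoring_rate
    censor[early] = rng.uniform(0.1, horizon_years, size=n)[early]
    time = np.minimum(onset, censor)
    event = (onset <= censor).astype(int)
    return pd.DataFrame({"score": score, "time_years": time, "event": event})


# -- scenario presets ------------------------------------------------------


def scenario_config(name: str, seed: int = 0) -> GeneratorConfig:
    """Named study scenarios.

    small
        3 cohorts x 5,000 persons, 60 phecodes, 2 diseases (pipeline-scale).
    recovery
        1 cohort x 20,000 persons, 50 phecodes, one disease with 5 causal
        phecodes at log-OR 0.8 (parameter-recovery conditions).
    transfer
        the pair scenario base: 60 phecodes, one disease with 10 causal
        phecodes at log-OR 0.5, 5,000 persons per cohort.
    orthogonality
        1 cohort x 50,000 persons; both the phecode channel (5 causal at
        log-OR 0.8) and the genetic channel (log-HR 0.35 per SD) carry signal.
    null
        all generative effects zero.
    """
    if name == "small":
        return GeneratorConfig(seed=seed)
    if name == "recovery":
        base = GeneratorConfig(seed=seed, n_cohorts=1, n_persons=20_000, n_phecodes=50,
                               diseases=(_PLACEHOLDER,))
        dz = default_diseases(base, n_diseases=1)[0]
        dz = replace(dz, causal_parents=dz.causal_parents[:5], gamma=0.8)
        return replace(base, diseases=(dz,))
    if name == "transfer":
        base = GeneratorConfig(seed=seed, n_cohorts=2, n_persons=5_000,
                               diseases=(_PLACEHOLDER,))
        dz = default_diseases(base, n_diseases=1)[0]
        dz = replace(dz, gamma=0.5)
        return replace(base, diseases=(dz,))
    if name == "orthogonality":
        base = GeneratorConfig(seed=seed, n_cohorts=1, n_persons=50_000,
                               diseases=(_PLACEHOLDER,))
        dz = default_diseases(base, n_diseases=1)[0]
        dz = replace(dz, causal_parents=dz.causal_parents[:5], gamma=0.8,
                     pgs_effect=0.35)
        return replace(base, diseases=(dz,))
    if name == "null":
        base = GeneratorConfig(seed=seed, n_cohorts=1, n_persons=5_000,
                               diseases=(_PLACEHOLDER,))
        dz = default_diseases(base, n_diseases=1)[0]
        dz = replace(dz, gamma=0.0, age_effect=0.0, sex_effect=0.0, pgs_effect=0.0)
        return replace(base, diseases=(dz,))
    raise GeneratorError(f"unknown scenario {name!r}")


_PLACEHOLDER = SyntheticDisease(
    name="placeholder", phecode="901.1", icd_code="DZ01", causal_parents=(),
)
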