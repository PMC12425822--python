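"""Plain-text interchange formats.

Long diagnosis tables and person tables round-trip as TSV/CSV; cohorts are
written as a sparse triplet TSV (person, phecode, value) plus a
covariate/outcome CSV; study configurations are YAML; evaluation results
are a flat TSV with one row per (cohort, disease, score, metric).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .cohort import Cohort, DiseaseDefinition, StudyDesign
from .evaluation import EffectEstimate


def read_diagnoses(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"person_id": str, "code": str})
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_diagnoses(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, sep="\t", index=False)


def read_persons(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    for col in ("birth_date", "followup_end"):
        df[col] = pd.to_datetime(df[col])
    return df


def write_persons(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("birth_date", "followup_end"):
        out[col] = pd.to_datetime(out[col]).dt.date
    out.to_csv(path, index=False)


def write_cohort(cohort: Cohort, directory) -> None:
    """Sparse triplet feature TSV plus a covariate/outcome CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stacked = cohort.features.stack()
    triplets = stacked[stacked > 0].rename("value").reset_index()
    triplets.columns = ["person_id", "phecode", "value"]
    triplets.to_csv(directory / "features.tsv", sep="\t", index=False)
    meta = cohort.covariates.join(cohort.outcome)
    meta.to_csv(directory / "covariates_outcome.csv", index_label="person_id")
    (directory / "vocabulary.txt").write_text("\n".join(cohort.vocabulary) + "\n")


def read_cohort_features(directory) -> pd.DataFrame:
    directory = Path(directory)
    vocab = (directory / "vocabulary.txt").read_text().split()
    trip = pd.read_csv(directory / "features.tsv", sep="\t",
                       dtype={"person_id": str, "phecode": str})
    meta = pd.read_csv(directory / "covariates_outcome.csv", dtype={"person_id": str})
    mat = trip.pivot_table(index="person_id", columns="phecode", values="value",
                           aggfunc="max", fill_value=0)
    mat = mat.reindex(index=meta["person_id"], columns=vocab, fill_value=0).astype("int8")
    return mat


def load_study_config(path) -> dict:
    """YAML study configuration -> design, diseases and options.

    Returns ``{"design": StudyDesign, "diseases": [DiseaseDefinition, ...],
    "min_prevalence": float}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    design = StudyDesign(**(raw.get("design") or {}))
    diseases = [
        DiseaseDefinition(
            name=d["name"],
            case_icd_codes=frozenset(map(str, d["case_icd_codes"])),
            disease_phecode=str(d["disease_phecode"]),
            sex_restriction=d.get("sex_restriction", "none"),
        )
        for d in raw.get("diseases", [])
    ]
    return {
        "design": design,
        "diseases": diseases,
        "min_prevalence": float(raw.get("min_prevalence", 0.01)),
    }


def evaluation_report(
    rows: Iterable[tuple[str, str, str, EffectEstimate]],
    p_adjusted: dict | None = None,
) -> pd.DataFrame:
    """Flatten (cohort, disease, score, estimate) tuples into the report table."""
    out = []
    for cohort, disease, score, est in rows:
        out.append({
            "cohort": cohort, "disease": disease, "score": score, "metric": est.kind,
            "estimate": est.estimate, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p,
            "n_cases": est.n_cases, "n_controls": est.n_controls,
        })
    return pd.DataFrame(out)
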