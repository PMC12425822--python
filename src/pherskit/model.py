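"""Elastic-net phenotype risk score (PheRS) models.

A PheRS is a regularized logistic regression of disease onset on binary
parent-phecode indicators plus age and sex.  The training protocol:

* 50% of the cohort is held out as the evaluation test set; the other
  half is split 85% / 15% into an inner training set and a hold-out set;
* predictors are imputed to the training mean and standardized to zero
  mean / unit variance on the training data;
* the L1:L2 mixing ratio (0.05-0.95, step 0.05) and the inverse
  regularization strength C (1e-5 ... 1) are chosen by 5-fold
  cross-validated grid search maximizing average precision, with
  balanced class weights and a stochastic average gradient (saga) solver;
* a ridge preset (l1_ratio = 0) drops the mixing-ratio dimension, used
  for the leave-one-out importance analysis.

Because the standardization statistics are stored on the fitted model,
a PheRS transfers across cohorts without retraining: scoring a target
cohort standardizes the target features with the *source* means and
standard deviations, and a predictor absent from the target is imputed
to the source mean — standardized value 0 — so its coefficient
contributes exactly nothing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: the full hyperparameter protocol: 19 mixing ratios x 11 strengths
DEFAULT_L1_RATIOS: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
DEFAULT_CS: tuple[float, ...] = (1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1, 5e-1, 1.0)


class SplitError(ValueError):
    pass


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    """Cohort splitting protocol: 50% test, then 85/15 train/hold-out."""

    seed: int = 0
    train_fraction: float = 0.5
    inner_train_fraction: float = 0.85

    def __post_init__(self):
        for f in (self.train_fraction, self.inner_train_fraction):
            if not 0 < f < 1:
                raise SplitError("split fractions must lie in (0, 1)")


@dataclass(frozen=True)
class HyperGrid:
    """Grid-search protocol for the elastic-net hyperparameters."""

    l1_ratios: tuple[float, ...] = DEFAULT_L1_RATIOS
    Cs: tuple[float, ...] = DEFAULT_CS
    cv_folds: int = 5
    selection_metric: str = "average_precision"

    def __post_init__(self):
        if any(not 0 <= l <= 1 for l in self.l1_ratios):
            raise FitError("l1_ratios must lie in [0, 1]")
        if any(c <= 0 for c in self.Cs):
            raise FitError("inverse regularization strengths must be positive")

    @property
    def size(self) -> int:
        return len(self.l1_ratios) * len(self.Cs)


def small_grid() -> HyperGrid:
    """A reduced grid for simulation-scale fits (3 x 3 candidates, 3 folds)."""
    return HyperGrid(l1_ratios=(0.05, 0.5, 0.95), Cs=(1e-3, 1e-2, 1e-1), cv_folds=3)


def split_cohort(index: Sequence, events: Sequence[int], spec: SplitSpec) -> dict[str, np.ndarray]:
    """Partition person ids into test / train / holdout, stratified by event.

    With the default fractions, half the cohort becomes the test set and
    the other half splits 85/15 into train and holdout.  Reproducible
    under ``spec.seed``.
    """
    index = np.asarray(index)
    events = np.asarray(events).astype(int)
    try:
        modelling, test = train_test_split(
            index, train_size=spec.train_fraction, random_state=spec.seed, stratify=events,
        )
        ev = pd.Series(events, index=np.asarray(index)).loc[modelling].to_numpy()
        train, holdout = train_test_split(
            modelling, train_size=spec.inner_train_fraction, random_state=spec.seed, stratify=ev,
        )
    except ValueError as exc:
        raise SplitError(f"stratified split failed (too few cases?): {exc}") from exc
    parts = {"train": train, "holdout": holdout, "test": test}
    ev_all = pd.Series(events, index=index)
    for name, part in parts.items():
        if ev_all.loc[part].sum() == 0:
            raise SplitError(
                f"split {name!r} contains zero cases; re-seed or use a larger cohort"
            )
    return parts


class PheRS(BaseEstimator, ClassifierMixin):
    """Elastic-net phenotype risk score, an sklearn-compatible classifier.

    Parameters
    ----------
    penalty : {"elastic_net", "ridge"}
        Ridge fixes l1_ratio at 0 and searches only over C.
    l1_ratios, Cs, cv, scoring
        The hyperparameter grid; defaults follow the full protocol
        (19 x 11 candidates, 5-fold CV, average-precision selection).
        Grid ties are broken toward larger l1_ratio, then larger C.
    random_state
        Seeds the CV fold assignment and the saga solver.
    disease, source_cohort
        Metadata carried on the model for provenance and serialization.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Coefficients on the standardized scale.
    feature_means_, feature_sds_ : ndarray
        Imputation / standardization statistics from the training data
        (constant columns get sd 1 so they standardize to exactly 0).
    l1_ratio_, C_ : float
        Selected hyperparameters.
    """

    def __init__(
        self,
        penalty: str = "elastic_net",
        l1_ratios: Sequence[float] = DEFAULT_L1_RATIOS,
        Cs: Sequence[float] = DEFAULT_CS,
        cv: int = 5,
        scoring: str = "average_precision",
        class_weight: str | None = "balanced",
        solver: str = "saga",
        tol: float = 1e-4,
        max_iter: int = 2000,
        random_state: int | None = None,
        disease: str | None = None,
        source_cohort: str | None = None,
    ):
        self.penalty = penalty
        self.l1_ratios = l1_ratios
        self.Cs = Cs
        self.cv = cv
        self.scoring = scoring
        self.class_weight = class_weight
        self.solver = solver
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.disease = disease
        self.source_cohort = source_cohort

    # -- fitting ---------------------------------------------------------

    def _candidates(self) -> list[dict]:
        if self.penalty == "ridge":
            pairs = [(0.0, c) for c in sorted(self.Cs, reverse=True)]
        elif self.penalty == "elastic_net":
            pairs = [
                (l, c)
                for l in sorted(self.l1_ratios, reverse=True)
                for c in sorted(self.Cs, reverse=True)
            ]
        else:
            raise FitError(f"unknown penalty {self.penalty!r}")
        return [{"l1_ratio": [l], "C": [c]} for l, c in pairs]

    def fit(self, X, y):
        X_df = self._as_frame(X, fit=True)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise FitError("training labels contain a single class")
        if np.isinf(X_df.to_numpy(dtype=float, na_value=np.nan)).any():
            raise FitError("non-finite (infinite) feature values in training data")
        self.classes_ = classes

        means = X_df.mean(axis=0, skipna=True)
        X_imp = X_df.fillna(means)
        sds = X_imp.std(axis=0, ddof=0)
        sds = sds.where(sds > 0, 1.0)
        self.feature_means_ = means.to_numpy(dtype=float)
        self.feature_sds_ = sds.to_numpy(dtype=float)
        Z = (X_imp - means) / sds

        base = LogisticRegression(
            solver=self.solver,
            class_weight=self.class_weight,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        candidates = self._candidates()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=FutureWarning)
            if len(candidates) == 1:
                params = {k: v[0] for k, v in candidates[0].items()}
                est = base.set_params(**params).fit(Z.to_numpy(), y)
                self.l1_ratio_, self.C_ = params["l1_ratio"], params["C"]
            else:
                cv = StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state)
                search = GridSearchCV(
                    base, candidates, scoring=self.scoring, cv=cv, refit=True, n_jobs=None,
                )
                search.fit(Z.to_numpy(), y)
                est = search.best_estimator_
                self.l1_ratio_ = search.best_params_["l1_ratio"]
                self.C_ = search.best_params_["C"]
                self.cv_results_ = {
                    "mean_test_score": search.cv_results_["mean_test_score"],
                    "params": search.cv_results_["params"],
                }
        self.coef_ = est.coef_.ravel().copy()
        self.intercept_ = float(est.intercept_[0])
        return self

    # -- scoring ---------------------------------------------------------

    def _as_frame(self, X, fit: bool = False) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            df = X.astype(float)
            if fit:
                self.feature_names_in_ = np.asarray(df.columns, dtype=object)
            return df
        X = np.asarray(X, dtype=float)
        if fit:
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(X.shape[1])], dtype=object
            )
        return pd.DataFrame(X, columns=self.feature_names_in_)

    def standardize(self, X) -> pd.DataFrame:
        """Align columns to the model's predictors, impute to the source
        mean and standardize with the source statistics.

        A column missing from ``X`` is treated as all-missing, hence
        standardizes to exactly 0 and contributes nothing to the score.
        """
        names = list(self.feature_names_in_)
        if isinstance(X, pd.DataFrame):
            missing = [c for c in names if c not in X.columns]
            if missing:
                non_core = [c for c in missing if c not in ("age", "sex")]
                present = [c for c in names if c in X.columns and c not in ("age", "sex")]
                if not present:
                    warnings.warn(
                        "no overlap between model predictors and target vocabulary "
                        "beyond age/sex; score carries no phecode information"
                    )
                logger.info("imputing %d absent predictor columns to source means", len(missing))
            df = X.reindex(columns=names).astype(float)
        else:
            df = pd.DataFrame(np.asarray(X, dtype=float), columns=names)
        means = pd.Series(self.feature_means_, index=names)
        sds = pd.Series(self.feature_sds_, index=names)
        return (df.fillna(means) - means) / sds

    def decision_function(self, X) -> np.ndarray:
        """Raw PheRS: the linear predictor (log-odds scale)."""
        Z = self.standardize(X)
        return self.intercept_ + Z.to_numpy() @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-s))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    # -- introspection / serialization ------------------------------------

    def phecode_coefficients(self) -> pd.Series:
        """Coefficients of the phecode predictors (age/sex excluded)."""
        s = pd.Series(self.coef_, index=list(self.feature_names_in_))
        return s.drop(index=[c for c in ("age", "sex") if c in s.index])

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "disease": self.disease,
            "source_cohort": self.source_cohort,
            "penalty": self.penalty,
            "predictors": [str(c) for c in self.feature_names_in_],
            "coefficients": self.coef_.tolist(),
            "intercept": self.intercept_,
            "feature_means": self.feature_means_.tolist(),
            "feature_sds": self.feature_sds_.tolist(),
            "l1_ratio": self.l1_ratio_,
            "C": self.C_,
            "random_state": self.random_state,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "PheRS":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise FitError(f"unsupported model schema version: {d.get('schema_version')}")
        m = cls(
            penalty=d["penalty"],
            random_state=d.get("random_state"),
            disease=d.get("disease"),
            source_cohort=d.get("source_cohort"),
        )
        m.feature_names_in_ = np.asarray(d["predictors"], dtype=object)
        m.coef_ = np.asarray(d["coefficients"], dtype=float)
        m.intercept_ = float(d["intercept"])
        m.feature_means_ = np.asarray(d["feature_means"], dtype=float)
        m.feature_sds_ = np.asarray(d["feature_sds"], dtype=float)
        m.l1_ratio_ = d["l1_ratio"]
        m.C_ = d["C"]
        m.classes_ = np.array([0, 1])
        return m

    @classmethod
    def from_json(cls, text_or_path) -> "PheRS":
        s = str(text_or_path)
        if s.lstrip().startswith("{"):
            return cls.from_dict(json.loads(s))
        with open(s) as fh:
            return cls.from_dict(json.load(fh))


# -- module-level operation wrappers --------------------------------------


def fit_phers(
    X: pd.DataFrame,
    y: Sequence[int],
    grid: HyperGrid | None = None,
    penalty: str = "elastic_net",
    seed: int | None = None,
    disease: str | None = None,
    source_cohort: str | None = None,
) -> PheRS:
    """Fit a PheRS under the grid-search protocol (thin wrapper over PheRS)."""
    grid = grid or HyperGrid()
    model = PheRS(
        penalty=penalty,
        l1_ratios=grid.l1_ratios,
        Cs=grid.Cs,
        cv=grid.cv_folds,
        scoring=grid.selection_metric,
        random_state=seed,
        disease=disease,
        source_cohort=source_cohort,
    )
    return model.fit(X, y)


def score_cohort(model: PheRS, features: pd.DataFrame) -> pd.Series:
    """Raw PheRS (linear predictor) for every person in ``features``."""
    return pd.Series(model.decision_function(features), index=features.index, name="phers")


def transfer_score(
    model: PheRS,
    target_features: pd.DataFrame,
    common_codes: Sequence[str] | None = None,
) -> pd.Series:
    """Score a target cohort with a model trained elsewhere, no retraining.

    Predictors absent from the target vocabulary are imputed to the
    source-training mean, so their standardized value is 0 and their
    coefficient is effectively multiplied by zero.  ``common_codes``
    optionally restricts the phecode predictors to a shared vocabulary
    (columns outside it are treated as absent).
    """
    X = target_features
    if common_codes is not None:
        keep = set(map(str, common_codes)) | {"age", "sex"}
        X = X[[c for c in X.columns if str(c) in keep]]
    return pd.Series(model.decision_function(X), index=target_features.index, name="phers")


def loo_importance(
    X: pd.DataFrame,
    y: Sequence[int],
    eval_X: pd.DataFrame,
    eval_y: Sequence[int],
    grid: HyperGrid | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Leave-one-phecode-out importance under the ridge preset.

    Refits the model once per phecode column with that column removed and
    reports the change in evaluation average precision relative to the
    full model (negative delta = the phecode carried unique signal).
    """
    grid = grid or HyperGrid()
    y = np.asarray(y).astype(int)
    eval_y = np.asarray(eval_y).astype(int)

    def _fit_ap(cols):
        m = fit_phers(X[cols], y, grid=grid, penalty="ridge", seed=seed)
        return m, average_precision_score(eval_y, m.decision_function(eval_X[cols]))

    all_cols = list(X.columns)
    full_model, full_ap = _fit_ap(all_cols)
    rows = []
    for col in all_cols:
        if col in ("age", "sex"):
            continue
        try:
            _, ap = _fit_ap([c for c in all_cols if c != col])
        except FitError as exc:  # pragma: no cover - propagated fit failures
            logger.warning("leave-one-out refit failed for %s: %s", col, exc)
            continue
        rows.append({"phecode": col, "metric_full": full_ap, "metric_loo": ap,
                     "delta": ap - full_ap})
    return pd.DataFrame(rows).set_index("phecode")


def rank_coefficients(model: PheRS) -> pd.DataFrame:
    """Display-standardized phecode coefficients with descending-value ranks.

    The phecode coefficients of one model are scaled to mean 0 / SD 1 so
    their relative importance can be compared across models whose
    regularization strengths differ.  Rank 1 is the largest coefficient;
    ties keep stable input order and are flagged.
    """
    coefs = model.phecode_coefficients()
    n = len(coefs)
    order = np.argsort(-coefs.to_numpy(), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    if n >= 2:
        scaled = (coefs - coefs.mean()) / coefs.std(ddof=0)
    else:
        warnings.warn("fewer than 2 phecode coefficients; display scaling skipped")
        scaled = pd.Series(np.nan, index=coefs.index)
    values = coefs.to_numpy()
    tied = pd.Series(values).duplicated(keep=False).to_numpy()
    return pd.DataFrame({
        "phecode": coefs.index,
        "coefficient": values,
        "scaled_coefficient": scaled.to_numpy(),
        "rank": ranks,
        "tied": tied,
    }).set_index("phecode").sort_values("rank")
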