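"""Survival-model evaluation of risk scores.

Scores are first *residualized*: the effects of age, sex (and, when a
genetic score is in play, the first ten genetic principal components) are
regressed out and the residuals rescaled to mean 0 / SD 1, so every
downstream association is independent of those covariates.  Evaluation
then uses Cox proportional-hazards models (hazard ratio per 1 SD of the
score, and top-10% vs mid-40-60% percentile-group contrasts), Harrell's
concordance index with a Noether-type (influence function) standard
error, the area under the precision-recall curve, Nagelkerke's pseudo-R2,
and z-score comparisons of effect estimates with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sklearn.metrics import average_precision_score

Z95 = 1.959963984540054


class EvaluationError(ValueError):
    pass


@dataclass
class EffectEstimate:
    """One effect measure with its uncertainty — the unit of all comparisons.

    ``kind`` is one of log_hr_per_sd, log_hr_group, cindex, auprc,
    correlation, nagelkerke_r2.  ``estimate`` is on the natural comparison
    scale (log-HR for hazard ratios).
    """

    kind: str
    estimate: float
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")
    n_cases: int = 0
    n_controls: int = 0
    label: str = ""

    @property
    def hr(self) -> float:
        """exp(estimate); meaningful for the log_hr kinds."""
        return float(np.exp(self.estimate))

    def __post_init__(self):
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise EvaluationError("confidence interval does not contain the estimate")


@dataclass
class ComparisonResult:
    z: float
    p: float
    sidedness: str
    bonferroni_m: int
    p_adjusted: float


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = covariates.astype(float)
    cols = list(X.columns)
    M = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in cols])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        warnings.warn("rank-deficient covariate matrix; collinear columns are absorbed")
    return M, cols


def residualize_score(
    score: pd.Series,
    covariates: pd.DataFrame,
    family: str = "gaussian",
) -> pd.Series:
    """Regress covariates out of a score and rescale to mean 0 / SD 1.

    The default is ordinary least squares on the raw score.  A logistic
    sensitivity variant squashes the score to (0, 1) by min-max scaling and
    takes binomial-GLM response residuals before rescaling; it exists for
    robustness checks only.
    """
    y = score.to_numpy(dtype=float)
    M, _ = _design_matrix(covariates.loc[score.index])
    if family == "gaussian":
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ beta
    elif family == "logistic":
        lo, hi = y.min(), y.max()
        if hi <= lo:
            raise EvaluationError("degenerate score: zero variance")
        eps = 1e-6
        y01 = (y - lo) / (hi - lo) * (1 - 2 * eps) + eps
        import statsmodels.api as sm

        fit = sm.GLM(y01, M, family=sm.families.Binomial()).fit()
        resid = np.asarray(y01 - fit.predict(M))
    else:
        raise EvaluationError(f"unknown residualization family {family!r}")
    sd = resid.std(ddof=0)
    if sd < 1e-10:
        raise EvaluationError("degenerate score: fully explained by the covariates")
    out = (resid - resid.mean()) / sd
    return pd.Series(out, index=score.index, name=f"{score.name or 'score'}_resid")


def _cox_fit(df: pd.DataFrame, covariate_cols: Sequence[str]) -> CoxPHFitter:
    if df["event"].sum() == 0:
        raise EvaluationError("zero events: cannot fit a proportional-hazards model")
    cph = CoxPHFitter()
    try:
        cph.fit(df[["time_years", "event", *covariate_cols]],
                duration_col="time_years", event_col="event",
                fit_options={"precision": 1e-10})
    except ConvergenceError as exc:
        raise EvaluationError(f"Cox model failed to converge: {exc}") from exc
    return cph


def _cox_effect(cph: CoxPHFitter, term: str, kind: str, n_cases: int, n_controls: int,
                label: str = "") -> EffectEstimate:
    beta = float(cph.params_[term])
    se = float(cph.standard_errors_[term])
    return EffectEstimate(
        kind=kind, estimate=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        p=float(2 * stats.norm.sf(abs(beta / se))),
        n_cases=n_cases, n_controls=n_controls, label=label,
    )


def fit_cox_per_sd(
    score: pd.Series,
    outcome: pd.DataFrame,
    label: str = "",
) -> EffectEstimate:
    """Log hazard ratio per 1 SD of the (residualized) score.

    The score enters a proportional-hazards model (Efron ties) as the sole
    covariate; Wald SE, 95% CI and two-sided p are reported.
    """
    df = outcome.loc[score.index, ["time_years", "event"]].copy()
    df["score"] = score.to_numpy(dtype=float)
    cph = _cox_fit(df, ["score"])
    ev = int(df["event"].sum())
    return _cox_effect(cph, "score", "log_hr_per_sd", ev, len(df) - ev, label)


def percentile_group_hr(
    score: pd.Series,
    outcome: pd.DataFrame,
    top: tuple[float, float] = (0.90, 1.00),
    reference: tuple[float, float] = (0.40, 0.60),
    label: str = "",
) -> EffectEstimate:
    """Cox HR of the top score percentile band vs the mid-risk band.

    Membership uses empirical percentiles of the score; a person exactly on
    a boundary falls in the lower band (strictly-greater lower edge).
    """
    x = score.to_numpy(dtype=float)

    def band(bounds):
        lo, hi = bounds
        lo_v = np.quantile(x, lo) if lo > 0 else -np.inf
        hi_v = np.quantile(x, hi) if hi < 1 else np.inf
        return (x > lo_v) & (x <= hi_v)

    in_top, in_ref = band(top), band(reference)
    for name, mask, bounds in (("top", in_top, top), ("reference", in_ref, reference)):
        if not mask.any():
            raise EvaluationError(f"empty {name} percentile band {bounds}")
    sel = in_top | in_ref
    df = outcome.loc[score.index[sel], ["time_years", "event"]].copy()
    df["top_group"] = in_top[sel].astype(float)
    if df.groupby("top_group")["event"].sum().min() == 0:
        raise EvaluationError("a percentile band contains zero events")
    cph = _cox_fit(df, ["top_group"])
    ev = int(df["event"].sum())
    return _cox_effect(cph, "top_group", "log_hr_group", ev, len(df) - ev, label)


def concordance_index(
    predictions: pd.Series | np.ndarray,
    outcome: pd.DataFrame,
    label: str = "",
) -> EffectEstimate:
    """Harrell's c with an influence-function (Noether-type) SE.

    Usable pairs are (i, j) with an observed event in i and t_i < t_j
    (or t_i = t_j with j censored, so the event is the worse outcome);
    prediction ties count one half.  When all subjects share one
    administrative follow-up time and the outcome is binary, c equals the
    ROC AUC of event status against the prediction, and the SE reduces to
    the DeLong form.
    """
    pred = np.asarray(predictions, dtype=float)
    t = outcome["time_years"].to_numpy(dtype=float)
    e = outcome["event"].to_numpy(dtype=int)
    n = len(pred)
    conc = 0.0
    A = np.zeros(n)
    B = np.zeros(n)
    event_idx = np.flatnonzero(e == 1)
    for i in event_idx:
        usable = (t > t[i]) | ((t == t[i]) & (e == 0))
        if not usable.any():
            continue
        wins = np.where(pred[i] > pred[usable], 1.0, 0.0)
        wins[pred[i] == pred[usable]] = 0.5
        a_i, b_i = wins.sum(), float(usable.sum())
        conc += a_i
        A[i] += a_i
        B[i] += b_i
        A[usable] += wins
        B[usable] += 1.0
    P = B.sum() / 2.0
    if P == 0:
        raise EvaluationError("no usable pairs for the concordance index")
    c = conc / P
    psi = (A - c * B) / (2 * P)
    se = float(np.sqrt(np.sum(psi**2) * 4))
    ev = int(e.sum())
    return EffectEstimate(
        kind="cindex", estimate=float(c), se=se,
        ci_low=c - Z95 * se, ci_high=c + Z95 * se,
        p=float(2 * stats.norm.sf(abs((c - 0.5) / se))) if se > 0 else float("nan"),
        n_cases=ev, n_controls=n - ev, label=label,
    )


def cox_model_cindex(
    covariates: pd.DataFrame,
    outcome: pd.DataFrame,
    label: str = "",
) -> EffectEstimate:
    """c-index of the linear predictor of a multivariable Cox model.

    Fits a proportional-hazards model on the supplied covariate columns and
    scores each person with its linear predictor; used to compare nested
    models (e.g. age+sex vs age+sex+PheRS).
    """
    df = outcome[["time_years", "event"]].join(covariates.astype(float), how="inner")
    cph = _cox_fit(df, list(covariates.columns))
    lp = cph.predict_partial_hazard(df).to_numpy()
    return concordance_index(pd.Series(lp, index=df.index), df, label=label)


def compare_effects(
    a: EffectEstimate,
    b: EffectEstimate,
    sidedness: str = "two_tailed",
    bonferroni_m: int = 13,
) -> ComparisonResult:
    """z test of the difference of two effect estimates.

    z = (a - b) / sqrt(se_a^2 + se_b^2); the estimates are treated as
    independent even when computed on the same test set.  One-tailed tests
    the increase a > b.  Bonferroni adjustment defaults to m = 13.
    """
    if not (np.isfinite(a.se) and np.isfinite(b.se)):
        raise EvaluationError("compare_effects requires standard errors on both estimates")
    z = (a.estimate - b.estimate) / np.hypot(a.se, b.se)
    if sidedness == "two_tailed":
        p = float(2 * stats.norm.sf(abs(z)))
    elif sidedness == "one_tailed":
        p = float(stats.norm.sf(z))
    else:
        raise EvaluationError(f"unknown sidedness {sidedness!r}")
    return ComparisonResult(
        z=float(z), p=p, sidedness=sidedness, bonferroni_m=bonferroni_m,
        p_adjusted=min(1.0, p * bonferroni_m),
    )


def auprc(predictions, y, label: str = "") -> EffectEstimate:
    """Area under the precision-recall curve (step interpolation).

    The null reference is the outcome prevalence.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUPRC requires both outcome classes")
    ap = float(average_precision_score(y, np.asarray(predictions, dtype=float)))
    return EffectEstimate(kind="auprc", estimate=ap,
                          n_cases=int(y.sum()), n_controls=int((1 - y).sum()), label=label)


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int,
                  label: str = "") -> EffectEstimate:
    """Nagelkerke's pseudo-R2 from fitted and null log-likelihoods.

    Cox-Snell R2 = 1 - exp(2 (L0 - L1) / n), divided by its attainable
    maximum 1 - exp(2 L0 / n).
    """
    if loglik_model < loglik_null:
        warnings.warn("model log-likelihood below the null; R2 floored at 0")
    cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    value = float(max(0.0, cs / max_cs)) if max_cs > 0 else 0.0
    return EffectEstimate(kind="nagelkerke_r2", estimate=value, label=label)


def correlation(
    x: pd.Series,
    y: pd.Series,
    partial_covariates: pd.DataFrame | None = None,
    label: str = "",
) -> EffectEstimate:
    """Pearson correlation with Fisher-z CI; optionally partial.

    With ``partial_covariates``, both vectors are residualized on the
    covariates first and the CI degrees of freedom are reduced accordingly.
    """
    x = np.array(x, dtype=float, copy=True)
    y = np.array(y, dtype=float, copy=True)
    n = len(x)
    if n < 4:
        raise EvaluationError("correlation requires n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise EvaluationError("zero variance in a correlation input")
    k = 0
    if partial_covariates is not None:
        M, cols = _design_matrix(partial_covariates)
        k = len(cols)
        x = x - M @ np.linalg.lstsq(M, x, rcond=None)[0]
        y = y - M @ np.linalg.lstsq(M, y, rcond=None)[0]
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 3 - k
    if df <= 0:
        raise EvaluationError("not enough observations for a Fisher-z interval")
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se_z = 1.0 / np.sqrt(df)
    lo, hi = np.tanh(zr - Z95 * se_z), np.tanh(zr + Z95 * se_z)
    p = float(2 * stats.norm.sf(abs(zr) / se_z))
    return EffectEstimate(kind="correlation", estimate=r, se=float(se_z),
                          ci_low=float(min(lo, r)), ci_high=float(max(hi, r)),
                          p=p, label=label)
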