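"""Random-effects meta-analysis of per-cohort effect estimates.

Log hazard ratios are pooled on the log scale and c-indices on the raw
scale (a logit option exists).  The between-study variance tau^2 is
estimated by REML (default) or the DerSimonian-Laird closed form; pooling
uses inverse-variance weights 1 / (se_i^2 + tau^2) with a Wald 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .evaluation import EffectEstimate, Z95


class MetaError(ValueError):
    pass


@dataclass
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    k: int
    method: str

    def __post_init__(self):
        if self.tau2 < 0:
            raise MetaError("tau2 must be non-negative")
        if not (self.ci_low <= self.pooled <= self.ci_high):
            raise MetaError("CI does not contain the pooled estimate")


def dersimonian_laird_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """Closed-form DerSimonian-Laird tau^2: max(0, (Q - (k-1)) / (S1 - S2/S1))."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    k = len(y)
    s1 = np.sum(w)
    denom = s1 - np.sum(w**2) / s1
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / denom)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    k = len(y)
    if k < 2:
        return 0.0

    def neg_restricted_ll(tau2: float) -> float:
        vi = v + tau2
        w = 1.0 / vi
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(vi)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    hi = max(dersimonian_laird_tau2(y, v) * 10, np.var(y), v.max()) * 10 + 1e-8
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-12})
    return float(max(0.0, res.x))


def random_effects_meta(
    estimates: Sequence[EffectEstimate],
    method: str = "REML",
    tau2: float | None = None,
) -> MetaResult:
    """Pool k effect estimates under a random-effects model.

    All estimates must be on a common scale.  ``tau2`` can be fixed (e.g.
    at 0 for the fixed-effect inverse-variance limit); otherwise it is
    estimated by the requested method.  With k = 1 the single estimate is
    returned with tau2 = 0.
    """
    if len(estimates) == 0:
        raise MetaError("meta-analysis needs at least one estimate")
    y = np.array([e.estimate for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise MetaError("every estimate needs a positive standard error")
    v = se**2
    k = len(y)
    if tau2 is None:
        if k == 1:
            tau2 = 0.0
        elif method.upper() == "REML":
            tau2 = _reml_tau2(y, v)
        elif method.upper() in ("DL", "DERSIMONIAN-LAIRD"):
            tau2 = dersimonian_laird_tau2(y, v)
        else:
            raise MetaError(f"unknown tau2 method {method!r}")
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / pooled_se
    return MetaResult(
        pooled=pooled, se=pooled_se,
        ci_low=pooled - Z95 * pooled_se, ci_high=pooled + Z95 * pooled_se,
        p=float(2 * stats.norm.sf(abs(z))),
        tau2=float(tau2), k=k, method=method.upper(),
    )


def forest_table(
    estimates: Sequence[EffectEstimate],
    labels: Sequence[str] | None = None,
    method: str = "REML",
) -> pd.DataFrame:
    """Per-study rows plus a pooled row, with random-effects weights (%)."""
    res = random_effects_meta(estimates, method=method)
    w = np.array([1.0 / (e.se**2 + res.tau2) for e in estimates])
    w = 100.0 * w / w.sum()
    labels = list(labels) if labels is not None else [
        e.label or f"study_{i + 1}" for i, e in enumerate(estimates)
    ]
    rows = [
        {"study": lab, "estimate": e.estimate, "ci_low": e.ci_low,
         "ci_high": e.ci_high, "weight_pct": wi}
        for lab, e, wi in zip(labels, estimates, w)
    ]
    rows.append({"study": f"pooled ({res.method})", "estimate": res.pooled,
                 "ci_low": res.ci_low, "ci_high": res.ci_high, "weight_pct": 100.0})
    return pd.DataFrame(rows)


def meta_analyze_cindex(
    estimates: Sequence[EffectEstimate],
    method: str = "REML",
    scale: str = "raw",
) -> MetaResult:
    """Pool c-indices, on the raw scale by default or on the logit scale."""
    if scale == "raw":
        return random_effects_meta(estimates, method=method)
    if scale != "logit":
        raise MetaError(f"unknown c-index pooling scale {scale!r}")
    transformed = []
    for e in estimates:
        c = np.clip(e.estimate, 1e-9, 1 - 1e-9)
        lc = np.log(c / (1 - c))
        se = e.se / (c * (1 - c))
        transformed.append(EffectEstimate(kind="cindex_logit", estimate=float(lc),
                                          se=float(se), ci_low=lc - Z95 * se,
                                          ci_high=lc + Z95 * se))
    res = random_effects_meta(transformed, method=method)
    inv = lambda x: 1.0 / (1.0 + np.exp(-x))
    pooled = float(inv(res.pooled))
    return MetaResult(
        pooled=pooled,
        se=float(res.se * pooled * (1 - pooled)),
        ci_low=float(inv(res.ci_low)), ci_high=float(inv(res.ci_high)),
        p=res.p, tau2=res.tau2, k=res.k, method=res.method,
    )
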