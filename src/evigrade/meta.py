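"""Summary-level meta-analysis statistics.

Inverse-variance fixed-effect pooling, Cochran's Q with its chi-square
p-value, the I-squared heterogeneity percentage, and Egger's regression
test for funnel-plot asymmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm
from scipy.stats import t as t_dist

__all__ = [
    "MetaSummary",
    "pool_fixed",
    "heterogeneity",
    "egger_test",
    "summarize_studies",
]


@dataclass(frozen=True)
class MetaSummary:
    pooled_log_or: float
    pooled_se: float
    ci_low: float
    ci_high: float
    k: int
    q_stat: float | None = None
    q_p: float | None = None
    i_squared: float | None = None
    egger_intercept: float | None = None
    egger_p: float | None = None


def _as_arrays(log_ors: Sequence[float], ses: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(log_ors, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.shape != se.shape or theta.ndim != 1:
        raise ValueError("log_ors and ses must be 1-D sequences of equal length")
    if theta.size == 0:
        raise ValueError("at least one study is required")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    return theta, se


def pool_fixed(
    log_ors: Sequence[float], ses: Sequence[float], ci_level: float = 0.95
) -> MetaSummary:
    """Inverse-variance fixed-effect pooled estimate with OR-scale CI."""
    theta, se = _as_arrays(log_ors, ses)
    weights = 1.0 / se**2
    pooled = float(np.sum(weights * theta) / np.sum(weights))
    pooled_se = float(np.sum(weights) ** -0.5)
    z_crit = float(norm.ppf(0.5 * (1.0 + ci_level)))
    return MetaSummary(
        pooled_log_or=pooled,
        pooled_se=pooled_se,
        ci_low=math.exp(pooled - z_crit * pooled_se),
        ci_high=math.exp(pooled + z_crit * pooled_se),
        k=theta.size,
    )


def heterogeneity(
    log_ors: Sequence[float], ses: Sequence[float]
) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square p-value (k-1 df), and I-squared (%)."""
    theta, se = _as_arrays(log_ors, ses)
    k = theta.size
    if k < 2:
        raise ValueError("heterogeneity requires at least two studies")
    weights = 1.0 / se**2
    pooled = float(np.sum(weights * theta) / np.sum(weights))
    q_stat = float(np.sum(weights * (theta - pooled) ** 2))
    q_p = float(chi2.sf(q_stat, k - 1))
    i_squared = 0.0 if q_stat <= 0 else max(0.0, (q_stat - (k - 1)) / q_stat) * 100.0
    return q_stat, q_p, i_squared


def egger_test(log_ors: Sequence[float], ses: Sequence[float]) -> tuple[float, float]:
    """Egger's regression: standardized effect on precision, intercept and
    its two-sided t-test p-value (k-2 df)."""
    theta, se = _as_arrays(log_ors, ses)
    k = theta.size
    if k < 3:
        raise ValueError("Egger's test requires at least three studies")
    y = theta / se
    x = 1.0 / se
    design = np.column_stack([np.ones(k), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ coef
    dof = k - 2
    sigma2 = float(residuals @ residuals) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    intercept = float(coef[0])
    se_intercept = math.sqrt(sigma2 * xtx_inv[0, 0])
    if se_intercept == 0.0:
        return intercept, 1.0
    t_stat = intercept / se_intercept
    p_value = float(2.0 * t_dist.sf(abs(t_stat), dof))
    return intercept, p_value


def summarize_studies(
    log_ors: Sequence[float], ses: Sequence[float], ci_level: float = 0.95
) -> MetaSummary:
    """Pooling plus heterogeneity and Egger fields where computable
    (heterogeneity needs k >= 2, Egger k >= 3)."""
    base = pool_fixed(log_ors, ses, ci_level)
    q_stat = q_p = i_squared = None
    egger_intercept = egger_p = None
    if base.k >= 2:
        q_stat, q_p, i_squared = heterogeneity(log_ors, ses)
    if base.k >= 3:
        egger_intercept, egger_p = egger_test(log_ors, ses)
    return MetaSummary(
        pooled_log_or=base.pooled_log_or,
        pooled_se=base.pooled_se,
        ci_low=base.ci_low,
        ci_high=base.ci_high,
        k=base.k,
        q_stat=q_stat,
        q_p=q_p,
        i_squared=i_squared,
        egger_intercept=egger_intercept,
        egger_p=egger_p,
    )
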