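"""Rubin's rules: combining estimates across multiply-imputed analyses.

Given per-imputation point estimates ``q_1..q_m`` and squared standard
errors ``u_1..u_m``, the pooled estimate is the mean ``qbar``; the total
variance is ``T = W + (1 + 1/m) B`` with ``W`` the mean within-imputation
variance and ``B`` the between-imputation sample variance; the reference
distribution is Student-t with ``df = (m-1) * (1 + W / ((1+1/m) B))**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PooledEstimate", "rubin_pool"]


@dataclass(frozen=True)
class PooledEstimate:
    qbar: float
    w: float
    b: float
    t: float
    df: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return math.sqrt(self.t)


def rubin_pool(
    estimates,
    variances,
    alpha: float = 0.05,
    df_method: str = "rubin",
    dfcom: float | None = None,
) -> PooledEstimate:
    """Pool ``m >= 2`` estimates and their squared standard errors.

    ``df_method="rubin"`` uses the classical large-sample degrees of
    freedom; ``"barnard-rubin"`` applies the small-sample adjustment and
    then requires ``dfcom``, the complete-data degrees of freedom.  When the
    between-imputation variance is exactly zero the df are infinite and the
    interval reduces to the normal-based Wald interval with variance ``W``.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be 1-d and equal length")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2 imputations")
    if np.any(u <= 0) or not np.all(np.isfinite(q)) or not np.all(np.isfinite(u)):
        raise ValueError("variances must be positive and all inputs finite")

    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    # identical estimates leave a floating-point residue; snap it to zero
    if b <= 1e-14 * (w + qbar * qbar + 1.0):
        b = 0.0
    t = w + (1.0 + 1.0 / m) * b

    if b == 0.0:
        df = math.inf
    else:
        rm = (1.0 + 1.0 / m) * b / w
        df = (m - 1) * (1.0 + 1.0 / rm) ** 2
        if df_method == "barnard-rubin":
            if dfcom is None:
                raise ValueError("barnard-rubin df requires dfcom")
            lam = (1.0 + 1.0 / m) * b / t
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)
        elif df_method != "rubin":
            raise ValueError("df_method must be 'rubin' or 'barnard-rubin'")

    quant = (
        stats.norm.ppf(1.0 - alpha / 2.0)
        if math.isinf(df)
        else stats.t.ppf(1.0 - alpha / 2.0, df)
    )
    half = quant * math.sqrt(t)
    return PooledEstimate(
        qbar=qbar, w=w, b=b, t=t, df=df,
        ci_low=qbar - half, ci_high=qbar + half,
    )
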