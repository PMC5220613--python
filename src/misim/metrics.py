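"""Monte-Carlo performance measures: bias, absolute error, coverage, power.

For a true log-odds-ratio ``z`` and per-replication estimates ``z_hat_i``:

* mean bias            ``mean(z - z_hat_i)``  (note: truth minus estimate,
  so a *negative* bias means the estimates overshoot the truth),
* mean absolute error  ``mean(|z - z_hat_i|)``,
* coverage             fraction of 95% CIs containing ``z``,
* power                fraction of 95% CIs excluding zero.

Metrics are computed over converged replications only; the number of
converged and attempted replications is reported alongside, and each
metric carries a Monte-Carlo standard error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dgp import TRUE_LOG_ODDS_RATIOS

__all__ = [
    "mean_bias",
    "mean_abs_error",
    "coverage",
    "power",
    "summarize_replications",
]


def _as_1d(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if a.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return a


def mean_bias(true_value: float, estimates) -> float:
    """Mean of (truth - estimate) across replications."""
    est = _as_1d(estimates, "estimates")
    return float(np.mean(true_value - est))


def mean_abs_error(true_value: float, estimates) -> float:
    """Mean of |truth - estimate| across replications."""
    est = _as_1d(estimates, "estimates")
    return float(np.mean(np.abs(true_value - est)))


def coverage(true_value: float, ci_lows, ci_highs) -> float:
    """Fraction of intervals containing the true value."""
    lo = _as_1d(ci_lows, "ci_lows")
    hi = _as_1d(ci_highs, "ci_highs")
    if lo.shape != hi.shape:
        raise ValueError("ci_lows and ci_highs must have equal length")
    return float(np.mean((lo <= true_value) & (true_value <= hi)))


def power(ci_lows, ci_highs) -> float:
    """Fraction of intervals excluding zero."""
    lo = _as_1d(ci_lows, "ci_lows")
    hi = _as_1d(ci_highs, "ci_highs")
    if lo.shape != hi.shape:
        raise ValueError("ci_lows and ci_highs must have equal length")
    return float(np.mean((lo > 0.0) | (hi < 0.0)))


def summarize_replications(
    replications: pd.DataFrame,
    true_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate a replication-level table into per-scenario metrics.

    Expects columns ``mechanism, level, n, strategy, parameter, estimate,
    ci_low, ci_high, converged`` (the output of the runner).  Returns one
    row per (mechanism, level, n, strategy, parameter) with the four
    performance measures, their Monte-Carlo standard errors and the
    convergence accounting.
    """
    if true_values is None:
        true_values = TRUE_LOG_ODDS_RATIOS
    keys = ["mechanism", "level", "n", "strategy", "parameter"]
    rows = []
    for key, grp in replications.groupby(keys, sort=True):
        rec = dict(zip(keys, key))
        z = true_values[rec["parameter"]]
        conv = grp[grp["converged"] & grp["estimate"].notna()]
        rec["true_value"] = z
        rec["n_reps"] = len(grp)
        rec["n_converged"] = len(conv)
        if len(conv) == 0:
            for c in (
                "mean_bias", "mean_bias_mcse", "mean_abs_error",
                "mean_abs_error_mcse", "coverage", "coverage_mcse",
                "power", "power_mcse",
            ):
                rec[c] = np.nan
        else:
            est = conv["estimate"].to_numpy()
            lo = conv["ci_low"].to_numpy()
            hi = conv["ci_high"].to_numpy()
            r = len(conv)
            bias = mean_bias(z, est)
            mae = mean_abs_error(z, est)
            cov = coverage(z, lo, hi)
            pwr = power(lo, hi)
            rec["mean_bias"] = bias
            rec["mean_bias_mcse"] = float(np.std(z - est, ddof=1) / np.sqrt(r)) if r > 1 else np.nan
            rec["mean_abs_error"] = mae
            rec["mean_abs_error_mcse"] = (
                float(np.std(np.abs(z - est), ddof=1) / np.sqrt(r)) if r > 1 else np.nan
            )
            rec["coverage"] = cov
            rec["coverage_mcse"] = float(np.sqrt(cov * (1 - cov) / r))
            rec["power"] = pwr
            rec["power_mcse"] = float(np.sqrt(pwr * (1 - pwr) / r))
        rows.append(rec)
    return pd.DataFrame(rows)
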