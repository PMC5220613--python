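"""The eight analysis strategies compared by the simulation study.

Every strategy receives the same amputed dataset and returns pooled
estimates of the substantive logistic model
``logit Pr(Y=1) = beta0 + beta1*E + beta2*X + beta3*E*X``:

==  ========================================================================
A   complete case analysis (rows with observed X and Y), no imputation
B   drop missing-Y rows; impute X *without* the outcome (predictor: E)
C   drop missing-Y rows; impute X with the outcome (predictors: E, Y)
D   impute both X and Y on all rows, analyse everything
E   as D, then delete rows whose Y was imputed before fitting (von Hippel's
    multiple-imputation-then-deletion)
F   as C, plus the secondary outcome Y' in the imputation model (imputed too)
G   as D, plus the secondary outcome Y' in the imputation model (imputed too)
H   as D, but X is excluded from both the imputation and analysis models
==  ========================================================================

Strategies B-E and H ignore Y'.  All multiple-imputation strategies use
main-effects conditional models and pool with Rubin's rules.  Strategy H's
analysis model is ``Y ~ E`` alone, so it estimates the marginal
(confounded) exposure effect — its bias against the conditional ``beta1``
measures the cost of dropping an informative covariate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .amputation import AmputedDataset
from .fcs_imputer import ImputationError, ImputationSpec, impute_chained
from .pooling import rubin_pool

__all__ = [
    "STRATEGY_IDS",
    "StrategyResult",
    "fit_substantive",
    "run_strategy",
]

STRATEGY_IDS = ("A", "B", "C", "D", "E", "F", "G", "H")

_FULL_PARAMS = ("beta1", "beta2", "beta3")
_MARGINAL_PARAMS = ("beta1",)


@dataclass
class _Fit:
    params: dict[str, float]
    ses: dict[str, float]
    converged: bool
    nobs: int


@dataclass
class StrategyResult:
    """Pooled per-parameter estimates for one strategy on one dataset."""

    strategy: str
    estimates: dict[str, float] = field(default_factory=dict)
    std_errors: dict[str, float] = field(default_factory=dict)
    dfs: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_analysed: int = 0
    reason: Optional[str] = None

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.estimates)

    def to_rows(self, **extra) -> list[dict]:
        rows = []
        for p in self.estimates:
            rows.append(
                {
                    **extra,
                    "strategy": self.strategy,
                    "parameter": p,
                    "estimate": self.estimates[p],
                    "se": self.std_errors[p],
                    "df": self.dfs[p],
                    "ci_low": self.ci_low[p],
                    "ci_high": self.ci_high[p],
                    "converged": self.converged,
                    "n_analysed": self.n_analysed,
                }
            )
        return rows


def fit_substantive(frame: pd.DataFrame, include_covariate: bool = True) -> _Fit:
    """Maximum-likelihood logistic fit of the substantive model.

    ``Y ~ E + X + E*X`` (Wald standard errors), or ``Y ~ E`` when the
    covariate is excluded.  Separation, non-convergence or a degenerate
    outcome are reported through ``converged=False`` — estimates with
    absurdly large coefficients (|beta| > 40) are treated as separated.
    """
    names = _FULL_PARAMS if include_covariate else _MARGINAL_PARAMS
    y = frame["y"].to_numpy(float)
    e = frame["e"].to_numpy(float)
    if include_covariate:
        x = frame["x"].to_numpy(float)
        design = np.column_stack([np.ones(len(y)), e, x, e * x])
    else:
        design = np.column_stack([np.ones(len(y)), e])
    nobs = len(y)
    failed = _Fit(
        params={p: math.nan for p in names},
        ses={p: math.nan for p in names},
        converged=False,
        nobs=nobs,
    )
    if nobs < design.shape[1] + 1 or len(np.unique(y)) < 2:
        return failed
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
        params = np.asarray(res.params, dtype=float)
        ses = np.asarray(res.bse, dtype=float)
        ok = (
            bool(res.mle_retvals.get("converged", False))
            and np.all(np.isfinite(params))
            and np.all(np.isfinite(ses))
            and np.max(np.abs(params)) <= 40.0
        )
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return failed
    if not ok:
        return failed
    return _Fit(
        params={p: float(params[i + 1]) for i, p in enumerate(names)},
        ses={p: float(ses[i + 1]) for i, p in enumerate(names)},
        converged=True,
        nobs=nobs,
    )


def _single_fit_result(strategy: str, fit: _Fit) -> StrategyResult:
    res = StrategyResult(strategy=strategy, converged=fit.converged, n_analysed=fit.nobs)
    zq = stats.norm.ppf(0.975)
    for p, est in fit.params.items():
        se = fit.ses[p]
        res.estimates[p] = est
        res.std_errors[p] = se
        res.dfs[p] = math.inf
        res.ci_low[p] = est - zq * se
        res.ci_high[p] = est + zq * se
    if not fit.converged:
        res.reason = "substantive fit failed"
    return res


def _strategy_spec(strategy: str, m: int, cycles: int, ridge: float) -> ImputationSpec:
    preds = {
        "B": {"x": ("e",)},
        "C": {"x": ("e", "y")},
        "D": {"x": ("e", "y"), "y": ("e", "x")},
        "E": {"x": ("e", "y"), "y": ("e", "x")},
        "F": {"x": ("e", "y", "y_sec"), "y_sec": ("e", "x", "y")},
        "G": {
            "x": ("e", "y", "y_sec"),
            "y": ("e", "x", "y_sec"),
            "y_sec": ("e", "x", "y"),
        },
        "H": {"y": ("e",)},
    }[strategy]
    order = tuple(t for t in ("x", "y", "y_sec") if t in preds)
    return ImputationSpec(targets=order, predictors=preds, m=m, cycles=cycles, ridge=ridge)


def _pool_fits(
    strategy: str, fits: list[_Fit], names: tuple[str, ...], n_analysed: int
) -> StrategyResult:
    res = StrategyResult(strategy=strategy, n_analysed=n_analysed)
    good = [f for f in fits if f.converged]
    if len(good) < len(fits):
        res.converged = False
        res.reason = f"{len(fits) - len(good)} of {len(fits)} analysis fits failed"
    if len(good) < 2:
        res.converged = False
        res.reason = res.reason or "fewer than 2 analysable imputations"
        for p in names:
            res.estimates[p] = math.nan
            res.std_errors[p] = math.nan
            res.dfs[p] = math.nan
            res.ci_low[p] = math.nan
            res.ci_high[p] = math.nan
        return res
    for p in names:
        pooled = rubin_pool(
            [f.params[p] for f in good], [f.ses[p] ** 2 for f in good]
        )
        res.estimates[p] = pooled.qbar
        res.std_errors[p] = pooled.se
        res.dfs[p] = pooled.df
        res.ci_low[p] = pooled.ci_low
        res.ci_high[p] = pooled.ci_high
    return res


def run_strategy(
    strategy: str,
    amputed: AmputedDataset,
    m: int = 10,
    cycles: int = 10,
    ridge: float = 1e-6,
    rng: np.random.Generator | int | None = None,
) -> StrategyResult:
    """Evaluate one analysis strategy on an amputed dataset.

    Imputation failures (separation and the like) and analysis-model
    failures are reported via ``converged=False`` with a reason; they never
    raise.
    """
    if strategy not in STRATEGY_IDS:
        raise ValueError(f"strategy must be one of {STRATEGY_IDS}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    frame = amputed.masked_frame()

    if strategy == "A":
        cc = frame[frame["x"].notna() & frame["y"].notna()]
        return _single_fit_result("A", fit_substantive(cc))

    include_covariate = strategy != "H"
    names = _FULL_PARAMS if include_covariate else _MARGINAL_PARAMS

    if strategy in ("B", "C", "F"):
        work = frame[frame["y"].notna()].reset_index(drop=True)
        delete_mask = None
    elif strategy == "E":
        work = frame
        delete_mask = frame["y"].isna().to_numpy()
    else:  # D, G, H
        work = frame
        delete_mask = None

    n_analysed = int((~delete_mask).sum()) if delete_mask is not None else len(work)
    spec = _strategy_spec(strategy, m, cycles, ridge)
    # columns irrelevant to the strategy (e.g. y_sec outside F/G) are dropped
    needed = {"e", "y"} | set(spec.targets)
    for ps in spec.predictors.values():
        needed |= set(ps)
    if include_covariate:
        needed.add("x")
    cols = [c for c in ("x", "e", "y", "y_sec") if c in needed]
    try:
        stack = impute_chained(work[cols], spec, rng)
    except (ImputationError, ValueError) as exc:
        res = StrategyResult(
            strategy=strategy, converged=False,
            n_analysed=n_analysed, reason=f"imputation failed: {exc}",
        )
        for p in names:
            res.estimates[p] = math.nan
            res.std_errors[p] = math.nan
            res.dfs[p] = math.nan
            res.ci_low[p] = math.nan
            res.ci_high[p] = math.nan
        return res

    fits = []
    for df in stack.completed:
        sub = df[~delete_mask] if delete_mask is not None else df
        fits.append(fit_substantive(sub, include_covariate=include_covariate))
    return _pool_fits(strategy, fits, names, n_analysed)
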