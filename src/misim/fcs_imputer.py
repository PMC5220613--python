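"""Multiple imputation by chained equations with proper Bayesian draws.

Each incomplete variable gets a univariate conditional model — Bayesian
linear regression for continuous targets, maximum-likelihood logistic
regression with an approximate-posterior coefficient draw for binary ones.
Imputation is "proper": model parameters are drawn from their (approximate)
posterior before each predictive draw, so the between-imputation variance
reflects parameter uncertainty as Rubin's rules require.

The chained-equation scheme initialises missing cells by resampling
observed values, then cycles through the targets in a fixed visit order for
a set number of iterations; the whole procedure is repeated independently
``m`` times to produce a stack of completed datasets.  Conditional models
are main-effects only — deliberately simpler than a substantive model with
an interaction term, as is common in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ImputationSpec",
    "ImputedStack",
    "ImputationError",
    "draw_linear_imputation",
    "draw_logistic_imputation",
    "impute_chained",
]


class ImputationError(RuntimeError):
    """A conditional imputation model could not be fit (e.g. separation)."""


@dataclass(frozen=True)
class ImputationSpec:
    """Which variables to impute, from which predictors, and how often.

    ``targets`` fixes the visit order of the chained equations.  Every
    predictor of a target must be fully observed or itself a target.
    """

    targets: tuple[str, ...]
    predictors: Mapping[str, tuple[str, ...]]
    m: int = 10
    cycles: int = 10
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(
            self, "predictors", {k: tuple(v) for k, v in self.predictors.items()}
        )
        if self.m < 2:
            raise ValueError("m must be >= 2 (between-imputation variance)")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        missing = set(self.targets) - set(self.predictors)
        if missing:
            raise ValueError(f"no predictor set for targets: {sorted(missing)}")


@dataclass
class ImputedStack:
    """``m`` completed copies of an incomplete dataset plus diagnostics.

    ``diagnostics[var]`` is an ``(m, cycles)`` array of the mean imputed
    value of ``var`` after each cycle — a quick trace for assessing drift.
    """

    completed: list[pd.DataFrame]
    observed: pd.DataFrame
    diagnostics: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.completed)

    def to_long_frame(self) -> pd.DataFrame:
        frames = []
        for i, df in enumerate(self.completed):
            out = df.copy()
            out.insert(0, "row_id", np.arange(len(df)))
            out.insert(0, "imputation_index", i)
            frames.append(out)
        return pd.concat(frames, ignore_index=True)

    def to_long_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def _design(frame: pd.DataFrame, cols: Sequence[str], rows: np.ndarray) -> np.ndarray:
    mat = frame.loc[rows, list(cols)].to_numpy(float)
    return np.column_stack([np.ones(len(mat)), mat])


def draw_linear_imputation(
    y_obs: np.ndarray,
    x_obs: np.ndarray,
    x_mis: np.ndarray,
    rng: np.random.Generator,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Posterior-predictive draws for a continuous target.

    Fits least squares on the observed rows (ridge-stabilised normal
    equations), draws the residual variance from its scaled
    inverse-chi-squared posterior and the coefficients from their
    conditional normal posterior, then draws the missing values from the
    predictive normal.
    """
    if len(x_mis) == 0:
        return np.empty(0)
    n, p = x_obs.shape
    if n < p + 2:
        raise ImputationError(
            f"too few complete cases ({n}) for a {p}-parameter linear model"
        )
    xtx = x_obs.T @ x_obs + ridge * np.eye(p)
    try:
        beta_hat = np.linalg.solve(xtx, x_obs.T @ y_obs)
        resid = y_obs - x_obs @ beta_hat
        df = n - p
        sigma2 = float(resid @ resid) / rng.chisquare(df)
        cov = sigma2 * np.linalg.inv(xtx)
        beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    except np.linalg.LinAlgError as exc:  # singular even after ridge
        raise ImputationError("singular design in linear imputation") from exc
    return x_mis @ beta + rng.standard_normal(len(x_mis)) * np.sqrt(sigma2)


def draw_logistic_imputation(
    y_obs: np.ndarray,
    x_obs: np.ndarray,
    x_mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Approximate posterior-predictive draws for a binary target.

    Fits maximum-likelihood logistic regression on the observed rows, draws
    one coefficient vector from the asymptotic multivariate-normal
    approximation to the posterior, and draws missing values as Bernoulli
    with the implied probabilities.  Separation or non-convergence raises
    :class:`ImputationError` rather than being silently repaired.
    """
    if len(x_mis) == 0:
        return np.empty(0)
    classes = np.unique(y_obs)
    if len(classes) < 2:
        raise ImputationError("observed rows contain a single outcome class")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y_obs, x_obs).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
        raise ImputationError(f"logistic imputation model failed: {exc}") from exc
    if (
        not converged
        or not np.all(np.isfinite(params))
        or not np.all(np.isfinite(cov))
        or np.max(np.abs(params)) > 40.0
    ):
        raise ImputationError("logistic imputation model did not converge")
    try:
        beta = rng.multivariate_normal(params, cov, method="cholesky")
    except np.linalg.LinAlgError:
        beta = rng.multivariate_normal(params, cov, method="svd")
    prob = special.expit(x_mis @ beta)
    return (rng.random(len(x_mis)) < prob).astype(float)


def _is_binary(values: np.ndarray) -> bool:
    return bool(np.isin(values, (0.0, 1.0)).all())


def impute_chained(
    frame: pd.DataFrame,
    spec: ImputationSpec,
    rng: np.random.Generator | int | None = None,
) -> ImputedStack:
    """Run chained-equations multiple imputation on a masked data frame.

    ``frame`` holds NaN for missing cells.  Binary targets are recognised
    by their observed values being a subset of {0, 1}.  Observed cells are
    never altered; the ``m`` completed copies differ only in the imputed
    cells.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    observed = frame.notna()
    for tgt in spec.targets:
        for pred in spec.predictors[tgt]:
            if pred not in spec.targets and not observed[pred].all():
                raise ValueError(
                    f"predictor {pred!r} of {tgt!r} has missing values but is "
                    "not itself an imputation target"
                )

    miss_rows = {t: (~observed[t]).to_numpy() for t in spec.targets}
    obs_vals = {t: frame.loc[observed[t], t].to_numpy(float) for t in spec.targets}
    binary = {t: _is_binary(obs_vals[t]) for t in spec.targets}
    active = [t for t in spec.targets if miss_rows[t].any()]

    completed: list[pd.DataFrame] = []
    diagnostics = {
        t: np.full((spec.m, spec.cycles), np.nan) for t in active
    }
    for i in range(spec.m):
        work = frame.copy()
        for t in active:
            if len(obs_vals[t]) == 0:
                raise ImputationError(f"target {t!r} has no observed values")
            init = rng.choice(obs_vals[t], size=int(miss_rows[t].sum()), replace=True)
            work.loc[miss_rows[t], t] = init
        for cycle in range(spec.cycles):
            for t in active:
                preds = spec.predictors[t]
                obs = ~miss_rows[t]
                x_obs = _design(work, preds, obs)
                x_mis = _design(work, preds, miss_rows[t])
                y_obs = work.loc[obs, t].to_numpy(float)
                if binary[t]:
                    drawn = draw_logistic_imputation(y_obs, x_obs, x_mis, rng)
                else:
                    drawn = draw_linear_imputation(
                        y_obs, x_obs, x_mis, rng, ridge=spec.ridge
                    )
                work.loc[miss_rows[t], t] = drawn
                diagnostics[t][i, cycle] = float(np.mean(drawn))
        completed.append(work)
    return ImputedStack(completed=completed, observed=observed, diagnostics=diagnostics)
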