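"""Synthetic cohort generator with a known exposure-confounder-outcome structure.

The data-generating process produces, for each of ``n`` subjects:

* ``X``  — a standard-normal continuous confounder,
* ``E``  — a binary exposure obtained by dichotomising a latent standard
  normal correlated with ``X``, so that the *Pearson* (point-biserial)
  correlation between ``X`` and ``E`` hits a stated target,
* ``Y``  — a binary outcome from the logistic model
  ``logit Pr(Y=1) = beta0 + beta1*E + beta2*X + beta3*E*X``,
* ``Y'`` — a secondary binary outcome drawn conditionally on ``Y`` alone,
  with conditional probabilities calibrated so that the tetrachoric
  correlation between ``Y`` and ``Y'`` and the marginal ``Pr(Y'=1)`` hit
  stated targets.  By construction ``Y'`` is independent of ``(X, E)``
  given ``Y``.

The default effect sizes are odds ratios 2 (exposure), 1.5 (confounder)
and 1.2 (interaction).  The intercept is calibrated numerically so that
``Pr(Y=1 | E=0) = 0.091`` once the confounder shift within exposure groups
is accounted for; this implies ``Pr(Y=1 | E=1) ~= 0.233`` and a marginal
outcome prevalence of ~0.162.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import integrate, optimize, stats

__all__ = [
    "DGPConfig",
    "CompleteDataset",
    "CalibrationError",
    "latent_corr_for_point_biserial",
    "calibrate_secondary_conditionals",
    "calibrate_intercept",
    "outcome_prevalence_given_exposure",
    "tetrachoric_corr",
    "generate_complete",
    "TRUE_LOG_ODDS_RATIOS",
]

#: True log-odds-ratio parameters of the substantive model; the Monte-Carlo
#: metrics score every strategy against these.
TRUE_LOG_ODDS_RATIOS = {
    "beta1": math.log(2.0),
    "beta2": math.log(1.5),
    "beta3": math.log(1.2),
}


class CalibrationError(ValueError):
    """A requested correlation / margin combination is not attainable."""


# ---------------------------------------------------------------------------
# latent-normal calibration helpers
# ---------------------------------------------------------------------------

def latent_corr_for_point_biserial(target_corr: float, p_exposure: float) -> float:
    """Latent bivariate-normal correlation giving a target point-biserial one.

    ``E = 1{L > z}`` with ``(X, L)`` standard bivariate normal with
    correlation ``r`` and ``z`` the upper-``p_exposure`` quantile.  Then
    ``corr(X, E) = r * phi(z) / sqrt(p(1-p))``, so the latent correlation is
    ``r = target * sqrt(p(1-p)) / phi(z)``.

    Raises
    ------
    CalibrationError
        If the target exceeds the attainable point-biserial bound
        ``phi(z)/sqrt(p(1-p))`` (attained at ``r = 1``).
    """
    if not 0.0 < p_exposure < 1.0:
        raise ValueError("p_exposure must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - p_exposure)
    bound = stats.norm.pdf(z) / math.sqrt(p_exposure * (1.0 - p_exposure))
    if abs(target_corr) >= bound:
        raise CalibrationError(
            f"point-biserial correlation {target_corr} not attainable for "
            f"Pr(E=1)={p_exposure} (bound {bound:.4f})"
        )
    return target_corr * math.sqrt(p_exposure * (1.0 - p_exposure)) / stats.norm.pdf(z)


def _bvn_upper_tail(h: float, k: float, rho: float) -> float:
    """Pr(Z1 > h, Z2 > k) for standard bivariate normal with correlation rho.

    Computed as ``int_h^inf phi(x) * Phibar((k - rho x)/sqrt(1-rho^2)) dx``,
    which stays stable arbitrarily close to ``rho = +/-1`` (where the frozen
    bivariate normal is singular).
    """
    if rho >= 1.0 - 1e-12:
        return float(stats.norm.sf(max(h, k)))
    if rho <= -1.0 + 1e-12:
        return float(max(0.0, stats.norm.sf(h) - stats.norm.cdf(k)))
    s = math.sqrt(1.0 - rho * rho)

    def integrand(x):
        return stats.norm.pdf(x) * stats.norm.sf((k - rho * x) / s)

    val, _ = integrate.quad(integrand, h, 9.0 + abs(h), limit=200)
    return float(val)


def calibrate_secondary_conditionals(
    rho_sec: float, p_y: float, p_sec_marginal: float
) -> tuple[float, float]:
    """Conditional probabilities ``(Pr(Y'=1|Y=1), Pr(Y'=1|Y=0))``.

    Chooses the 2x2 distribution of ``(Y, Y')`` with the given margins whose
    tetrachoric correlation equals ``rho_sec``: the joint cell
    ``Pr(Y=1, Y'=1)`` is the upper-orthant probability of a bivariate normal
    with correlation ``rho_sec`` and thresholds set by the margins.

    Raises
    ------
    CalibrationError
        If the implied conditionals fall outside [0, 1] (infeasible margins).
    """
    for p, name in ((p_y, "p_y"), (p_sec_marginal, "p_sec_marginal")):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    if not -1.0 <= rho_sec <= 1.0:
        raise ValueError("rho_sec must lie in [-1, 1]")
    h = stats.norm.ppf(1.0 - p_y)
    k = stats.norm.ppf(1.0 - p_sec_marginal)
    p11 = _bvn_upper_tail(h, k, rho_sec)
    p1 = p11 / p_y
    p0 = (p_sec_marginal - p11) / (1.0 - p_y)
    eps = 1e-12
    if not (-eps <= p1 <= 1.0 + eps and -eps <= p0 <= 1.0 + eps):
        raise CalibrationError(
            f"tetrachoric rho={rho_sec} infeasible for margins "
            f"({p_y}, {p_sec_marginal})"
        )
    return float(np.clip(p1, 0.0, 1.0)), float(np.clip(p0, 0.0, 1.0))


def tetrachoric_corr(y: np.ndarray, y_sec: np.ndarray, tol: float = 1e-8) -> float:
    """Maximum-likelihood tetrachoric correlation of two binary vectors.

    Inverts the bivariate-normal model with thresholds fixed at the observed
    margins, solving for the latent correlation whose implied
    ``Pr(Y=1, Y'=1)`` matches the observed joint cell (root-finding to
    ``tol``).
    """
    y = np.asarray(y)
    y_sec = np.asarray(y_sec)
    p_y = y.mean()
    p_q = y_sec.mean()
    p11 = float(np.mean((y == 1) & (y_sec == 1)))
    if not (0.0 < p_y < 1.0 and 0.0 < p_q < 1.0):
        raise ValueError("both margins must be non-degenerate")
    h = stats.norm.ppf(1.0 - p_y)
    k = stats.norm.ppf(1.0 - p_q)

    def cell(rho: float) -> float:
        return _bvn_upper_tail(h, k, rho) - p11

    lo, hi = -1.0 + 1e-10, 1.0 - 1e-10
    if cell(lo) > 0 or cell(hi) < 0:  # boundary cases (empty / full cell)
        return -1.0 if cell(lo) > 0 else 1.0
    return float(optimize.brentq(cell, lo, hi, xtol=tol))


# ---------------------------------------------------------------------------
# intercept calibration
# ---------------------------------------------------------------------------

def _conditional_x_weight(x, e, latent_r, z):
    """Density ratio f(x | E=e) / phi(x) under the dichotomised-latent model."""
    s = math.sqrt(1.0 - latent_r**2)
    if e == 1:
        return stats.norm.sf((z - latent_r * x) / s)
    return stats.norm.cdf((z - latent_r * x) / s)


def outcome_prevalence_given_exposure(
    beta0: float,
    beta1: float,
    beta2: float,
    beta3: float,
    corr_xe: float,
    p_exposure: float,
    exposed: bool,
) -> float:
    """``Pr(Y=1 | E=e)`` under the model, by quadrature over ``X | E=e``."""
    r = latent_corr_for_point_biserial(corr_xe, p_exposure)
    z = stats.norm.ppf(1.0 - p_exposure)
    e = 1 if exposed else 0
    denom = p_exposure if exposed else 1.0 - p_exposure
    slope = beta2 + beta3 * e
    const = beta0 + beta1 * e

    def integrand(x):
        w = _conditional_x_weight(x, e, r, z) / denom
        return stats.norm.pdf(x) * w / (1.0 + np.exp(-(const + slope * x)))

    val, _ = integrate.quad(integrand, -9.0, 9.0, limit=200)
    return float(val)


def calibrate_intercept(
    beta1: float,
    beta2: float,
    beta3: float,
    corr_xe: float,
    p_exposure: float,
    target_p_unexposed: float = 0.091,
) -> float:
    """Intercept ``beta0`` such that ``Pr(Y=1 | E=0)`` equals its target.

    The confounder is shifted within exposure groups (mean ``-0.4`` among the
    unexposed under the defaults), so the intercept that achieves a stated
    baseline outcome probability differs from ``logit`` of that probability;
    it is found by root-finding on the quadrature expression.
    """

    def f(b0):
        return (
            outcome_prevalence_given_exposure(
                b0, beta1, beta2, beta3, corr_xe, p_exposure, exposed=False
            )
            - target_p_unexposed
        )

    return float(optimize.brentq(f, -20.0, 10.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# configuration and dataset containers
# ---------------------------------------------------------------------------

@dataclass
class DGPConfig:
    """Parameters of the data-generating process.

    ``beta0=None`` (the default) requests calibration of the intercept so
    that ``Pr(Y=1 | E=0) = p_y_unexposed`` exactly; pass an explicit value to
    bypass calibration.  ``p_sec_marginal=None`` defaults the marginal
    ``Pr(Y'=1)`` to the model's own marginal outcome prevalence.
    """

    n: int = 1000
    beta0: Optional[float] = None
    beta1: float = TRUE_LOG_ODDS_RATIOS["beta1"]
    beta2: float = TRUE_LOG_ODDS_RATIOS["beta2"]
    beta3: float = TRUE_LOG_ODDS_RATIOS["beta3"]
    corr_xe: float = 0.4
    p_exposure: float = 0.5
    rho_sec: float = 0.49
    p_sec_marginal: Optional[float] = None
    p_y_unexposed: float = 0.091
    seed: Optional[int] = None
    # derived, filled in __post_init__
    p_y_marginal: float = field(init=False, repr=False, default=float("nan"))
    latent_corr: float = field(init=False, repr=False, default=float("nan"))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be a positive integer")
        for p, name in (
            (self.p_exposure, "p_exposure"),
            (self.p_y_unexposed, "p_y_unexposed"),
        ):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not -1.0 < self.corr_xe < 1.0:
            raise ValueError("corr_xe must lie in (-1, 1)")
        if not -1.0 <= self.rho_sec <= 1.0:
            raise ValueError("rho_sec must lie in [-1, 1]")
        self.latent_corr = latent_corr_for_point_biserial(
            self.corr_xe, self.p_exposure
        )
        if self.beta0 is None:
            self.beta0 = calibrate_intercept(
                self.beta1,
                self.beta2,
                self.beta3,
                self.corr_xe,
                self.p_exposure,
                self.p_y_unexposed,
            )
        p0 = outcome_prevalence_given_exposure(
            self.beta0, self.beta1, self.beta2, self.beta3,
            self.corr_xe, self.p_exposure, exposed=False,
        )
        p1 = outcome_prevalence_given_exposure(
            self.beta0, self.beta1, self.beta2, self.beta3,
            self.corr_xe, self.p_exposure, exposed=True,
        )
        self.p_y_marginal = (
            self.p_exposure * p1 + (1.0 - self.p_exposure) * p0
        )
        if self.p_sec_marginal is None:
            self.p_sec_marginal = self.p_y_marginal
        elif not 0.0 < self.p_sec_marginal < 1.0:
            raise ValueError("p_sec_marginal must lie in (0, 1)")

    def with_n(self, n: int) -> "DGPConfig":
        return replace(self, n=n)

    # -- serialisation -----------------------------------------------------

    _YAML_FIELDS = (
        "n", "beta0", "beta1", "beta2", "beta3", "corr_xe", "p_exposure",
        "rho_sec", "p_sec_marginal", "p_y_unexposed", "seed",
    )

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = {k: getattr(self, k) for k in self._YAML_FIELDS}
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "DGPConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = yaml.safe_load(text) or {}
        return cls(**{k: v for k, v in payload.items() if k in cls._YAML_FIELDS})


@dataclass
class CompleteDataset:
    """A generated cohort with its true parameters attached."""

    x: np.ndarray
    e: np.ndarray
    y: np.ndarray
    y_sec: np.ndarray
    config: DGPConfig

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.e) == len(self.y) == len(self.y_sec) == n):
            raise ValueError("all columns must have identical length")
        for name in ("e", "y", "y_sec"):
            v = getattr(self, name)
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"{name} must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "e": self.e, "y": self.y, "y_sec": self.y_sec}
        )

    def to_csv(self, path: str | Path, config_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if config_path is not None:
            self.config.to_yaml(config_path)

    @classmethod
    def from_csv(cls, path: str | Path, config: DGPConfig | str | Path) -> "CompleteDataset":
        df = pd.read_csv(path)
        if not isinstance(config, DGPConfig):
            config = DGPConfig.from_yaml(config)
        return cls(
            x=df["x"].to_numpy(float),
            e=df["e"].to_numpy(int),
            y=df["y"].to_numpy(int),
            y_sec=df["y_sec"].to_numpy(int),
            config=config,
        )


def generate_complete(
    config: DGPConfig, rng: np.random.Generator | int | None = None
) -> CompleteDataset:
    """Draw one complete cohort from the data-generating process.

    The draw order (latent exposure, confounder residual, outcome uniforms,
    secondary-outcome uniforms) is fixed, so a given ``(config, seed)`` pair
    is bit-reproducible.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    n = config.n
    r = config.latent_corr
    z = stats.norm.ppf(1.0 - config.p_exposure)

    latent = rng.standard_normal(n)
    resid = rng.standard_normal(n)
    x = r * latent + math.sqrt(1.0 - r * r) * resid
    e = (latent > z).astype(np.int8)

    eta = (
        config.beta0
        + config.beta1 * e
        + config.beta2 * x
        + config.beta3 * e * x
    )
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)

    p1, p0 = calibrate_secondary_conditionals(
        config.rho_sec, config.p_y_marginal, config.p_sec_marginal
    )
    y_sec = (rng.random(n) < np.where(y == 1, p1, p0)).astype(np.int8)
    return CompleteDataset(x=x, e=e, y=y, y_sec=y_sec, config=config)
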