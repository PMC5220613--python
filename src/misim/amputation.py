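"""Calibrated amputation: imposing MCAR/MAR/MNAR missingness on complete data.

Missingness is imposed independently on the confounder ``X``, the outcome
``Y`` and the secondary outcome ``Y'``; the exposure ``E`` is always fully
observed.  Each variable is masked by an independent Bernoulli draw whose
probability depends on the mechanism:

* MCAR — a constant, equal to the target level;
* MAR  — logistic in the exposure, odds ratio ``or_missing`` (default 5)
  for exposed versus unexposed;
* MNAR — logistic in the variable's *own true value*: per exposure-group
  analogue for the binary outcomes, and per standard-deviation unit of ``X``
  for the confounder.

In every case the intercept is calibrated so the *marginal* expected
missingness equals the target level exactly (root-finding to ~1e-14;
Gauss-Hermite quadrature over the standard-normal confounder for MNAR-X).
Masked values are retained internally so that simulation metrics can score
against the truth; analysis strategies only ever see the masked view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dgp import CompleteDataset

__all__ = [
    "MECHANISMS",
    "MissingnessConfig",
    "AmputedDataset",
    "calibrate_mar_intercept",
    "calibrate_mnar_intercept",
    "apply_missingness",
]

MECHANISMS = ("MCAR", "MAR", "MNAR")

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(96)


@dataclass(frozen=True)
class MissingnessConfig:
    """Mechanism, target marginal level per variable, and missingness OR.

    ``level=0`` is allowed as a degenerate no-missingness setting (useful as
    a null scenario); otherwise levels lie in ``(0, 1)``.
    """

    mechanism: str
    level: float
    or_missing: float = 5.0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 <= self.level < 1.0:
            raise ValueError("level must lie in [0, 1)")
        if self.or_missing <= 0:
            raise ValueError("or_missing must be positive")


def calibrate_mar_intercept(
    level: float, or_missing: float, p_driver: float
) -> float:
    """Logistic intercept for missingness driven by a binary variable.

    Solves ``(1-p)*expit(a) + p*expit(a + log OR) = level`` for ``a``; the
    left side is strictly increasing in ``a`` so the root is unique.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if not 0.0 <= p_driver <= 1.0:
        raise ValueError("p_driver must lie in [0, 1]")
    log_or = math.log(or_missing)

    def expected(a: float) -> float:
        return (
            (1.0 - p_driver) * special.expit(a)
            + p_driver * special.expit(a + log_or)
            - level
        )

    return float(optimize.brentq(expected, -60.0, 60.0, xtol=1e-14))


def calibrate_mnar_intercept(
    level: float,
    or_missing: float,
    driver: str = "continuous",
    prevalence: Optional[float] = None,
) -> float:
    """Logistic intercept for missingness driven by the value itself.

    ``driver="binary"`` needs the driver's prevalence and reduces to
    :func:`calibrate_mar_intercept`.  ``driver="continuous"`` assumes a
    standard-normal driver with odds ratio ``or_missing`` per 1-SD unit and
    calibrates ``E[expit(a + log(OR) * X)] = level`` by Gauss-Hermite
    quadrature.
    """
    if driver == "binary":
        if prevalence is None:
            raise ValueError("binary driver requires its prevalence")
        return calibrate_mar_intercept(level, or_missing, prevalence)
    if driver != "continuous":
        raise ValueError("driver must be 'continuous' or 'binary'")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    log_or = math.log(or_missing)
    x = _GH_NODES * math.sqrt(2.0)
    w = _GH_WEIGHTS / math.sqrt(math.pi)

    def expected(a: float) -> float:
        return float(w @ special.expit(a + log_or * x)) - level

    return float(optimize.brentq(expected, -80.0, 80.0, xtol=1e-14))


@dataclass
class AmputedDataset:
    """Complete data plus missingness masks (``True`` = missing).

    The exposure carries no mask by construction.  ``masked_frame`` is the
    view the analysis strategies receive: masked cells are NaN, the truth is
    only reachable through ``data``.
    """

    data: CompleteDataset
    miss_x: np.ndarray
    miss_y: np.ndarray
    miss_ysec: np.ndarray
    config: MissingnessConfig

    def __post_init__(self) -> None:
        n = self.data.n
        for name in ("miss_x", "miss_y", "miss_ysec"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if len(m) != n:
                raise ValueError(f"{name} must have length n={n}")
            setattr(self, name, m)

    @property
    def n(self) -> int:
        return self.data.n

    def masked_frame(self) -> pd.DataFrame:
        df = self.data.to_frame().astype(
            {"x": float, "y": float, "y_sec": float}
        )
        df.loc[self.miss_x, "x"] = np.nan
        df.loc[self.miss_y, "y"] = np.nan
        df.loc[self.miss_ysec, "y_sec"] = np.nan
        return df

    def realized_levels(self) -> dict[str, float]:
        return {
            "x": float(self.miss_x.mean()),
            "y": float(self.miss_y.mean()),
            "y_sec": float(self.miss_ysec.mean()),
        }

    def to_csv(self, path: str | Path, masks_path: str | Path | None = None) -> None:
        self.masked_frame().to_csv(path, index=False)
        if masks_path is not None:
            pd.DataFrame(
                {
                    "miss_x": self.miss_x.astype(int),
                    "miss_y": self.miss_y.astype(int),
                    "miss_ysec": self.miss_ysec.astype(int),
                }
            ).to_csv(masks_path, index=False)


def _missingness_probabilities(
    data: CompleteDataset, config: MissingnessConfig
) -> dict[str, np.ndarray]:
    """Per-row missingness probability for each of x, y, y_sec."""
    n = data.n
    level, orm = config.level, config.or_missing
    if level == 0.0:
        zero = np.zeros(n)
        return {"x": zero, "y": zero, "y_sec": zero}
    if config.mechanism == "MCAR":
        flat = np.full(n, level)
        return {"x": flat, "y": flat, "y_sec": flat}
    log_or = math.log(orm)
    if config.mechanism == "MAR":
        a = calibrate_mar_intercept(level, orm, data.config.p_exposure)
        p = special.expit(a + log_or * data.e)
        return {"x": p, "y": p, "y_sec": p}
    # MNAR: each variable driven by its own true value
    a_x = calibrate_mnar_intercept(level, orm, "continuous")
    a_y = calibrate_mnar_intercept(
        level, orm, "binary", prevalence=data.config.p_y_marginal
    )
    a_q = calibrate_mnar_intercept(
        level, orm, "binary", prevalence=data.config.p_sec_marginal
    )
    return {
        "x": special.expit(a_x + log_or * data.x),
        "y": special.expit(a_y + log_or * data.y),
        "y_sec": special.expit(a_q + log_or * data.y_sec),
    }


def apply_missingness(
    data: CompleteDataset,
    config: MissingnessConfig,
    rng: np.random.Generator | int | None = None,
) -> AmputedDataset:
    """Draw independent missingness masks for X, Y and Y'; E stays observed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    probs = _missingness_probabilities(data, config)
    masks = {k: rng.random(data.n) < p for k, p in probs.items()}
    return AmputedDataset(
        data=data,
        miss_x=masks["x"],
        miss_y=masks["y"],
        miss_ysec=masks["y_sec"],
        config=config,
    )
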