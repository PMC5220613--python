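"""Orchestration of the full factorial simulation.

A scenario is a (mechanism, level, cohort size) cell; within each scenario
``R`` replications are drawn, and every requested strategy is evaluated on
the *same* amputed dataset per replication (paired comparison, which
removes dataset-to-dataset Monte-Carlo noise from between-strategy
contrasts).

Seeding is counter-based: the substream for a replication is derived from
``(base_seed, mechanism, level, n, replication_index)``, so any cell can be
recomputed in isolation and the results are invariant to the worker count
and execution order.  Each replication splits its stream into named
substreams for generation, amputation and imputation, so the strategies
within a replication see identical data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .amputation import MECHANISMS, MissingnessConfig, apply_missingness
from .dgp import DGPConfig, generate_complete
from .metrics import summarize_replications
from .strategies import STRATEGY_IDS, run_strategy

__all__ = ["ScenarioGrid", "replication_seed", "run_replication", "run_grid",
           "performance_table"]

logger = logging.getLogger("misim")

_MECH_CODE = {m: i for i, m in enumerate(MECHANISMS)}


@dataclass(frozen=True)
class ScenarioGrid:
    """The factorial design: mechanisms x levels x sizes x strategies x R."""

    mechanisms: tuple[str, ...] = MECHANISMS
    levels: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    sizes: tuple[int, ...] = (1000, 10000)
    strategies: tuple[str, ...] = STRATEGY_IDS
    replications: int = 1000
    base_seed: int = 0
    workers: int = 1
    m: int = 10
    cycles: int = 10
    or_missing: float = 5.0

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        unknown = set(self.strategies) - set(STRATEGY_IDS)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")
        unknown = set(self.mechanisms) - set(MECHANISMS)
        if unknown:
            raise ValueError(f"unknown mechanisms: {sorted(unknown)}")

    @property
    def scenarios(self) -> list[tuple[str, float, int]]:
        return [
            (mech, lvl, n)
            for mech in self.mechanisms
            for lvl in self.levels
            for n in self.sizes
        ]


def replication_seed(
    base_seed: int, mechanism: str, level: float, n: int, rep: int
) -> np.random.SeedSequence:
    """Deterministic seed for one (scenario, replication) cell."""
    return np.random.SeedSequence(
        entropy=(base_seed, _MECH_CODE[mechanism], int(round(level * 10_000)), n, rep)
    )


def run_replication(
    dgp_config: DGPConfig,
    mechanism: str,
    level: float,
    rep: int,
    base_seed: int = 0,
    strategies: tuple[str, ...] = STRATEGY_IDS,
    m: int = 10,
    cycles: int = 10,
    or_missing: float = 5.0,
) -> list[dict]:
    """Generate, ampute and analyse one replication; never raises on
    strategy-level failures (they surface as ``converged=False`` rows)."""
    ss = replication_seed(base_seed, mechanism, level, dgp_config.n, rep)
    gen_ss, amp_ss, imp_ss = ss.spawn(3)
    data = generate_complete(dgp_config, np.random.default_rng(gen_ss))
    amputed = apply_missingness(
        data,
        MissingnessConfig(mechanism=mechanism, level=level, or_missing=or_missing),
        np.random.default_rng(amp_ss),
    )
    rows: list[dict] = []
    # one imputation substream per strategy, derived deterministically
    strat_streams = imp_ss.spawn(len(STRATEGY_IDS))
    for sid in strategies:
        rng = np.random.default_rng(strat_streams[STRATEGY_IDS.index(sid)])
        result = run_strategy(sid, amputed, m=m, cycles=cycles, rng=rng)
        rows.extend(
            result.to_rows(
                replication=rep, mechanism=mechanism, level=level, n=dgp_config.n
            )
        )
    return rows


def run_grid(
    grid: ScenarioGrid, dgp_config: DGPConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the whole grid; returns (replication-level table, metrics table)."""
    if dgp_config is None:
        dgp_config = DGPConfig()
    all_rows: list[dict] = []
    for mech, lvl, n in grid.scenarios:
        cfg = dgp_config.with_n(n)
        tasks = (
            delayed(run_replication)(
                cfg, mech, lvl, rep,
                base_seed=grid.base_seed, strategies=grid.strategies,
                m=grid.m, cycles=grid.cycles, or_missing=grid.or_missing,
            )
            for rep in range(grid.replications)
        )
        chunks = Parallel(n_jobs=grid.workers)(tasks)
        scen_rows = [row for chunk in chunks for row in chunk]
        all_rows.extend(scen_rows)
        n_fail = sum(1 for r in scen_rows if not r["converged"]) // max(
            1, len({r["parameter"] for r in scen_rows})
        )
        logger.info(
            "scenario %s level=%.0f%% n=%d: %d replications, ~%d non-converged "
            "strategy runs", mech, 100 * lvl, n, grid.replications, n_fail,
        )
    reps_df = pd.DataFrame(all_rows)
    metrics_df = summarize_replications(reps_df)
    return reps_df, metrics_df


_METRIC_ORDER = ("mean_bias", "mean_abs_error", "coverage", "power")


def performance_table(
    metrics: pd.DataFrame, n: int, parameter: str = "beta1"
) -> pd.DataFrame:
    """Reshape a metrics table into the study's presentation layout.

    One row per (mechanism, metric, missingness level), one column per
    strategy — the layout of the published performance tables.
    """
    sub = metrics[(metrics["n"] == n) & (metrics["parameter"] == parameter)]
    if sub.empty:
        raise ValueError(f"no metrics rows for n={n}, parameter={parameter}")
    long = sub.melt(
        id_vars=["mechanism", "level", "strategy"],
        value_vars=list(_METRIC_ORDER),
        var_name="metric",
    )
    wide = long.pivot_table(
        index=["mechanism", "metric", "level"],
        columns="strategy",
        values="value",
    ).reset_index()
    wide["metric"] = pd.Categorical(wide["metric"], categories=_METRIC_ORDER, ordered=True)
    wide["mechanism"] = pd.Categorical(wide["mechanism"], categories=MECHANISMS, ordered=True)
    wide = wide.sort_values(["mechanism", "metric", "level"]).reset_index(drop=True)
    wide.columns.name = None
    return wide
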