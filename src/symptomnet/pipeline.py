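"""End-to-end orchestration: polychoric -> networks -> centrality (-> stability, invariance)."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    DirectedNetwork,
    InvarianceResult,
    ItemResponseTable,
    PipelineConfig,
    PolychoricResult,
    StabilityResult,
    UndirectedNetwork,
)
from .centrality import centrality_table, z_transform
from .glasso import fit_undirected
from .invariance import invariance_report
from .polychoric import correlation_matrix
from .stability import case_drop_bootstrap
from .tmfg import fit_directed

log = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    config: PipelineConfig
    polychoric: PolychoricResult
    undirected: UndirectedNetwork
    directed: DirectedNetwork
    centrality: pd.DataFrame
    stability: Optional[StabilityResult] = None
    invariance: Optional[InvarianceResult] = None
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        """Deterministic JSON rendering of the numeric results."""
        payload: dict = {
            "seed": self.config.seed,
            "config": {
                "item_columns": list(self.config.item_columns),
                "group_column": self.config.group_column,
                "ebic_gamma": self.config.ebic_gamma,
                "lambda_count": self.config.lambda_count,
                "lambda_min_ratio": self.config.lambda_min_ratio,
                "bootstrap_reps": self.config.bootstrap_reps,
                "retention_levels": list(self.config.retention_levels),
                "missing_policy": self.config.missing_policy,
            },
            "polychoric": {
                "items": self.polychoric.items,
                "rho": self.polychoric.rho.tolist(),
                "smoothed": self.polychoric.smoothed,
            },
            "undirected": {
                "lambda_selected": self.undirected.lambda_selected,
                "n_edges": self.undirected.n_edges,
                "weights": self.undirected.weights.tolist(),
            },
            "directed": {
                "skeleton": [list(e) for e in self.directed.skeleton],
                "dependency": self.directed.dependency.tolist(),
            },
            "centrality": self.centrality.to_dict(orient="records"),
        }
        if self.stability is not None:
            payload["stability"] = {
                "reps": self.stability.reps,
                "correlations": self.stability.correlations.to_dict(),
                "failures": {str(k): v for k, v in self.stability.failures.items()},
            }
        if self.invariance is not None:
            payload["invariance"] = {
                "group_column": self.invariance.group_column,
                "group_sizes": self.invariance.group_sizes,
                "tests": self.invariance.tests.reset_index().to_dict(orient="records"),
            }
        return json.dumps(payload, indent=indent, sort_keys=True)


def run_pipeline(
    table: ItemResponseTable,
    config: PipelineConfig | None = None,
    with_stability: bool = False,
    with_invariance: bool | None = None,
    stability_reps: int | None = None,
) -> PipelineReport:
    """Run the estimation chain on a validated response table.

    Always runs polychoric estimation, the EBIC-glasso undirected network,
    the dependency-TMFG directed network and the centrality table; the
    case-dropping bootstrap and group-invariance stages run on request
    (invariance defaults to on when ``config.group_column`` is set).
    Deterministic given (table, config): every stochastic stage derives its
    randomness from ``config.seed``.
    """
    config = config or PipelineConfig()
    if with_invariance is None:
        with_invariance = config.group_column is not None
    timings: dict[str, float] = {}

    def timed(stage: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        timings[stage] = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs", stage, timings[stage])
        return out

    poly = timed("polychoric", lambda: correlation_matrix(table))
    log.info("polychoric: %d items, n=%d", poly.n_items, table.n)
    undirected = timed(
        "glasso_ebic",
        lambda: fit_undirected(
            poly,
            n=table.n,
            gamma=config.ebic_gamma,
            lambda_count=config.lambda_count,
            lambda_min_ratio=config.lambda_min_ratio,
        ),
    )
    directed = timed("tmfg_directed", lambda: fit_directed(poly))
    cent = timed("centrality", lambda: z_transform(centrality_table(directed)))

    stability = None
    if with_stability:
        stability = timed(
            "stability",
            lambda: case_drop_bootstrap(
                table,
                config,
                reps=stability_reps if stability_reps is not None else config.bootstrap_reps,
                seed=config.seed,
            ),
        )
    invariance = None
    if with_invariance:
        if config.group_column is None:
            raise ValueError("with_invariance requires config.group_column")
        invariance = timed(
            "invariance", lambda: invariance_report(table, config.group_column, config)
        )
    return PipelineReport(
        config=config,
        polychoric=poly,
        undirected=undirected,
        directed=directed,
        centrality=cent,
        stability=stability,
        invariance=invariance,
        timings=timings,
    )
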