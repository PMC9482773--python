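"""Case-dropping bootstrap for centrality-index stability.

Subsamples retaining a fixed fraction of respondents are drawn without
replacement; the whole estimation chain (polychoric correlations ->
dependency-TMFG -> centrality) is re-run on each, the per-node index values
are averaged over replications, and the Spearman rank correlation between
those averages and the full-sample values is reported per index and
retention level.  A rank-mean variant (average the per-replication ranks,
then correlate) is emitted alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ItemResponseTable, PipelineConfig, StabilityResult
from .centrality import centrality_table
from .polychoric import correlation_matrix
from .tmfg import fit_directed

INDEX_NAMES = ["in_strength", "out_strength", "betweenness", "closeness"]


def _indices_for(table: ItemResponseTable) -> pd.DataFrame:
    net = fit_directed(correlation_matrix(table))
    cent = centrality_table(net, sort=False).set_index("symptom")
    return cent[INDEX_NAMES]


def case_drop_bootstrap(
    table: ItemResponseTable,
    config: PipelineConfig | None = None,
    retention_levels=None,
    reps: int | None = None,
    seed: int | None = None,
) -> StabilityResult:
    """Stability of centrality rankings under case dropping.

    For each retention level q, draws ``reps`` subsamples of floor(q*N)
    respondents without replacement (each replication seeded independently
    from the master seed), re-estimates the directed network and its
    centrality indices, and correlates the across-replication mean values
    (Spearman) with the full-sample values.  q = 1.0 reproduces the full
    sample exactly, so every correlation is 1.
    """
    config = config or PipelineConfig()
    levels = tuple(retention_levels) if retention_levels is not None else config.retention_levels
    reps = int(reps) if reps is not None else config.bootstrap_reps
    seed = int(seed) if seed is not None else config.seed

    full = _indices_for(table)
    nodes = full.index
    n = table.n
    result_warnings: list[str] = []

    corr = pd.DataFrame(index=INDEX_NAMES, columns=list(levels), dtype=float)
    corr_rank = pd.DataFrame(index=INDEX_NAMES, columns=list(levels), dtype=float)
    failures: dict[float, int] = {}

    for qi, q in enumerate(levels):
        m = int(np.floor(q * n))
        if m < 50:
            result_warnings.append(
                f"retention {q}: subsample size {m} < 50; estimates may be unstable"
            )
        sums = np.zeros((len(nodes), len(INDEX_NAMES)))
        rank_sums = np.zeros_like(sums)
        n_ok = 0
        for r in range(reps):
            rng = np.random.default_rng([seed, qi, r])
            rows = rng.choice(n, size=m, replace=False)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sub = _indices_for(table.subset(rows))
            except Exception:
                continue
            if not sub.index.equals(nodes):
                continue  # an item went degenerate in this subsample
            vals = sub.to_numpy()
            sums += vals
            rank_sums += stats.rankdata(vals, axis=0)
            n_ok += 1
        failures[q] = reps - n_ok
        if failures[q] > 0.05 * reps:
            result_warnings.append(
                f"retention {q}: {failures[q]}/{reps} replications failed estimation"
            )
        if n_ok == 0:
            corr.loc[:, q] = np.nan
            corr_rank.loc[:, q] = np.nan
            continue
        means = sums / n_ok
        rank_means = rank_sums / n_ok
        for ci, name in enumerate(INDEX_NAMES):
            corr.loc[name, q] = _spearman(full[name].to_numpy(), means[:, ci])
            corr_rank.loc[name, q] = _spearman(full[name].to_numpy(), rank_means[:, ci])

    return StabilityResult(
        correlations=corr,
        rank_mean_correlations=corr_rank,
        reps=reps,
        seed=seed,
        failures=failures,
        warnings=result_warnings,
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return np.nan
    if np.array_equal(rx, ry):
        return 1.0  # identical rankings: exact by construction
    return float(np.corrcoef(rx, ry)[0, 1])
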