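"""Core containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: default item column names (PHQ-9 style)
DEFAULT_ITEMS = [f"D{i}" for i in range(1, 10)]

#: ordinal response levels ("not at all" ... "nearly every day")
ORDINAL_LEVELS = (0, 1, 2, 3)

#: age-group cut: respondents aged <= AGE_CUT form the younger group
AGE_CUT = 28
AGE_GROUP_YOUNG = "18-28"
AGE_GROUP_OLD = "29+"


def age_group_of(age_years: pd.Series | np.ndarray) -> pd.Series:
    """Map age in years to the two-level age group (<=28 vs >=29)."""
    age = pd.Series(np.asarray(age_years))
    return pd.Series(
        np.where(age <= AGE_CUT, AGE_GROUP_YOUNG, AGE_GROUP_OLD), index=age.index
    )


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


class ValidationError(ValueError):
    """Item responses violate the ordinal range or type contract."""


class DegenerateItemError(ValueError):
    """An item has a single non-empty response category."""


@dataclass
class ItemResponseTable:
    """Respondent-by-item table of ordinal responses plus group covariates.

    ``data`` holds one row per respondent.  Item columns contain integers in
    {0,1,2,3} (NaN marks missing).  ``gender`` / ``age_group`` columns, when
    present, carry the grouping covariates used by the invariance stage.
    """

    data: pd.DataFrame
    item_columns: list[str] = field(default_factory=lambda: list(DEFAULT_ITEMS))

    def __post_init__(self) -> None:
        missing = [c for c in self.item_columns if c not in self.data.columns]
        if missing:
            raise SchemaError(f"item columns missing from table: {missing}")
        if len(self.item_columns) < 3:
            raise SchemaError("at least 3 item columns are required")
        if len(self.data) < 1:
            raise ValidationError("table must contain at least one respondent")

    @property
    def n(self) -> int:
        return len(self.data)

    def items(self) -> pd.DataFrame:
        return self.data[self.item_columns]

    def subset(self, row_positions: np.ndarray) -> "ItemResponseTable":
        """Positional row subset (used by the case-dropping bootstrap)."""
        return ItemResponseTable(
            self.data.iloc[row_positions].reset_index(drop=True),
            list(self.item_columns),
        )

    def split(self, group_column: str) -> dict[str, "ItemResponseTable"]:
        if group_column not in self.data.columns:
            raise SchemaError(f"group column {group_column!r} not in table")
        out = {}
        for label, sub in self.data.groupby(group_column, observed=True, sort=True):
            out[str(label)] = ItemResponseTable(
                sub.reset_index(drop=True), list(self.item_columns)
            )
        return out


@dataclass
class PipelineConfig:
    """Tunable knobs for the full pipeline; defaults follow common practice."""

    item_columns: list[str] = field(default_factory=lambda: list(DEFAULT_ITEMS))
    group_column: Optional[str] = None
    ebic_gamma: float = 0.5
    lambda_count: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_reps: int = 1000
    retention_levels: tuple[float, ...] = (0.7, 0.6, 0.5)
    seed: int = 0
    missing_policy: str = "listwise"

    def __post_init__(self) -> None:
        if self.missing_policy not in ("listwise", "pairwise"):
            raise ValueError("missing_policy must be 'listwise' or 'pairwise'")
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be >= 0")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.bootstrap_reps < 1 or self.lambda_count < 1:
            raise ValueError("counts must be positive")
        levels = tuple(self.retention_levels)
        if any(not 0 < q <= 1 for q in levels):
            raise ValueError("retention levels must lie in (0, 1]")
        if list(levels) != sorted(levels, reverse=True):
            raise ValueError("retention_levels must be sorted descending")
        self.retention_levels = levels


@dataclass
class PolychoricResult:
    """Latent correlation matrix with per-item thresholds.

    ``thresholds[i]`` are the increasing latent cut-points of item i (fewer
    than K-1 entries when empty categories collapsed).  ``rho`` is symmetric
    with unit diagonal; ``smoothed`` records whether an eigenvalue-clipping
    positive-definiteness repair was applied.  ``n_used`` is the per-pair
    effective sample size.
    """

    items: list[str]
    thresholds: dict[str, np.ndarray]
    rho: np.ndarray
    n_used: np.ndarray
    smoothed: bool = False
    collapsed: dict[str, int] = field(default_factory=dict)
    boundary_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass
class UndirectedNetwork:
    """Regularized partial-correlation network selected by EBIC."""

    nodes: list[str]
    weights: np.ndarray  # symmetric, zero diagonal
    lambda_selected: float
    gamma: float
    ebic_value: float

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(len(self.nodes), k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        p = len(self.nodes)
        for i in range(p):
            for j in range(i + 1, p):
                w = self.weights[i, j]
                if w != 0:
                    out.append((self.nodes[i], self.nodes[j], float(w)))
        return out


@dataclass
class DirectedNetwork:
    """Arc-weighted directed network on a TMFG planar skeleton.

    Each undirected skeleton edge {i, j} carries two opposing arcs: the arc
    i -> j is weighted by ``dependency[j, i]`` (how much node j depends on
    node i, i.e. the influence of i on j) and vice versa.
    """

    nodes: list[str]
    skeleton: list[tuple[int, int]]  # sorted (i, j) index pairs
    dependency: np.ndarray  # full asymmetric dependency matrix

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def arcs(self) -> list[tuple[int, int, float]]:
        """All 2*|skeleton| arcs as (source, target, weight) index triples."""
        out = []
        for i, j in self.skeleton:
            out.append((i, j, float(self.dependency[j, i])))
            out.append((j, i, float(self.dependency[i, j])))
        return out

    def dominant_directions(self) -> list[tuple[int, int] | None]:
        """Per skeleton edge, the arc with the larger |weight| (None on tie)."""
        out: list[tuple[int, int] | None] = []
        for i, j in self.skeleton:
            w_ij = abs(self.dependency[j, i])  # arc i -> j
            w_ji = abs(self.dependency[i, j])
            if w_ij > w_ji:
                out.append((i, j))
            elif w_ji > w_ij:
                out.append((j, i))
            else:
                out.append(None)
        return out


#: a CentralityTable is a DataFrame with columns
#: symptom, out_strength, in_strength, relative_influence, betweenness, closeness
CentralityTable = pd.DataFrame


@dataclass
class StabilityResult:
    """Case-dropping bootstrap rank correlations per index and retention level."""

    correlations: pd.DataFrame  # rows: index name, columns: retention level
    rank_mean_correlations: pd.DataFrame
    reps: int
    seed: int
    failures: dict[float, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class WilcoxonResult:
    w_plus: float
    w_minus: float
    n_effective: int
    p_value: float
    method: str  # exact | normal_approximation | degenerate


@dataclass
class InvarianceResult:
    """Per-group centrality tables plus paired Wilcoxon tests per index."""

    group_column: str
    group_labels: list[str]
    group_sizes: dict[str, int]
    group_centrality: dict[str, pd.DataFrame]
    tests: pd.DataFrame  # rows: index; columns: W_plus, W_minus, n_effective, p_value, method
    dropped_items: list[str] = field(default_factory=list)


@dataclass
class SyntheticSpec:
    """Ground truth for the ordinal-response generator.

    Latent vectors are multivariate normal with the correlation matrix implied
    by ``partial`` (a partial-correlation matrix with zero diagonal, taken
    with unit-diagonal precision), then discretized per item at ``thresholds``.
    ``group_effect`` != 1 multiplies every latent partial correlation for the
    second level of ``effect_column``, giving a controllable violation of
    group invariance.
    """

    partial: np.ndarray
    thresholds: np.ndarray  # n_items x (n_levels - 1), strictly increasing rows
    n_respondents: int = 975
    gender_split: float = 0.65  # fraction female
    age_group_split: float = 0.5  # fraction in the younger (18-28) group
    group_effect: float = 1.0
    effect_column: str = "gender"
    seed: int = 0
    item_names: list[str] = field(default_factory=lambda: list(DEFAULT_ITEMS))

    def __post_init__(self) -> None:
        P = np.asarray(self.partial, dtype=float)
        if P.shape[0] != P.shape[1]:
            raise ValueError("partial matrix must be square")
        if not np.allclose(P, P.T):
            raise ValueError("partial matrix must be symmetric")
        if np.any(np.diag(P) != 0):
            raise ValueError("partial matrix must have zero diagonal")
        self.partial = P
        self.thresholds = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        if self.thresholds.shape[0] == 1 and self.n_items > 1:
            self.thresholds = np.repeat(self.thresholds, self.n_items, axis=0)
        if self.thresholds.shape[0] != self.n_items:
            raise ValueError("one threshold row per item required")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        if not 0 < self.gender_split < 1 or not 0 < self.age_group_split < 1:
            raise ValueError("group splits must lie in (0, 1)")
        # both group-level precision matrices must be positive definite
        for scale in (1.0, self.group_effect):
            omega = np.eye(self.n_items) - scale * P
            ev = np.linalg.eigvalsh(omega)
            if ev.min() <= 1e-10:
                raise ValueError(
                    "implied precision matrix is not positive definite "
                    f"(min eigenvalue {ev.min():.3e} at edge scale {scale})"
                )
        if len(self.item_names) != self.n_items:
            self.item_names = [f"D{i + 1}" for i in range(self.n_items)]

    @property
    def n_items(self) -> int:
        return self.partial.shape[0]

    def latent_correlation(self, scale: float = 1.0) -> np.ndarray:
        """Correlation matrix implied by the (possibly scaled) partials."""
        omega = np.eye(self.n_items) - scale * self.partial
        sigma = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma))
        return sigma / np.outer(d, d)
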