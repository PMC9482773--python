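"""File I/O: response CSVs, network edge lists / GraphML, result tables, YAML config."""

from __future__ import annotations

import os
from dataclasses import asdict

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    DirectedNetwork,
    ItemResponseTable,
    PipelineConfig,
    SchemaError,
    UndirectedNetwork,
    ValidationError,
    age_group_of,
)

EDGE_COLUMNS = ["source", "target", "weight", "directed_flag"]


def read_responses(path: str, config: PipelineConfig | None = None) -> ItemResponseTable:
    """Read and validate an ordinal response CSV.

    Item columns must exist and contain integers in {0,1,2,3} (empty cells
    mark missing).  Out-of-range or non-integer values raise a
    :class:`ValidationError` naming the offending rows and column.  Missing
    values are handled per ``config.missing_policy`` (listwise deletion by
    default).  An ``age_group`` column is derived from ``age_years`` when
    present (cut at <=28 vs >=29).
    """
    config = config or PipelineConfig()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in config.item_columns if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing item columns in {path}: {missing_cols}")

    for col in config.item_columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = (~raw_na) & (
            vals.isna() | (vals != np.floor(vals)) | (vals < 0) | (vals > 3)
        )
        if bad.any():
            rows = df.index[bad].tolist()[:20]
            raise ValidationError(
                f"column {col!r}: non-integer or out-of-range values in rows {rows}"
            )
        df[col] = vals

    if config.missing_policy == "listwise":
        before = len(df)
        df = df.dropna(subset=config.item_columns).reset_index(drop=True)
        if len(df) < before:
            import logging

            logging.getLogger(__name__).info(
                "listwise deletion removed %d of %d rows", before - len(df), before
            )
    if "age_years" in df.columns and "age_group" not in df.columns:
        df["age_group"] = age_group_of(df["age_years"]).to_numpy()
    return ItemResponseTable(df, list(config.item_columns))


def _edge_frame(net: UndirectedNetwork | DirectedNetwork) -> pd.DataFrame:
    rows = []
    if isinstance(net, DirectedNetwork):
        for s, t, w in net.arcs():
            rows.append((net.nodes[s], net.nodes[t], w, 1))
    else:
        for s, t, w in net.edge_list():
            rows.append((s, t, w, 0))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def write_network(net: UndirectedNetwork | DirectedNetwork, path: str) -> None:
    """Write a network as an edge-list CSV plus a GraphML file.

    ``path`` may end in ``.csv``; the GraphML sibling replaces the suffix.
    Weights use the shortest exact decimal representation, so a round-trip
    read reproduces them bit for bit.
    """
    if len(net.nodes) < 1:
        raise ValueError("network must have at least one node")
    base = path[:-4] if path.endswith(".csv") else path
    _edge_frame(net).to_csv(base + ".csv", index=False)

    directed = isinstance(net, DirectedNetwork)
    G = nx.DiGraph() if directed else nx.Graph()
    G.add_nodes_from(net.nodes)
    for _, row in _edge_frame(net).iterrows():
        G.add_edge(row["source"], row["target"], weight=float(row["weight"]))
    nx.write_graphml(G, base + ".graphml")


def read_network(path: str) -> pd.DataFrame:
    """Read an edge-list CSV back as a DataFrame (exact weights)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"edge list {path} lacks columns {missing}")
    return df


def write_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def read_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "retention_levels" in raw:
        raw["retention_levels"] = tuple(raw["retention_levels"])
    return PipelineConfig(**raw)
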