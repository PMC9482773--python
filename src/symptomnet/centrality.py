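"""Centrality indices and relative influence for directed weighted networks.

Strength sums absolute arc weights by origin (out) and destination (in).
Path-based indices use the standard inverse-weight distance transform
(arc length = 1 / |weight|): betweenness counts, with fractional credit for
ties, how many ordered node pairs route their shortest directed path through
a node; closeness is the reciprocal of the mean shortest directed distance
to the other nodes.  Relative influence is (out - in) / (out + in).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CentralityTable, DirectedNetwork

INDEX_COLUMNS = ["out_strength", "in_strength", "relative_influence", "betweenness", "closeness"]


def to_digraph(net: DirectedNetwork) -> nx.DiGraph:
    """networkx view of the arc set; zero-weight arcs carry no length."""
    G = nx.DiGraph()
    G.add_nodes_from(range(net.n_nodes))
    for s, t, w in net.arcs():
        if w != 0.0:
            G.add_edge(s, t, weight=w, length=1.0 / abs(w))
    return G


def strength(net: DirectedNetwork) -> pd.DataFrame:
    """Per-node out- and in-strength (sums of absolute arc weights)."""
    out = np.zeros(net.n_nodes)
    inc = np.zeros(net.n_nodes)
    for s, t, w in net.arcs():
        out[s] += abs(w)
        inc[t] += abs(w)
    return pd.DataFrame({"out_strength": out, "in_strength": inc}, index=net.nodes)


def relative_influence(out_strength, in_strength):
    """(out - in) / (out + in); zero (flagged via warning) for isolated nodes.

    Accepts scalars or aligned arrays; positive values mark nodes whose
    outgoing influence exceeds what they receive.
    """
    out = np.asarray(out_strength, dtype=float)
    inc = np.asarray(in_strength, dtype=float)
    total = out + inc
    isolated = total == 0
    if np.any(isolated):
        warnings.warn("isolated node(s): relative influence set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ri = np.where(isolated, 0.0, (out - inc) / np.where(isolated, 1.0, total))
    return float(ri) if ri.ndim == 0 else ri


def betweenness(net: DirectedNetwork, normalized: bool = False) -> np.ndarray:
    """Shortest-path betweenness over directed inverse-weight distances.

    Raw (unnormalized) counts by default, fractional credit for tied
    shortest paths; ``normalized`` divides by (n-1)(n-2).
    """
    G = to_digraph(net)
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    values = np.array([bc[i] for i in range(net.n_nodes)])
    if normalized:
        n = net.n_nodes
        if n > 2:
            values = values / ((n - 1) * (n - 2))
    return values


def closeness(net: DirectedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Outward closeness: (number reached) / (sum of directed distances).

    Returns (closeness values, fully-reaching flags).  Nodes that do not
    reach every other node are scored over their reachable set and flagged;
    TMFG skeletons with both arcs retained are strongly connected, so the
    flag only trips on degenerate weight patterns.
    """
    G = to_digraph(net)
    n = net.n_nodes
    values = np.zeros(n)
    full = np.ones(n, dtype=bool)
    for v in range(n):
        dist = nx.single_source_dijkstra_path_length(G, v, weight="length")
        reached = {u: d for u, d in dist.items() if u != v}
        if len(reached) < n - 1:
            full[v] = False
            warnings.warn(
                f"node {net.nodes[v]!r} reaches {len(reached)}/{n - 1} nodes; "
                "closeness computed over the reachable set",
                stacklevel=2,
            )
        total = sum(reached.values())
        values[v] = len(reached) / total if total > 0 else 0.0
    return values, full


def centrality_table(net: DirectedNetwork, sort: bool = True) -> CentralityTable:
    """The full per-node index table, sorted by descending out-strength."""
    st = strength(net)
    out = st["out_strength"].to_numpy()
    inc = st["in_strength"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ri = relative_influence(out, inc)
        clo, _ = closeness(net)
    table = pd.DataFrame(
        {
            "symptom": net.nodes,
            "out_strength": out,
            "in_strength": inc,
            "relative_influence": np.atleast_1d(ri),
            "betweenness": betweenness(net),
            "closeness": clo,
        }
    )
    if sort:
        table = table.sort_values("out_strength", ascending=False, kind="stable")
    return table.reset_index(drop=True)


def z_transform(table: CentralityTable) -> CentralityTable:
    """Add z-scored variants of every index column (mean 0, sd 1)."""
    out = table.copy()
    for col in INDEX_COLUMNS:
        if col in out.columns:
            x = out[col].to_numpy(dtype=float)
            sd = x.std()
            out[f"{col}_z"] = (x - x.mean()) / sd if sd > 0 else 0.0
    return out
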