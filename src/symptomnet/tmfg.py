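"""Directed network construction: node dependency + TMFG planar filtering.

The dependency matrix quantifies, for each ordered pair (i, j), how much of
node i's correlations with third parties vanishes once node j is partialled
out — the influence of j on i.  A Triangulated Maximally Filtered Graph
(TMFG) over the symmetrized dependency strengths retains a planar skeleton
of exactly 3n-6 edges; each retained edge carries two opposing arcs weighted
by the corresponding dependency entries.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DirectedNetwork, PolychoricResult


def dependency_matrix(rho_matrix: np.ndarray) -> np.ndarray:
    """Asymmetric node-dependency matrix from a correlation matrix.

    D(i, j) = mean over k not in {i, j} of [ r(i,k) - r(i,k | j) ], where
    r(i,k | j) is the first-order partial correlation controlling for j:
    (r_ik - r_ij r_jk) / sqrt((1 - r_ij^2)(1 - r_jk^2)).  D(i, j) is the
    dependency of node i on node j.  The diagonal is zero; the identity
    correlation matrix maps to the zero matrix.
    """
    R = np.asarray(rho_matrix, dtype=float)
    n = R.shape[0]
    if n < 3:
        raise ValueError("dependency matrix needs at least 3 nodes")
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(R[off]) >= 1.0):
        raise ValueError("a |correlation| of 1 makes first-order partials degenerate")

    # partial[i, k, j] = r(i,k | j), vectorized over the full index cube
    s = np.sqrt(1.0 - R * R)  # s[i, j] = sqrt(1 - r_ij^2), diagonal -> 0 guarded below
    np.fill_diagonal(s, 1.0)  # r(i,i)=1 cells are excluded by the masks anyway
    partial = (R[:, :, None] - R[:, None, :] * R.T[None, :, :]) / (
        s[:, None, :] * s.T[None, :, :]
    )
    diff = R[:, :, None] - partial  # diff[i, k, j]

    mask = np.ones((n, n, n), dtype=bool)
    idx = np.arange(n)
    mask[idx, idx, :] = False  # k == i
    mask[:, idx, idx] = False  # k == j
    mask[idx, :, idx] = False  # j == i (diagonal of D)
    D = np.where(mask, diff, 0.0).sum(axis=1) / (n - 2)
    np.fill_diagonal(D, 0.0)
    return D


def tmfg_skeleton(assoc: np.ndarray, allow_small: bool = False) -> list[tuple[int, int]]:
    """Planar triangulation retaining maximal association weight, greedily.

    Seeds with the 4-clique over the four nodes of largest total association;
    each remaining node is then inserted into the triangular face maximizing
    the summed weight of the three new edges (best node-face pair per step),
    splitting that face into three.  Ties break toward the lowest node index,
    then the earliest-created face.  Returns exactly 3n-6 sorted index pairs.

    ``allow_small`` returns the complete graph for n in {1, 2, 3}.
    """
    W = np.asarray(assoc, dtype=float)
    n = W.shape[0]
    if W.shape[0] != W.shape[1]:
        raise ValueError("association matrix must be square")
    if not np.all(np.isfinite(W)):
        raise ValueError("association weights must be finite")
    if n < 4:
        if allow_small:
            return [(i, j) for i in range(n) for j in range(i + 1, n)]
        raise ValueError("TMFG requires n >= 4 (pass allow_small=True for K_n)")

    Wd = W.copy()
    np.fill_diagonal(Wd, 0.0)
    totals = Wd.sum(axis=1)
    # largest total association; ties toward the lowest index
    order = np.lexsort((np.arange(n), -totals))
    seed = sorted(int(v) for v in order[:4])

    edges = [(seed[a], seed[b]) for a in range(4) for b in range(a + 1, 4)]
    faces = [
        (seed[0], seed[1], seed[2]),
        (seed[0], seed[1], seed[3]),
        (seed[0], seed[2], seed[3]),
        (seed[1], seed[2], seed[3]),
    ]
    remaining = [v for v in range(n) if v not in seed]

    while remaining:
        best_gain = -np.inf
        best_v = best_f = -1
        for v in remaining:  # ascending index: first strict improvement wins
            for f_idx, (a, b, c) in enumerate(faces):
                gain = Wd[v, a] + Wd[v, b] + Wd[v, c]
                if gain > best_gain:
                    best_gain, best_v, best_f = gain, v, f_idx
        a, b, c = faces.pop(best_f)
        v = best_v
        edges.extend([tuple(sorted((v, a))), tuple(sorted((v, b))), tuple(sorted((v, c)))])
        faces.extend([(a, b, v), (a, c, v), (b, c, v)])
        remaining.remove(v)

    assert len(edges) == 3 * n - 6
    return sorted(edges)


def fit_directed(polychoric: PolychoricResult | np.ndarray, nodes=None) -> DirectedNetwork:
    """Directed weighted network from a polychoric (or plain) correlation matrix.

    The TMFG skeleton is built on the symmetrized dependency strength
    max(|D(i,j)|, |D(j,i)|); every retained edge {i, j} carries the arc
    i -> j with weight D(j, i) and the arc j -> i with weight D(i, j).
    """
    if isinstance(polychoric, PolychoricResult):
        R = polychoric.rho
        nodes = list(polychoric.items)
    else:
        R = np.asarray(polychoric, dtype=float)
        if nodes is None:
            nodes = [f"V{i + 1}" for i in range(R.shape[0])]
    D = dependency_matrix(R)
    strength = np.maximum(np.abs(D), np.abs(D.T))
    skeleton = tmfg_skeleton(strength)
    return DirectedNetwork(nodes=list(nodes), skeleton=skeleton, dependency=D)
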