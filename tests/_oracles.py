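"""Independent brute-force oracles used to validate the fast implementations."""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_shortest_paths(lengths: dict[tuple[int, int], float], n: int):
    """All shortest directed paths per ordered pair, by enumerating simple paths.

    ``lengths`` maps arcs to positive lengths.  Returns
    {(s, t): (distance, [paths])} for reachable pairs.
    """
    nodes = range(n)
    out: dict[tuple[int, int], tuple[float, list[tuple[int, ...]]]] = {}
    for s, t in itertools.permutations(nodes, 2):
        best = np.inf
        best_paths: list[tuple[int, ...]] = []
        others = [v for v in nodes if v not in (s, t)]
        for k in range(len(others) + 1):
            for mid in itertools.permutations(others, k):
                path = (s, *mid, t)
                try:
                    d = sum(lengths[(path[i], path[i + 1])] for i in range(len(path) - 1))
                except KeyError:
                    continue
                if d < best - 1e-12:
                    best, best_paths = d, [path]
                elif abs(d - best) <= 1e-12:
                    best_paths.append(path)
        if best_paths:
            out[(s, t)] = (best, best_paths)
    return out


def brute_force_betweenness(lengths, n: int) -> np.ndarray:
    """Fractional-credit betweenness by exhaustive path enumeration."""
    sp = brute_force_shortest_paths(lengths, n)
    bc = np.zeros(n)
    for (s, t), (_, paths) in sp.items():
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def brute_force_closeness(lengths, n: int) -> np.ndarray:
    """(number reached) / (sum of shortest distances), exhaustively."""
    sp = brute_force_shortest_paths(lengths, n)
    out = np.zeros(n)
    for v in range(n):
        dists = [d for (s, t), (d, _) in sp.items() if s == v]
        if dists:
            out[v] = len(dists) / sum(dists)
    return out


def naive_tmfg(W: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Step-by-step exhaustive-face-search triangulation (reference TMFG).

    Independently re-derives each greedy step by scanning every remaining
    vertex against every current face; returns (edges, total adopted weight).
    """
    W = np.asarray(W, dtype=float).copy()
    n = W.shape[0]
    np.fill_diagonal(W, 0.0)
    totals = [(float(-W[v].sum()), v) for v in range(n)]
    seed = sorted(v for _, v in sorted(totals)[:4])
    edges = [(a, b) for i, a in enumerate(seed) for b in seed[i + 1:]]
    score = sum(W[a, b] for a, b in edges)
    faces = [tuple(sorted(f)) for f in itertools.combinations(seed, 3)]
    remaining = [v for v in range(n) if v not in seed]
    while remaining:
        candidates = []
        for rank_v, v in enumerate(sorted(remaining)):
            for f_idx, (a, b, c) in enumerate(faces):
                gain = W[v, a] + W[v, b] + W[v, c]
                candidates.append((-gain, rank_v, f_idx, v))
        _, _, f_idx, v = min(candidates)
        a, b, c = faces.pop(f_idx)
        for u in (a, b, c):
            edges.append(tuple(sorted((v, u))))
            score += W[v, u]
        faces.extend([tuple(sorted((a, b, v))), tuple(sorted((a, c, v))),
                      tuple(sorted((b, c, v)))])
        remaining.remove(v)
    return sorted(edges), score


def brute_force_wilcoxon_p(w_plus: float, abs_diffs: np.ndarray) -> float:
    """Two-sided exact p by literally enumerating all 2^n sign assignments."""
    from scipy.stats import rankdata

    ranks = rankdata(abs_diffs)
    n = len(ranks)
    stats = []
    for signs in itertools.product((0, 1), repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    lower = np.mean(stats <= w_plus + 1e-9)
    upper = np.mean(stats >= w_plus - 1e-9)
    return float(min(1.0, 2.0 * min(lower, upper)))
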