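"""Polychoric correlation estimation for ordinal items.

Two-step estimator: item thresholds from the marginal category proportions
(normal quantiles of the cumulative proportions), then each pairwise latent
correlation by one-dimensional maximum likelihood over the bivariate-normal
rectangle probabilities of the observed contingency table.  Partial
correlations come from the inverse of the assembled correlation matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import (
    DegenerateItemError,
    ItemResponseTable,
    PolychoricResult,
)

RHO_BOUND = 0.999
_PD_EIG_TOL = 1e-6


def bvn_cdf(x, y, rho: float) -> np.ndarray:
    """P(X <= x, Y <= y) for standard bivariate normal with correlation rho.

    Closed form via Owen's T function; absolute accuracy ~1e-14.  Handles
    infinite limits elementwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = np.broadcast_arrays(x, y)
    out = np.empty(x.shape, dtype=float)

    lo = (x == -np.inf) | (y == -np.inf)
    xi = x == np.inf
    yi = y == np.inf
    out[lo] = 0.0
    out[xi & ~lo] = stats.norm.cdf(y[xi & ~lo])
    out[yi & ~lo & ~xi] = stats.norm.cdf(x[yi & ~lo & ~xi])

    fin = ~(lo | xi | yi)
    if np.any(fin):
        h = x[fin]
        k = y[fin]
        if rho == 0.0:
            out[fin] = stats.norm.cdf(h) * stats.norm.cdf(k)
        else:
            # Owen (1956): shift exact zeros off the axis so the arctan
            # limits and the quadrant term fall out of the generic formula
            h = np.where(h == 0.0, 1e-13, h)
            k = np.where(k == 0.0, 1e-13, k)
            s = np.sqrt(1.0 - rho * rho)
            ah = (k - rho * h) / (h * s)
            ak = (h - rho * k) / (k * s)
            quadrant = np.where(h * k < 0.0, 0.5, 0.0)
            out[fin] = (
                0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
                - special.owens_t(h, ah)
                - special.owens_t(k, ak)
                - quadrant
            )
    return np.clip(out, 0.0, 1.0)


def estimate_thresholds(category_counts) -> tuple[np.ndarray, int]:
    """Thresholds from marginal counts: tau_k = Phi^-1(cumulative proportion).

    Returns (thresholds, n_collapsed) where n_collapsed counts empty
    categories merged into their neighbour (each removes one threshold).

    Raises :class:`DegenerateItemError` when only one category is populated.
    """
    counts = np.asarray(category_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DegenerateItemError("item has no observations")
    if np.count_nonzero(counts) < 2:
        raise DegenerateItemError("item has a single non-empty category")
    cum = np.cumsum(counts)[:-1] / total
    interior = cum[(cum > 0) & (cum < 1)]
    tau = stats.norm.ppf(np.unique(interior))
    n_collapsed = (len(counts) - 1) - len(tau)
    return tau, int(n_collapsed)


def _rectangle_probs(tau_i: np.ndarray, tau_j: np.ndarray, rho: float) -> np.ndarray:
    ti = np.concatenate(([-np.inf], tau_i, [np.inf]))
    tj = np.concatenate(([-np.inf], tau_j, [np.inf]))
    grid = bvn_cdf(ti[:, None], tj[None, :], rho)
    return np.diff(np.diff(grid, axis=0), axis=1)


def polychoric_rho(
    pair_table,
    tau_i,
    tau_j,
    return_se: bool = False,
):
    """ML estimate of the latent correlation for one pair of ordinal items.

    ``pair_table`` holds the cross-classified counts; ``tau_i`` / ``tau_j``
    are the (fixed) thresholds of the two items.  The estimate maximizes
    sum n_ab log P_ab(rho) over rho in [-0.999, 0.999].

    Returns ``(rho_hat, at_boundary)``, plus a standard error from the
    observed information when ``return_se`` is set.
    """
    table = np.asarray(pair_table, dtype=float)
    if table.sum() < 10:
        raise ValueError("pair table total must be >= 10")
    tau_i = np.asarray(tau_i, dtype=float)
    tau_j = np.asarray(tau_j, dtype=float)
    mask = table > 0

    def nll(rho: float) -> float:
        probs = _rectangle_probs(tau_i, tau_j, rho)
        return -float(np.sum(table[mask] * np.log(np.maximum(probs[mask], 1e-300))))

    res = optimize.minimize_scalar(
        nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:  # pragma: no cover - bounded Brent essentially never fails
        raise RuntimeError(f"polychoric optimizer failed to converge: {res}")
    rho_hat = float(res.x)
    at_boundary = False
    if RHO_BOUND - abs(rho_hat) < 1e-4:
        rho_hat = float(np.sign(rho_hat)) * RHO_BOUND
        at_boundary = True
    if not return_se:
        return rho_hat, at_boundary
    if at_boundary:
        return rho_hat, at_boundary, np.nan
    h = 1e-4
    d2 = (nll(rho_hat + h) - 2.0 * nll(rho_hat) + nll(rho_hat - h)) / h**2
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
    return rho_hat, at_boundary, se


def _pair_counts(xi: np.ndarray, xj: np.ndarray, ki: int, kj: int) -> np.ndarray:
    return np.bincount(xi * kj + xj, minlength=ki * kj).reshape(ki, kj).astype(float)


def correlation_matrix(table: ItemResponseTable) -> PolychoricResult:
    """Pairwise polychoric correlation matrix for all items of a table.

    Thresholds are estimated once per item from its full margin; each pair
    uses pairwise-complete observations.  If the assembled matrix is not
    positive definite it is repaired by eigenvalue clipping (negative
    eigenvalues raised to 1e-6, then rescaled to unit diagonal).

    Items with a single populated category are excluded with a warning; with
    fewer than two usable items an error is raised.
    """
    items = list(table.item_columns)
    values = table.items()

    usable: list[str] = []
    codes: dict[str, np.ndarray] = {}
    cats: dict[str, np.ndarray] = {}
    thresholds: dict[str, np.ndarray] = {}
    collapsed: dict[str, int] = {}
    for name in items:
        col = values[name].to_numpy(dtype=float)
        obs = col[~np.isnan(col)]
        levels = np.unique(obs)
        counts = np.array([(obs == lv).sum() for lv in levels], dtype=float)
        try:
            tau, n_coll = estimate_thresholds(counts)
        except DegenerateItemError:
            warnings.warn(
                f"item {name!r} is degenerate (single category); excluded",
                stacklevel=2,
            )
            continue
        usable.append(name)
        cats[name] = levels
        code = np.full(len(col), -1, dtype=np.int64)
        ok = ~np.isnan(col)
        code[ok] = np.searchsorted(levels, col[ok])
        codes[name] = code
        thresholds[name] = tau
        if n_coll:
            collapsed[name] = n_coll

    if len(usable) < 2:
        raise DegenerateItemError("fewer than 2 non-degenerate items")

    p = len(usable)
    rho = np.eye(p)
    n_used = np.full((p, p), table.n, dtype=np.int64)
    boundary_pairs: list[tuple[str, str]] = []
    for a in range(p):
        for b in range(a + 1, p):
            ia, ib = usable[a], usable[b]
            ca, cb = codes[ia], codes[ib]
            ok = (ca >= 0) & (cb >= 0)
            tab = _pair_counts(ca[ok], cb[ok], len(cats[ia]), len(cats[ib]))
            r, at_bound = polychoric_rho(tab, thresholds[ia], thresholds[ib])
            rho[a, b] = rho[b, a] = r
            n_used[a, b] = n_used[b, a] = int(ok.sum())
            if at_bound:
                boundary_pairs.append((ia, ib))

    smoothed = False
    ev, vec = np.linalg.eigh(rho)
    if ev.min() < _PD_EIG_TOL:
        smoothed = True
        ev = np.maximum(ev, _PD_EIG_TOL)
        repaired = (vec * ev) @ vec.T
        d = np.sqrt(np.diag(repaired))
        rho = repaired / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)

    return PolychoricResult(
        items=usable,
        thresholds=thresholds,
        rho=rho,
        n_used=n_used,
        smoothed=smoothed,
        collapsed=collapsed,
        boundary_pairs=boundary_pairs,
    )


def partial_correlations(rho_matrix: np.ndarray) -> np.ndarray:
    """Full partial correlations from a correlation matrix.

    p(i,j) = -theta(i,j) / sqrt(theta(i,i) theta(j,j)) with theta the
    precision matrix.  Requires a positive-definite input.
    """
    rho = np.asarray(rho_matrix, dtype=float)
    ev = np.linalg.eigvalsh(rho)
    if ev.min() <= 0:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular or indefinite; apply "
            "positive-definiteness smoothing first"
        )
    theta = np.linalg.inv(rho)
    d = np.sqrt(np.diag(theta))
    partial = -theta / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    return partial


def thresholds_frame(result: PolychoricResult) -> pd.DataFrame:
    """Per-item thresholds as a long-format DataFrame for export."""
    rows = []
    for item in result.items:
        for k, tau in enumerate(result.thresholds[item], start=1):
            rows.append({"item": item, "threshold_index": k, "tau": tau})
    return pd.DataFrame(rows, columns=["item", "threshold_index", "tau"])
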