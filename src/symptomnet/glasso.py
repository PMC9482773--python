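"""Undirected regularized partial-correlation network: glasso + extended BIC.

A log-spaced penalty grid runs from lambda_max (the largest off-diagonal
|correlation|, at which the graph is empty) down by ``lambda_min_ratio``;
each penalized precision matrix is scored by the extended Bayesian
information criterion and the minimizer is kept, with ties broken toward
the sparser (larger-penalty) model.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .datatypes import PolychoricResult, UndirectedNetwork

#: entries of the precision matrix below this magnitude count as absent edges
EDGE_FLOOR = 1e-6


def lambda_grid(
    rho_matrix: np.ndarray, count: int = 100, min_ratio: float = 0.01
) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max to lambda_max*min_ratio."""
    R = np.asarray(rho_matrix, dtype=float)
    off = np.abs(R[~np.eye(R.shape[0], dtype=bool)])
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1e-2  # identity input: any positive grid selects the empty graph
    return np.geomspace(lam_max, lam_max * min_ratio, count)


def glasso_path(
    rho_matrix: np.ndarray, lambdas, max_iter: int = 500
) -> list[np.ndarray]:
    """Penalized precision matrices along a penalty path.

    Each solution maximizes log det(Theta) - tr(R Theta) - lambda * sum of
    off-diagonal |theta_ij|.  Raises on non-convergence, naming the penalty.
    """
    R = np.asarray(rho_matrix, dtype=float)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise np.linalg.LinAlgError("glasso input must be positive definite")
    path = []
    for lam in np.asarray(lambdas, dtype=float):
        try:
            with warnings.catch_warnings():
                # near-zero penalties stall at dual gaps ~1e-3, far below
                # anything that moves EBIC selection; hard failures still raise
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, precision = graphical_lasso(R, alpha=float(lam), max_iter=max_iter)
        except FloatingPointError as err:  # pragma: no cover - pathological inputs
            raise RuntimeError(f"glasso failed to converge at lambda={lam:.6g}") from err
        if np.linalg.eigvalsh(precision).min() <= 0:  # pragma: no cover
            raise RuntimeError(f"glasso returned an indefinite solution at lambda={lam:.6g}")
        path.append(precision)
    return path


def ebic_score(
    theta: np.ndarray, rho_matrix: np.ndarray, n: int, gamma: float = 0.5
) -> float:
    """Extended BIC of a precision matrix against a correlation matrix.

    -n [log det(Theta) - tr(R Theta)] + E log n + 4 E gamma log p, with E the
    number of nonzero upper-triangle entries and p the node count.
    """
    theta = np.asarray(theta, dtype=float)
    R = np.asarray(rho_matrix, dtype=float)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise np.linalg.LinAlgError("EBIC needs a positive-definite precision matrix")
    p = theta.shape[0]
    iu = np.triu_indices(p, k=1)
    E = int(np.count_nonzero(np.abs(theta[iu]) > EDGE_FLOOR))
    loglik = n * (logdet - float(np.trace(R @ theta)))
    return -loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def precision_to_partial(theta: np.ndarray) -> np.ndarray:
    """Partial-correlation weights from a precision matrix, small entries zeroed."""
    d = np.sqrt(np.diag(theta))
    w = -theta / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) < EDGE_FLOOR] = 0.0
    return w


def fit_undirected(
    polychoric: PolychoricResult | np.ndarray,
    n: int | None = None,
    gamma: float = 0.5,
    lambda_count: int = 100,
    lambda_min_ratio: float = 0.01,
    nodes=None,
) -> UndirectedNetwork:
    """EBIC-selected glasso network from a polychoric correlation matrix.

    Returns the network at the EBIC-minimizing penalty; equal scores keep the
    larger penalty (sparser model).  Weights are the partial correlations
    implied by the selected precision matrix.
    """
    if isinstance(polychoric, PolychoricResult):
        R = polychoric.rho
        nodes = list(polychoric.items)
        if n is None:
            n = int(polychoric.n_used.min())
    else:
        R = np.asarray(polychoric, dtype=float)
        if n is None:
            raise ValueError("sample size n is required with a bare matrix input")
        if nodes is None:
            nodes = [f"V{i + 1}" for i in range(R.shape[0])]

    lambdas = lambda_grid(R, count=lambda_count, min_ratio=lambda_min_ratio)
    path = glasso_path(R, lambdas)
    best_idx, best_score = 0, np.inf
    for idx, theta in enumerate(path):  # descending lambda: strict < keeps sparser
        score = ebic_score(theta, R, n=n, gamma=gamma)
        if score < best_score:
            best_idx, best_score = idx, score
    return UndirectedNetwork(
        nodes=list(nodes),
        weights=precision_to_partial(path[best_idx]),
        lambda_selected=float(lambdas[best_idx]),
        gamma=gamma,
        ebic_value=float(best_score),
    )


def path_diagnostics(rho_matrix: np.ndarray, n: int, gamma: float = 0.5,
                     lambda_count: int = 100, lambda_min_ratio: float = 0.01):
    """(lambda, edge count, EBIC) rows along the path, for export."""
    import pandas as pd

    lambdas = lambda_grid(rho_matrix, count=lambda_count, min_ratio=lambda_min_ratio)
    rows = []
    for lam, theta in zip(lambdas, glasso_path(rho_matrix, lambdas)):
        p = theta.shape[0]
        iu = np.triu_indices(p, k=1)
        rows.append(
            {
                "lambda": float(lam),
                "n_edges": int(np.count_nonzero(np.abs(theta[iu]) > EDGE_FLOOR)),
                "ebic": ebic_score(theta, rho_matrix, n=n, gamma=gamma),
            }
        )
    return pd.DataFrame(rows)
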