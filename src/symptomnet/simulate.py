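"""Synthetic ordinal symptom data with known latent network structure.

Responses are generated from a latent multivariate normal whose correlation
matrix is implied by a sparse partial-correlation ground truth, discretized
per item at fixed thresholds into the ordinal levels {0,1,2,3}.  Default
thresholds (0.25, 0.9, 1.6) give the right-skewed marginals typical of
community depression-screening samples; default group splits mirror a
65/35 female/male sample with a two-level age split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    AGE_CUT,
    ItemResponseTable,
    SyntheticSpec,
    age_group_of,
)

DEFAULT_THRESHOLDS = (0.25, 0.9, 1.6)

STRUCTURES = ("chain", "hub", "random_sparse", "planar")


def make_ground_truth(
    structure: str,
    n_items: int = 9,
    edge_weight_range: tuple[float, float] = (0.3, 0.3),
    seed: int = 0,
    **spec_kwargs,
) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` with a named partial-correlation support.

    Structures: ``chain`` (i - i+1), ``hub`` (node 0 to all others),
    ``random_sparse`` (each pair present with probability 0.25, redrawn up to
    50 times if the implied precision is not positive definite) and
    ``planar`` (fan triangulation: hub plus chain, a valid planar graph).
    Edge weights are drawn uniformly from ``edge_weight_range``.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; choose from {STRUCTURES}")
    if n_items < 4:
        raise ValueError("n_items must be >= 4")
    lo, hi = edge_weight_range
    rng = np.random.default_rng(seed)

    def weights(m: int) -> np.ndarray:
        return rng.uniform(lo, hi, size=m) if hi > lo else np.full(m, lo)

    def build(edges: list[tuple[int, int]]) -> np.ndarray:
        P = np.zeros((n_items, n_items))
        w = weights(len(edges))
        for (i, j), wij in zip(edges, w):
            P[i, j] = P[j, i] = wij
        return P

    if structure == "chain":
        P = build([(i, i + 1) for i in range(n_items - 1)])
    elif structure == "hub":
        P = build([(0, j) for j in range(1, n_items)])
    elif structure == "planar":
        edges = [(0, j) for j in range(1, n_items)]
        edges += [(i, i + 1) for i in range(1, n_items - 1)]
        P = build(edges)
    else:  # random_sparse
        P = None
        for _ in range(50):
            iu = np.triu_indices(n_items, k=1)
            present = rng.random(len(iu[0])) < 0.25
            cand = np.zeros((n_items, n_items))
            w = weights(int(present.sum()))
            cand[iu[0][present], iu[1][present]] = w
            cand = cand + cand.T
            ev = np.linalg.eigvalsh(np.eye(n_items) - cand)
            if ev.min() > 1e-6:
                P = cand
                break
        if P is None:
            raise ValueError(
                "could not draw a positive-definite random_sparse structure "
                f"with weights in {edge_weight_range}; reduce the weights"
            )

    thresholds = spec_kwargs.pop("thresholds", np.array(DEFAULT_THRESHOLDS))
    return SyntheticSpec(partial=P, thresholds=thresholds, seed=seed, **spec_kwargs)


def simulate_responses(spec: SyntheticSpec, seed: int | None = None) -> ItemResponseTable:
    """Draw an ordinal response table from a synthetic specification.

    Group labels are drawn first (Bernoulli at the configured splits), then
    one latent normal vector per respondent using the group's correlation
    matrix (the ``effect_column``'s second level has every partial scaled by
    ``group_effect``), then each coordinate is discretized at the item's
    thresholds.  Identical spec and seed give an identical table.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, p = spec.n_respondents, spec.n_items

    female = rng.random(n) < spec.gender_split
    gender = np.where(female, "female", "male")
    young = rng.random(n) < spec.age_group_split
    age_years = np.where(
        young,
        rng.integers(18, AGE_CUT + 1, size=n),
        rng.integers(AGE_CUT + 1, 69, size=n),
    )

    base = rng.standard_normal((n, p))
    L1 = np.linalg.cholesky(spec.latent_correlation(1.0))
    z = base @ L1.T
    if spec.group_effect != 1.0:
        L2 = np.linalg.cholesky(spec.latent_correlation(spec.group_effect))
        if spec.effect_column == "gender":
            affected = ~female  # males carry the altered structure
        elif spec.effect_column == "age_group":
            affected = ~young
        else:
            raise ValueError("effect_column must be 'gender' or 'age_group'")
        z[affected] = base[affected] @ L2.T

    responses = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        responses[:, j] = np.searchsorted(spec.thresholds[j], z[:, j])

    data = pd.DataFrame(responses, columns=spec.item_names)
    data.insert(0, "respondent_id", [f"R{i + 1:05d}" for i in range(n)])
    data["gender"] = gender
    data["age_years"] = age_years
    data["age_group"] = age_group_of(age_years).to_numpy()
    return ItemResponseTable(data, list(spec.item_names))
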