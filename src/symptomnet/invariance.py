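"""Group invariance of centrality profiles via paired Wilcoxon signed-rank tests.

Networks are estimated independently per demographic group over the common
item set; for each centrality index the two per-symptom profiles are
compared by the paired Wilcoxon signed-rank test.  Zero differences are
dropped before ranking and tied absolute differences receive midranks.
The p-value is exact (full sign-assignment distribution) when there are at
most 25 nonzero differences and no ties, otherwise a normal approximation
with continuity correction and tie-corrected variance is used.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DegenerateItemError,
    InvarianceResult,
    ItemResponseTable,
    PipelineConfig,
    WilcoxonResult,
)
from .centrality import centrality_table
from .polychoric import correlation_matrix
from .stability import INDEX_NAMES
from .tmfg import fit_directed

EXACT_MAX_N = 25


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank statistics W+ and W- with a two-sided p.

    W+ (W-) is the sum of the midranks of the absolute nonzero differences
    x - y that are positive (negative); W+ + W- = n'(n'+1)/2 with n' the
    number of nonzero differences.  All differences zero gives the flagged
    degenerate result (W+ = W- = 0, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays of length >= 2")
    d = x - y
    d = d[d != 0]
    n_eff = len(d)
    if n_eff == 0:
        return WilcoxonResult(0.0, 0.0, 0, 1.0, "degenerate")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    has_ties = len(np.unique(absd)) < n_eff

    if n_eff <= EXACT_MAX_N and not has_ties:
        p = _exact_two_sided_p(w_plus, n_eff)
        method = "exact"
    else:
        p = _normal_approx_p(w_plus, n_eff, absd)
        method = "normal_approximation"
    return WilcoxonResult(w_plus, w_minus, n_eff, p, method)


def _exact_two_sided_p(w_plus: float, n: int) -> float:
    """Exact two-sided p over all 2^n sign assignments of untied ranks 1..n.

    The null distribution of W+ is built by convolution over rank sums,
    which enumerates the sign assignments without materializing them.
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[:-r]
    total = counts.sum()  # == 2**n
    w = int(round(w_plus))
    lower = counts[: w + 1].sum() / total
    upper = counts[w:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def _normal_approx_p(w_plus: float, n: int, absd: np.ndarray) -> float:
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return 1.0
    dev = w_plus - mean
    # continuity correction shrinks the deviation toward the null mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var) if dev != 0 else 0.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def split_and_fit(
    table: ItemResponseTable,
    group_column: str,
    min_group_n: int = 50,
) -> dict[str, pd.DataFrame]:
    """Per-group directed networks and centrality tables over common items.

    An item degenerate in any group is dropped from every group (the paired
    test needs a common node set); a warning names it.
    """
    groups = table.split(group_column)
    if len(groups) < 2:
        raise ValueError(
            f"group column {group_column!r} has {len(groups)} level(s); need >= 2"
        )
    for label, sub in groups.items():
        if sub.n < min_group_n:
            warnings.warn(
                f"group {label!r} has only {sub.n} respondents", stacklevel=2
            )

    items = list(table.item_columns)
    dropped: list[str] = []
    for name in items:
        for sub in groups.values():
            col = sub.items()[name].dropna()
            if col.nunique() < 2:
                dropped.append(name)
                break
    if dropped:
        warnings.warn(
            f"items degenerate in at least one group dropped from all groups: {dropped}",
            stacklevel=2,
        )
        items = [c for c in items if c not in dropped]
        if len(items) < 4:
            raise DegenerateItemError("fewer than 4 common non-degenerate items")
        groups = {
            label: ItemResponseTable(sub.data, items) for label, sub in groups.items()
        }

    out: dict[str, pd.DataFrame] = {}
    for label, sub in groups.items():
        net = fit_directed(correlation_matrix(sub))
        out[label] = centrality_table(net, sort=False)
    return out


def invariance_report(
    table: ItemResponseTable,
    group_column: str,
    config: PipelineConfig | None = None,
) -> InvarianceResult:
    """Wilcoxon signed-rank comparison of the four index profiles across groups."""
    per_group = split_and_fit(table, group_column)
    labels = sorted(per_group)
    if len(labels) != 2:
        raise ValueError(
            f"invariance test compares exactly 2 groups; {group_column!r} has {len(labels)}"
        )
    a, b = labels
    ta = per_group[a].set_index("symptom")
    tb = per_group[b].set_index("symptom")
    common = [s for s in ta.index if s in tb.index]

    rows = []
    for name in INDEX_NAMES:
        res = wilcoxon_signed_rank(
            ta.loc[common, name].to_numpy(), tb.loc[common, name].to_numpy()
        )
        rows.append(
            {
                "index": name,
                "W_plus": res.w_plus,
                "W_minus": res.w_minus,
                "n_effective": res.n_effective,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    sizes = {
        label: int((table.data[group_column] == label).sum()) for label in labels
    }
    dropped = [c for c in table.item_columns if c not in common]
    return InvarianceResult(
        group_column=group_column,
        group_labels=labels,
        group_sizes=sizes,
        group_centrality=per_group,
        tests=pd.DataFrame(rows).set_index("index"),
        dropped_items=dropped,
    )
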