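# Methods

## Model

Each of the K ordinal items (default K = 9, levels 0–3) is modeled as a
discretized latent standard-normal variable: item j takes level c when its
latent score falls between thresholds τ<sub>j,c</sub> and τ<sub>j,c+1</sub>.
The latent vector is multivariate normal with correlation matrix R. All
network quantities are functions of R and of the sample size.

**Polychoric estimation** is two-step: thresholds from the marginal
cumulative proportions (τ = Φ⁻¹(p), empty categories collapse into their
neighbour and are recorded), then each pairwise ρ by one-dimensional
maximum likelihood over the 4×4 contingency table, with rectangle
probabilities from the closed-form bivariate-normal CDF (Owen's T
function; absolute accuracy ≈ 1e−14, far below the 1e−7 the estimate
needs). ρ is constrained to [−0.999, 0.999]; estimates within 1e−4 of the
bound are snapped to it and flagged (perfect-association tables). The
assembled matrix is repaired, if needed, by eigenvalue clipping (negative
eigenvalues raised to 1e−6, rescaled to unit diagonal) — chosen over
nearest-correlation iteration because it is deterministic and adequate at
9 items. Two-step rather than full joint ML: standard, fast, and the
difference is negligible at these sample sizes.

**Undirected network.** Graphical lasso (the scikit-learn coordinate
solver) along a 100-point log-spaced penalty grid from
λ<sub>max</sub> = max off-diagonal |ρ| down to λ<sub>max</sub>/100; model
selection by extended BIC, −n[log det Θ − tr(RΘ)] + E log n + 4Eγ log p,
with γ = 0.5 (the usual conservative default). The likelihood multiplier
is n (not n/2) throughout; only EBIC differences matter for selection.
EBIC ties break toward the larger penalty (sparser model). Precision
entries below 1e−6 in magnitude count as absent edges.

**Directed network.** The dependency of node i on node j is
D(i,j) = (1/(n−2)) Σ<sub>k∉{i,j}</sub> [r(i,k) − r(i,k|j)], with r(i,k|j)
the first-order partial correlation. The divisor n−2 averages over the
actual summands; any constant divisor rescales all arc weights uniformly
and leaves every rank-based result unchanged, so strength magnitudes are
comparable across analyses only up to this convention. The TMFG skeleton
is built on the symmetrized strength max(|D(i,j)|, |D(j,i)|): seed
4-clique of the nodes with largest total association, then repeated
insertion of the best remaining (vertex, face) pair, maximizing the summed
weight of the three adopted edges, until 3n−6 edges are placed. Ties break
toward the lowest vertex index, then the earliest-created face, making the
construction deterministic. Both opposing arcs are retained per skeleton
edge — arc i→j weighted by D(j,i) — so that every node has nonzero
incoming and outgoing strength and Σout = Σin holds exactly; the dominant
direction per edge is recorded separately.

**Centrality.** Out-/in-strength sum absolute arc weights. Relative
influence is (out − in)/(out + in), zero (flagged) for isolated nodes.
Betweenness and closeness use the standard inverse-weight distance
(length = 1/|weight|); betweenness is reported as raw Brandes counts with
fractional credit for ties (a normalized variant is available), closeness
as (number reached)/(summed distance), computed over the reachable set
with a coverage flag — with both arcs retained the TMFG digraph is
strongly connected unless weights vanish.

**Stability.** Case-dropping bootstrap: for each retention level q,
subsamples of ⌊qN⌋ respondents are drawn without replacement (each
replication seeded as (master seed, level index, replication index)), the
full chain is re-estimated, per-node index values are averaged over
replications, and the Spearman correlation between averages and
full-sample values is reported. A rank-mean variant (average the
per-replication ranks first) is emitted alongside; the two coincide up to
ties. Failed replications (e.g. an item degenerate in a subsample) are
dropped and counted, with a warning above 5 %. q = 1 reproduces the full
sample exactly, so its correlations are exactly 1 — a structural check.

**Invariance.** Networks are estimated independently per group over the
common item set (an item degenerate in any group is dropped from all
groups, because the paired test needs matched nodes). For each index the
two 9-value profiles are compared by the paired Wilcoxon signed-rank test:
zero differences dropped, midranks for tied |d|, W⁺/W⁻ the positive and
negative rank sums (W⁺ + W⁻ = n′(n′+1)/2). The two-sided p is exact —
the null distribution of W⁺ built by rank-sum convolution, equivalent to
enumerating all 2<sup>n′</sup> sign assignments — when n′ ≤ 25 with no
ties, otherwise a normal approximation with continuity correction and
tie-corrected variance. The method used is reported with the p-value,
because different conventions differ visibly at n′ = 9.

A caveat the test suite documents: the nine paired differences share
sampling error through the common estimated network (a fluctuation in one
group's overall connectivity shifts all nine differences the same way), so
the profile-level test is anti-conservative under the null — its p-values
are not uniformly distributed even when both groups share the same latent
structure. The calibration tests therefore check the median null p (well
above the rejection region) and power against a strong group effect,
rather than a nominal type-I rate.

## Synthetic data

The generator emulates a community depression-screening sample: N = 975
respondents by default, 9 items, a latent Gaussian with a sparse
partial-correlation ground truth (chain, hub, random-sparse or planar-fan
support; unit-diagonal precision, positive definiteness checked at
construction), default thresholds (0.25, 0.9, 1.6) giving right-skewed
marginals (≈ 60/22/13/5 % per level) typical of non-clinical samples,
a 65/35 female/male split and an even two-level age split (18–28 vs
29–68). Group differences are introduced, when wanted, by multiplying
every latent partial correlation for one group by `group_effect`, giving a
controllable alternative for power checks.

What it does not emulate: item-specific threshold profiles, local
dependence beyond the Gaussian copula, response styles, and missingness —
so passing recovery tests shows the estimators work under the model's own
assumptions, not that real questionnaire data satisfy them.

## Problem sizes used in tests

Unit tests run at n = 400–2 000; parameter recovery uses a chain with
partials 0.3 at n = 5 000 (single seed) and n = 2 000 across seeds 1–20
for glasso support recovery; stability uses n = 2 000 with 200
replications at 70 % retention (the library default remains 1 000
replications at 70/60/50 %), and the retention-monotonicity check runs
5 seeds at n = 800 with 40 replications. Monte-Carlo consistency checks
run at n ∈ {500, 5 000, 50 000} with tolerances 0.1/0.05/0.02.

## Degenerate inputs and numerical choices

- Items with one populated category are excluded (whole-sample) or dropped
  from all groups (grouped analysis), with warnings.
- Perfect-association pair tables return the boundary ρ = ±0.999, flagged.
- Polychoric optimization: bounded Brent, |x| tolerance 1e−8.
- Glasso non-convergence raises, naming the penalty.
- Missing data: listwise deletion by default; a pairwise option keeps all
  rows and uses pairwise-complete contingency tables (per-pair n is
  recorded). The default keeps one consistent N across all pairs.
- Betweenness/closeness treat zero-weight arcs as absent; unreachable
  pairs are skipped (betweenness) or handled over the reachable set with a
  flag (closeness).

## Known limitations

- Dependency arc weights are reported on the 1/(n−2) scale; comparisons
  with analyses using a different divisor require uniform rescaling.
- The TMFG greedy is order-deterministic but, like all greedy information
  filters, not guaranteed globally optimal; tests verify step-wise
  optimality against exhaustive face search at small n.
- Exact Wilcoxon p-values require untied ranks; tied profiles fall back to
  the normal approximation regardless of n′.
- The EBIC γ = 0.5 default favours sparsity; very weak true edges near the
  penalty floor may be retained as near-zero weights or dropped depending
  on sample size.
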