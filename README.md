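# symptomnet

Network analysis of depressive symptoms from ordinal questionnaire data
(PHQ-9 style: nine items scored 0–3). The package estimates which symptoms
are central in the web of mutual symptom associations, which symptoms
*influence* versus *are influenced by* the rest, how stable those
conclusions are under case dropping, and whether they differ between
demographic groups.

## What it computes

Ordinal items are treated as discretizations of latent standard-normal
variables. From a respondent-by-item table the pipeline estimates:

1. **Polychoric correlations** — per-item thresholds
   τ<sub>k</sub> = Φ⁻¹(cumulative proportion), then each pairwise latent
   correlation ρ̂ by maximizing Σ n<sub>ab</sub> log P<sub>ab</sub>(ρ) over
   the bivariate-normal rectangle probabilities of the contingency table.
2. **Undirected network** — graphical lasso over a log-spaced penalty path,
   with the penalty chosen by the extended BIC
   −n[log det Θ − tr(RΘ)] + E log n + 4Eγ log p (γ = 0.5); edge weights
   are the regularized partial correlations −θ<sub>ij</sub>/√(θ<sub>ii</sub>θ<sub>jj</sub>).
3. **Directed network** — a node-dependency matrix
   D(i,j) = mean<sub>k∉{i,j}</sub>[r(i,k) − r(i,k|j)] (how much of i's
   correlations run through j), filtered to a planar Triangulated Maximally
   Filtered Graph (TMFG) skeleton of 3n−6 edges; each edge carries two
   opposing arcs weighted by the corresponding dependency entries.
4. **Centrality** — out-/in-strength (sums of absolute arc weights),
   relative influence (out − in)/(out + in), and betweenness/closeness over
   inverse-weight shortest directed paths.
5. **Stability** — case-dropping bootstrap: re-estimate everything on
   subsamples retaining 70/60/50 % of respondents and rank-correlate the
   averaged centralities with the full-sample values.
6. **Invariance** — estimate per-group networks (gender; age ≤28 vs ≥29)
   and compare centrality profiles with the paired Wilcoxon signed-rank
   test (zero differences dropped, midranks for ties, exact p for ≤25
   untied differences).

A seeded synthetic-data generator with known sparse latent structure
(chain / hub / random / planar supports) makes every stage testable and
supports parameter-recovery experiments.

## Worked example

```python
import symptomnet as sn

spec = sn.make_ground_truth("chain", 9, (0.3, 0.3), seed=1, n_respondents=2000)
table = sn.simulate_responses(spec)          # 2000 respondents x 9 ordinal items
poly = sn.correlation_matrix(table)          # polychoric rho + thresholds
net = sn.fit_directed(poly)                  # dependency-TMFG directed network
print(sn.centrality_table(net).round(3).to_string(index=False))
```

```
symptom  out_strength  in_strength  relative_influence  betweenness  closeness
     D4         0.084        0.055               0.203         30.0      0.009
     D6         0.080        0.067               0.093         20.0      0.008
     D8         0.065        0.047               0.156          7.0      0.006
     D3         0.063        0.045               0.168         24.0      0.008
     D7         0.060        0.051               0.082          7.0      0.007
     D5         0.043        0.064              -0.195         20.0      0.008
     D2         0.027        0.045              -0.240         14.0      0.004
     D1         0.009        0.025              -0.467          0.0      0.002
     D9         0.003        0.035              -0.842          0.0      0.002
```

The mid-chain items (D4–D6) are the most central — they carry the most
arc weight and lie on the most shortest paths — while the chain ends (D1,
D9) receive more influence than they emit (negative relative influence).
`sn.case_drop_bootstrap(table, reps=200, seed=7)` then reports, per index
and retention level, the Spearman correlation between subsample-averaged
and full-sample centralities, and
`sn.invariance_report(table, "gender")` the per-group W⁺/W⁻/p table.

The same stages are runnable from a shell:

```sh
symptomnet simulate --structure chain --n 975 --seed 1 data.csv
symptomnet fit --seed 1 data.csv
symptomnet stability --reps 1000 --seed 1 data.csv
symptomnet invariance --group gender data.csv
symptomnet report --group gender --stability data.csv
```

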