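# Methods

This note documents the models, defaults and numerical choices behind
`prizenet`, and what the synthetic benchmark does and does not establish.

## Differential filtering

Features are retained when `|log2FC| ≥ log2(fold_threshold)` **and**
`p_adjusted < alpha` (strict boundary; the fold bound is inclusive and
symmetric in direction). FDR adjustment is Benjamini–Hochberg step-up,
implemented directly and cross-checked against statsmodels in the tests.
Defaults: fold threshold 1.25 everywhere; transcript alpha 0.05 per cluster;
ubiquitinome alpha 0.1; proteome alpha 1e-4 in the `methods` preset and 0.05
in the `results` preset. Both proteome presets are first-class because the
strict threshold is only attainable with deep replication — the synthetic
benchmark (4 replicates/group) uses `results`.

diGly ubiquitin sites are collapsed to one nonredundant record per parent
protein *before* filtering, keeping the most significant site (minimum
adjusted p; ties by larger |log2FC|, then lexicographic site id).

TMT channel intensities can be normalized by total signal: each value is
divided by its channel total and rescaled by the mean total, so channel sums
agree exactly afterwards.

### Two-sample tests

Three tests are provided:

* `cluster_de_test` — two-sided Wilcoxon rank-sum with midranks; exact by
  enumeration of all labelings when both groups have ≤ 8 observations,
  otherwise a normal approximation with tie correction and a 0.5 continuity
  correction. The exact two-sided p counts labelings whose rank-sum deviates
  from its mean at least as much as observed (the null distribution is
  symmetric, so this equals the usual doubled tail).
* `welch_t_test` — per-feature Welch t, vectorized.
* `moderated_t_test_matrix` — pooled two-sample t with empirical-Bayes
  variance moderation: per-feature pooled variances are shrunk toward a
  scaled-inverse-chi-square prior fitted from the moments of `log s²`
  (Newton inversion of the trigamma function); the statistic uses the
  posterior variance with residual + prior degrees of freedom.

The synthetic generator produces its p-values with the moderated test. The
reason is statistical, not cosmetic: with 4 replicates per group an exact
rank-sum p cannot go below `2/C(8,4) ≈ 0.029` and a per-feature t-test has
only 6 degrees of freedom, so after BH adjustment over hundreds of features
essentially nothing is callable even for a true 4-sigma effect. Sharing
variance information across features is the standard small-replicate remedy
in omics DE, and in the generator's homogeneous-noise world the prior
degrees of freedom are correctly estimated as infinite (the pooled z-test
limit) while FDR remains controlled under the null (measured in the tests).
With noise sd 0 the test degenerates gracefully: p = 1 for equal means, the
smallest representable p otherwise.

## Prizes and edge costs

Prizes: `p(v) = (−log10 q_v) · m(v)` with `m(v) = c_v / c̄` for genes
measured in the single-cell data and `m(v) = 1` otherwise (unmeasured is not
unchanged; a zero multiplier would silently erase proteomic evidence). `c̄`
averages cluster counts over genes with at least one DE cluster; if no gene
has any, the single-cell adjustment is skipped entirely (multipliers 1,
base edge costs). Dual-evidence nodes (proteome + ubiquitinome) sum their
layer prizes and are tagged `terminal_both`. An adjusted p of exactly 0 is
rejected (infinite prize).

Edge costs: base cost `max(1 − confidence, 0.01)`; the floor prevents
zero-cost edges from degenerating the solver. Cluster ratios are ranked
**descending** so that edges between genes DE in many cell types receive the
smallest multipliers (`rank/|E|` ∈ (0, 1]) — the direction that implements
"prioritize genes differentially expressed across many cell types".
Ranking is performed on the integer count sums (same order as the ratios,
which differ only by the positive constant `1/(2c̄)`) so ties are detected
exactly rather than at floating-point whim. Multipliers never exceed 1, so
adjusted costs never exceed base costs, and any strictly increasing
transform of the ratios leaves them unchanged.

## PCSF solvers

Objective: `β·Σ_{v∉F} p(v) + Σ_{e∈F} c(e) + ω·κ`. Defaults β = 1, ω = 2,
both exposed; no published values exist for the original analysis, and ω = 2
makes an isolated hit enter the forest only when its β-scaled prize exceeds
2 (q below 0.01 at multiplier 1), a sensible bar against singleton noise.

**Exact oracle** (≤ 14 nodes): for each node subset `S`, the cheapest forest
on `S` is the minimum spanning tree of `S ∪ {root}` where the virtual root
joins every node at cost ω — deleting the root yields κ trees and the MST
cost equals forest cost + ωκ. Ties between optima break toward fewer nodes,
then lexicographically smaller node sets (tolerance 1e-9).

**Heuristic**: Goemans–Williamson moat growth on the rooted transformation
(root edges of cost ω to every prized node; β-scaled prizes as cluster
potentials). Active clusters grow uniformly; an edge whose slack is consumed
merges its clusters, a cluster that exhausts its potential deactivates, and
clusters containing the root never grow. The merge forest's root component
is kept; each subtree hanging off a root edge is strong-pruned (a child
subtree is cut when its net value — β-prize sum minus internal cost — falls
below its attaching edge; a whole tree is dropped when its net value falls
below ω). A final **split pass** removes any tree edge costing more than ω:
trading one such edge for one extra tree penalty strictly lowers the
objective. Everything is deterministic: fixed edge ordering resolves all
simultaneous events, so identical instances give identical forests without
any seed. On random small instances the heuristic never beats the oracle and
stays within the 2·optimum + ω bound of the underlying approximation scheme
(verified on 200 instances in the acceptance tests).

`prune` is idempotent, never increases the objective, and leaves no leaf
with zero prize.

## Modules and enrichment

The recovered forest (edges weighted by interactome confidence) is
partitioned with seeded Louvain modularity maximization (networkx
implementation behind the package surface); community ids are renumbered by
smallest member for stable output. Modularity is recomputed independently
from the Newman–Girvan definition `Q = Σ_c [w_c/m − γ(d_c/2m)²]` as a
cross-check.

Enrichment per module: one-sided over-representation p by exact rational
hypergeometric summation (`P(X ≥ k)`; overlap 0 gives exactly 1); a term's
z-score is the deviation of its observed rank (terms sorted by ascending p,
average ranks on ties) from the mean rank over `n_permutations` (default
100) random gene sets of the module's size, divided by the null sd (floored
at 1e-9, sample sd); combined score `c = ln(p)·z`. Raw p-values are reported
by default, mirroring how enrichment services print them; BH across terms is
available by flag. Depletion is not scored.

## Synthetic benchmark

The generator emulates the statistical shape of a fly-brain
loss-of-function multi-omic study: 24 single-cell clusters; site-level
ubiquitination mapped to proteins at roughly 2 sites per covered protein
(uniform on {1, 2, 3}, 25% coverage); log2FC-with-FDR tables for all layers.
The interactome is Barabási–Albert preferential attachment (heavy-tailed
degrees like STRING; 500 nodes, 3 edges/node) with confidences from a
right-skewed Beta(2, 5). The planted module is grown by seeded breadth-first
random expansion, so its induced subgraph is connected; each planted gene is
truly DE in Binomial(24, 0.5) clusters (minimum 1). Default effect 2-fold
(log2FC 1.0), replicate noise sd 0.25, 4 replicates/group. All stages draw
from independent children of one seed sequence; outputs are bit-reproducible.

What a green benchmark establishes: that the whole chain — simulation, BH
filtering, cluster-informed weighting, PCSF recovery — finds a connected
planted module under realistic noise (median node-level F1 ≥ 0.8 over 10
seeds) and returns essentially nothing when no signal is planted. What it
does not establish: robustness to the features of real data the generator
omits — per-feature variance heterogeneity, correlated replicates,
batch/loading effects, annotation errors in the interactome, hub-biased
study coverage, and identifier mismatch between layers.

## Degenerate inputs and numerics

* Empty prize set → the pipeline reports an empty forest (κ = 0) rather than
  failing; `assemble_instance` errors only when prizes exist but none maps
  into the graph.
* Confidence exactly 1 → cost floor 0.01; confidences outside (0, 1] are
  format errors.
* All solver comparisons use 1e-9 tolerances; BH and modularity checks are
  exact to 1e-12 in the tests.
* GraphML/TSV/JSON outputs sort nodes, edges and keys, and are byte-stable
  across runs for identical inputs.

## Known limitations

* The heuristic carries the primal–dual scheme's approximation guarantee
  empirically, not as a proof for the forest variant with the split pass;
  the oracle-bound test is the evidence.
* Louvain is seeded-deterministic but, like all greedy modularity methods,
  resolution-dependent; resolution defaults to 1.
* The rank z-score uses Monte-Carlo nulls (100 permutations), so z values
  have sampling error of order 1/√100; p-values and combined scores inherit
  it only through z.
* No ILP or belief-propagation solver backend; no randomized edge-noise
  robustness ensembles.
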