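# Methods

`morphnet` builds and analyzes *morphological similarity networks* at the
single-neuron level. Each neuron is summarized by a vector of morphometric
features; the similarity between two neurons is the Pearson correlation of
their z-scored feature vectors; thresholding the similarity matrix yields a
binary graph whose topology is then characterized with the standard
graph-theoretic toolkit of network neuroscience. This note records the model
choices, defaults, and numerical decisions, and what the synthetic-data
tests do and do not establish.

## Morphometric features

SWC reconstructions (id, type, x, y, z, radius, parent; µm) are validated as
rooted trees: unique ids, a single `parent = -1` root, no dangling parents,
no cycles. Contiguous type-1 (soma) nodes collapse into one soma; the soma
surface uses the single-point convention 4πr² on the root radius, the common
dialect of public repositories.

The built-in catalogue has 21 L-Measure-compatible features: `Soma_Surface`,
`N_stems`, `N_bifs`, `N_branch`, `N_tips`, `Width`/`Height`/`Depth`
(coordinate extents), `Diameter` (mean 2r over neurite nodes), `Length`,
`Surface`, `Volume` (per-compartment cylinder sums, radius taken from the
child node), `EucDistance`, `PathDistance`, `Branch_Order`, `Contraction`
(per-branch straight-line/path ratio; zero-length branches excluded),
`Fragmentation`, `Partition_asymmetry` (|n₁−n₂|/(n₁+n₂−2) over tip counts,
0 for 1-vs-1 splits), `Bif_ampl_local`, `Bif_ampl_remote` (angles in
degrees, local between first daughter compartments, remote between vectors
to each daughter subtree's next bifurcation-or-tip), and `Daughter_Ratio`.
Degenerate statistics (e.g. bifurcation angles of an unbranched neurite)
return 0 with a warning rather than NaN, so downstream matrices stay
finite. Richer feature sets (e.g. a full 42-feature L-Measure export) enter
through `read_feature_table`, and everything downstream is agnostic to the
catalogue's identity.

## Network construction

1. **Z-transform** each feature across neurons (sample sd, ddof = 1);
   zero-variance features are an error, for the caller to drop explicitly.
2. **Similarity**: Pearson correlation between neuron feature vectors,
   computed across features (≥3 features required).
3. **Thresholding**: negative and zero correlations are discarded. Edges
   are admitted in descending correlation until all nodes form a single
   connected component; the critical threshold r\* found this way equals the
   minimum edge weight of the maximum spanning tree of the positive-weight
   graph (verified against brute-force MSTs in the tests). All ties at r\*
   are retained, making the result deterministic and order-independent. If
   the resulting edge density (sparsity = E / (N(N−1)/2)) is still below
   the small-world estimability bound — mean degree 2·log₁₀(N), i.e.
   sparsity 2·log₁₀(N)/(N−1) — additional whole tie-classes of edges are
   admitted in descending weight until the bound is met, and the report
   flags the bound as binding.

The log base of the bound deserves a note: of the four lower sparsity
limits printed in the source literature for networks of 1035, 1741, 101
and 572 nodes (0.007, 0.004, 0.046, 0.011), only the 1741-node value is
consistent with 2·log_b(N)/(N−1) for b = 10, and no single base reproduces
all four. The formula is implemented with log₁₀ as stated; the discrepancy
is documented rather than resolved.

## Graph measures

Clustering coefficient (mean over nodes, 0 for degree < 2), characteristic
path length (mean over unordered pairs; NaN when disconnected), global
efficiency (mean 1/d with unreachable pairs contributing 0), cost (edge
density) and cost efficiency (E_glob − cost) are computed with dense
unweighted BFS (scipy csgraph) and networkx clustering. Edge betweenness is
Brandes' algorithm normalized by N(N−1)/2, i.e. the fraction of all-pairs
shortest paths through an edge, with equal splitting among ties.

**Small-world indices.** γ and λ normalize Cp and Lp by the means of M
degree-preserving Maslov–Sneppen null networks (default M = 100, the
field's convention; 10·E attempted double-edge swaps per null, rejecting
self-loops and multi-edges). Disconnected nulls are redrawn up to 10
times, then Lp falls back to the largest component with a warning.
σ = γ/λ.

**Degree-distribution fits.** Three candidate models for P(k) on k ≥ 1:
power law k^(α−1), exponential e^(−k/k_c), exponentially truncated power
law k^(α−1)·e^(−k/k_c), each normalized over the observed support and
fitted by discrete maximum likelihood (Nelder–Mead; α initialized at 1.5,
k_c at the mean degree), with AIC = 2p − 2logL selection. MLE was chosen
over least squares on the log empirical CCDF after a direct comparison:
equally weighted CCDF points let the sparse tail (counts of one) dominate
and bias α downward by ≈0.25 at n = 2000, and an RSS-based AIC on
cumulative — hence strongly autocorrelated — residuals grossly overstates
the evidence for the larger nested model. With MLE, simulated truncated
power-law degrees (α = 1.3, k_c = 70, n = 2000) are recovered within
±0.15 on α and ±20% on k_c. Because the truncated model nests the
exponential at the interior point α = 1, AIC selects the exponential on
truly exponential data with asymptotic probability P(χ²₁ < 2) ≈ 0.84 —
a property of AIC itself, not a defect of the fit.

## Hubs, bridges, DCC

Hubs are the top 10% of nodes by degree, bridges the top 10% of edges by
edge betweenness; the count is floor(0.1·total) — the unique convention
consistent with the published counts 103/1035, 3,898/38,984 and
13,970/139,705 — with cutoff ties broken by stable identifier order. The
disproportionate contribution coefficient of class i,

    DCC_i = (N_hubs_i / N_hubs) / (N_nodes_i / N_nodes),

is 1 under proportional allocation (the node-share-weighted mean of DCC is
identically 1). For edges the same ratio is taken over within-class edges,
class pairs, or intra- vs inter-class aggregates. Unlabeled elements are
excluded from numerator and denominator, with a warning.

## Resilience

Nodes or edges are removed one at a time — uniformly at random (default
100 repetitions, averaged) or targeted at the current highest-degree node
/ highest-betweenness edge — and cost efficiency of the survivors is
recorded on a 0–100% grid in 1% steps. Targeting is adaptive (re-ranked
after every removal), the stricter attack; a flag restores the
initial-ranking variant. After node removals the cost denominator uses the
surviving node count, so an intact subgraph is scored self-consistently.
Resilience is summarized by the trapezoidal area under the curve. One
empirical subtlety: removing a top-degree node can transiently *raise*
cost efficiency (the cost term falls faster than efficiency), so random
failure dominates targeted attack per-fraction only for edge removal; at
the AUC level the ordering random > targeted holds for both.

## Inference

Two procedures recur. The **bootstrap-like subset Z**: the mean of a
distinguished subset (intra-class connections; hub neurons) minus the mean
of n same-size uniform subsets' means, divided by their sd (default
n = 10,000 draws, without replacement within a draw), with a two-sided
standard-normal p. The **permutation test**: ANOVA-F or two-sample t
recomputed under label shuffles, p = (1 + #{null ≥ observed})/(1 + n).
Benjamini–Hochberg FDR (q = 0.05) corrects across features or pairwise
contrasts; the implementation is checked against statsmodels in the tests.
The cross-group comparison rebuilds both groups' networks through the full
pipeline for every random size-preserving reallocation of the pooled
neurons and benchmarks each metric's observed difference as a Z against
that null. All procedures take explicit seeds and are deterministic given
them.

## Region-level projection comparison

Neuron-level matrices aggregate to region matrices by averaging *nonzero*
contributing entries only (zeros encode absence); similarity aggregation
masks to the binary network's retained edges. Projection matrices are
symmetrized by addition with the transpose. Association between the
modalities is tested four ways: Pearson chi-square (no continuity
correction) on the 2×2 presence table over region pairs; a permutation
two-sample t of similarity by projection presence; Pearson correlation
between the two cosine-similarity profile matrices (profiles exclude the
diagonal and the pair's own two entries, preventing self-inflation); and a
matched-sparsity comparison of nodal degrees and hub sets. Matched
thresholding is count-primary: published 3-decimal sparsities are rounded
from edge counts (1426/3741 → 0.381, 800/3741 → 0.214) and no floor/round
convention recovers both counts from the rounded values, so the API
accepts an exact edge count as well as a fractional sparsity (floor
convention, like the top-10% rule).

## Stability analyses

Leave-one-feature-out, random feature subsets (sizes 21–39 by 3, default
10,000 repetitions), and correlation-matrix PCA retaining the smallest
component set with cumulative explained variance ≥ 95% (component signs
fixed by the largest-magnitude loading). Agreement between conditions is
the Pearson r across upper triangles of the interneuron correlation
matrices. Note that Pearson-across-features is not rotation-invariant (row
means shift in the component basis), so rebuilding similarity from the
*full* component set lands near, not at, r = 1 (≈0.98 on 42-feature synthetic
tables); likewise removing one copy of a duplicated feature changes the
feature weighting slightly, so its leave-one-out agreement is the maximal,
but not exactly 1.

## Synthetic data

The generator is the test substrate and defines the study conditions:

- **Feature tables**: neurons in class c are μ_c + ε with μ_c drawn once
  per class (sd set by the target within-class correlation w through
  scale = noise_sd·√(w/(1−w))) and i.i.d. noise. Defaults: 120 neurons in
  3 equal classes, 42 features (the feature count of the motivating
  datasets), w = 0.3, unit noise. w = 0 yields exchangeable data for null
  calibration. Under the default conditions the resulting networks are
  quantitatively in the regime reported for real data (sparsity ≈ 0.07,
  γ ≈ 3–4, λ ≈ 1.2–1.4, cost efficiency ≈ 0.3).
- **SWC trees**: binary-branching neurites grown from a soma with
  configurable stem count, branching probability, depth, segment length and
  direction jitter; all tree invariants hold by construction.
- **Projections**: strength = ρ·(rank-transformed region similarity) +
  (1−ρ)·uniform noise, weakest fraction zeroed.
- **Degree sequences**: i.i.d. draws from any of the three fit models'
  pmfs on k ≥ 1.

What this generator does *not* emulate: measurement noise correlated
across features, heavy-tailed feature marginals, hierarchical class
structure (layers within regions), or any spatial embedding of neurons.
Passing tests therefore establish internal correctness and statistical
calibration/power of the procedures under clean class structure, not
biological fidelity of any particular dataset's numbers.

## Problem sizes used in the test suite

Desk-scale defaults keep the whole suite fast while preserving the
regimes of interest: networks of 60–120 neurons, 200–1,000 resampling
draws per test (10,000 remains the library default), 3–30 null networks
for small-world indices in tests (100 remains the default), 200 random
graphs of ≤8 nodes for the brute-force oracle comparisons, and 20 seeds
for the resilience ordering.
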