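# morphnet

Single-neuron **morphological brain networks**: build them from neuron
reconstructions or morphometric feature tables, and analyze their topology.

Morphological similarity networks extend the single-subject MRI idea of
cross-feature correlation down to the microscopic scale: each neuron
(reconstructed as an SWC tree, summarized by morphometric features such as
soma surface, branch counts, extents, and bifurcation angles) becomes a
node, and the edge weight between two neurons is the Pearson correlation of
their z-scored feature vectors, computed across features. Thresholding the
similarity matrix to the sparsest single-component binary graph gives a
network whose organization — small-worldness, cost efficiency, hub and
bridge structure, resilience to attack — can be compared across cell
classes, brain regions, and species. The package is aimed at computational
neuroanatomists and network neuroscientists who want this pipeline as a
library and CLI, with every stochastic step seeded.

## The core quantities

- similarity: `r_ij = corr(z(x_i), z(x_j))` across features; negative
  correlations are excluded before thresholding.
- threshold: edges are admitted in descending `r` until all `N` neurons
  form one connected component (the critical `r*` is exactly the maximum
  spanning tree bottleneck); sparsity is raised further if needed so mean
  degree exceeds `2·log10(N)`.
- small-worldness: `γ = Cp/⟨Cp_rand⟩`, `λ = Lp/⟨Lp_rand⟩`, `σ = γ/λ`,
  against degree-preserving Maslov–Sneppen nulls.
- cost efficiency: `E_glob − cost`, recomputed under node/edge attack.
- degree fits: power law `k^(α−1)`, exponential `e^(−k/k_c)`, truncated
  power law `k^(α−1)·e^(−k/k_c)`, AIC-selected.
- hubs / bridges: top 10% by degree / edge betweenness;
  `DCC_i = (N_hubs_i/N_hubs)/(N_nodes_i/N_nodes)` quantifies
  over-representation of a class (DCC > 1) among hubs or bridges.
- inference: bootstrap-like subset Z tests, permutation ANOVA/t with
  Benjamini–Hochberg FDR, and a cross-group permutation comparison that
  rebuilds networks per reallocation.

See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic population of 120 neurons in three morphological
classes (42 features, within-class correlation 0.3), build its network, and
analyze it:

```sh
morphnet synth --out table.tsv --metadata-out meta.tsv --n-neurons 120 --seed 1
morphnet build table.tsv --out-dir out/
morphnet metrics table.tsv --out out/metrics.json --nulls 100 --seed 2
morphnet hubs table.tsv --metadata meta.tsv --out out/hubs.json
```

prints

```
wrote 120 neurons x 42 features
N=120 E=588 sparsity=0.0824 min_r=0.2822 bound_binding=False
Cp=0.3615 Lp=3.0315 Eglob=0.3953 costE=0.3130 gamma=3.121 lambda=1.283 sigma=2.432
12 hubs, 58 bridges -> out/hubs.json
```

Reading: the sparsest connected binarization keeps 588 of 7,140 possible
edges (sparsity 0.082, weakest retained correlation 0.28); the network is
small-world (clustering 3.1× its degree-matched nulls at near-random path
length, σ = 2.43) and economical (global efficiency exceeds wiring cost by
0.31). Of the 12 hubs (top 10% of 120 by degree), 8 fall in class C —
`out/hubs.json` reports `DCC = 2.0` for C and 0.5 for A and B, i.e. class C
is over-represented among hubs twofold relative to its share of neurons.
The same library calls are available in Python (`morphnet.build_network`,
`morphnet.graphmetrics.small_world`, `morphnet.hubs_bridges.node_dcc`, ...),
and `morphnet attack`, `morphnet stats`, `morphnet robustness`, and
`morphnet projection` cover resilience curves, class/hub inference,
feature-stability, and region-level projection comparison.

SWC input works the same way: `morphnet features <dir-of-swc> --out
table.tsv` computes the built-in 21-feature catalogue; externally computed
feature tables (e.g. a full L-Measure export) drop in via the same TSV
format.

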