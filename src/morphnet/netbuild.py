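"""Construction of binary morphological similarity networks.

Each neuron's morphometric feature vector is z-scored feature-wise, pairs of
neurons are correlated across features (Pearson), and the resulting
similarity matrix is thresholded to the sparsest binary graph that (a) keeps
only positive correlations, (b) forms a single connected component with no
isolated node, and (c) has mean degree of at least 2*log10(N). The critical
threshold r* is found exactly by inserting edges in descending correlation
with union-find; ties at r* are all retained, so the result is deterministic
and independent of edge enumeration order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .morpho_io import FeatureTable

__all__ = [
    "SimilarityMatrix",
    "BinaryNetwork",
    "ThresholdReport",
    "zscore_features",
    "pairwise_similarity",
    "sparsity_lower_bound",
    "binarize_connected",
    "sparsity",
]


def sparsity(n_nodes: int, n_edges: int) -> float:
    """Edge density: existing edges over the N(N-1)/2 possible edges."""
    if n_nodes < 2:
        raise ValueError("sparsity needs at least 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1) / 2)


class SimilarityMatrix:
    """Symmetric neuron-by-neuron Pearson correlation matrix.

    The diagonal is never treated as an edge; it is stored as 1 but ignored
    by every downstream consumer.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("similarity matrix is not symmetric")
        if np.nanmax(np.abs(values)) > 1 + 1e-12:
            raise ValueError("|r| exceeds 1")
        self.labels = list(labels)
        self.values = (values + values.T) / 2.0  # enforce exact symmetry

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="neuron")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


class BinaryNetwork:
    """Undirected simple graph over neuron labels (thin networkx wrapper)."""

    def __init__(self, labels: Sequence[str], edges: Sequence[tuple[str, str]]):
        self.labels = list(labels)
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            g.add_edge(u, v)
        self.graph = g

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def e(self) -> int:
        return self.graph.number_of_edges()

    @property
    def sparsity(self) -> float:
        return sparsity(self.n, self.e)

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.labels, dtype=float)

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(map(sorted, self.graph.edges())):
                fh.write(f"{u}\t{v}\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"BinaryNetwork(N={self.n}, E={self.e})"


@dataclass
class ThresholdReport:
    """Provenance of a thresholding run."""

    n: int
    e: int
    sparsity: float
    min_retained_r: float
    small_world_bound: float
    bound_binding: bool

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def zscore_features(table: FeatureTable) -> FeatureTable:
    """Z-transform each feature column to mean 0, sample (n-1) sd 1."""
    if table.n_neurons < 2:
        raise ValueError("z-scoring requires at least 2 neurons")
    sd = table.values.std(axis=0, ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance feature(s): {dead}")
    z = (table.values - table.values.mean(axis=0)) / sd
    return FeatureTable(z, table.metadata)


def pairwise_similarity(table: FeatureTable) -> SimilarityMatrix:
    """Pearson correlation between each pair of neurons, across features."""
    if table.n_features < 3:
        raise ValueError("pairwise similarity requires at least 3 features")
    x = table.values.to_numpy()
    row_sd = x.std(axis=1)
    flat = np.asarray(table.neuron_labels)[row_sd == 0]
    if len(flat):
        raise ValueError(f"neuron(s) with zero feature variance: {list(flat)}")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return SimilarityMatrix(table.neuron_labels, r)


def sparsity_lower_bound(n: int) -> float:
    """Sparsity at which the mean degree equals 2*log10(N)."""
    if n < 3:
        raise ValueError("lower bound needs N >= 3")
    return 2.0 * math.log10(n) / (n - 1)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n
        self.n_components = n

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        self.n_components -= 1
        return True


def binarize_connected(sim: SimilarityMatrix) -> tuple[BinaryNetwork, ThresholdReport]:
    """Threshold a similarity matrix to the sparsest single-component graph.

    Edges are admitted in descending correlation (positive correlations
    only). The connectivity threshold r* is the weight at which all nodes
    first form one component — equivalently the minimum edge weight on the
    maximum spanning tree of the positive-weight graph. All ties at r* are
    retained. If the resulting sparsity still falls below the small-world
    lower bound 2*log10(N)/(N-1), further whole tie-classes of edges are
    admitted in descending weight until the bound is met; the report flags
    which criterion bound the threshold.
    """
    n = sim.n
    if n < 3:
        raise ValueError("need at least 3 neurons to build a network")
    iu, ju = np.triu_indices(n, k=1)
    w = sim.values[iu, ju]
    pos = w > 0
    if not pos.any():
        raise ValueError("all correlations are non-positive; no edges available")
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.argsort(-w, kind="stable")
    iu, ju, w = iu[order], ju[order], w[order]

    uf = _UnionFind(n)
    r_star = None
    for k in range(len(w)):
        uf.union(int(iu[k]), int(ju[k]))
        if uf.n_components == 1:
            r_star = w[k]
            break
    if r_star is None:
        raise ValueError(
            "cannot form single component: positive-correlation graph disconnected"
        )

    keep = w >= r_star
    bound = sparsity_lower_bound(n)
    max_e = n * (n - 1) / 2
    bound_binding = False
    if keep.sum() / max_e < bound:
        bound_binding = True
        # admit further edges in descending weight, whole tie-classes at a time
        need = math.ceil(bound * max_e)
        k = int(keep.sum())
        while k < len(w) and (k < need or (k > 0 and w[k] == w[k - 1])):
            k += 1
        keep[:k] = True
    min_r = float(w[keep].min())
    labels = sim.labels
    edges = [(labels[int(a)], labels[int(b)]) for a, b in zip(iu[keep], ju[keep])]
    net = BinaryNetwork(labels, edges)
    report = ThresholdReport(
        n=n,
        e=net.e,
        sparsity=net.sparsity,
        min_retained_r=min_r,
        small_world_bound=bound,
        bound_binding=bound_binding,
    )
    return net, report


def build_network(table: FeatureTable) -> tuple[BinaryNetwork, ThresholdReport, SimilarityMatrix]:
    """Full pipeline: z-score -> pairwise Pearson -> connected binarization."""
    sim = pairwise_similarity(zscore_features(table))
    net, report = binarize_connected(sim)
    return net, report, sim
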