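"""Region-level comparison of morphological similarity and axonal projections.

Neuron-level quantities are aggregated into region-by-region matrices
(means over nonzero contributing elements only — zeros encode absence, not
strength), projection matrices are symmetrized by addition with their
transpose, and the two modalities are compared four ways: a chi-square test
of edge presence, a permutation t test of similarity by projection status, a
Pearson correlation between cosine-similarity connectivity profiles, and a
matched-sparsity comparison of nodal degrees and hubs.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hubs_bridges import identify_top_fraction, TopSet
from .inference import TestResult
from .netbuild import SimilarityMatrix, BinaryNetwork, sparsity as _sparsity

__all__ = [
    "RegionMatrix",
    "aggregate_regions",
    "symmetrize",
    "presence_association",
    "similarity_by_projection_test",
    "profile_cosine_correlation",
    "matched_sparsity_hubs",
]


class RegionMatrix:
    """Square region-by-region matrix of nonnegative strengths or mean similarities."""

    def __init__(self, labels: Sequence[str], values: np.ndarray,
                 symmetric: bool | None = None):
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} != ({n}, {n})")
        self.labels = list(labels)
        self.values = values
        self.symmetric = (
            bool(np.allclose(values, values.T)) if symmetric is None else symmetric
        )

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="region")

    @classmethod
    def read_tsv(cls, path) -> "RegionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def aggregate_regions(
    neuron_matrix: np.ndarray | SimilarityMatrix,
    neuron_labels: Sequence[str],
    region_labels: Mapping[str, str],
    mask: np.ndarray | None = None,
) -> RegionMatrix:
    """Average a neuron-level matrix into a region-by-region matrix.

    Entry (A, B) is the mean over *nonzero* contributing elements between
    neurons of region A and neurons of region B; pairs with no nonzero
    element get 0 (absence). For similarity matrices, pass the binary
    network's adjacency as ``mask`` so that only retained edges contribute.
    Regions with no neurons are omitted with a warning.
    """
    values = (
        neuron_matrix.values if isinstance(neuron_matrix, SimilarityMatrix)
        else np.asarray(neuron_matrix, dtype=float)
    )
    unlabeled = [l for l in neuron_labels if region_labels.get(l) is None]
    if unlabeled:
        raise ValueError(f"neuron(s) without region label: {unlabeled[:5]}")
    contrib = values if mask is None else values * (np.asarray(mask) != 0)
    regions = sorted({region_labels[l] for l in neuron_labels})
    idx_of = {r: [i for i, l in enumerate(neuron_labels) if region_labels[l] == r]
              for r in regions}
    empty = [r for r in regions if not idx_of[r]]
    if empty:  # pragma: no cover - unreachable with labels derived from neurons
        warnings.warn(f"region(s) with no neurons omitted: {empty}", stacklevel=2)
        regions = [r for r in regions if idx_of[r]]
    n = len(regions)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            block = contrib[np.ix_(idx_of[regions[a]], idx_of[regions[b]])]
            if a == b:
                # exclude the diagonal of the block (self-pairs)
                block = block[~np.eye(block.shape[0], dtype=bool)]
            nz = block[block != 0]
            out[a, b] = nz.mean() if nz.size else 0.0
    return RegionMatrix(regions, out)


def symmetrize(m: RegionMatrix) -> RegionMatrix:
    """Symmetrize by addition with the transpose."""
    return RegionMatrix(m.labels, m.values + m.values.T, symmetric=True)


def _check_same_regions(a: RegionMatrix, b: RegionMatrix) -> None:
    if a.labels != b.labels:
        raise ValueError("region matrices must share the same region set")


def presence_association(sim: RegionMatrix, proj: RegionMatrix) -> tuple[float, float]:
    """Chi-square association between edge presence in the two matrices.

    Builds the 2x2 contingency of (morphological connection present/absent)
    x (projection present/absent) over the off-diagonal upper triangle;
    Pearson chi-square without continuity correction, 1 df.
    """
    _check_same_regions(sim, proj)
    s = sim.upper_triangle() != 0
    p = proj.upper_triangle() != 0
    table = np.array([
        [np.sum(s & p), np.sum(s & ~p)],
        [np.sum(~s & p), np.sum(~s & ~p)],
    ], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a margin is zero")
    chi2, pval, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(pval)


def similarity_by_projection_test(
    sim: RegionMatrix, proj: RegionMatrix, n: int = 10_000, seed: int | None = None
) -> TestResult:
    """Permutation two-sample t: similarity of projected vs unprojected pairs."""
    _check_same_regions(sim, proj)
    s = sim.upper_triangle()
    grp = proj.upper_triangle() != 0
    a, b = s[grp], s[~grp]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one projection-presence group is empty")

    def tstat(x, y):
        sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (
            len(x) + len(y) - 2)
        return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))

    obs = tstat(a, b)
    rng = np.random.default_rng(seed)
    null = np.empty(n)
    for i in range(n):
        perm = rng.permutation(len(s))
        null[i] = tstat(s[perm[: len(a)]], s[perm[len(a):]])
    pval = (1 + np.sum(np.abs(null) >= abs(obs))) / (1 + n)
    sd = null.std(ddof=1)
    z = (obs - null.mean()) / sd if sd > 0 else np.nan
    return TestResult("projected_vs_unprojected_t", float(obs), float(null.mean()),
                      float(sd), float(z), float(pval), n, seed)


def _cosine_profile_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of rows, excluding for each pair the
    diagonal and the pair's mutual entries."""
    n = values.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            keep = np.ones(n, dtype=bool)
            keep[[i, j]] = False
            u, v = values[i, keep], values[j, keep]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu == 0 or nv == 0:
                raise ValueError(f"zero-norm profile at region index {i if nu == 0 else j}")
            out[i, j] = out[j, i] = float(u @ v / (nu * nv))
    np.fill_diagonal(out, 0.0)
    return out


def profile_cosine_correlation(sim: RegionMatrix, proj: RegionMatrix) -> float:
    """Pearson r between the two modalities' cosine-profile matrices.

    For each region pair, the cosine similarity of their connectivity
    profiles is computed per modality (profiles exclude the diagonal and the
    pair's own two entries); r is taken across upper-triangle entries.
    """
    _check_same_regions(sim, proj)
    cs = _cosine_profile_matrix(sim.values)
    cp = _cosine_profile_matrix(proj.values)
    iu = np.triu_indices(sim.n, k=1)
    return float(np.corrcoef(cs[iu], cp[iu])[0, 1])


def threshold_region_matrix(
    m: RegionMatrix, sparsity: float | None = None, n_edges: int | None = None
) -> BinaryNetwork:
    """Binarize a symmetric region matrix by keeping the strongest edges.

    Exactly one of ``sparsity`` (floor(sparsity * possible-edge count) edges,
    the same floor convention as the top-10% rule) or ``n_edges`` must be
    given. Ties at the cutoff are broken by stable label order.
    """
    if not m.symmetric:
        raise ValueError("threshold requires a symmetric matrix")
    if (sparsity is None) == (n_edges is None):
        raise ValueError("give exactly one of sparsity or n_edges")
    max_e = m.n * (m.n - 1) // 2
    k = int(sparsity * max_e) if n_edges is None else int(n_edges)
    if not 0 < k <= max_e:
        raise ValueError(f"infeasible edge count {k} (max {max_e})")
    iu, ju = np.triu_indices(m.n, k=1)
    w = m.values[iu, ju]
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    edges = [(m.labels[int(iu[x])], m.labels[int(ju[x])]) for x in keep]
    return BinaryNetwork(m.labels, edges)


def matched_sparsity_hubs(
    sim: RegionMatrix,
    proj: RegionMatrix,
    sparsity: float | None = None,
    n_edges: int | None = None,
    hub_fraction: float = 0.10,
) -> dict:
    """Threshold both matrices at the same sparsity and compare hubs.

    Both matrices keep their top-weight edges at the matched sparsity; the
    result reports the Pearson correlation between the two nodal-degree
    vectors, each network's hub set (top ``hub_fraction`` by degree), and
    their intersection.
    """
    _check_same_regions(sim, proj)
    net_s = threshold_region_matrix(sim, sparsity=sparsity, n_edges=n_edges)
    net_p = threshold_region_matrix(proj, sparsity=sparsity, n_edges=n_edges)
    deg_s = np.array([net_s.degrees()[r] for r in sim.labels], dtype=float)
    deg_p = np.array([net_p.degrees()[r] for r in sim.labels], dtype=float)
    r = float(np.corrcoef(deg_s, deg_p)[0, 1])
    hubs_s = identify_top_fraction(net_s.degrees(), hub_fraction)
    hubs_p = identify_top_fraction(net_p.degrees(), hub_fraction)
    return {
        "degree_correlation": r,
        "n_edges": net_s.e,
        "sparsity": net_s.sparsity,
        "hubs_similarity": hubs_s,
        "hubs_projection": hubs_p,
        "common_hubs": sorted(set(hubs_s.members) & set(hubs_p.members)),
    }
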