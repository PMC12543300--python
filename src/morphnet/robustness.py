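"""Feature-stability analyses: leave-one-feature-out, subsampling, PCA.

Each analysis rebuilds the interneuron correlation matrix under a perturbed
feature set and scores its agreement with the all-feature matrix as the
Pearson correlation across upper-triangle entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .morpho_io import FeatureTable
from .netbuild import SimilarityMatrix, pairwise_similarity, zscore_features

__all__ = [
    "StabilityReport",
    "matrix_agreement",
    "leave_one_feature_out",
    "feature_subsample_stability",
    "pca_reduce",
]


@dataclass
class StabilityReport:
    kind: str
    conditions: pd.DataFrame = field(repr=False)
    reps: int = 1
    seed: int | None = None

    def to_tsv(self, path) -> None:
        self.conditions.to_csv(path, sep="\t", index=False)


def matrix_agreement(a: SimilarityMatrix, b: SimilarityMatrix) -> float:
    """Pearson r between two similarity matrices' upper triangles."""
    if a.labels != b.labels:
        raise ValueError("similarity matrices must share neuron labels")
    return float(np.corrcoef(a.upper_triangle(), b.upper_triangle())[0, 1])


def _similarity(table: FeatureTable) -> SimilarityMatrix:
    return pairwise_similarity(zscore_features(table))


def leave_one_feature_out(table: FeatureTable) -> StabilityReport:
    """Agreement of each one-feature-removed matrix with the full matrix."""
    if table.n_features < 3 + 1:
        raise ValueError("leave-one-feature-out needs at least 4 features")
    full = _similarity(table)
    rows = []
    for feat in table.feature_names:
        rest = [f for f in table.feature_names if f != feat]
        r = matrix_agreement(_similarity(table.subset_features(rest)), full)
        rows.append({"left_out": feat, "r": r})
    return StabilityReport("leave_one_feature_out", pd.DataFrame(rows))


def feature_subsample_stability(
    table: FeatureTable,
    sizes: Sequence[int] = (21, 24, 27, 30, 33, 36, 39),
    reps: int = 10_000,
    seed: int | None = None,
) -> StabilityReport:
    """Mean agreement with the full matrix over random feature subsets.

    For each subset size, ``reps`` random subsets are drawn and the mean
    (and sd) of the agreement r is reported.
    """
    bad = [s for s in sizes if not 3 <= s < table.n_features]
    if bad:
        raise ValueError(
            f"subset size(s) {bad} must be in [3, n_features={table.n_features})"
        )
    full = _similarity(table)
    rng = np.random.default_rng(seed)
    feats = np.asarray(table.feature_names, dtype=object)
    rows = []
    for size in sizes:
        rs = np.empty(reps)
        for i in range(reps):
            pick = rng.choice(len(feats), size=size, replace=False)
            sub = table.subset_features(list(feats[np.sort(pick)]))
            rs[i] = matrix_agreement(_similarity(sub), full)
        rows.append({"size": size, "mean_r": rs.mean(),
                     "sd_r": rs.std(ddof=1) if reps > 1 else 0.0})
    return StabilityReport("feature_subsample", pd.DataFrame(rows), reps, seed)


def pca_reduce(
    table: FeatureTable, variance: float = 0.95
) -> tuple[FeatureTable, int]:
    """Project onto the leading principal components of the z-scored table.

    Keeps the smallest number of components whose cumulative explained
    variance reaches ``variance``. PCA is on the correlation matrix (the
    z-scored features); each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    if not 0 < variance <= 1:
        raise ValueError("variance must lie in (0, 1]")
    z = zscore_features(table)
    x = z.values.to_numpy()
    n = x.shape[0]
    cov = x.T @ x / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.maximum(evals, 0.0)
    share = evals / evals.sum()
    k = int(np.searchsorted(np.cumsum(share), variance - 1e-12) + 1)
    k = min(k, len(evals))
    comps = evecs[:, :k]
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(k)])
    comps = comps * flip
    scores = x @ comps
    reduced = pd.DataFrame(
        scores, index=z.values.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    return FeatureTable(reduced, table.metadata), k
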