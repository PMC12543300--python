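"""Bootstrap-style Z tests, permutation tests, FDR, and group contrasts.

Two inferential idioms recur throughout morphological-network analysis:

* a bootstrap-like subset test — the mean of a distinguished subset
  (intra-class connections, hub neurons) is benchmarked against the means of
  equally sized random subsets, Z = (observed - mean_null) / sd_null, with a
  two-sided p from the standard normal;
* label permutation — an F (ANOVA) or t statistic is recomputed under random
  relabelings, with p = (1 + #{null >= observed}) / (1 + n_perm).

Multiple comparisons are corrected by Benjamini-Hochberg FDR. The
cross-group comparison rebuilds full similarity networks for random
reallocations of the pooled neurons and benchmarks each network metric's
observed group difference against that null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import graphmetrics, netbuild, resilience
from .hubs_bridges import TopSet
from .morpho_io import FeatureTable

__all__ = [
    "TestResult",
    "FdrResult",
    "bootstrap_subset_z",
    "permutation_group_test",
    "fdr_bh",
    "hub_feature_contrast",
    "cross_group_network_test",
]


@dataclass
class TestResult:
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_draws: int
    seed: int | None
    extra: dict = field(default_factory=dict)


@dataclass
class FdrResult:
    p_values: np.ndarray
    q: float
    rejected: np.ndarray

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def bootstrap_subset_z(
    values: Sequence[float],
    subset: Sequence[int],
    n: int = 10_000,
    seed: int | None = None,
    statistic: str = "subset_mean",
) -> TestResult:
    """Mean of a distinguished subset vs means of random same-size subsets.

    Each of the ``n`` null draws samples ``len(subset)`` indices without
    replacement from all values. Z = (observed - null mean) / null sd; the
    two-sided p comes from the standard normal.
    """
    values = np.asarray(values, dtype=float)
    subset = np.asarray(subset, dtype=int)
    if len(subset) < 1:
        raise ValueError("subset must be non-empty")
    if len(subset) >= len(values):
        raise ValueError("subset must be a proper subset of the values")
    observed = float(values[subset].mean())
    rng = np.random.default_rng(seed)
    k = len(subset)
    null = np.empty(n)
    for i in range(n):
        null[i] = values[rng.choice(len(values), size=k, replace=False)].mean()
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: all subset means identical")
    z = (observed - mu) / sd
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(statistic, observed, mu, sd, z, float(p), n, seed)


def _f_stat(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(k):
        grp = values[codes == g]
        ss_between += len(grp) * (grp.mean() - grand) ** 2
        ss_within += ((grp - grp.mean()) ** 2).sum()
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def _t_stat(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def permutation_group_test(
    values: Sequence[float],
    labels: Sequence,
    mode: str = "anova_f",
    n: int = 10_000,
    seed: int | None = None,
) -> TestResult | dict[tuple, TestResult]:
    """Permutation ANOVA-F across groups, or pairwise permutation t tests.

    Labels are shuffled ``n`` times; p = (1 + #{|null| >= |observed|}) /
    (1 + n). ``pairwise_t`` returns one TestResult per unordered group pair
    (intended as post hoc after a significant F).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = groups[counts < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    rng = np.random.default_rng(seed)

    if mode == "anova_f":
        obs = _f_stat(values, codes, len(groups))
        null = np.empty(n)
        for i in range(n):
            null[i] = _f_stat(values, rng.permutation(codes), len(groups))
        p = (1 + np.sum(null >= obs)) / (1 + n)
        z = (obs - null.mean()) / null.std(ddof=1) if null.std(ddof=1) > 0 else np.nan
        return TestResult("anova_F", float(obs), float(null.mean()),
                          float(null.std(ddof=1)), float(z), float(p), n, seed)
    if mode == "pairwise_t":
        out: dict[tuple, TestResult] = {}
        for ia in range(len(groups)):
            for ib in range(ia + 1, len(groups)):
                a = values[codes == ia]
                b = values[codes == ib]
                pooled = np.concatenate([a, b])
                obs = _t_stat(a, b)
                null = np.empty(n)
                for i in range(n):
                    perm = rng.permutation(len(pooled))
                    null[i] = _t_stat(pooled[perm[: len(a)]], pooled[perm[len(a):]])
                p = (1 + np.sum(np.abs(null) >= abs(obs))) / (1 + n)
                sd = null.std(ddof=1)
                z = (obs - null.mean()) / sd if sd > 0 else np.nan
                out[(groups[ia], groups[ib])] = TestResult(
                    "pairwise_t", float(obs), float(null.mean()), float(sd),
                    float(z), float(p), n, seed,
                )
        return out
    raise ValueError(f"unknown mode {mode!r}")


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up rejections at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FdrResult(p, q, np.zeros(0, dtype=bool))
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    rejected = np.zeros(m, dtype=bool)
    if below.any():
        k_max = int(np.max(np.nonzero(below)[0]))
        rejected[order[: k_max + 1]] = True
    return FdrResult(p, q, rejected)


def hub_feature_contrast(
    table: FeatureTable,
    hubs: TopSet,
    n: int = 10_000,
    seed: int | None = None,
) -> tuple[dict[str, TestResult], FdrResult]:
    """Per-feature hub-vs-network bootstrap-Z contrast with BH-FDR.

    For each feature, the hub mean M_hub is compared against means M_net of
    random neuron subsets of the same size; FDR is applied across features.
    """
    hub_labels = [h for h in hubs.members]
    missing = set(hub_labels) - set(table.neuron_labels)
    if missing:
        raise ValueError(f"hub neuron(s) not in table: {sorted(missing)}")
    idx = [table.neuron_labels.index(h) for h in hub_labels]
    rng = np.random.default_rng(seed)
    results: dict[str, TestResult] = {}
    for feat in table.feature_names:
        results[feat] = bootstrap_subset_z(
            table.values[feat].to_numpy(), idx, n=n,
            seed=int(rng.integers(2**31)), statistic=f"M_hub[{feat}]",
        )
    fdr = fdr_bh([results[f].p for f in table.feature_names])
    return results, fdr


_METRIC_NAMES = ("gamma", "lambda", "sigma", "cost_efficiency",
                 "node_attack_auc", "edge_attack_auc")


def _network_metrics(
    table: FeatureTable,
    metrics: Sequence[str],
    m_nulls: int,
    seed: int,
) -> dict[str, float]:
    net, _, _ = netbuild.build_network(table)
    out: dict[str, float] = {}
    if {"gamma", "lambda", "sigma"} & set(metrics):
        sw = graphmetrics.small_world(net, m=m_nulls, seed=seed)
        out.update(gamma=sw.gamma, **{"lambda": sw.lam}, sigma=sw.sigma)
    if "cost_efficiency" in metrics:
        out["cost_efficiency"] = graphmetrics.global_metrics(net).cost_efficiency
    if "node_attack_auc" in metrics:
        curve = resilience.attack_curve(net, "node", "targeted")
        out["node_attack_auc"] = resilience.curve_auc(curve).auc
    if "edge_attack_auc" in metrics:
        curve = resilience.attack_curve(net, "edge", "targeted")
        out["edge_attack_auc"] = resilience.curve_auc(curve).auc
    return {k: v for k, v in out.items() if k in metrics}


def cross_group_network_test(
    table_a: FeatureTable,
    table_b: FeatureTable,
    metrics: Sequence[str] = ("gamma", "lambda", "sigma", "cost_efficiency"),
    n: int = 10_000,
    seed: int | None = None,
    m_nulls: int = 100,
) -> dict[str, TestResult]:
    """Permutation comparison of network metrics between two neuron groups.

    D_real = metric(A) - metric(B), with each group's network built by the
    full z-score/Pearson/threshold pipeline. The null mixes all neurons and
    reallocates them into groups of the original sizes, rebuilding both
    networks per permutation; Z = (D_real - mean D_rand) / sd D_rand with a
    two-sided normal p.
    """
    unknown = set(metrics) - set(_METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metric(s): {sorted(unknown)}")
    if table_a.n_neurons < 10 or table_b.n_neurons < 10:
        raise ValueError("each group needs at least 10 neurons to threshold")
    if list(table_a.feature_names) != list(table_b.feature_names):
        raise ValueError("groups must share a feature catalogue")
    rng = np.random.default_rng(seed)
    ma = _network_metrics(table_a, metrics, m_nulls, int(rng.integers(2**31)))
    mb = _network_metrics(table_b, metrics, m_nulls, int(rng.integers(2**31)))
    d_real = {k: ma[k] - mb[k] for k in metrics}

    pooled = np.vstack([table_a.values.to_numpy(), table_b.values.to_numpy()])
    labels = [f"n{i}" for i in range(pooled.shape[0])]
    na = table_a.n_neurons
    nulls = {k: np.empty(n) for k in metrics}
    cols = list(table_a.feature_names)
    for i in range(n):
        perm = rng.permutation(pooled.shape[0])
        ta = FeatureTable(pd.DataFrame(
            pooled[perm[:na]], index=[labels[j] for j in perm[:na]], columns=cols))
        tb = FeatureTable(pd.DataFrame(
            pooled[perm[na:]], index=[labels[j] for j in perm[na:]], columns=cols))
        mra = _network_metrics(ta, metrics, m_nulls, int(rng.integers(2**31)))
        mrb = _network_metrics(tb, metrics, m_nulls, int(rng.integers(2**31)))
        for k in metrics:
            nulls[k][i] = mra[k] - mrb[k]
    out: dict[str, TestResult] = {}
    for k in metrics:
        mu, sd = float(nulls[k].mean()), float(nulls[k].std(ddof=1))
        z = (d_real[k] - mu) / sd if sd > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        out[k] = TestResult(f"D_real[{k}]", float(d_real[k]), mu, sd,
                            float(z), float(p), n, seed,
                            extra={"metric_a": ma[k], "metric_b": mb[k]})
    return out
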