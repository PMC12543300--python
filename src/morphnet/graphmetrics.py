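"""Global graph measures, degree-preserving nulls, small-worldness, degree fits.

Small-world indices follow the usual normalization: gamma = Cp / <Cp_rand>,
lambda = Lp / <Lp_rand>, sigma = gamma / lambda, with the random ensemble
generated by Maslov-Sneppen double-edge swaps that preserve the exact degree
sequence. Degree distributions are fitted with three candidate models —
power law P(k) ~ k^(alpha-1), exponential P(k) ~ e^(-k/k_c), and the
exponentially truncated power law P(k) ~ k^(alpha-1) e^(-k/k_c) — by
least squares between the log empirical and log model complementary
cumulative distributions, with AIC selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import optimize, sparse
from scipy.sparse.csgraph import shortest_path

from .netbuild import BinaryNetwork, sparsity as _sparsity

__all__ = [
    "GraphMetrics",
    "SmallWorld",
    "DegreeFit",
    "global_metrics",
    "edge_betweenness",
    "rewire_preserving_degree",
    "small_world",
    "fit_degree_distribution",
]


@dataclass
class GraphMetrics:
    cp: float
    lp: float
    eglob: float
    cost: float
    cost_efficiency: float


@dataclass
class SmallWorld:
    gamma: float
    lam: float
    sigma: float
    m: int
    seed: int | None


@dataclass
class DegreeFit:
    model: str
    alpha: float | None
    k_c: float | None
    rate: float | None
    aic: float
    selected: bool = False


def _distance_matrix(net: BinaryNetwork) -> np.ndarray:
    adj = sparse.csr_matrix(net.adjacency())
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def _metrics_from_dist(dist: np.ndarray, n: int, e: int) -> GraphMetrics:
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    lp = float(d.mean()) if finite.all() else float("nan")
    inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    eglob = float(inv.mean()) if len(d) else 0.0
    cost = _sparsity(n, e) if n >= 2 else 0.0
    return GraphMetrics(cp=np.nan, lp=lp, eglob=eglob, cost=cost,
                        cost_efficiency=eglob - cost)


def global_metrics(net: BinaryNetwork) -> GraphMetrics:
    """Clustering, path length, global efficiency, cost, and cost efficiency.

    Cp averages the per-node ratio of closed triangles to possible triangles
    (0 for nodes of degree < 2). Lp is the mean shortest-path length over
    all unordered pairs and is NaN on disconnected graphs; Eglob counts
    unreachable pairs as 0 contribution. Cost efficiency = Eglob - cost.
    """
    n = net.n
    if n < 2:
        raise ValueError("metrics need at least 2 nodes")
    m = _metrics_from_dist(_distance_matrix(net), n, net.e)
    m.cp = float(np.mean(list(nx.clustering(net.graph).values())))
    return m


def edge_betweenness(net: BinaryNetwork) -> dict[tuple[str, str], float]:
    """Fraction of all-pairs shortest paths traversing each edge (Brandes).

    Paths split equally among equal-length alternatives; values are
    normalized by the N(N-1)/2 pairs so a star's spokes score 0.5.
    """
    if not net.is_connected():
        raise ValueError("edge betweenness requires a connected graph")
    raw = nx.edge_betweenness_centrality(net.graph, normalized=True)
    return {tuple(sorted((u, v))): val for (u, v), val in raw.items()}


def rewire_preserving_degree(
    net: BinaryNetwork, seed: int | None = None, n_attempts: int | None = None
) -> BinaryNetwork:
    """Maslov-Sneppen double-edge swap randomization.

    Attempts ``n_attempts`` (default 10*E) swaps of edge pairs (a-b, c-d) ->
    (a-d, c-b), rejecting any swap that would create a self-loop or a
    duplicate edge. The degree sequence is preserved exactly. Graphs with no
    valid swap (e.g. complete graphs) come back as unchanged copies.
    """
    rng = np.random.default_rng(seed)
    edges = [tuple(sorted(e)) for e in net.graph.edges()]
    edges.sort()
    if len(edges) < 2:
        return BinaryNetwork(net.labels, edges)
    edge_set = set(edges)
    attempts = n_attempts if n_attempts is not None else 10 * len(edges)
    m = len(edges)
    idx_pairs = rng.integers(0, m, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    for (i, j), flip in zip(idx_pairs, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # proposed: a-d and c-b
        if a == d or c == b:
            continue
        e1, e2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
    return BinaryNetwork(net.labels, sorted(edge_set))


def small_world(
    net: BinaryNetwork, m: int = 100, seed: int | None = None
) -> SmallWorld:
    """Normalized clustering (gamma), path length (lambda), and sigma.

    ``m`` degree-matched Maslov-Sneppen nulls are generated (the field's
    standard ensemble size is 100). Nulls that come out disconnected are
    redrawn up to 10 times; as a last resort Lp is taken on the largest
    component with a warning.
    """
    if not net.is_connected():
        raise ValueError("small-world indices require a connected graph")
    real = global_metrics(net)
    rng = np.random.default_rng(seed)
    cps, lps = [], []
    for _ in range(m):
        null = None
        for _retry in range(10):
            cand = rewire_preserving_degree(net, seed=int(rng.integers(2**31)))
            if cand.is_connected():
                null = cand
                break
        if null is None:
            warnings.warn(
                "null network disconnected after 10 retries; using largest component for Lp",
                stacklevel=2,
            )
            null = cand
            comp = max(nx.connected_components(null.graph), key=len)
            sub = null.graph.subgraph(comp)
            sub_net = BinaryNetwork(list(sub.nodes), list(sub.edges))
            lps.append(global_metrics(sub_net).lp)
            cps.append(float(np.mean(list(nx.clustering(null.graph).values()))))
            continue
        gm = global_metrics(null)
        cps.append(gm.cp)
        lps.append(gm.lp)
    gamma = real.cp / float(np.mean(cps))
    lam = real.lp / float(np.mean(lps))
    return SmallWorld(gamma=gamma, lam=lam, sigma=gamma / lam, m=m, seed=seed)


# ---------------------------------------------------------------------------
# degree-distribution fitting
# ---------------------------------------------------------------------------

def _log_pmf(model: str, params: np.ndarray, k_max: int) -> np.ndarray:
    """Log pmf of a candidate model normalized over k = 1..k_max."""
    k = np.arange(1, k_max + 1, dtype=float)
    if model == "power_law":
        logp = (params[0] - 1.0) * np.log(k)
    elif model == "exponential":
        logp = -k / params[0]
    elif model == "truncated_power_law":
        logp = (params[0] - 1.0) * np.log(k) - k / params[1]
    else:  # pragma: no cover
        raise ValueError(model)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return np.log(np.maximum(p, 1e-300))


def fit_degree_distribution(degrees: Sequence[int]) -> list[DegreeFit]:
    """Fit power-law / exponential / truncated power-law models to degrees.

    Each candidate pmf — k^(alpha-1), e^(-k/k_c), and k^(alpha-1)e^(-k/k_c),
    normalized over the observed support k = 1..max(degrees) — is fitted by
    maximum likelihood; the model with the lowest AIC = 2 n_params - 2 logL
    is flagged ``selected``. MLE keeps the parameter estimates consistent
    (log-CCDF least squares, a common alternative, is dominated by sparse
    tail points and biases alpha downward).
    """
    ks = np.asarray(sorted(degrees), dtype=int)
    if len(ks) < 2 or ks.min() < 1:
        raise ValueError("degrees must be positive integers, at least 2 of them")
    if len(np.unique(ks)) < 2:
        raise ValueError("degenerate distribution: all degrees equal")
    k_max = int(ks.max())
    mean_k = float(ks.mean())
    specs = {
        "power_law": np.array([1.5]),
        "exponential": np.array([mean_k]),
        "truncated_power_law": np.array([1.5, mean_k]),
    }

    fits: list[DegreeFit] = []
    for model, x0 in specs.items():
        def nll(params: np.ndarray, model=model) -> float:
            if model != "power_law" and params[-1] <= 0:
                return 1e12
            return float(-_log_pmf(model, params, k_max)[ks - 1].sum())

        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9,
                                         "maxiter": 5000})
        loglik = -float(res.fun)
        npar = len(res.x)
        aic = 2 * npar - 2 * loglik
        if model == "power_law":
            fit = DegreeFit("power_law", alpha=float(res.x[0]), k_c=None,
                            rate=None, aic=aic)
        elif model == "exponential":
            fit = DegreeFit("exponential", alpha=None, k_c=float(res.x[0]),
                            rate=1.0 / float(res.x[0]), aic=aic)
        else:
            fit = DegreeFit("truncated_power_law", alpha=float(res.x[0]),
                            k_c=float(res.x[1]), rate=None, aic=aic)
        fits.append(fit)
    best_fit = min(fits, key=lambda f: f.aic)
    best_fit.selected = True
    return fits
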