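import itertools

import networkx as nx
import numpy as np
import pytest

from morphnet.graphmetrics import (
    edge_betweenness,
    fit_degree_distribution,
    global_metrics,
    rewire_preserving_degree,
    small_world,
)
from morphnet.netbuild import BinaryNetwork
from morphnet.synthgen import synth_degree_sequence


def net_from_graph(g):
    return BinaryNetwork([str(v) for v in g.nodes],
                         [(str(u), str(v)) for u, v in g.edges])


def brute_force_metrics(g):
    """Floyd-Warshall distances + exhaustive triangle counting."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                dist[i, j] = min(dist[i, j], dist[i, k] + dist[k, j])
    cps = []
    for v in nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            cps.append(0.0)
            continue
        tri = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        cps.append(tri / (k * (k - 1) / 2))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ds = [dist[i, j] for i, j in pairs]
    lp = float(np.mean(ds)) if all(np.isfinite(ds)) else float("nan")
    eglob = float(np.mean([1.0 / d if np.isfinite(d) else 0.0 for d in ds]))
    return float(np.mean(cps)), lp, eglob


def brute_force_edge_betweenness(g):
    """Exhaustive shortest-path enumeration."""
    nodes = list(g.nodes)
    n = len(nodes)
    scores = {tuple(sorted(e)): 0.0 for e in g.edges}
    for a, b in itertools.combinations(nodes, 2):
        paths = list(nx.all_shortest_paths(g, a, b))
        for path in paths:
            for u, v in zip(path, path[1:]):
                scores[tuple(sorted((u, v)))] += 1.0 / len(paths)
    n_pairs = n * (n - 1) / 2
    return {e: s / n_pairs for e, s in scores.items()}


class TestGlobalMetrics:
    def test_complete_graph(self):
        m = global_metrics(net_from_graph(nx.complete_graph(4)))
        assert (m.cp, m.lp, m.eglob, m.cost) == (1.0, 1.0, 1.0, 1.0)
        assert m.cost_efficiency == 0.0

    def test_path_graph_hand_enumeration(self):
        m = global_metrics(net_from_graph(nx.path_graph(4)))
        assert m.lp == pytest.approx(10 / 6)
        assert m.eglob == pytest.approx((3 + 2 * 0.5 + 1 / 3) / 6)
        assert m.cost == pytest.approx(0.5)
        assert m.cost_efficiency == pytest.approx(m.eglob - 0.5)

    def test_triangle_plus_pendant_clustering(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (0, 3)])
        m = global_metrics(net_from_graph(g))
        assert m.cp == pytest.approx((1 / 3 + 1 + 1 + 0) / 4)

    def test_agrees_with_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            m = global_metrics(net_from_graph(g))
            cp, lp, eglob = brute_force_metrics(g)
            assert m.cp == pytest.approx(cp, abs=1e-12)
            assert m.eglob == pytest.approx(eglob, abs=1e-12)
            if nx.is_connected(g):
                assert m.lp == pytest.approx(lp, abs=1e-12)
            else:
                assert np.isnan(m.lp)


class TestEdgeBetweenness:
    def test_star(self):
        eb = edge_betweenness(net_from_graph(nx.star_graph(3)))
        assert all(v == pytest.approx(0.5) for v in eb.values())

    def test_triangle(self):
        eb = edge_betweenness(net_from_graph(nx.complete_graph(3)))
        assert all(v == pytest.approx(1 / 3) for v in eb.values())

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 10:
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            checked += 1
            got = edge_betweenness(net_from_graph(g))
            want = brute_force_edge_betweenness(g)
            for e, v in want.items():
                key = tuple(sorted((str(e[0]), str(e[1]))))
                assert got[key] == pytest.approx(v, abs=1e-9)

    def test_disconnected_rejected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            edge_betweenness(net_from_graph(g))


class TestRewire:
    def test_degree_sequence_preserved(self):
        g = nx.gnp_random_graph(25, 0.2, seed=3)
        net = net_from_graph(g)
        null = rewire_preserving_degree(net, seed=5)
        assert null.degrees() == net.degrees()
        assert null.n == net.n and null.e == net.e

    def test_complete_graph_unchanged(self):
        net = net_from_graph(nx.complete_graph(4))
        null = rewire_preserving_degree(net, seed=1)
        assert set(map(tuple, map(sorted, null.graph.edges()))) == set(
            map(tuple, map(sorted, net.graph.edges())))

    def test_seed_determinism(self):
        net = net_from_graph(nx.gnp_random_graph(20, 0.3, seed=9))
        a = rewire_preserving_degree(net, seed=123)
        b = rewire_preserving_degree(net, seed=123)
        assert sorted(a.graph.edges()) == sorted(b.graph.edges())

    def test_actually_rewires(self):
        net = net_from_graph(nx.gnp_random_graph(30, 0.2, seed=2))
        null = rewire_preserving_degree(net, seed=0)
        assert sorted(null.graph.edges()) != sorted(net.graph.edges())


class TestSmallWorld:
    def test_sigma_identity_and_er_self_consistency(self):
        g = nx.gnp_random_graph(40, 0.2, seed=11)
        assert nx.is_connected(g)
        sw = small_world(net_from_graph(g), m=30, seed=4)
        assert sw.sigma == pytest.approx(sw.gamma / sw.lam)
        # an ER graph is its own null up to sampling error
        assert 0.6 < sw.gamma < 1.5
        assert 0.9 < sw.lam < 1.1

    def test_ring_lattice_is_highly_clustered(self):
        g = nx.watts_strogatz_graph(50, 4, 0.0, seed=0)
        sw = small_world(net_from_graph(g), m=20, seed=8)
        assert sw.gamma > 3.0


class TestDegreeFit:
    def test_constant_degrees_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_degree_distribution([4] * 50)

    def test_truncated_model_recovers_parameters(self):
        deg = synth_degree_sequence(
            "truncated_power_law", {"alpha": 1.3, "k_c": 70}, 2000, seed=1)
        fits = {f.model: f for f in fit_degree_distribution(deg)}
        tf = fits["truncated_power_law"]
        assert tf.alpha == pytest.approx(1.3, abs=0.15)
        assert tf.k_c == pytest.approx(70, rel=0.20)
        assert tf.selected

    def test_exponential_data_prefers_exponential_under_aic(self):
        # the truncated model nests the exponential, so AIC keeps the extra
        # parameter with asymptotic probability P(chi2_1 > 2) ~ 0.16; the
        # simpler model must win in the large majority of replicates
        wins = 0
        for seed in range(40):
            deg = synth_degree_sequence("exponential", {"k_c": 8.0}, 1500,
                                        seed=seed)
            sel = [f.model for f in fit_degree_distribution(deg) if f.selected]
            wins += sel[0] == "exponential"
        assert wins >= 28  # >= 70% of 40

    def test_returns_three_models_one_selected(self):
        deg = synth_degree_sequence("exponential", {"k_c": 10.0}, 500, seed=0)
        fits = fit_degree_distribution(deg)
        assert sorted(f.model for f in fits) == [
            "exponential", "power_law", "truncated_power_law"]
        assert sum(f.selected for f in fits) == 1
        assert all(np.isfinite(f.aic) for f in fits)
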