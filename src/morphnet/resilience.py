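"""Network resilience: random-failure and targeted-attack simulations.

Nodes (or edges) are removed one by one — uniformly at random, or targeting
the current highest-degree node / highest-betweenness edge — and the cost
efficiency (global efficiency minus edge density) of the surviving graph is
recorded on a 0-100% removal grid with 1% steps. Targeted attacks re-rank
after every removal by default (the adaptive, stricter variant); a flag
switches to the initial-ranking variant. Resilience is summarized by the
area under the cost-efficiency curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import shortest_path

from .netbuild import BinaryNetwork

__all__ = ["AttackCurve", "AucResult", "attack_curve", "curve_auc"]

FRACTION_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class AttackCurve:
    element: str  # "node" | "edge"
    strategy: str  # "random" | "targeted"
    fractions: np.ndarray
    cost_efficiency: np.ndarray  # mean over repetitions for random
    sd: np.ndarray | None
    repetitions: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"fraction": self.fractions, "cost_efficiency": self.cost_efficiency}
        )
        if self.sd is not None:
            df["sd"] = self.sd
        return df


@dataclass
class AucResult:
    auc: float


def _cost_efficiency_adj(adj: np.ndarray, n_edges: int) -> float:
    """Cost efficiency of a graph given its dense adjacency matrix.

    Unreachable pairs contribute 0 to efficiency; the cost denominator uses
    the surviving node count.
    """
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = shortest_path(sparse.csr_matrix(adj), method="D", unweighted=True,
                         directed=False)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    eglob = float(inv.mean())
    cost = n_edges / (n * (n - 1) / 2)
    return eglob - cost


def _node_attack(adj: np.ndarray, order_fn, grid_counts: np.ndarray) -> np.ndarray:
    """Remove nodes one by one; record cost efficiency at each grid count."""
    alive = np.ones(adj.shape[0], dtype=bool)
    a = adj.copy()
    out = np.empty(len(grid_counts))
    removed = 0
    gi = 0
    while gi < len(grid_counts):
        while removed < grid_counts[gi]:
            victim = order_fn(a, alive)
            alive[victim] = False
            a[victim, :] = 0.0
            a[:, victim] = 0.0
            removed += 1
        sub = a[np.ix_(alive, alive)]
        out[gi] = _cost_efficiency_adj(sub, int(sub.sum() / 2))
        gi += 1
    return out


def _edge_attack(net: BinaryNetwork, pick_fn, grid_counts: np.ndarray) -> np.ndarray:
    """Remove edges one by one; node count stays fixed."""
    g = ig.Graph(n=net.n)
    index = {lbl: i for i, lbl in enumerate(net.labels)}
    g.add_edges([(index[u], index[v]) for u, v in net.graph.edges()])
    n = net.n
    out = np.empty(len(grid_counts))
    removed = 0
    gi = 0
    while gi < len(grid_counts):
        while removed < grid_counts[gi]:
            g.delete_edges([pick_fn(g)])
            removed += 1
        adj = np.array(g.get_adjacency().data, dtype=float)
        out[gi] = _cost_efficiency_adj(adj, g.ecount())
        gi += 1
    return out


def attack_curve(
    net: BinaryNetwork,
    element: str = "node",
    strategy: str = "targeted",
    reps: int = 100,
    seed: int | None = None,
    adaptive: bool = True,
) -> AttackCurve:
    """Cost-efficiency degradation under removal of nodes or edges.

    Targeted node attacks remove the highest-degree node (ties broken by
    stable label order); targeted edge attacks remove the
    highest-betweenness edge. With ``adaptive`` (default) the ranking is
    refreshed after every removal. Random failure averages ``reps``
    uniformly ordered removal sequences.
    """
    if element not in {"node", "edge"}:
        raise ValueError("element must be 'node' or 'edge'")
    if strategy not in {"random", "targeted"}:
        raise ValueError("strategy must be 'random' or 'targeted'")
    if not net.is_connected():
        raise ValueError("attack simulations start from a connected graph")
    total = net.n if element == "node" else net.e
    grid_counts = np.floor(FRACTION_GRID * total + 1e-9).astype(int)
    rng = np.random.default_rng(seed)

    if strategy == "targeted":
        if element == "node":
            if adaptive:
                def order_fn(a, alive):
                    deg = a.sum(axis=1)
                    deg[~alive] = -1
                    return int(np.argmax(deg))
            else:
                static = np.argsort(-net.adjacency().sum(axis=1), kind="stable")
                queue = iter(static.tolist())

                def order_fn(a, alive, queue=queue):
                    return next(queue)
            ce = _node_attack(net.adjacency(), order_fn, grid_counts)
        else:
            if adaptive:
                def pick_fn(g):
                    eb = g.edge_betweenness()
                    return int(np.argmax(eb))
            else:
                ranked_state = {"queue": None}

                def pick_fn(g, state=ranked_state):
                    if state["queue"] is None:
                        eb = np.asarray(g.edge_betweenness())
                        order = np.argsort(-eb, kind="stable")
                        pairs = [tuple(sorted(g.es[int(i)].tuple)) for i in order]
                        state["queue"] = pairs
                    u, v = state["queue"].pop(0)
                    return g.get_eid(u, v)
            ce = _edge_attack(net, pick_fn, grid_counts)
        return AttackCurve(element, strategy, FRACTION_GRID.copy(), ce, None, 1, seed)

    # random failure
    curves = np.empty((reps, len(grid_counts)))
    adj0 = net.adjacency()
    for rep in range(reps):
        if element == "node":
            perm = rng.permutation(net.n)
            queue = iter(perm.tolist())
            curves[rep] = _node_attack(
                adj0, lambda a, alive, q=queue: next(q), grid_counts
            )
        else:
            order = rng.permutation(net.e)
            state = {"queue": None}

            def pick_fn(g, state=state, order=order, net=net):
                if state["queue"] is None:
                    index = {lbl: i for i, lbl in enumerate(net.labels)}
                    edges = [tuple(sorted((index[u], index[v])))
                             for u, v in sorted(map(tuple, map(sorted, net.graph.edges())))]
                    state["queue"] = [edges[i] for i in order]
                u, v = state["queue"].pop(0)
                return g.get_eid(u, v)

            curves[rep] = _edge_attack(net, pick_fn, grid_counts)
    return AttackCurve(
        element, strategy, FRACTION_GRID.copy(), curves.mean(axis=0),
        curves.std(axis=0, ddof=0), reps, seed,
    )


def curve_auc(curve: AttackCurve) -> AucResult:
    """Trapezoidal area under the cost-efficiency curve over fraction in [0,1]."""
    return AucResult(auc=float(np.trapezoid(curve.cost_efficiency, curve.fractions)))
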