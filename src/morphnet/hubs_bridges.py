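"""Hub nodes, bridge edges, and the disproportionate contribution coefficient.

Hubs are the top 10% of nodes by degree; bridges the top 10% of edges by
edge betweenness. For a class partition of the nodes (cortical layer, cell
type, brain region, ...), the disproportionate contribution coefficient of
class i is

    DCC_i = (N_hubs_i / N_hubs) / (N_nodes_i / N_nodes),

i.e. the class's share of hubs over its share of nodes; DCC > 1 marks
over-representation. The same coefficient applies to bridge edges counted
within a class, between a pair of classes, or aggregated intra vs inter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import pandas as pd

from .netbuild import BinaryNetwork

__all__ = [
    "TopSet",
    "DccTable",
    "identify_top_fraction",
    "hub_nodes",
    "bridge_edges",
    "node_dcc",
    "edge_dcc",
    "RAT_GROUPINGS",
]

# Category groupings for the rat somatosensory taxonomy: superficial vs deep
# cortical layers, excitatory vs inhibitory cell types, and molecular-marker
# subtypes of the inhibitory population.
RAT_GROUPINGS: dict[str, dict[str, list[str]]] = {
    "layer_depth": {
        "superficial": ["L1", "L2/3"],
        "deep": ["L4", "L5", "L6"],
    },
    "ei": {
        "excitatory": ["PC"],
        "inhibitory": ["NBC", "DBC", "BP", "LBC", "MC", "NGC", "BTC"],
    },
    "marker": {
        "PV": ["LBC", "NBC"],
        "Sst": ["MC"],
        "5HT3aR": ["BTC", "DBC", "BP"],
    },
}


@dataclass
class TopSet:
    """Top-fraction element set (hubs or bridges) with its cutoff statistic."""

    kind: str  # "node" | "edge"
    fraction: float
    members: list[Hashable]
    threshold: float

    def __contains__(self, item: Hashable) -> bool:
        return item in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DccTable:
    """Per-category hub/bridge counts and DCC values."""

    kind: str
    n_total: int
    n_top: int
    rows: pd.DataFrame = field(repr=False)

    def dcc(self, category: Hashable) -> float:
        return float(self.rows.loc[category, "dcc"])

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index_label="category")


def identify_top_fraction(
    stat: Mapping[Hashable, float], fraction: float = 0.10, kind: str = "node"
) -> TopSet:
    """Select the floor(fraction * total) elements with the highest statistic.

    Ties at the cutoff are broken by stable element-identifier order, so the
    selection is deterministic. Requires at least 10 elements.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if len(stat) < 10:
        raise ValueError("need at least 10 elements to rank")
    k = int(fraction * len(stat))
    ranked = sorted(stat.items(), key=lambda kv: (-kv[1], str(kv[0])))
    members = [key for key, _ in ranked[:k]]
    return TopSet(kind=kind, fraction=fraction, members=members,
                  threshold=float(ranked[k - 1][1]))


def hub_nodes(net: BinaryNetwork, fraction: float = 0.10) -> TopSet:
    """Hubs: top-fraction nodes by degree."""
    return identify_top_fraction(net.degrees(), fraction, kind="node")


def bridge_edges(
    betweenness: Mapping[tuple[str, str], float], fraction: float = 0.10
) -> TopSet:
    """Bridges: top-fraction edges by edge betweenness."""
    return identify_top_fraction(dict(betweenness), fraction, kind="edge")


def _labeled_universe(
    class_labels: Mapping[Hashable, Hashable], elements: Sequence[Hashable]
) -> list[Hashable]:
    labeled = [e for e in elements if class_labels.get(e) is not None]
    if len(labeled) < len(elements):
        warnings.warn(
            f"{len(elements) - len(labeled)} unlabeled element(s) excluded from DCC",
            stacklevel=3,
        )
    return labeled


def node_dcc(class_labels: Mapping[str, Hashable], hubs: TopSet,
             grouping: Mapping[Hashable, Sequence[Hashable]] | None = None) -> DccTable:
    """DCC of hub nodes per class (or per category grouping of classes).

    ``class_labels`` maps every node to its class; unlabeled nodes are
    excluded from numerator and denominator with a warning. ``grouping``
    optionally maps category names to lists of classes (e.g. superficial ->
    [L1, L2/3]), in which case DCCs are computed per category.
    """
    nodes = _labeled_universe(class_labels, list(class_labels))
    hub_set = set(hubs.members) & set(nodes)
    if grouping is not None:
        def cat(node):
            c = class_labels[node]
            for name, classes in grouping.items():
                if c in classes:
                    return name
            return None
        labels = {v: cat(v) for v in nodes}
        nodes = [v for v in nodes if labels[v] is not None]
        hub_set &= set(nodes)
    else:
        labels = {v: class_labels[v] for v in nodes}
    n_nodes, n_hubs = len(nodes), len(hub_set)
    rows = {}
    for c in sorted({labels[v] for v in nodes}, key=str):
        members = [v for v in nodes if labels[v] == c]
        hubs_i = sum(1 for v in members if v in hub_set)
        share_nodes = len(members) / n_nodes
        share_hubs = hubs_i / n_hubs if n_hubs else 0.0
        rows[c] = {
            "n_nodes": len(members),
            "n_hubs": hubs_i,
            "dcc": share_hubs / share_nodes,
        }
    return DccTable(kind="node", n_total=n_nodes, n_top=n_hubs,
                    rows=pd.DataFrame.from_dict(rows, orient="index"))


def edge_dcc(
    class_labels: Mapping[str, Hashable],
    edges: Sequence[tuple[str, str]],
    bridges: TopSet,
    mode: str = "intra_inter",
) -> DccTable:
    """DCC of bridge edges over edge categories.

    ``mode``: ``intra_inter`` aggregates edges into within-class vs
    between-class; ``per_class`` scores the within-class edges of each
    class; ``per_pair`` scores each unordered class pair (including the
    within-class pairs).
    """
    if mode not in {"intra_inter", "per_class", "per_pair"}:
        raise ValueError(f"unknown mode {mode!r}")

    def norm(e):
        return tuple(sorted(e))

    labeled_edges = [
        norm(e) for e in edges
        if class_labels.get(e[0]) is not None and class_labels.get(e[1]) is not None
    ]
    if len(labeled_edges) < len(edges):
        warnings.warn(
            f"{len(edges) - len(labeled_edges)} edge(s) with unlabeled endpoints "
            "excluded from DCC",
            stacklevel=2,
        )
    bridge_set = {norm(e) for e in bridges.members} & set(labeled_edges)

    def category(e):
        ca, cb = class_labels[e[0]], class_labels[e[1]]
        if mode == "intra_inter":
            return "intra" if ca == cb else "inter"
        if mode == "per_class":
            return ca if ca == cb else None
        return tuple(sorted((str(ca), str(cb))))

    cats = {e: category(e) for e in labeled_edges}
    universe = [e for e in labeled_edges if cats[e] is not None]
    in_universe_bridges = bridge_set & set(universe)
    # shares are always taken against the full labeled edge universe
    n_edges, n_bridges = len(labeled_edges), len(bridge_set)
    rows = {}
    for c in sorted({cats[e] for e in universe}, key=str):
        members = [e for e in universe if cats[e] == c]
        b_i = sum(1 for e in members if e in in_universe_bridges)
        share_edges = len(members) / n_edges
        share_bridges = b_i / n_bridges if n_bridges else 0.0
        rows[c] = {
            "n_edges": len(members),
            "n_bridges": b_i,
            "dcc": share_bridges / share_edges,
        }
    return DccTable(kind="edge", n_total=n_edges, n_top=n_bridges,
                    rows=pd.DataFrame.from_dict(rows, orient="index"))
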