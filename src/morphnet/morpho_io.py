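"""SWC neuron reconstructions, morphometric features, and feature tables.

SWC is the plain-text standard for single-neuron reconstructions: one node
per line with ``id type x y z radius parent``, ``parent = -1`` marking the
root (soma). This module validates the tree invariants, computes an
L-Measure-compatible catalogue of morphometric features, and reads/writes
neuron-by-feature tables with per-neuron class metadata (layer, cell type,
region, species) as delimited text.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SwcNode",
    "NeuronReconstruction",
    "FeatureTable",
    "SwcParseError",
    "SwcValidationError",
    "FEATURE_CATALOGUE",
    "read_swc",
    "write_swc",
    "compute_features",
    "read_feature_table",
    "write_feature_table",
]

SOMA = 1


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SwcValidationError(ValueError):
    """The parsed records do not form a valid rooted tree."""


@dataclass(frozen=True)
class SwcNode:
    """One SWC record: sample id, structure code, position (um), radius (um), parent id."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


class NeuronReconstruction:
    """A validated rooted SWC tree.

    Parameters
    ----------
    label:
        Neuron identifier (by convention the file stem).
    nodes:
        SWC records in file order. Must satisfy the tree invariants:
        unique ids, exactly one root (``parent == -1``), every parent id
        present, and no cycles.
    """

    def __init__(self, label: str, nodes: Sequence[SwcNode]):
        self.label = label
        self.nodes = list(nodes)
        self._by_id = {n.id: n for n in self.nodes}
        self._validate()
        self.children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent != -1:
                self.children[n.parent].append(n.id)

    def _validate(self) -> None:
        if len(self._by_id) != len(self.nodes):
            seen: set[int] = set()
            for n in self.nodes:
                if n.id in seen:
                    raise SwcValidationError(f"duplicate node id {n.id}")
                seen.add(n.id)
        roots = [n for n in self.nodes if n.parent == -1]
        if len(roots) == 0:
            raise SwcValidationError("no root node (parent = -1) found")
        if len(roots) > 1:
            raise SwcValidationError(
                f"multiple roots: nodes {[n.id for n in roots]} have parent = -1"
            )
        self.root = roots[0].id
        for n in self.nodes:
            if n.parent != -1 and n.parent not in self._by_id:
                raise SwcValidationError(
                    f"dangling parent: node {n.id} references missing parent {n.parent}"
                )
        # parent links must be acyclic and reach the root
        for n in self.nodes:
            seen_path = {n.id}
            cur = n
            while cur.parent != -1:
                cur = self._by_id[cur.parent]
                if cur.id in seen_path:
                    raise SwcValidationError(f"cycle in parent links at node {cur.id}")
                seen_path.add(cur.id)

    def node(self, node_id: int) -> SwcNode:
        return self._by_id[node_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"NeuronReconstruction({self.label!r}, {len(self)} nodes)"


def read_swc(path: str | Path, label: str | None = None) -> NeuronReconstruction:
    """Read and validate a 7-column SWC file.

    Lines starting with ``#`` and blank lines are ignored. Raises
    :class:`SwcParseError` naming the offending line on malformed input and
    :class:`SwcValidationError` on tree-invariant violations.
    """
    path = Path(path)
    nodes: list[SwcNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 7:
                raise SwcParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nodes.append(
                    SwcNode(
                        id=int(parts[0]),
                        type_code=int(parts[1]),
                        x=float(parts[2]),
                        y=float(parts[3]),
                        z=float(parts[4]),
                        radius=float(parts[5]),
                        parent=int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SwcParseError(f"{path.name}:{lineno}: {exc}") from None
    if not nodes:
        raise SwcParseError(f"{path.name}: no data lines")
    return NeuronReconstruction(label or path.stem, nodes)


def write_swc(recon: NeuronReconstruction, path: str | Path) -> None:
    """Write a reconstruction back to the 7-column SWC dialect."""
    with open(path, "w") as fh:
        fh.write(f"# {recon.label}\n# id type x y z radius parent\n")
        for n in recon.nodes:
            fh.write(
                f"{n.id} {n.type_code} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                f"{n.radius:.6g} {n.parent}\n"
            )


# ---------------------------------------------------------------------------
# morphometric feature catalogue
# ---------------------------------------------------------------------------

FEATURE_CATALOGUE: tuple[str, ...] = (
    "Soma_Surface",
    "N_stems",
    "N_bifs",
    "N_branch",
    "N_tips",
    "Width",
    "Height",
    "Depth",
    "Diameter",
    "Length",
    "Surface",
    "Volume",
    "EucDistance",
    "PathDistance",
    "Branch_Order",
    "Contraction",
    "Fragmentation",
    "Partition_asymmetry",
    "Bif_ampl_local",
    "Bif_ampl_remote",
    "Daughter_Ratio",
)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


@dataclass
class _Tree:
    """Derived quantities shared by the feature functions."""

    recon: NeuronReconstruction
    soma_ids: set[int] = field(default_factory=set)
    warn_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        r = self.recon
        # contiguous type-1 nodes hanging off the root collapse to one soma
        self.soma_ids = set()
        root = r.node(r.root)
        if root.type_code == SOMA:
            stack = [r.root]
            while stack:
                nid = stack.pop()
                self.soma_ids.add(nid)
                for c in r.children[nid]:
                    if r.node(c).type_code == SOMA:
                        stack.append(c)
        self.neurite_ids = [n.id for n in r.nodes if n.id not in self.soma_ids]
        # bifurcations: nodes outside the soma with >= 2 children
        self.bif_ids = [
            nid for nid in self.neurite_ids if len(r.children[nid]) >= 2
        ]
        self.tip_ids = [
            nid for nid in self.neurite_ids if len(r.children[nid]) == 0
        ]

    def seg_len(self, nid: int) -> float:
        n = self.recon.node(nid)
        p = self.recon.node(n.parent)
        return float(np.linalg.norm(n.xyz - p.xyz))

    def subtree_tips(self, nid: int) -> int:
        r = self.recon
        count = 0
        stack = [nid]
        while stack:
            cur = stack.pop()
            kids = r.children[cur]
            if not kids and cur not in self.soma_ids:
                count += 1
            stack.extend(kids)
        return count

    def next_critical(self, nid: int) -> int:
        """Follow the unbranched chain from `nid` to the next bifurcation or tip."""
        r = self.recon
        cur = nid
        while len(r.children[cur]) == 1:
            cur = r.children[cur][0]
        return cur

    def branches(self) -> list[list[int]]:
        """Unbranched paths (node-id chains, starting at the parent critical node)."""
        r = self.recon
        out: list[list[int]] = []
        # branch starts: children of soma nodes (stems) and children of bifurcations
        starts: list[int] = []
        for sid in self.soma_ids:
            starts.extend(c for c in r.children[sid] if c not in self.soma_ids)
        if r.node(r.root).type_code != SOMA:
            starts.extend(r.children[r.root])
            # a non-soma root with one child begins a branch itself
        for b in self.bif_ids:
            starts.extend(r.children[b])
        for s in starts:
            chain = [r.node(s).parent, s]
            cur = s
            while len(r.children[cur]) == 1:
                cur = r.children[cur][0]
                chain.append(cur)
            out.append(chain)
        return out


def _soma_surface(t: _Tree) -> float:
    root = t.recon.node(t.recon.root)
    return 4.0 * math.pi * root.radius**2


def _features(t: _Tree) -> dict[str, float]:
    r = t.recon
    xs = np.array([n.x for n in r.nodes])
    ys = np.array([n.y for n in r.nodes])
    zs = np.array([n.z for n in r.nodes])
    root_xyz = r.node(r.root).xyz

    non_soma = [r.node(i) for i in t.neurite_ids]
    seg = {n.id: t.seg_len(n.id) for n in non_soma}

    # cumulative path distance from the root
    pathdist: dict[int, float] = {r.root: 0.0}
    order: dict[int, int] = {r.root: 0}
    stack = [r.root]
    while stack:
        nid = stack.pop()
        for c in r.children[nid]:
            step = float(np.linalg.norm(r.node(c).xyz - r.node(nid).xyz))
            pathdist[c] = pathdist[nid] + step
            bump = 1 if (nid in t.bif_ids) else 0
            order[c] = order[nid] + bump
            stack.append(c)

    vals: dict[str, float] = {}
    vals["Soma_Surface"] = _soma_surface(t)
    stems = 0
    for sid in t.soma_ids:
        stems += sum(1 for c in r.children[sid] if c not in t.soma_ids)
    if not t.soma_ids:
        stems = len(r.children[r.root])
    vals["N_stems"] = float(stems)
    vals["N_bifs"] = float(len(t.bif_ids))
    branches = t.branches()
    vals["N_branch"] = float(len(branches))
    vals["N_tips"] = float(len(t.tip_ids))
    vals["Width"] = float(xs.max() - xs.min())
    vals["Height"] = float(ys.max() - ys.min())
    vals["Depth"] = float(zs.max() - zs.min())
    if non_soma:
        vals["Diameter"] = float(np.mean([2 * n.radius for n in non_soma]))
        vals["Length"] = float(sum(seg.values()))
        vals["Surface"] = float(
            sum(2 * math.pi * n.radius * seg[n.id] for n in non_soma)
        )
        vals["Volume"] = float(
            sum(math.pi * n.radius**2 * seg[n.id] for n in non_soma)
        )
    else:
        t.warn_flags.append("no neurite nodes")
        vals["Diameter"] = vals["Length"] = vals["Surface"] = vals["Volume"] = 0.0
    vals["EucDistance"] = float(
        max(np.linalg.norm(r.node(i).xyz - root_xyz) for i in pathdist)
    )
    vals["PathDistance"] = float(max(pathdist.values()))
    vals["Branch_Order"] = float(max(order.values()))
    vals["Fragmentation"] = float(len(non_soma))

    # Contraction: per-branch straight-line / path-length ratio
    ratios = []
    for chain in branches:
        plen = sum(
            float(np.linalg.norm(r.node(b).xyz - r.node(a).xyz))
            for a, b in zip(chain, chain[1:])
        )
        if plen <= 0:  # degenerate zero-length branch excluded
            continue
        euc = float(np.linalg.norm(r.node(chain[-1]).xyz - r.node(chain[0]).xyz))
        ratios.append(euc / plen)
    if ratios:
        vals["Contraction"] = float(np.mean(ratios))
    else:
        t.warn_flags.append("no measurable branches for Contraction")
        vals["Contraction"] = 0.0

    # bifurcation statistics
    pa, local, remote, dratio = [], [], [], []
    for b in t.bif_ids:
        kids = r.children[b][:2]
        n1 = t.subtree_tips(kids[0])
        n2 = t.subtree_tips(kids[1])
        if n1 == 1 and n2 == 1:
            pa.append(0.0)
        else:
            pa.append(abs(n1 - n2) / (n1 + n2 - 2))
        bx = r.node(b).xyz
        local.append(
            _angle_deg(r.node(kids[0]).xyz - bx, r.node(kids[1]).xyz - bx)
        )
        e1 = t.next_critical(kids[0])
        e2 = t.next_critical(kids[1])
        remote.append(_angle_deg(r.node(e1).xyz - bx, r.node(e2).xyz - bx))
        r1, r2 = r.node(kids[0]).radius, r.node(kids[1]).radius
        if min(r1, r2) > 0:
            dratio.append(max(r1, r2) / min(r1, r2))
    if t.bif_ids:
        vals["Partition_asymmetry"] = float(np.mean(pa))
        vals["Bif_ampl_local"] = float(np.mean(local))
        vals["Bif_ampl_remote"] = float(np.mean(remote))
        vals["Daughter_Ratio"] = float(np.mean(dratio)) if dratio else 0.0
    else:
        t.warn_flags.append("no bifurcations; bifurcation statistics set to 0")
        vals["Partition_asymmetry"] = 0.0
        vals["Bif_ampl_local"] = 0.0
        vals["Bif_ampl_remote"] = 0.0
        vals["Daughter_Ratio"] = 0.0
    return vals


def compute_features(
    recon: NeuronReconstruction,
    catalogue: Iterable[str] | None = None,
) -> dict[str, float]:
    """Compute morphometric features for one reconstruction.

    Lengths/extents in um, angles in degrees, areas in um^2, volumes in um^3.
    Degenerate statistics (e.g. bifurcation angles of an unbranched neurite)
    come back as 0 with a warning. Unknown feature names raise ``KeyError``
    listing the catalogue.
    """
    if len(recon) < 2:
        raise ValueError(
            f"{recon.label}: at least 2 nodes required for feature computation"
        )
    names = list(catalogue) if catalogue is not None else list(FEATURE_CATALOGUE)
    unknown = [n for n in names if n not in FEATURE_CATALOGUE]
    if unknown:
        raise KeyError(
            f"unknown feature(s) {unknown}; catalogue: {list(FEATURE_CATALOGUE)}"
        )
    t = _Tree(recon)
    all_vals = _features(t)
    for flag in t.warn_flags:
        warnings.warn(f"{recon.label}: {flag}", stacklevel=2)
    return {n: all_vals[n] for n in names}


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

METADATA_FIELDS = ("layer", "cell_type", "region", "species")


class FeatureTable:
    """Neurons x features matrix with per-neuron class metadata.

    ``values`` is a pandas DataFrame (index = neuron labels, columns =
    feature names, finite floats); ``metadata`` a DataFrame on the same
    index whose columns are class labels (any subset of layer / cell_type /
    region / species, plus free-form columns).
    """

    def __init__(self, values: pd.DataFrame, metadata: pd.DataFrame | None = None):
        values = values.astype(float)
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate neuron labels: {dupes}")
        if values.columns.has_duplicates:
            raise ValueError("duplicate feature names")
        bad = values.columns[~np.isfinite(values.to_numpy()).all(axis=0)]
        if len(bad):
            raise ValueError(f"non-finite values in feature(s): {list(bad)}")
        self.values = values
        if metadata is None:
            metadata = pd.DataFrame(index=values.index)
        self.metadata = metadata.reindex(values.index)

    @property
    def neuron_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_neurons(self) -> int:
        return len(self.values.index)

    @property
    def n_features(self) -> int:
        return len(self.values.columns)

    def class_labels(self, column: str) -> pd.Series:
        if column not in self.metadata.columns:
            raise KeyError(f"metadata column {column!r} not present")
        return self.metadata[column]

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.values[list(names)], self.metadata)

    def subset_neurons(self, labels: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(labels)], self.metadata.loc[list(labels)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureTable({self.n_neurons} neurons x {self.n_features} features)"


def feature_table_from_reconstructions(
    recons: Sequence[NeuronReconstruction],
    catalogue: Iterable[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> FeatureTable:
    """Run :func:`compute_features` over a set of reconstructions."""
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rc in recons:
            rows[rc.label] = compute_features(rc, catalogue)
    return FeatureTable(pd.DataFrame.from_dict(rows, orient="index"), metadata)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_feature_table(
    values_path: str | Path, metadata_path: str | Path | None = None
) -> FeatureTable:
    """Read a neuron x feature table (CSV/TSV, first column = neuron label).

    Metadata rows for neurons absent from the value table are dropped with a
    warning; neurons without metadata get null class labels. Non-numeric or
    missing cells are reported with their row/column location.
    """
    values_path = Path(values_path)
    raw = pd.read_csv(values_path, sep=_sep_for(values_path), index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"{values_path.name}: duplicate neuron labels {dupes}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan)))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"{values_path.name}: non-numeric or missing cell at neuron "
            f"{raw.index[i]!r}, feature {raw.columns[j]!r}"
        )
    metadata = None
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        metadata = pd.read_csv(
            metadata_path, sep=_sep_for(metadata_path), index_col=0, dtype=str
        )
        extra = metadata.index.difference(numeric.index)
        if len(extra):
            warnings.warn(
                f"{metadata_path.name}: {len(extra)} metadata neuron(s) not in the "
                "value table are ignored",
                stacklevel=2,
            )
            metadata = metadata.drop(index=extra)
    return FeatureTable(numeric, metadata)


def write_feature_table(
    table: FeatureTable,
    values_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    values_path = Path(values_path)
    table.values.to_csv(values_path, sep=_sep_for(values_path), index_label="neuron")
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        table.metadata.to_csv(
            metadata_path, sep=_sep_for(metadata_path), index_label="neuron"
        )
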