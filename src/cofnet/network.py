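"""Inter-cofactor distances, threshold electron-transfer graphs and paths.

Two metrics are computed for every cofactor pair, following standard practice
for redox chains:

* **center-to-center**: Euclidean distance between geometric centers (for
  flavins/nicotinamide the center of the redox-active ring);
* **edge-to-edge** (side-to-side): the minimum distance over all non-hydrogen
  atom pairs, the operative quantity for electron-tunneling feasibility.

An edge is drawn between two cofactors when their edge-to-edge distance is at
most a threshold tau (default 14 Å, the practical limit for productive
single-step tunneling).  On the resulting graph, degree-3 nodes are branch
points ("Y"-shaped cluster arrangements), degree-1 nodes that are not
designated entry/exit terminals are dead ends, and simple or minimax
(bottleneck-optimal) paths describe candidate electron-transfer routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .cofactors import Cofactor, FES_CODES
from .errors import DegenerateCofactorError, LabelError

DEFAULT_TAU = 14.0


@dataclass
class DistancePair:
    """Both distance metrics for one unordered cofactor pair."""

    label_a: str
    label_b: str
    center_distance: float
    edge_distance: float
    closest_atom_pair: tuple[str, str]

    def as_row(self) -> dict:
        return {
            "label_a": self.label_a, "label_b": self.label_b,
            "center_distance": round(self.center_distance, 1),
            "edge_distance": round(self.edge_distance, 1),
            "closest_atom_a": self.closest_atom_pair[0],
            "closest_atom_b": self.closest_atom_pair[1],
        }


def center_distance(a: Cofactor, b: Cofactor) -> float:
    """Center-to-center distance in Å (symmetric)."""
    return float(np.linalg.norm(a.center - b.center))


def edge_distance(a: Cofactor, b: Cofactor,
                  include_hydrogens: bool = False) -> tuple[float, tuple[str, str]]:
    """Edge-to-edge distance and the achieving atom pair.

    Minimum over all cross atom pairs; ties are broken by source atom order.
    """
    atoms_a = a.distance_atoms(include_hydrogens)
    atoms_b = b.distance_atoms(include_hydrogens)
    if not atoms_a or not atoms_b:
        empty = a.label if not atoms_a else b.label
        raise DegenerateCofactorError(f"cofactor {empty!r} has no distance atoms")
    d = cdist(np.array([x.position for x in atoms_a]),
              np.array([x.position for x in atoms_b]))
    i, j = np.unravel_index(int(np.argmin(d)), d.shape)
    return float(d[i, j]), (atoms_a[i].atom_name, atoms_b[j].atom_name)


def distance_matrix(cofactors: list[Cofactor],
                    include_hydrogens: bool = False) -> list[DistancePair]:
    """All n(n-1)/2 unordered pairs with both metrics."""
    labels = [c.label for c in cofactors]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise LabelError(f"duplicate cofactor labels: {dupes}")
    pairs = []
    for a, b in combinations(cofactors, 2):
        ed, closest = edge_distance(a, b, include_hydrogens)
        pairs.append(DistancePair(a.label, b.label, center_distance(a, b), ed, closest))
    return pairs


def distance_frame(cofactors: list[Cofactor]):
    """Distance matrix as a pandas DataFrame (0.1 Å reporting precision)."""
    import pandas as pd
    return pd.DataFrame([p.as_row() for p in distance_matrix(cofactors)])


@dataclass
class ETGraph:
    """Threshold electron-transfer graph over cofactor labels."""

    graph: nx.Graph
    tau: float
    terminals: frozenset[str] = frozenset()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def degree(self, label: str) -> int:
        return self.graph.degree[label]


def build_et_graph(cofactors: list[Cofactor], tau: float = DEFAULT_TAU,
                   terminals=()) -> ETGraph:
    """Graph with an edge wherever edge-to-edge distance <= tau.

    Edges carry both metrics; the edge set grows monotonically with tau.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    g = nx.Graph()
    for c in cofactors:
        g.add_node(c.label, type=c.type.code, chain=c.chain_id,
                   center=tuple(np.round(c.center, 4)))
    for p in distance_matrix(cofactors):
        if p.edge_distance <= tau:
            g.add_edge(p.label_a, p.label_b,
                       edge_distance=p.edge_distance,
                       center_distance=p.center_distance,
                       closest_atom_pair=p.closest_atom_pair)
    return ETGraph(graph=g, tau=tau, terminals=frozenset(terminals))


@dataclass
class TopologyReport:
    branch_points: list[str]
    dead_ends: list[str]
    components: list[list[str]]

    def to_dict(self) -> dict:
        return {"branch_points": self.branch_points,
                "dead_ends": self.dead_ends,
                "components": self.components}


def topology(et: ETGraph) -> TopologyReport:
    """Branch points (degree >= 3), non-terminal leaves, components."""
    g = et.graph
    branch = sorted(n for n in g.nodes if g.degree[n] >= 3)
    dead = sorted(n for n in g.nodes
                  if g.degree[n] == 1 and n not in et.terminals)
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: (-len(c), c))
    return TopologyReport(branch_points=branch, dead_ends=dead, components=comps)


@dataclass
class PathReport:
    """One candidate electron-transfer route."""

    labels: list[str]
    step_distances: list[float]
    max_gap: float
    n_intermediate_fes: int

    def to_dict(self) -> dict:
        return {"labels": self.labels,
                "step_distances": [round(d, 1) for d in self.step_distances],
                "max_gap": round(self.max_gap, 1),
                "n_intermediate_fes": self.n_intermediate_fes}


def _report_from_labels(labels, weight, node_types) -> PathReport:
    steps = [weight(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
    inter = [l for l in labels[1:-1]] if len(labels) > 2 else []
    n_fes = sum(1 for l in inter if node_types.get(l) in FES_CODES)
    return PathReport(labels=list(labels), step_distances=steps,
                      max_gap=max(steps) if steps else 0.0,
                      n_intermediate_fes=n_fes)


def enumerate_paths(et: ETGraph, src: str, dst: str,
                    max_nodes: int | None = None) -> list[PathReport]:
    """All simple paths src->dst with at most ``max_nodes`` nodes.

    Sorted by (node count, max_gap, label sequence).  A disconnected pair
    yields an empty list; src == dst yields one zero-length path.
    """
    g = et.graph
    for n in (src, dst):
        if n not in g:
            raise KeyError(f"{n!r} is not a node of the graph")
    node_types = nx.get_node_attributes(g, "type")
    weight = lambda a, b: g.edges[a, b]["edge_distance"]
    if src == dst:
        return [_report_from_labels([src], weight, node_types)]
    cutoff = None if max_nodes is None else max_nodes - 1
    reports = [_report_from_labels(p, weight, node_types)
               for p in nx.all_simple_paths(g, src, dst, cutoff=cutoff)]
    reports.sort(key=lambda r: (len(r.labels), r.max_gap, r.labels))
    return reports


def minimax_path(cofactors: list[Cofactor], src: str, dst: str) -> PathReport:
    """The path minimizing the maximum step edge distance (no threshold).

    Computed on the complete distance graph: the bottleneck value is taken
    from the minimum spanning tree, then among all paths achieving it the one
    with fewest nodes (then lexicographically smallest label sequence) is
    returned.  Useful for reasoning about gaps slightly beyond tau without
    committing to a hard cutoff.
    """
    labels = {c.label for c in cofactors}
    for n in (src, dst):
        if n not in labels:
            raise KeyError(f"{n!r} is not a cofactor label")
    node_types = {c.label: c.type.code for c in cofactors}
    full = nx.Graph()
    full.add_nodes_from(labels)
    for p in distance_matrix(cofactors):
        full.add_edge(p.label_a, p.label_b, edge_distance=p.edge_distance)
    weight = lambda a, b: full.edges[a, b]["edge_distance"]
    if src == dst:
        return _report_from_labels([src], weight, node_types)
    # bottleneck value via the MST (minimax path property)
    mst = nx.minimum_spanning_tree(full, weight="edge_distance")
    tree_path = nx.shortest_path(mst, src, dst)
    bottleneck = max(weight(tree_path[i], tree_path[i + 1])
                     for i in range(len(tree_path) - 1))
    # restrict to edges within the bottleneck, take fewest hops, then lexicographic
    sub = nx.Graph((u, v) for u, v, d in full.edges(data=True)
                   if d["edge_distance"] <= bottleneck + 1e-12)
    shortest = min(nx.all_shortest_paths(sub, src, dst), key=list)
    return _report_from_labels(shortest, weight, node_types)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_graphml(et: ETGraph, path: str) -> None:
    g = et.graph.copy()
    for _, _, d in g.edges(data=True):
        d["closest_atom_pair"] = "|".join(d.pop("closest_atom_pair", ("", "")))
    for _, d in g.nodes(data=True):
        d["center"] = ",".join(f"{x:.4f}" for x in d.pop("center", ()))
        d["terminal"] = False
    for n in et.terminals:
        if n in g:
            g.nodes[n]["terminal"] = True
    nx.write_graphml(g, path)


def write_dot(et: ETGraph, path: str) -> None:
    """Minimal DOT export (undirected; edge labels carry distances)."""
    lines = ["graph etgraph {"]
    for n, d in sorted(et.graph.nodes(data=True)):
        shape = "doublecircle" if n in et.terminals else "circle"
        lines.append(f'  "{n}" [shape={shape}, type="{d.get("type", "")}"];')
    for u, v, d in sorted(et.graph.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" [label="{d["edge_distance"]:.1f}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
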