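"""Distance metrics, threshold graphs, topology and path algorithms,
checked against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

import cofnet as cn
from cofnet.errors import LabelError

from conftest import point_cofactor, random_cluster_cofactor


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_center(a, b):
    ca = np.mean([x.position for x in a.center_atoms()], axis=0)
    cb = np.mean([x.position for x in b.center_atoms()], axis=0)
    return float(np.linalg.norm(ca - cb))


def brute_edge(a, b):
    best = None
    for x in a.distance_atoms():
        for y in b.distance_atoms():
            d = float(np.linalg.norm(x.position - y.position))
            if best is None or d < best:
                best = d
    return best


def brute_simple_paths(adj, src, dst):
    """Recursive DFS enumeration of all simple paths."""
    out = []

    def walk(node, seen, path):
        if node == dst:
            out.append(list(path))
            return
        for nxt in sorted(adj.get(node, ())):
            if nxt not in seen:
                walk(nxt, seen | {nxt}, path + [nxt])

    walk(src, {src}, [src])
    return out


def brute_minimax(weights, nodes, src, dst):
    """Exhaustive minimax over all simple paths of a complete graph."""
    adj = {n: [m for m in nodes if m != n] for n in nodes}
    best = None
    for path in brute_simple_paths(adj, src, dst):
        gap = max(weights[frozenset(p)] for p in zip(path, path[1:]))
        key = (gap, len(path), path)
        if best is None or key < best:
            best = key
    return best


# ---------------------------------------------------------------------------
# distance metrics
# ---------------------------------------------------------------------------

class TestDistances:
    def test_three_four_five_triangle(self):
        a = point_cofactor("a", [0, 0, 0])
        b = point_cofactor("b", [3, 4, 0])
        assert cn.center_distance(a, b) == pytest.approx(5.0)

    def test_self_distance_zero(self):
        a = point_cofactor("a", [1, 2, 3])
        assert cn.center_distance(a, a) == 0.0
        assert cn.edge_distance(a, a)[0] == 0.0

    def test_single_atom_edge_equals_center(self):
        a = point_cofactor("a", [0, 0, 0])
        b = point_cofactor("b", [7.5, 0, 0])
        assert cn.edge_distance(a, b)[0] == pytest.approx(cn.center_distance(a, b))

    def test_random_clusters_match_bruteforce_to_1e9(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = random_cluster_cofactor("a", rng)
            b = random_cluster_cofactor("b", rng)
            assert cn.center_distance(a, b) == pytest.approx(brute_center(a, b), abs=1e-9)
            assert cn.edge_distance(a, b)[0] == pytest.approx(brute_edge(a, b), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = random_cluster_cofactor("a", rng)
        b = random_cluster_cofactor("b", rng)
        assert cn.center_distance(a, b) == cn.center_distance(b, a)
        assert cn.edge_distance(a, b)[0] == cn.edge_distance(b, a)[0]

    def test_edge_bounded_by_center_plus_radii(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = random_cluster_cofactor("a", rng)
            b = random_cluster_cofactor("b", rng)
            ra = max(np.linalg.norm(x.position - a.center) for x in a.atoms)
            rb = max(np.linalg.norm(x.position - b.center) for x in b.atoms)
            assert cn.edge_distance(a, b)[0] <= cn.center_distance(a, b) + ra + rb + 1e-9

    def test_fixture_fmn_b1_edge_is_6A(self, pb_cofactors):
        by = {c.label: c for c in pb_cofactors}
        d, _ = cn.edge_distance(by["FMN"], by["B1"])
        assert d == pytest.approx(6.0, abs=0.05)


class TestDistanceMatrix:
    def test_row_count_and_consistency(self, apo_cofactors):
        pairs = cn.distance_matrix(apo_cofactors)
        n = len(apo_cofactors)
        assert len(pairs) == n * (n - 1) // 2
        by = {c.label: c for c in apo_cofactors}
        for p in pairs[:20]:
            assert p.center_distance == pytest.approx(
                cn.center_distance(by[p.label_a], by[p.label_b]), abs=1e-12)
            assert p.edge_distance == pytest.approx(
                cn.edge_distance(by[p.label_a], by[p.label_b])[0], abs=1e-12)

    def test_duplicate_labels_rejected(self):
        a = point_cofactor("same", [0, 0, 0])
        b = point_cofactor("same", [5, 0, 0])
        with pytest.raises(LabelError):
            cn.distance_matrix([a, b])


# ---------------------------------------------------------------------------
# threshold graph + topology
# ---------------------------------------------------------------------------

class TestGraph:
    def test_tau_must_be_positive(self, apo_cofactors):
        with pytest.raises(ValueError):
            cn.build_et_graph(apo_cofactors, tau=0)

    def test_huge_tau_gives_complete_graph(self, apo_cofactors):
        g = cn.build_et_graph(apo_cofactors, tau=1e6)
        n = len(apo_cofactors)
        assert len(g.edges) == n * (n - 1) // 2

    def test_edge_set_monotone_in_tau(self, pb_cofactors):
        previous = set()
        for tau in (4, 8, 11.5, 14, 17, 20, 30, 60):
            edges = set(cn.build_et_graph(pb_cofactors, tau=tau).edges)
            assert previous <= edges
            previous = edges

    def test_every_edge_within_tau(self, pb_cofactors):
        et = cn.build_et_graph(pb_cofactors, tau=14)
        for a, b in et.edges:
            assert et.graph.edges[a, b]["edge_distance"] <= 14

    def test_apo_gates_open(self, apo_cofactors):
        g = cn.build_et_graph(apo_cofactors, tau=14)
        assert not g.has_edge("C1", "B2")      # 19 Å in the apo state
        assert not g.has_edge("B2", "B3")      # 18 Å in the apo state
        assert g.has_edge("C1", "B5")          # 11 Å

    def test_pb_gate_closed(self, pb_cofactors):
        g = cn.build_et_graph(pb_cofactors, tau=14)
        assert g.has_edge("C1", "B2")          # 13.4 Å in the PB state
        assert not g.has_edge("B2", "B3")      # 17.0 Å stays open

    def test_topology_on_path_graph(self):
        cofs = [point_cofactor(l, [i * 5.0, 0, 0], resnum=i + 1)
                for i, l in enumerate("abc")]
        top = cn.topology(cn.build_et_graph(cofs, tau=6, terminals={"a", "c"}))
        assert top.branch_points == [] and top.dead_ends == []
        assert top.components == [["a", "b", "c"]]

    def test_topology_matches_degree_tally(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            cofs = [point_cofactor(f"n{i}", rng.uniform(0, 25, 3), resnum=i + 1)
                    for i in range(n)]
            et = cn.build_et_graph(cofs, tau=12)
            top = cn.topology(et)
            degree = {c.label: 0 for c in cofs}
            for a, b in et.edges:
                degree[a] += 1
                degree[b] += 1
            assert set(top.branch_points) == {l for l, d in degree.items() if d >= 3}
            assert set(top.dead_ends) == {l for l, d in degree.items() if d == 1}


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------

class TestPaths:
    def test_unique_chain_on_pb_fixture(self, pb_cofactors):
        et = cn.build_et_graph(pb_cofactors, tau=14, terminals=cn.HYDABCSL_TERMINALS)
        reports = cn.enumerate_paths(et, "FMN", "NiFe")
        assert len(reports) == 1
        assert reports[0].labels == ["FMN", "B1", "A1", "A2", "A3", "S1", "NiFe"]
        assert reports[0].n_intermediate_fes == 5
        assert not {"A4", "A5", "B5"} & set(reports[0].labels)

    def test_src_equals_dst(self, pb_cofactors):
        et = cn.build_et_graph(pb_cofactors, tau=14)
        reports = cn.enumerate_paths(et, "A2", "A2")
        assert len(reports) == 1
        assert reports[0].labels == ["A2"] and reports[0].max_gap == 0.0

    def test_disconnected_pair_yields_empty_list(self, pb_cofactors):
        et = cn.build_et_graph(pb_cofactors, tau=14)
        assert cn.enumerate_paths(et, "FMN", "B3") == []   # B3/B4 island in PB

    def test_unknown_node_raises(self, pb_cofactors):
        et = cn.build_et_graph(pb_cofactors, tau=14)
        with pytest.raises(KeyError):
            cn.enumerate_paths(et, "FMN", "nope")

    def test_enumeration_matches_dfs_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(12):
            n = int(rng.integers(4, 9))
            cofs = [point_cofactor(f"n{i}", rng.uniform(0, 20, 3), resnum=i + 1)
                    for i in range(n)]
            et = cn.build_et_graph(cofs, tau=11)
            adj = {}
            for a, b in et.edges:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            got = {tuple(r.labels) for r in cn.enumerate_paths(et, "n0", f"n{n-1}")}
            want = {tuple(p) for p in brute_simple_paths(adj, "n0", f"n{n-1}")}
            assert got == want

    def test_minimax_two_nodes(self):
        a = point_cofactor("a", [0, 0, 0])
        b = point_cofactor("b", [9, 0, 0], resnum=2)
        r = cn.minimax_path([a, b], "a", "b")
        assert r.labels == ["a", "b"] and r.max_gap == pytest.approx(9.0)

    def test_minimax_src_equals_dst(self):
        a = point_cofactor("a", [0, 0, 0])
        b = point_cofactor("b", [9, 0, 0], resnum=2)
        r = cn.minimax_path([a, b], "a", "a")
        assert r.labels == ["a"] and r.max_gap == 0.0

    def test_minimax_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            n = int(rng.integers(3, 8))
            cofs = [point_cofactor(f"n{i}", rng.uniform(0, 30, 3), resnum=i + 1)
                    for i in range(n)]
            labels = [c.label for c in cofs]
            weights = {frozenset((a.label, b.label)): cn.edge_distance(a, b)[0]
                       for a, b in itertools.combinations(cofs, 2)}
            got = cn.minimax_path(cofs, "n0", f"n{n-1}")
            gap, length, path = brute_minimax(weights, labels, "n0", f"n{n-1}")
            assert got.max_gap == pytest.approx(gap, abs=1e-9)
            assert len(got.labels) == length
            assert got.labels == path

    def test_minimax_pb_low_potential_branch(self, pb_cofactors):
        # C1 -> B3 must bottleneck at the 17.0 Å B2-B3 step, not the direct
        # 17.4 Å C1-B3 contact
        r = cn.minimax_path(pb_cofactors, "C1", "B3")
        assert r.labels == ["C1", "B2", "B3"]
        assert r.max_gap == pytest.approx(17.0, abs=0.05)


# ---------------------------------------------------------------------------
# rigid-motion invariance
# ---------------------------------------------------------------------------

def test_rigid_motion_leaves_network_unchanged(pb_structure, label_map):
    rng = np.random.default_rng(3)
    from cofnet.synthetic import _quat_to_matrix
    R = _quat_to_matrix(rng.normal(size=4))
    t = rng.uniform(-40, 40, 3)
    moved = pb_structure.transformed(R, t)
    cofs = cn.detect_cofactors(pb_structure, label_map=label_map)
    cofs_m = cn.detect_cofactors(moved, label_map=label_map)
    by, by_m = ({c.label: c for c in cc} for cc in (cofs, cofs_m))
    for la, lb in [("C1", "B2"), ("FMN", "B1"), ("A1", "A2"), ("NiFe", "S1")]:
        assert cn.edge_distance(by[la], by[lb])[0] == pytest.approx(
            cn.edge_distance(by_m[la], by_m[lb])[0], abs=1e-9)
        assert cn.center_distance(by[la], by[lb]) == pytest.approx(
            cn.center_distance(by_m[la], by_m[lb]), abs=1e-9)
    g = cn.build_et_graph(cofs, tau=14)
    g_m = cn.build_et_graph(cofs_m, tau=14)
    assert set(g.edges) == set(g_m.edges)
    assert [p.labels for p in cn.enumerate_paths(g, "FMN", "NiFe")] == \
           [p.labels for p in cn.enumerate_paths(g_m, "FMN", "NiFe")]


def test_graphml_and_dot_exports(tmp_path, pb_cofactors):
    et = cn.build_et_graph(pb_cofactors, tau=14, terminals=cn.HYDABCSL_TERMINALS)
    gml = tmp_path / "g.graphml"
    dot = tmp_path / "g.dot"
    cn.write_graphml(et, str(gml))
    cn.write_dot(et, str(dot))
    import networkx as nx
    back = nx.read_graphml(str(gml))
    assert set(back.nodes) == set(et.nodes)
    assert len(back.edges) == len(et.edges)
    text = dot.read_text()
    assert '"C1" -- ' in text or ' -- "C1"' in text
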