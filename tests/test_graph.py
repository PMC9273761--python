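import numpy as np
import pytest

from conftest import analyze_mask, symmetric_y
from oracles import cyclomatic_number, strahler_reference
from vasctree.graph import (
    GeometricGraph,
    SkeletonSegment,
    VascularTree,
    Vertex,
    assign_strahler,
    build_geometric_graph,
    detect_topology_abnormalities,
    remove_od_region,
    track_trees,
)
from vasctree.skeleton import OpticDisc, detect_landmarks, skeletonize
from vasctree.synthetic import TreeSpec, generate_tree, inject_defect


class TestRemoveOd:
    def test_disjoint_od_is_identity(self):
        skel = np.zeros((64, 64), dtype=bool)
        skel[40, 10:50] = True
        out = remove_od_region(skel, OpticDisc((10, 10), 5))
        assert np.array_equal(out, skel)

    def test_line_crossing_od_splits_in_two(self):
        import scipy.ndimage as ndi

        skel = np.zeros((64, 64), dtype=bool)
        skel[32, 4:60] = True
        out = remove_od_region(skel, OpticDisc((32, 32), 6))
        _, n = ndi.label(out, structure=np.ones((3, 3)))
        assert n == 2

    def test_od_covering_all_warns(self):
        skel = np.zeros((32, 32), dtype=bool)
        skel[16, 10:20] = True
        with pytest.warns(UserWarning):
            remove_od_region(skel, OpticDisc((16, 16), 30))


class TestBuildGraph:
    def test_open_line_one_edge_two_vertices(self):
        skel = np.zeros((9, 40), dtype=bool)
        skel[4, 2:38] = True
        lm = detect_landmarks(skel)
        g = build_geometric_graph(skel, lm)
        assert len(g.edges) == 1 and len(g.vertices) == 2

    def test_symmetric_y_three_edges_four_vertices(self):
        skel = symmetric_y()
        lm = detect_landmarks(skel)
        g = build_geometric_graph(skel, lm)
        assert len(g.edges) == 3 and len(g.vertices) == 4

    def test_fixture_edge_count_matches_binary_tree_identity(self, od):
        """A full binary tree with B bifurcations has 2B+1 edges."""
        for depth in (2, 3, 4):
            mask, fov, truth = generate_tree(TreeSpec(depth=depth))
            skel, lm, g, trees, _ = analyze_mask(mask, fov, od)
            b = truth.n_bifurcations
            assert len(g.edges) == 2 * b + 1
            assert len(g.vertices) == len(g.edges) + 1

    def test_segment_interiors_have_degree_two(self, clean_analysis):
        _, lm, g, _, _ = clean_analysis
        counts = lm.neighbor_counts
        for seg in g.edges.values():
            for p in seg.pixel_path[1:-1]:
                assert counts[p] == 2


class TestTrackTrees:
    def test_single_path_single_tree(self):
        skel = np.zeros((9, 40), dtype=bool)
        skel[4, 2:38] = True
        lm = detect_landmarks(skel, od=OpticDisc((4, 2), 2))
        g = build_geometric_graph(skel, lm)
        trees, orphans = track_trees(g)
        assert len(trees) == 1 and len(trees[0].edges) == 1 and not orphans

    def test_forest_edge_partition(self):
        """k roots -> k trees with an exact partition of the edges."""
        spec = TreeSpec(shape=(512, 900), depth=3, root=(60.0, 200.0))
        mask, fov, truth = generate_tree(spec, n_trees=2, tree_spacing=440.0)
        od = OpticDisc(center=(60.0, 420.0), radius=220.0)
        skel, lm, g, trees, _ = analyze_mask(mask, fov, od)
        assert len(trees) == 2
        edge_sets = [set(t.edges) for t in trees]
        assert not (edge_sets[0] & edge_sets[1])
        assert edge_sets[0] | edge_sets[1] == set(g.edges)
        assert all(len(t.edges) == 7 for t in trees)

    def test_no_start_vertex_raises_with_candidates(self):
        skel = np.zeros((9, 40), dtype=bool)
        skel[4, 2:38] = True
        lm = detect_landmarks(skel, od=OpticDisc((100, 100), 2))
        g = build_geometric_graph(skel, lm)
        with pytest.raises(ValueError, match="candidate"):
            track_trees(g)

    def test_tracking_deterministic(self, clean_tree, od):
        mask, fov, _ = clean_tree
        runs = []
        for _ in range(2):
            _, _, g, trees, _ = analyze_mask(mask, fov, od)
            runs.append([sorted(t.edges.items()) for t in trees])
        assert runs[0] == runs[1]

    def test_edges_oriented_away_from_root(self, clean_analysis):
        _, _, g, trees, _ = clean_analysis
        for t in trees:
            seen_child = {t.root}
            for eid, (u, v) in sorted(t.edges.items()):
                assert u in seen_child or u in t.vertices
                seen_child.add(v)


def _chain_tree(edge_pairs, root=0):
    return VascularTree(
        tree_id=0, root=root, edges=dict(enumerate(edge_pairs)),
        vertices={v for uv in edge_pairs for v in uv} | {root},
    )


class TestStrahler:
    def test_single_edge_order_one(self):
        t = assign_strahler(_chain_tree([(0, 1)]))
        assert t.strahler == {0: 1}

    def test_perfect_binary_tree_depth3_root_order3(self):
        # root edge, then two subtrees each a perfect depth-2 binary tree
        edges = [(0, 1), (1, 2), (1, 3), (2, 4), (2, 5), (3, 6), (3, 7)]
        t = assign_strahler(_chain_tree(edges))
        assert t.strahler[0] == 3
        assert t.strahler == strahler_reference(dict(enumerate(edges)), 0)

    def test_caterpillar_root_order2(self):
        # each internal vertex has one leaf child and one chain child
        edges = [(0, 1), (1, 2), (1, 3), (3, 4), (3, 5), (5, 6), (5, 7)]
        t = assign_strahler(_chain_tree(edges))
        assert t.strahler[0] == 2

    def test_cycle_raises(self):
        t = _chain_tree([(0, 1), (1, 2), (2, 1)])
        with pytest.raises(ValueError, match="circle"):
            assign_strahler(t)

    def test_matches_reference_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            parents = [int(rng.integers(0, i)) for i in range(1, n)]
            edges = [(p, i + 1) for i, p in enumerate(parents)]
            t = assign_strahler(_chain_tree(edges))
            assert t.strahler == strahler_reference(dict(enumerate(edges)), 0)


def _abstract_graph(n, edge_pairs):
    """GeometricGraph over abstract vertices with unit-length dummy segments."""
    vertices = {
        i: Vertex(position=(float(i), 0.0), kind="start" if i == 0 else "end",
                  pixels=[(i, 0)])
        for i in range(n)
    }
    edges = {
        k: SkeletonSegment(pixel_path=[(u, 0), (v, 0)], endpoints=(u, v),
                           length=1.0 + 0.01 * k)
        for k, (u, v) in enumerate(edge_pairs)
    }
    return GeometricGraph(vertices=vertices, edges=edges)


class TestTopologyAbnormalities:
    def test_clean_fixture_empty_report(self, clean_analysis):
        _, _, _, _, report = clean_analysis
        assert report.is_clean
        assert not report.orphan_vertices

    def test_injected_loop_detected_as_single_cycle(self, tree_spec, od):
        mask, fov, truth = generate_tree(tree_spec)
        mask, truth = inject_defect(mask, truth, "loop")
        _, _, g, trees, report = analyze_mask(mask, fov, od)
        assert len(report.cycles) == 1
        assert len(report.cycles[0]) >= 3  # a genuine circle, not a self-loop

    def test_near_bifurcations_merge_to_overdegree_vertex(self, tree_spec, od):
        mask, fov, truth = generate_tree(tree_spec)
        mask, truth = inject_defect(mask, truth, "near_bifurcations")
        _, _, g, trees, report = analyze_mask(mask, fov, od)
        assert len(report.overdegree_vertices) == 1
        vid, degree = report.overdegree_vertices[0]
        assert degree == 4
        assert report.merged_bifurcation_candidates == [vid]

    def test_cycle_count_matches_dfs_oracle_on_random_graphs(self):
        """MST-based circle detection agrees with the cyclomatic number."""
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = int(rng.integers(3, 30))
            # random connected multigraph: spanning tree + extra edges
            pairs = [(int(rng.integers(0, i)), i) for i in range(1, n)]
            extra = int(rng.integers(0, 4))
            for _ in range(extra):
                u, v = rng.integers(0, n, 2)
                if u != v:
                    pairs.append((int(u), int(v)))
            g = _abstract_graph(n, pairs)
            trees, orphans = track_trees(g)
            report = detect_topology_abnormalities(g, trees, orphans)
            assert len(report.cycles) == cyclomatic_number(n, pairs)

    def test_tree_identity_edges_vertices(self, clean_analysis):
        _, _, _, trees, _ = clean_analysis
        for t in trees:
            assert len(t.edges) == len(t.vertices) - 1
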