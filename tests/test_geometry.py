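import math

import numpy as np
import pytest

from conftest import analyze_mask, straight_tube
from oracles import cross_section_width
from vasctree.geometry import (
    GeometryRuleConfig,
    MaskSegment,
    bifurcation_angle,
    classify_thick_thin,
    detect_geometry_abnormalities,
    estimate_diameters,
    extract_mask_segments,
    tortuosity_details,
    tortuosity_index,
)
from vasctree.graph import SkeletonSegment, VascularTree
from vasctree.skeleton import OpticDisc, detect_landmarks, skeletonize
from vasctree.synthetic import TreeSpec, draw_tube, generate_tree


def _graph_for(mask, od=None):
    skel = skeletonize(mask)
    lm = detect_landmarks(skel, od=od)
    from vasctree.graph import build_geometric_graph

    return build_geometric_graph(skel, lm)


class TestExtractMaskSegments:
    def test_single_tube_all_pixels_one_segment(self):
        mask = straight_tube(5)
        g = _graph_for(mask)
        segs = extract_mask_segments(g, mask)
        assert len(segs) == 1
        assert len(segs[0].vessel_pixels) == int(mask.sum())

    def test_parallel_tubes_share_nothing(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[20:25, 10:70] = True
        mask[60:65, 10:70] = True
        g = _graph_for(mask)
        segs = extract_mask_segments(g, mask)
        assert len(segs) == 2
        assert not (segs[0].vessel_pixels & segs[1].vessel_pixels)

    def test_fixture_partition_conserves_pixels(self, clean_tree, od):
        mask, fov, _ = clean_tree
        _, _, g, _, _ = analyze_mask(mask, fov, od)
        segs = extract_mask_segments(g, mask)
        total = sum(len(s.vessel_pixels) for s in segs)
        assert total == int(mask.sum())
        union = set()
        for s in segs:
            assert not (union & s.vessel_pixels)
            union |= s.vessel_pixels


class TestEstimateDiameters:
    @pytest.mark.parametrize("width", range(3, 16))
    def test_constant_width_recovered_within_1px(self, width):
        mask = straight_tube(width, length=60, shape=(90, 90))
        g = _graph_for(mask)
        segs = extract_mask_segments(g, mask)
        d = estimate_diameters(segs[0], mask)
        interior = d[5:-5]
        # independent oracle: perpendicular cross-section pixel count
        path = segs[0].segment.pixel_path
        mid = path[len(path) // 2]
        assert cross_section_width(mask, mid, (0.0, 1.0)) == width
        assert np.abs(interior - width).mean() <= 1.0

    def test_width1_line_diameter_one(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask[15, 5:55] = True
        g = _graph_for(mask)
        segs = extract_mask_segments(g, mask)
        d = estimate_diameters(segs[0], mask)
        assert (d == 1.0).all()

    def test_cone_widening_monotone(self):
        mask = np.zeros((60, 220), dtype=bool)
        for c in range(10, 210):
            w = 3 + 8 * (c - 10) / 200.0  # 3 -> 11 px
            half = w / 2.0
            r0 = int(math.floor(30 - half))
            r1 = int(math.ceil(30 + half))
            mask[r0 : r1 + 1, c] = True
        g = _graph_for(mask)
        segs = extract_mask_segments(g, mask)
        d = estimate_diameters(segs[0], mask)
        path = np.asarray(segs[0].segment.pixel_path)
        order = np.argsort(path[:, 1])
        prof = d[order][8:-8]
        smoothed = np.convolve(prof, np.ones(9) / 9, mode="valid")
        assert (np.diff(smoothed) >= -0.25).all()
        assert smoothed[-1] > smoothed[0] + 5

    def test_centreline_on_background_raises(self):
        mask = straight_tube(5)
        g = _graph_for(mask)
        segs = extract_mask_segments(g, mask)
        with pytest.raises(ValueError):
            estimate_diameters(segs[0], np.zeros_like(mask))


def _two_child_fixture(angle_deg):
    """Mask with a stem and two children meeting at ``angle_deg``."""
    mask = np.zeros((200, 200), dtype=bool)
    centre = np.array([100.0, 100.0])
    stem_dir = np.array([-1.0, 0.0])  # stem goes up (north)
    t = np.linspace(0, 60, 150)
    draw_tube(mask, centre + np.outer(t, stem_dir), 5)
    half = math.radians(angle_deg) / 2.0
    for sign in (1, -1):
        d = np.array([math.sin(half) * 0 + math.cos(half), sign * math.sin(half)])
        # children head south (+row) spread around the stem axis
        draw_tube(mask, centre + np.outer(t, d), 4)
    return mask


class TestBifurcationAngle:
    @pytest.mark.parametrize("angle", [60, 90])
    def test_recovers_drawn_angle(self, angle):
        mask = _two_child_fixture(angle)
        od = OpticDisc(center=(40.0, 100.0), radius=6.0)
        skel, lm, g, trees, _ = analyze_mask(mask, np.ones_like(mask), od)
        (tree,) = trees
        bif = [v for v in tree.vertices
               if g.vertices[v].kind == "bifurcation"
               and len(tree.children_edges(v)) == 2]
        assert len(bif) == 1
        measured = bifurcation_angle(g, tree, bif[0], radius=20.0)
        assert abs(measured - angle) <= 5.0

    def test_collinear_children_180(self):
        mask = np.zeros((100, 120), dtype=bool)
        mask[48:53, 10:110] = True  # horizontal bar
        mask[10:50, 58:61] = True  # stem from the top
        od = OpticDisc(center=(10.0, 59.0), radius=5.0)
        skel, lm, g, trees, _ = analyze_mask(mask, np.ones_like(mask), od)
        (tree,) = trees
        bif = [v for v in tree.vertices if len(tree.children_edges(v)) == 2]
        measured = bifurcation_angle(g, tree, bif[0], radius=15.0)
        assert abs(measured - 180.0) <= 8.0

    def test_non_bifurcation_raises(self, clean_analysis):
        _, _, g, trees, _ = clean_analysis
        (tree,) = trees
        leaf = next(v for v in tree.vertices if not tree.children_edges(v))
        with pytest.raises(ValueError):
            bifurcation_angle(g, tree, leaf)


def _arc_path(radius=60.0, sweep=math.pi / 2, n=200):
    th = np.linspace(0.0, sweep, n)
    return np.column_stack([radius - radius * np.cos(th), radius * np.sin(th)])


def _sine_path(periods=5, length=100.0, amplitude=8.0, n=400):
    t = np.linspace(0.0, 1.0, n)
    return np.column_stack(
        [amplitude * np.sin(2 * math.pi * periods * t), t * length]
    )


class TestTortuosity:
    def test_straight_line_zero(self):
        path = np.column_stack([np.zeros(100), np.arange(100.0)])
        assert tortuosity_index(path) == 0.0

    def test_arc_positive_fewer_critical_points_than_sine(self):
        arc = _arc_path()
        sine = _sine_path()
        assert tortuosity_index(arc) > 0.0
        assert (
            tortuosity_details(arc)["num_critical_points"]
            < tortuosity_details(sine)["num_critical_points"]
        )

    def test_sine_more_tortuous_than_arc(self):
        assert tortuosity_index(_sine_path()) > tortuosity_index(_arc_path())

    def test_monotone_in_oscillation_count(self):
        vals = [tortuosity_index(_sine_path(periods=p)) for p in (1, 3, 5)]
        assert vals[0] < vals[1] < vals[2]

    @pytest.mark.parametrize("angle", [30.0, 120.0, 261.0])
    def test_invariant_to_rotation_translation_reversal(self, angle):
        path = _sine_path(periods=3)
        base = tortuosity_index(path)
        th = math.radians(angle)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        transformed = path @ rot.T + np.array([13.0, -40.0])
        assert tortuosity_index(transformed) == pytest.approx(base, rel=1e-6)
        assert tortuosity_index(path[::-1]) == pytest.approx(base, rel=1e-6)

    def test_closed_path_flagged(self):
        th = np.linspace(0, 2 * math.pi, 100)
        ring = np.column_stack([np.cos(th), np.sin(th)]) * 20.0
        with pytest.raises(ValueError, match="chord"):
            tortuosity_index(ring)


def _seg(sid, diameters, path_len=30):
    seg = SkeletonSegment(
        pixel_path=[(0, i) for i in range(path_len)], endpoints=(0, 1),
        length=float(path_len - 1),
    )
    ms = MaskSegment(segment_id=sid, segment=seg, vessel_pixels=set())
    ms.diameters = np.asarray(diameters, dtype=float)
    return ms


class TestRules:
    def test_focal_variation_fires_above_threshold_only(self):
        cfg = GeometryRuleConfig()
        hot = _seg(0, [5, 5, 9, 5], path_len=4)  # variation 4 > 3
        cold = _seg(1, [5, 5, 8, 5], path_len=4)  # variation 3, not > 3
        report = detect_geometry_abnormalities(
            g=None.__class__ and _dummy_graph(), trees=[], segments=[hot, cold],
            cfg=cfg,
        )
        rules = {(f.subject, f.rule) for f in report.flags}
        assert (0, "focal_variation") in rules
        assert (1, "focal_variation") not in rules

    def test_parent_child_calibre_rule(self):
        cfg = GeometryRuleConfig()
        parent = _seg(0, [4.0] * 20)
        child = _seg(1, [6.0] * 20)
        tree = VascularTree(tree_id=0, root=0, edges={0: (0, 1), 1: (1, 2)},
                            vertices={0, 1, 2})
        report = detect_geometry_abnormalities(
            _dummy_graph(), [tree], [parent, child], cfg
        )
        assert [f.rule for f in report.flags] == ["parent_child_calibre"]
        assert report.flags[0].subject == 0

    def test_parent_equal_child_not_flagged(self):
        parent = _seg(0, [5.0] * 20)
        child = _seg(1, [5.0] * 20)
        tree = VascularTree(tree_id=0, root=0, edges={0: (0, 1), 1: (1, 2)},
                            vertices={0, 1, 2})
        report = detect_geometry_abnormalities(_dummy_graph(), [tree],
                                               [parent, child])
        assert report.is_clean

    @pytest.mark.parametrize("angle,expect_flag", [(155, True), (145, False)])
    def test_wide_angle_rule_straddle(self, angle, expect_flag):
        """Constructed graph with exact child directions at a known angle."""
        from vasctree.graph import GeometricGraph, Vertex

        half = math.radians(angle) / 2.0
        def _child_path(sign):
            d = np.array([math.cos(half), sign * math.sin(half)])
            return [tuple(np.round(50 + t * 30 * d, 6)) for t in np.linspace(0, 1, 40)]

        vertices = {
            0: Vertex(position=(20.0, 50.0), kind="start", pixels=[(20, 50)]),
            1: Vertex(position=(50.0, 50.0), kind="bifurcation", pixels=[(50, 50)]),
            2: Vertex(position=(90.0, 20.0), kind="end", pixels=[(90, 20)]),
            3: Vertex(position=(90.0, 80.0), kind="end", pixels=[(90, 80)]),
        }
        stem = [(float(r), 50.0) for r in range(20, 51)]
        edges = {
            0: SkeletonSegment(pixel_path=stem, endpoints=(0, 1), length=30.0),
            1: SkeletonSegment(pixel_path=_child_path(-1.0), endpoints=(1, 2),
                               length=30.0),
            2: SkeletonSegment(pixel_path=_child_path(1.0), endpoints=(1, 3),
                               length=30.0),
        }
        g = GeometricGraph(vertices=vertices, edges=edges)
        tree = VascularTree(tree_id=0, root=0,
                            edges={0: (0, 1), 1: (1, 2), 2: (1, 3)},
                            vertices={0, 1, 2, 3})
        report = detect_geometry_abnormalities(g, [tree], [])
        fired = bool(report.by_rule("wide_angle"))
        assert fired == expect_flag

    def test_high_tortuosity_rule_straddle(self):
        quiet = _sine_path(periods=1, amplitude=2.0)
        wild = _sine_path(periods=6, amplitude=10.0)
        assert tortuosity_index(quiet) <= 5.0 < tortuosity_index(wild)
        segs = []
        for sid, path in ((0, quiet), (1, wild)):
            seg = SkeletonSegment(
                pixel_path=[tuple(p) for p in path], endpoints=(0, 1),
                length=float(len(path)),
            )
            segs.append(MaskSegment(segment_id=sid, segment=seg, vessel_pixels=set()))
        report = detect_geometry_abnormalities(_dummy_graph(), [], segs)
        assert {f.subject for f in report.by_rule("high_tortuosity")} == {1}

    def test_clean_fixture_no_flags(self, clean_tree, od):
        mask, fov, _ = clean_tree
        _, _, g, trees, _ = analyze_mask(mask, fov, od)
        segs = extract_mask_segments(g, mask)
        for s in segs:
            estimate_diameters(s, mask)
        report = detect_geometry_abnormalities(g, trees, segs)
        assert report.is_clean


def _dummy_graph():
    from vasctree.graph import GeometricGraph

    return GeometricGraph(vertices={}, edges={})


class TestThickThin:
    def test_split_strictly_above_5(self):
        labels = classify_thick_thin([_seg(0, [6.0] * 5), _seg(1, [5.0] * 5),
                                      _seg(2, [4.0] * 5)])
        assert labels == {0: "thick", 1: "thin", 2: "thin"}

    def test_all_thin_fixture(self):
        mask, fov, _ = generate_tree(TreeSpec(root_width=4.0))
        od = OpticDisc(center=(60.0, 256.0), radius=20.0)
        _, _, g, _, _ = analyze_mask(mask, fov, od)
        segs = extract_mask_segments(g, mask)
        for s in segs:
            estimate_diameters(s, mask)
        labels = classify_thick_thin(segs)
        assert set(labels.values()) == {"thin"}
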