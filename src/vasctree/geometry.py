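"""Per-segment vessel geometry and rule-based geometrical abnormality
detection.

Three geometrical properties drive most visible vascular abnormality: vessel
calibre, bifurcation angle, and tortuosity.  Each skeleton segment is paired
with its cross-sectional vessel pixels (a *mask segment*), per-centreline
diameters are estimated from the Euclidean distance transform, bifurcation
angles are measured between the two child branches within a circular search
radius, and a vessel tortuosity index (VTI) summarises each segment's
centreline waviness.  A segment or bifurcation is flagged abnormal when any
of the four rules fires:

1. focal calibre variation above ``focal_variation_max`` pixels;
2. a parent segment's mean calibre below that of any child segment;
3. bifurcation angle above ``angle_max`` degrees;
4. tortuosity index above ``tortuosity_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .graph import GeometricGraph, SkeletonSegment, VascularTree, path_length

__all__ = [
    "GeometryRuleConfig",
    "MaskSegment",
    "GeometryFlag",
    "GeometryReport",
    "extract_mask_segments",
    "estimate_diameters",
    "bifurcation_angle",
    "tortuosity_index",
    "tortuosity_details",
    "detect_geometry_abnormalities",
    "classify_thick_thin",
]


@dataclass
class GeometryRuleConfig:
    """Thresholds of the geometrical abnormality rules (all in pixels at the
    1024 working scale except angles in degrees and the dimensionless VTI)."""

    focal_variation_max: float = 3.0
    angle_max: float = 150.0
    tortuosity_max: float = 5.0
    thick_threshold: float = 5.0
    angle_search_radius: float = 10.0
    focal_window: int = 10

    def __post_init__(self):
        for name in ("focal_variation_max", "angle_max", "tortuosity_max",
                     "thick_threshold", "angle_search_radius", "focal_window"):
            if getattr(self, name) <= 0:
                raise ValueError("%s must be positive" % name)


@dataclass
class MaskSegment:
    """A skeleton segment plus its cross-sectional vessel pixels and
    per-centreline-pixel diameters."""

    segment_id: int
    segment: SkeletonSegment
    vessel_pixels: set[tuple[int, int]]
    diameters: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def mean_diameter(self) -> float:
        return float(self.diameters.mean()) if self.diameters.size else 0.0


@dataclass
class GeometryFlag:
    subject: int  # segment id or vertex id, per rule
    rule: str  # focal_variation | parent_child_calibre | wide_angle | high_tortuosity
    value: float


@dataclass
class GeometryReport:
    flags: list[GeometryFlag]

    def by_rule(self, rule: str) -> list[GeometryFlag]:
        return [f for f in self.flags if f.rule == rule]

    @property
    def is_clean(self) -> bool:
        return not self.flags


def extract_mask_segments(
    g: GeometricGraph, mask: np.ndarray, od=None
) -> list[MaskSegment]:
    """Assign every vessel pixel to the segment whose centreline is nearest.

    Ties go to the lower segment id.  Pixels inside the optic-disc region are
    left unassigned.  The result partitions the (outside-OD) vessel pixels:
    no pixel is lost, none is claimed twice.
    """
    mask = np.asarray(mask, dtype=bool)
    seg_ids = sorted(g.edges)
    seg_pixels: list[tuple[int, int]] = []
    seg_of_pixel: list[int] = []
    for sid in seg_ids:
        for p in g.edges[sid].pixel_path:
            seg_pixels.append(p)
            seg_of_pixel.append(sid)
    out = {sid: MaskSegment(sid, g.edges[sid], set()) for sid in seg_ids}
    if not seg_pixels:
        return list(out.values())

    vr, vc = np.nonzero(mask)
    if od is not None:
        from .skeleton import OpticDisc

        if isinstance(od, OpticDisc):
            keep = ~od.contains(vr, vc)
        else:
            keep = ~np.asarray(od, dtype=bool)[vr, vc]
        vr, vc = vr[keep], vc[keep]

    tree = cKDTree(np.asarray(seg_pixels, dtype=float))
    # query both nearest neighbours so exact distance ties resolve to the
    # lower segment id regardless of KD-tree insertion order
    dist, idx = tree.query(np.column_stack([vr, vc]).astype(float), k=2)
    seg_arr = np.asarray(seg_of_pixel)
    if idx.ndim == 1:  # single centreline pixel
        chosen = seg_arr[idx]
    else:
        tie = np.isclose(dist[:, 0], dist[:, 1])
        chosen = seg_arr[idx[:, 0]]
        alt = seg_arr[idx[:, 1]]
        chosen = np.where(tie & (alt < chosen), alt, chosen)
    for r, c, sid in zip(vr.tolist(), vc.tolist(), chosen.tolist()):
        out[sid].vessel_pixels.add((r, c))
    return list(out.values())


def estimate_diameters(seg: MaskSegment, mask: np.ndarray) -> np.ndarray:
    """Per-centreline-pixel vessel diameter from the Euclidean distance
    transform: ``d(p) = 2 * EDT(p) - 1``, clamped to at least 1.

    For a centred centreline pixel of a width-w tube, the nearest background
    pixel is ceil(w/2) away, so 2*EDT-1 recovers w (odd widths exactly, even
    widths within 1 px).  The result is stored on the segment and returned.
    """
    mask = np.asarray(mask, dtype=bool)
    edt = ndi.distance_transform_edt(mask)
    path = np.asarray(seg.segment.pixel_path)
    vals = edt[path[:, 0], path[:, 1]]
    if (vals == 0).any():
        raise ValueError("centreline pixel lies on background")
    seg.diameters = np.maximum(2.0 * vals - 1.0, 1.0)
    return seg.diameters


def _child_direction(
    g: GeometricGraph, tree: VascularTree, eid: int, vertex: int, radius: float
) -> np.ndarray:
    """Unit direction from a bifurcation vertex towards a child edge's pixel
    at geodesic distance ``radius`` along its path (or its far end)."""
    pos = g.vertices[vertex].position
    path = g.edges[eid].oriented_from(pos)
    target = path[-1]
    acc = 0.0
    for a, b in zip(path[:-1], path[1:]):
        acc += float(np.hypot(b[0] - a[0], b[1] - a[1]))
        if acc >= radius:
            target = b
            break
    vec = np.array([target[0] - pos[0], target[1] - pos[1]], dtype=float)
    n = np.linalg.norm(vec)
    if n == 0:
        raise ValueError("degenerate child direction at vertex %d" % vertex)
    return vec / n


def bifurcation_angle(
    g: GeometricGraph,
    tree: VascularTree,
    vertex: int,
    radius: float = 10.0,
) -> float:
    """Angle in degrees between the two child branches of a bifurcation.

    Directions are taken from the vertex to each child's centreline pixel at
    geodesic distance ``radius`` (the circular searching area), in (0, 180].
    """
    kids = [e for e in tree.children_edges(vertex)]
    if len(kids) != 2:
        raise ValueError(
            "vertex %d has %d child edges; bifurcation angle needs exactly 2"
            % (vertex, len(kids))
        )
    u = _child_direction(g, tree, kids[0], vertex, radius)
    v = _child_direction(g, tree, kids[1], vertex, radius)
    cosang = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def _smooth_path(path: np.ndarray, window: int = 5) -> np.ndarray:
    if len(path) < window:
        return path
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [np.convolve(path[:, i], kernel, mode="valid") for i in range(2)]
    )
    return sm


def tortuosity_details(path) -> dict:
    """Tangent-angle statistics underlying the vessel tortuosity index.

    The path is smoothed with a 5-px moving average to suppress the
    8-connectivity staircase, tangent angles are computed between successive
    smoothed points and unwrapped, and curvature critical points are counted
    as strict local extrema of the angle sequence.
    """
    p = np.asarray(path, dtype=float)
    if len(p) < 5:
        raise ValueError("path too short for a tortuosity index (need >= 5 px)")
    chord = float(np.hypot(*(p[-1] - p[0])))
    if chord < 1e-6:
        raise ValueError("closed path: chord length is zero")
    arc = path_length(path)
    sm = _smooth_path(p)
    d = np.diff(sm, axis=0)
    angles = np.degrees(np.unwrap(np.arctan2(d[:, 0], d[:, 1])))
    sd = float(angles.std()) if len(angles) > 1 else 0.0
    # strict local extrema of the tangent-angle sequence
    n_crit = 0
    tol = 1e-9
    for i in range(1, len(angles) - 1):
        if (angles[i] - angles[i - 1] > tol and angles[i] - angles[i + 1] > tol) or (
            angles[i - 1] - angles[i] > tol and angles[i + 1] - angles[i] > tol
        ):
            n_crit += 1
    return {
        "sd_angle": sd,
        "num_critical_points": n_crit,
        "arc_length": arc,
        "chord_length": chord,
        "arc_chord_ratio": arc / chord,
    }


def tortuosity_index(seg_or_path) -> float:
    """Vessel tortuosity index (VTI) of a skeleton segment.

    Composition (documented here as the package's concrete definition):

        VTI = 0.1 * SD_theta * (N_critical + 1) * (L_arc / L_chord)

    where ``SD_theta`` is the standard deviation in degrees of the smoothed,
    unwrapped tangent-angle sequence, ``N_critical`` counts strict local
    extrema of that sequence (curvature direction changes), and the last
    factor is the arc-to-chord ratio.  A straight segment scores exactly 0;
    a single smooth arc scores a small positive value (no curvature
    reversals); oscillating paths grow with both the number of reversals and
    the angle spread.
    """
    path = (
        seg_or_path.pixel_path
        if isinstance(seg_or_path, SkeletonSegment)
        else seg_or_path
    )
    d = tortuosity_details(path)
    return 0.1 * d["sd_angle"] * (d["num_critical_points"] + 1) * d["arc_chord_ratio"]


def detect_geometry_abnormalities(
    g: GeometricGraph,
    trees: list[VascularTree],
    segments: list[MaskSegment],
    cfg: GeometryRuleConfig | None = None,
) -> GeometryReport:
    """Flag every violation of the four geometrical rules.

    Focal calibre variation is the max minus min diameter within a sliding
    window of ``focal_window`` centreline pixels along one segment.  The
    parent/child calibre rule and the bifurcation-angle rule are evaluated on
    the tracked trees at every 2-child bifurcation; tortuosity on every
    segment long enough to score.
    """
    cfg = cfg or GeometryRuleConfig()
    by_id = {s.segment_id: s for s in segments}
    flags: list[GeometryFlag] = []

    for s in segments:
        if s.diameters.size:
            # junction zone: the distance transform is inflated where a
            # segment meets a landmark, so trim roughly one local radius off
            # each end when the segment is long enough to afford it
            d = s.diameters
            trim = int(np.ceil(d.max() / 2.0)) + 1
            if d.size - 2 * trim >= cfg.focal_window:
                d = d[trim:-trim]
            w = min(cfg.focal_window, d.size)
            if w >= 2:
                variation = max(
                    float(d[i : i + w].max() - d[i : i + w].min())
                    for i in range(len(d) - w + 1)
                )
                if variation > cfg.focal_variation_max:
                    flags.append(GeometryFlag(s.segment_id, "focal_variation", variation))
        if len(s.segment.pixel_path) >= 5:
            vti = tortuosity_index(s.segment)
            if vti > cfg.tortuosity_max:
                flags.append(GeometryFlag(s.segment_id, "high_tortuosity", vti))

    for tree in trees:
        for eid, (_, child_v) in sorted(tree.edges.items()):
            kids = tree.children_edges(child_v)
            if not kids:
                continue
            parent_seg = by_id.get(eid)
            if parent_seg is not None and parent_seg.diameters.size:
                for k in kids:
                    kid_seg = by_id.get(k)
                    if kid_seg is None or not kid_seg.diameters.size:
                        continue
                    if parent_seg.mean_diameter < kid_seg.mean_diameter:
                        flags.append(
                            GeometryFlag(eid, "parent_child_calibre",
                                         kid_seg.mean_diameter)
                        )
                        break
            if len(kids) == 2:
                angle = bifurcation_angle(g, tree, child_v, cfg.angle_search_radius)
                if angle > cfg.angle_max:
                    flags.append(GeometryFlag(child_v, "wide_angle", angle))
    return GeometryReport(flags=flags)


def classify_thick_thin(
    segments: list[MaskSegment], cfg: GeometryRuleConfig | None = None
) -> dict[int, str]:
    """Label each segment thick or thin by mean calibre.

    A segment is thick iff its mean diameter is strictly greater than
    ``thick_threshold`` (default 5 px); exactly 5 px is thin.
    """
    cfg = cfg or GeometryRuleConfig()
    return {
        s.segment_id: "thick" if s.mean_diameter > cfg.thick_threshold else "thin"
        for s in segments
    }
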