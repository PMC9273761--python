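"""Synthetic vascular fixtures with known ground truth.

Renders binary tree-shaped vessel masks the way a vessel really occupies a
raster — as the envelope of a family of disks with continuously varying
centre and radius along an analytic centreline — so skeletonization, graph
construction, diameter estimation, angles and tortuosity can all be checked
against exact generator truth without any downloaded data.  Calibres span
the realistic 1-20 px range at the 1024 working scale.  Defects mimicking
real annotation noise (venous loops, interior holes, isolated small
components, near-coincident bifurcations, FOV-border spurs) can be injected
and are registered in the ground truth so each QC detector can be validated
for both sensitivity and specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "TreeSpec",
    "TruthVertex",
    "TruthEdge",
    "GroundTruth",
    "generate_tree",
    "inject_defect",
    "generate_fundus",
    "draw_tube",
]


@dataclass
class TreeSpec:
    """Parameters of one synthetic vascular tree.

    Calibres decrease geometrically child/parent (``width_ratio`` < 1) so a
    healthy fixture obeys the parent >= child calibre rule; they are clamped
    to the 1-20 px range.  ``tortuosity_amplitude``/``periods`` add a
    sinusoidal perpendicular displacement to every segment.
    """

    shape: tuple[int, int] = (512, 512)
    root: tuple[float, float] = (60.0, 256.0)
    root_direction_deg: float = 90.0  # 0 = +col (east), 90 = +row (south)
    depth: int = 3
    root_width: float = 11.0
    width_ratio: float = 0.8
    bifurcation_angle_deg: float = 60.0
    segment_length: float = 110.0
    length_ratio: float = 0.75
    tortuosity_amplitude: float = 0.0
    tortuosity_periods: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (1.0 <= self.root_width <= 20.0):
            raise ValueError("root_width must lie in [1, 20] px")

    def level_width(self, level: int) -> float:
        return max(1.0, min(20.0, self.root_width * self.width_ratio**level))


@dataclass
class TruthVertex:
    position: tuple[float, float]
    kind: str  # start | bifurcation | end


@dataclass
class TruthEdge:
    parent: int  # vertex index
    child: int
    path: np.ndarray  # (n, 2) float centreline samples
    width: float
    level: int


@dataclass
class GroundTruth:
    vertices: list[TruthVertex]
    edges: list[TruthEdge]
    defects: list[dict] = field(default_factory=list)

    @property
    def n_bifurcations(self) -> int:
        return sum(1 for v in self.vertices if v.kind == "bifurcation")

    @property
    def n_leaves(self) -> int:
        return sum(1 for v in self.vertices if v.kind == "end")

    def strahler_by_rule(self) -> dict[int, int]:
        """Strahler order of every truth edge computed by direct recursion."""
        kids: dict[int, list[int]] = {}
        for i, e in enumerate(self.edges):
            kids.setdefault(e.parent, [])
            kids.setdefault(e.child, [])
        for i, e in enumerate(self.edges):
            kids[e.parent].append(i)
        order: dict[int, int] = {}

        def _order(eidx: int) -> int:
            if eidx in order:
                return order[eidx]
            children = kids[self.edges[eidx].child]
            if not children:
                order[eidx] = 1
            else:
                vals = [_order(c) for c in children]
                top = max(vals)
                order[eidx] = top + 1 if vals.count(top) >= 2 else top
            return order[eidx]

        for i, e in enumerate(self.edges):
            _order(i)
        return order


def _sample_segment(
    p0: np.ndarray, direction: np.ndarray, length: float,
    amplitude: float, periods: float,
) -> np.ndarray:
    """Centreline samples of one segment: straight run plus a sinusoidal
    perpendicular displacement, ~2 samples per pixel of arc."""
    n = max(int(2 * length), 8)
    t = np.linspace(0.0, 1.0, n)
    perp = np.array([-direction[1], direction[0]])
    pts = (
        p0[None, :]
        + t[:, None] * length * direction[None, :]
        + (amplitude * np.sin(2 * math.pi * periods * t))[:, None] * perp[None, :]
    )
    return pts


def draw_tube(mask: np.ndarray, path: np.ndarray, width: float) -> None:
    """Stamp disks of diameter ``width`` along ``path`` (envelope of disks)."""
    radius = max(width / 2.0, 0.5)
    h, w = mask.shape
    r_int = int(math.ceil(radius))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disk = yy**2 + xx**2 <= radius**2
    if not disk.any():
        disk[r_int, r_int] = True
    for r, c in path:
        ri, ci = int(round(r)), int(round(c))
        r0, r1 = ri - r_int, ri + r_int + 1
        c0, c1 = ci - r_int, ci + r_int + 1
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError("tube exceeds the raster bounds")
        mask[r0:r1, c0:c1] |= disk


def generate_tree(
    spec: TreeSpec, n_trees: int = 1, tree_spacing: float = 160.0
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render one or more binary vascular trees with full ground truth.

    Trees are perfect binary trees of ``spec.depth`` levels; additional
    trees are laid side by side ``tree_spacing`` px apart.  Returns
    ``(vessel mask, FOV mask, ground truth)``; everything is a deterministic
    function of the spec (the RNG seed feeds only noise used by
    :func:`generate_fundus`).
    """
    mask = np.zeros(spec.shape, dtype=bool)
    vertices: list[TruthVertex] = []
    edges: list[TruthEdge] = []

    for k in range(n_trees):
        root = np.array(spec.root, dtype=float) + np.array([0.0, k * tree_spacing])
        theta = math.radians(spec.root_direction_deg)
        direction = np.array([math.sin(theta), math.cos(theta)])
        root_idx = len(vertices)
        vertices.append(TruthVertex(position=tuple(root), kind="start"))
        stack = [(root_idx, root, direction, 0)]
        while stack:
            parent_idx, p0, d, level = stack.pop()
            length = spec.segment_length * spec.length_ratio**level
            width = spec.level_width(level)
            path = _sample_segment(
                p0, d, length, spec.tortuosity_amplitude, spec.tortuosity_periods
            )
            draw_tube(mask, path, width)
            end = path[-1]
            child_idx = len(vertices)
            is_leaf = level == spec.depth - 1
            vertices.append(
                TruthVertex(
                    position=tuple(end), kind="end" if is_leaf else "bifurcation"
                )
            )
            edges.append(
                TruthEdge(parent=parent_idx, child=child_idx, path=path,
                          width=width, level=level)
            )
            if not is_leaf:
                half = math.radians(spec.bifurcation_angle_deg) / 2.0
                base = math.atan2(d[0], d[1])
                for sign in (1.0, -1.0):
                    ang = base + sign * half
                    nd = np.array([math.sin(ang), math.cos(ang)])
                    stack.append((child_idx, end, nd, level + 1))

    centre = ((spec.shape[0] - 1) / 2.0, (spec.shape[1] - 1) / 2.0)
    rr, cc = np.mgrid[: spec.shape[0], : spec.shape[1]]
    fov_radius = 0.48 * min(spec.shape)
    fov = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= fov_radius**2
    if (mask & ~fov).any():
        fov |= ndi.binary_dilation(mask, iterations=3)
    return mask, fov, GroundTruth(vertices=vertices, edges=edges)


def inject_defect(
    mask: np.ndarray,
    truth: GroundTruth,
    kind: str,
    **params,
) -> tuple[np.ndarray, GroundTruth]:
    """Inject one defect into a rendered mask and register it in the truth.

    Kinds
    -----
    loop : a tube joining the midpoints of the two child edges of a
        bifurcation (``vertex`` index, default: first bifurcation), closing a
        graph circle and, if it encloses background, adding a hole.
    hole : a small background hole punched inside a wide segment
        (``area`` px, default 9).
    small_cc : an isolated disk of ``area`` px (default 50) dropped at
        ``position`` (default: a corner well away from the tree).
    near_bifurcations : two extra short branches sprouting ``separation`` px
        apart (default 2) on one edge, so graph construction merges the two
        branch points into a single overdegree vertex.
    border_spur : a short tube crossing the FOV border at ``position``.
    """
    mask = mask.copy()
    if kind == "loop":
        bif_indices = [
            i for i, v in enumerate(truth.vertices) if v.kind == "bifurcation"
        ]
        if not bif_indices:
            raise ValueError("no bifurcation available to anchor a loop")
        vidx = params.get("vertex", bif_indices[0])
        kids = [e for e in truth.edges if e.parent == vidx]
        if len(kids) < 2:
            raise ValueError("vertex %d has fewer than 2 child edges" % vidx)
        a = kids[0].path[len(kids[0].path) // 2]
        b = kids[1].path[len(kids[1].path) // 2]
        n = max(int(2 * np.hypot(*(b - a))), 8)
        t = np.linspace(0, 1, n)
        path = a[None, :] + t[:, None] * (b - a)[None, :]
        width = params.get("width", max(1.0, min(k.width for k in kids) * 0.8))
        draw_tube(mask, path, width)
        truth.defects.append(
            {"kind": "loop", "between": (tuple(a), tuple(b)), "vertex": vidx}
        )
    elif kind == "hole":
        area = int(params.get("area", 9))
        edge = max(truth.edges, key=lambda e: e.width)
        if edge.width < 5:
            raise ValueError("no segment wide enough to host an interior hole")
        centre = edge.path[len(edge.path) // 2]
        side = max(int(round(math.sqrt(area))), 1)
        r0 = int(round(centre[0])) - side // 2
        c0 = int(round(centre[1])) - side // 2
        region = mask[r0 : r0 + side, c0 : c0 + side]
        if not region.all():
            raise ValueError("hole placement overlaps background")
        mask[r0 : r0 + side, c0 : c0 + side] = False
        truth.defects.append(
            {"kind": "hole", "position": (r0, c0), "area": side * side}
        )
    elif kind == "small_cc":
        area = int(params.get("area", 50))
        pos = params.get("position")
        if pos is None:
            pos = (mask.shape[0] - 30, 30)
        rr, cc = np.mgrid[: mask.shape[0], : mask.shape[1]]
        d2 = (rr - pos[0]) ** 2 + (cc - pos[1]) ** 2
        order = np.argsort(d2.ravel(), kind="stable")[:area]
        blob = np.zeros_like(mask)
        blob.ravel()[order] = True
        if (ndi.binary_dilation(blob, iterations=2) & mask).any():
            raise ValueError("small component placement touches the tree")
        mask |= blob
        truth.defects.append({"kind": "small_cc", "position": tuple(pos), "area": area})
    elif kind == "near_bifurcations":
        sep = float(params.get("separation", 2.0))
        edge = params.get("edge", 0)
        e = truth.edges[edge]
        mid = len(e.path) // 2
        step = max(int(sep * 2), 1)  # path sampled at ~0.5 px
        p1, p2 = e.path[mid], e.path[min(mid + step, len(e.path) - 1)]
        d = e.path[mid + 1] - e.path[mid]
        d = d / np.linalg.norm(d)
        perp = np.array([-d[1], d[0]])
        blen = params.get("branch_length", 40.0)
        bw = max(1.0, e.width * 0.6)
        for p, sign in ((p1, 1.0), (p2, -1.0)):
            bdir = (d + sign * 1.2 * perp)
            bdir = bdir / np.linalg.norm(bdir)
            path = _sample_segment(p, bdir, blen, 0.0, 1.0)
            draw_tube(mask, path, bw)
        truth.defects.append(
            {"kind": "near_bifurcations", "positions": (tuple(p1), tuple(p2)),
             "separation": sep}
        )
    elif kind == "border_spur":
        pos = np.array(params.get("position", (mask.shape[0] // 2, 8)), dtype=float)
        d = np.array(params.get("direction", (0.0, 1.0)))
        d = d / np.linalg.norm(d)
        path = _sample_segment(pos, d, params.get("length", 25.0), 0.0, 1.0)
        draw_tube(mask, path, params.get("width", 3.0))
        truth.defects.append({"kind": "border_spur", "position": tuple(pos)})
    else:
        raise ValueError("unknown defect kind %r" % kind)
    return mask, truth


def generate_fundus(
    mask: np.ndarray,
    fov: np.ndarray,
    seed: int = 0,
    vessel_contrast: float = 60.0,
    noise_sd: float = 4.0,
    blur_sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a toy colour fundus image and a soft vessel-probability map.

    The retina is a textured bright disk with a radial illumination falloff;
    vessels are drawn darker by ``vessel_contrast`` grey levels.  The
    probability map is the blurred, noise-corrupted mask clipped to [0, 1] —
    the kind of soft prediction a segmentation model emits, for exercising
    local adaptive binarization.
    """
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    rr, cc = np.mgrid[:h, :w]
    centre = ((h - 1) / 2.0, (w - 1) / 2.0)
    d = np.hypot(rr - centre[0], cc - centre[1]) / (0.5 * min(h, w))
    base = 170.0 - 50.0 * d**2
    texture = ndi.gaussian_filter(rng.normal(0.0, 8.0, size=mask.shape), 6.0)
    grey = base + texture
    grey[mask] -= vessel_contrast
    grey[~fov] = 0.0
    grey = np.clip(grey, 0, 255)
    image = np.stack(
        [np.clip(grey * f, 0, 255) for f in (1.0, 0.55, 0.30)], axis=-1
    ).astype(np.uint8)

    prob = ndi.gaussian_filter(mask.astype(float), blur_sigma)
    # confident models emit near-zero probabilities off-vessel, so noise is
    # confined to the vessel neighbourhood
    support = prob > 0.01
    prob = prob + rng.normal(0.0, noise_sd / 255.0, size=mask.shape) * support
    prob = np.clip(prob, 0.0, 1.0)
    prob[~fov] = 0.0
    return image, prob
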