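"""Vessel skeletonization and landmark-pixel classification.

Centrelines are extracted with Lee's 3-D thinning method (applied to the 2-D
raster), which produces 1-pixel-wide, spur-free skeletons of both thick and
thin vessels.  Landmark pixels — bifurcations, starting and ending points —
are classified from the number of 8-neighbours of each skeleton pixel, with
the centre pixel excluded from the count: terminals have exactly one
neighbour, bifurcations at least three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "OpticDisc",
    "LandmarkSet",
    "skeletonize",
    "count_neighbors",
    "detect_landmarks",
]

_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


@dataclass(frozen=True)
class OpticDisc:
    """Optic disc region given as centre (row, col) and radius in pixels."""

    center: tuple[float, float]
    radius: float

    def contains(self, rows, cols) -> np.ndarray:
        r0, c0 = self.center
        return (np.asarray(rows) - r0) ** 2 + (np.asarray(cols) - c0) ** 2 <= self.radius**2

    def boundary_distance(self, rows, cols) -> np.ndarray:
        """Unsigned distance to the disc boundary circle."""
        r0, c0 = self.center
        d = np.hypot(np.asarray(rows, dtype=float) - r0, np.asarray(cols, dtype=float) - c0)
        return np.abs(d - self.radius)


@dataclass
class LandmarkSet:
    """Classified skeleton landmark pixels.

    ``bifurcations`` are pixels with >= 3 skeleton neighbours; ``starts`` are
    terminal pixels (1 neighbour) close to the optic-disc boundary, where a
    vascular tree is rooted; ``ends`` are the remaining terminals.
    ``border_uncertain`` flags terminals on the FOV border, where the
    centreline is unreliable because part of the vessel cross-section lies
    outside the captured region.
    """

    bifurcations: set[tuple[int, int]]
    starts: set[tuple[int, int]]
    ends: set[tuple[int, int]]
    neighbor_counts: np.ndarray
    border_uncertain: set[tuple[int, int]] = field(default_factory=set)
    pure_loop: bool = False

    def all_landmarks(self) -> set[tuple[int, int]]:
        return self.bifurcations | self.starts | self.ends


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Reduce a binary vessel mask to 1-px-wide centrelines (Lee's method)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _sk_skeletonize(mask, method="lee").astype(bool)


def count_neighbors(skel: np.ndarray) -> np.ndarray:
    """Number of foreground 8-neighbours of every skeleton pixel (centre
    excluded); zero on background pixels."""
    skel = np.asarray(skel, dtype=bool)
    counts = ndi.convolve(skel.astype(np.uint8), _NEIGH_KERNEL, mode="constant")
    counts[~skel] = 0
    return counts


def detect_landmarks(
    skel: np.ndarray,
    od: OpticDisc | np.ndarray | None = None,
    fov: np.ndarray | None = None,
    delta: float = 20.0,
) -> LandmarkSet:
    """Classify skeleton pixels into bifurcation / starting / ending vertices.

    Terminal pixels within ``delta`` pixels of the optic-disc boundary become
    starting vertices (trees are tracked outward from the disc); all other
    terminals are ending vertices.  When no disc is given, distance to the
    image centre is used instead.  Terminals on the FOV border are
    additionally flagged ``border_uncertain``.
    """
    skel = np.asarray(skel, dtype=bool)
    counts = count_neighbors(skel)
    bif_r, bif_c = np.nonzero(skel & (counts >= 3))
    term_r, term_c = np.nonzero(skel & (counts == 1))
    bifurcations = set(zip(bif_r.tolist(), bif_c.tolist()))

    pure_loop = False
    if term_r.size == 0 and skel.any() and od is None:
        pure_loop = True

    if term_r.size:
        if od is None:
            centre = ((skel.shape[0] - 1) / 2.0, (skel.shape[1] - 1) / 2.0)
            dist = np.hypot(term_r - centre[0], term_c - centre[1])
        elif isinstance(od, OpticDisc):
            dist = od.boundary_distance(term_r, term_c)
        else:
            od_mask = np.asarray(od, dtype=bool)
            # distance to the OD region boundary: EDT outside, 0 inside
            dist = ndi.distance_transform_edt(~od_mask)[term_r, term_c]
        is_start = dist <= delta
    else:
        is_start = np.zeros(0, dtype=bool)

    starts = set(zip(term_r[is_start].tolist(), term_c[is_start].tolist()))
    ends = set(zip(term_r[~is_start].tolist(), term_c[~is_start].tolist()))

    border_uncertain: set[tuple[int, int]] = set()
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        interior = ndi.binary_erosion(fov, np.ones((3, 3), dtype=bool))
        rim = fov & ~interior
        for p in starts | ends:
            if rim[p]:
                border_uncertain.add(p)

    return LandmarkSet(
        bifurcations=bifurcations,
        starts=starts,
        ends=ends,
        neighbor_counts=counts,
        border_uncertain=border_uncertain,
        pure_loop=pure_loop,
    )
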