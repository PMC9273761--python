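"""Annotation quality control.

Hole detection and connected-component analysis locate annotation noise in
binary artery/vein masks: interior background holes break vascular topology
and corrupt skeletonization, while isolated small components are usually
either false-positive pixels or fragments broken off a large vessel.  Label
disambiguation compares a manual mask against an independent model
prediction and splits the non-consensus pixels into *unlabelled* (candidate
missed vessels) and *mislabelled* (candidate false annotations).  The patch
grid supports the subjective annotation-quality-rater workflow: a 1024x1024
image is tiled into 128x128 patches, each scored 0-5 by a human grader, and
scores are aggregated with patches of score 0 (no visible vessel) excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .skeleton import OpticDisc

__all__ = [
    "Hole",
    "SmallComponent",
    "QCReport",
    "PatchGrid",
    "detect_holes",
    "small_components",
    "disambiguate_labels",
    "tile_patches",
    "aggregate_scores",
]


@dataclass
class Hole:
    pixels: set[tuple[int, int]]
    location: str  # in_OD | outside_OD
    mask_name: str = ""

    @property
    def area(self) -> int:
        return len(self.pixels)


@dataclass
class SmallComponent:
    pixels: set[tuple[int, int]]
    area: int
    mask_name: str = ""


@dataclass
class QCReport:
    holes: list[Hole] = field(default_factory=list)
    small_ccs: list[SmallComponent] = field(default_factory=list)
    unlabelled: set[tuple[int, int]] = field(default_factory=set)
    mislabelled: set[tuple[int, int]] = field(default_factory=set)


def detect_holes(
    mask: np.ndarray,
    od: OpticDisc | np.ndarray | None = None,
    mask_name: str = "",
) -> list[Hole]:
    """Find interior holes of a binary mask via flood fill from the border.

    A hole is a 4-connected background component not connected to the raster
    border (4-connectivity on background is the dual of the 8-connected
    foreground).  Each hole is tagged in_OD / outside_OD by its centroid;
    holes in the optic disc arise from genuinely intertwined central vessels
    and must be retained, not filled.  Run separately per artery/vein mask.
    """
    mask = np.asarray(mask, dtype=bool)
    bg_lab, n = ndi.label(~mask, structure=ndi.generate_binary_structure(2, 1))
    border_labels = set(np.unique(bg_lab[0])) | set(np.unique(bg_lab[-1]))
    border_labels |= set(np.unique(bg_lab[:, 0])) | set(np.unique(bg_lab[:, -1]))
    holes = []
    for lab in range(1, n + 1):
        if lab in border_labels:
            continue
        rr, cc = np.nonzero(bg_lab == lab)
        centroid = (float(rr.mean()), float(cc.mean()))
        if od is None:
            loc = "outside_OD"
        elif isinstance(od, OpticDisc):
            loc = "in_OD" if bool(od.contains(*centroid)) else "outside_OD"
        else:
            od_mask = np.asarray(od, dtype=bool)
            loc = (
                "in_OD"
                if od_mask[int(round(centroid[0])), int(round(centroid[1]))]
                else "outside_OD"
            )
        holes.append(
            Hole(pixels=set(zip(rr.tolist(), cc.tolist())), location=loc,
                 mask_name=mask_name)
        )
    return holes


def small_components(
    mask: np.ndarray, min_area: int = 100, mask_name: str = ""
) -> list[SmallComponent]:
    """8-connected components with area strictly smaller than ``min_area``
    pixels, sorted by area (smallest first)."""
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndi.label(mask, structure=np.ones((3, 3)))
    out = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(lab == i)
        if rr.size < min_area:
            out.append(
                SmallComponent(
                    pixels=set(zip(rr.tolist(), cc.tolist())),
                    area=int(rr.size),
                    mask_name=mask_name,
                )
            )
    out.sort(key=lambda c: (c.area, min(c.pixels)))
    return out


def disambiguate_labels(
    manual: np.ndarray, predicted: np.ndarray, fov: np.ndarray | None = None
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Split non-consensus pixels between a manual mask and a model
    prediction into the two noise types.

    Returns ``(unlabelled, mislabelled)``: *unlabelled* pixels are predicted
    but not manually annotated (candidate missed vessels to join);
    *mislabelled* pixels are annotated but not predicted (candidate false
    annotations to remove).  Both restricted to the FOV; consensus pixels
    never appear.
    """
    manual = np.asarray(manual, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    if manual.shape != predicted.shape:
        raise ValueError("manual and predicted masks must share a shape")
    inside = np.ones_like(manual) if fov is None else np.asarray(fov, dtype=bool)
    unl = predicted & ~manual & inside
    mis = manual & ~predicted & inside
    return (
        set(zip(*(a.tolist() for a in np.nonzero(unl)))),
        set(zip(*(a.tolist() for a in np.nonzero(mis)))),
    )


@dataclass
class PatchGrid:
    """Grid of subjective quality scores, one integer 0-5 per image patch."""

    patch_size: int
    scores: np.ndarray  # (rows, cols) int grid

    def __post_init__(self):
        s = np.asarray(self.scores)
        if s.size and (s.min() < 0 or s.max() > 5):
            raise ValueError("scores must lie in [0, 5]")
        self.scores = s.astype(int)


def tile_patches(image_dim: int, patch: int = 128) -> PatchGrid:
    """Prepare an empty score grid tiling a square image into patches."""
    if image_dim % patch:
        raise ValueError("image dimension %d not divisible by patch %d" % (image_dim, patch))
    n = image_dim // patch
    return PatchGrid(patch_size=patch, scores=np.zeros((n, n), dtype=int))


def aggregate_scores(
    grid: PatchGrid, sample_sd: bool = True
) -> tuple[float, float, str]:
    """Aggregate patch scores, excluding score-0 (no visible vessel) patches.

    Returns ``(mean, sd, "mean ± 2*sd")``.  ``sample_sd`` selects the sample
    (ddof=1) vs population standard deviation.
    """
    vals = grid.scores[grid.scores > 0].astype(float)
    if vals.size == 0:
        raise ValueError("no patch with a visible vessel (all scores are 0)")
    mean = float(vals.mean())
    ddof = 1 if (sample_sd and vals.size > 1) else 0
    sd = float(vals.std(ddof=ddof))
    return mean, sd, f"{mean:.4f} ± {2 * sd:.4f}"
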