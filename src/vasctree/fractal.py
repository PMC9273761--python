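"""Box-counting fractal dimension of the retinal vasculature.

Fractal dimension (FD) summarises the geometric complexity of the vascular
tree; FD changes accompany disease progression, and macular vessel density
in particular responds to diabetic macular edema.  FD is measured over the
whole field of view and over a standardized macula region: a disk centred on
the macula with radius 0.6 times the macula-to-optic-disc centre distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FdResult", "macula_region", "box_counting_fd"]


@dataclass
class FdResult:
    fd: float
    box_sizes: list[int]
    counts: list[int]
    r_squared: float
    region: str = "fov"


def macula_region(
    macula_center: tuple[float, float],
    od_center: tuple[float, float],
    shape: tuple[int, int],
) -> np.ndarray:
    """Standardized macula disk: centred on the macula, radius 0.6 times the
    distance between macula centre and optic-disc centre."""
    mr, mc = macula_center
    orr, oc = od_center
    dist = float(np.hypot(mr - orr, mc - oc))
    if dist == 0:
        raise ValueError("macula and optic-disc centres coincide")
    radius = 0.6 * dist
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - mr) ** 2 + (cc - mc) ** 2 <= radius**2


def box_counting_fd(
    mask: np.ndarray,
    region: np.ndarray | None = None,
    region_name: str = "fov",
    offset_average: bool = False,
) -> FdResult:
    """Box-counting fractal dimension of a binary vessel raster.

    Boxes of side ``s = 2^k`` (from 2 px up to half the region bounding-box
    side, at least 4 scales) are laid over the region bounding box; ``N(s)``
    counts boxes containing at least one vessel pixel.  FD is the slope of
    the least-squares fit of ``log N(s)`` against ``log(1/s)``.  The grid
    origin is the region bounding-box corner; ``offset_average`` instead
    averages ``N(s)`` over all grid offsets (slower, slightly more stable).
    """
    mask = np.asarray(mask, dtype=bool)
    if region is not None:
        mask = mask & np.asarray(region, dtype=bool)
    if not mask.any():
        raise ValueError("no vessel pixel inside the measurement region")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    sub = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    side = max(sub.shape)

    sizes = []
    s = 2
    while s <= max(side // 2, 2):
        sizes.append(s)
        s *= 2
    while len(sizes) < 4:  # degenerate small regions: extend upward
        sizes.append(sizes[-1] * 2 if sizes else 2)

    counts = []
    for s in sizes:
        if offset_average:
            acc = []
            step = max(s // 2, 1)
            for dr in range(0, s, step):
                for dc in range(0, s, step):
                    acc.append(_count_boxes(sub, s, dr, dc))
            counts.append(int(round(float(np.mean(acc)))))
        else:
            counts.append(_count_boxes(sub, s, 0, 0))

    log_inv_s = np.log(1.0 / np.asarray(sizes, dtype=float))
    log_n = np.log(np.maximum(counts, 1))
    coeffs = np.polyfit(log_inv_s, log_n, 1)
    fit = np.polyval(coeffs, log_inv_s)
    ss_res = float(((log_n - fit) ** 2).sum())
    ss_tot = float(((log_n - log_n.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FdResult(
        fd=float(coeffs[0]),
        box_sizes=list(sizes),
        counts=[int(c) for c in counts],
        r_squared=r2,
        region=region_name,
    )


def _count_boxes(sub: np.ndarray, s: int, dr: int, dc: int) -> int:
    padded = np.pad(sub, ((dr, 0), (dc, 0)))
    h, w = padded.shape
    ph = (-h) % s
    pw = (-w) % s
    padded = np.pad(padded, ((0, ph), (0, pw)))
    blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
    return int(blocks.any(axis=(1, 3)).sum())
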