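"""Fundus preprocessing: FOV detection, crop/resize to a square working
resolution, contrast enhancement, FOV border extension, and local adaptive
binarization of soft vessel predictions.

The working convention is a 1024x1024 square raster holding the circular
field of view (FOV) with its aspect ratio preserved: the FOV bounding box is
cropped out of the full frame, trimmed to even dimensions, padded with black
to a square, then isotropically resized.  :class:`~vasctree.io_container.CropInfo`
records every step so masks produced at the working resolution can be placed
back into the original frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import exposure, transform
from skimage.color import rgb2ycbcr, ycbcr2rgb
from skimage.filters import threshold_sauvola
from skimage.measure import label

from .io_container import CropInfo

__all__ = [
    "PreprocessConfig",
    "detect_fov",
    "crop_resize",
    "restore_full",
    "enhance_clahe",
    "enhance_lce",
    "extend_fov_border",
    "sauvola_binarize",
]


@dataclass
class PreprocessConfig:
    """Knobs for the preprocessing stage.

    target_dim : side of the square working raster (px, even).
    clahe_clip / clahe_tile : CLAHE clip limit and tile grid size.
    lce_sigma : Gaussian scale (px) of the local-contrast high-pass.
    border_width : FOV border extension width (px).
    sauvola_window / sauvola_k / sauvola_r : local-threshold parameters;
        ``sauvola_r`` is the dynamic range, 0.5 for probability maps.
    """

    target_dim: int = 1024
    clahe_clip: float = 0.01
    clahe_tile: int = 8
    lce_sigma: float = 25.0
    border_width: int = 20
    sauvola_window: int = 25
    sauvola_k: float = 0.2
    sauvola_r: float = 0.5

    def __post_init__(self):
        if self.target_dim % 2:
            raise ValueError("target_dim must be even")
        for name in ("clahe_clip", "lce_sigma", "border_width", "sauvola_window",
                     "sauvola_k", "sauvola_r"):
            if getattr(self, name) <= 0:
                raise ValueError("%s must be positive" % name)


def _to_grey(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3:
        return image[..., :3].astype(np.float64).mean(axis=2)
    return image.astype(np.float64)


def detect_fov(image: np.ndarray, threshold: float = 10.0) -> np.ndarray:
    """Detect the field of view as the largest bright connected region.

    The FOV of a fundus photograph is the roughly circular illuminated disk;
    everything outside it is (near-)black camera background.  Pixels whose
    grey value exceeds ``threshold`` are kept, the largest 8-connected
    component is selected and its interior holes are filled.
    """
    grey = _to_grey(image)
    fg = grey > threshold
    if not fg.any():
        raise ValueError("no pixel exceeds the FOV threshold; image is empty")
    labels = label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    fov = labels == counts.argmax()
    return ndi.binary_fill_holes(fov)


def crop_resize(
    image: np.ndarray, fov: np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray, CropInfo]:
    """Crop the FOV bounding box, square it with black padding, and resize.

    Odd-sized originals are first trimmed to even dimensions by dropping the
    first row/column (recorded as ``dim_change``).  Returns the resized image,
    the resized FOV mask and the :class:`CropInfo` needed to invert the
    transform with :func:`restore_full`.
    """
    cfg = cfg or PreprocessConfig()
    image = np.asarray(image)
    fov = np.asarray(fov, dtype=bool)
    if fov.shape != image.shape[:2]:
        raise ValueError("fov shape must match image shape")
    if not fov.any():
        raise ValueError("empty FOV")
    ori_row, ori_col = fov.shape
    dim_change_row = ori_row % 2 == 1
    dim_change_col = ori_col % 2 == 1
    if dim_change_row:
        image, fov = image[1:], fov[1:]
    if dim_change_col:
        image, fov = image[:, 1:], fov[:, 1:]

    rows = np.nonzero(fov.any(axis=1))[0]
    cols = np.nonzero(fov.any(axis=0))[0]
    r0, r1, c0, c1 = rows[0], rows[-1], cols[0], cols[-1]
    # trim the crop itself to even dimensions (drop first row/col of the box)
    if (r1 - r0 + 1) % 2:
        r0 += 1
    if (c1 - c0 + 1) % 2:
        c0 += 1
    crop_img = image[r0 : r1 + 1, c0 : c1 + 1]
    crop_fov = fov[r0 : r1 + 1, c0 : c1 + 1]

    h, w = crop_fov.shape
    side = max(h, w)
    pad_top = (side - h) // 2
    pad_bottom = side - h - pad_top
    pad_left = (side - w) // 2
    pad_right = side - w - pad_left
    pad_img = ((pad_top, pad_bottom), (pad_left, pad_right)) + (
        ((0, 0),) if crop_img.ndim == 3 else ()
    )
    sq_img = np.pad(crop_img, pad_img)
    sq_fov = np.pad(crop_fov, ((pad_top, pad_bottom), (pad_left, pad_right)))

    out_img = resize_image(sq_img, cfg.target_dim)
    out_fov = resize_mask(sq_fov, cfg.target_dim)
    info = CropInfo(
        ori_row=ori_row,
        ori_col=ori_col,
        cropped_row=h,
        cropped_col=w,
        cropped_left=(int(r0), int(c0)),
        cropped_right=(int(r1), int(c1)),
        extension=(int(pad_top), int(pad_bottom), int(pad_left), int(pad_right)),
        dim_change_row=dim_change_row,
        dim_change_col=dim_change_col,
        target_dim=cfg.target_dim,
    )
    return out_img, out_fov, info


def resize_image(image: np.ndarray, dim: int) -> np.ndarray:
    """Isotropic bilinear resize of an intensity image to ``dim`` square."""
    image = np.asarray(image)
    out = transform.resize(
        image.astype(np.float64), (dim, dim), order=1, anti_aliasing=True,
        preserve_range=True,
    )
    if np.issubdtype(image.dtype, np.integer) or image.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out.astype(image.dtype)


def resize_mask(mask: np.ndarray, dim: int) -> np.ndarray:
    """Nearest-neighbour resize for label/binary masks (no anti-aliasing:
    interpolation would erode 1-px vessels)."""
    mask = np.asarray(mask)
    out = transform.resize(
        mask, (dim, dim), order=0, anti_aliasing=False, preserve_range=True
    )
    return out.astype(mask.dtype)


def restore_full(mask_small: np.ndarray, crop: CropInfo) -> np.ndarray:
    """Place a working-resolution mask back into the original image frame.

    Exact inverse of the geometry of :func:`crop_resize` for masks
    (nearest-neighbour upsampling, padding removal, bounding-box placement).
    """
    mask_small = np.asarray(mask_small)
    if mask_small.shape[0] != crop.target_dim or mask_small.shape[1] != crop.target_dim:
        raise ValueError("mask does not match CropInfo.target_dim")
    pt, pb, pl, pr = crop.extension
    side = crop.cropped_row + pt + pb
    if side != crop.cropped_col + pl + pr:
        raise ValueError("inconsistent CropInfo: padded raster not square")
    sq = resize_mask(mask_small, side)
    crop_arr = sq[pt : pt + crop.cropped_row, pl : pl + crop.cropped_col]
    even_shape = (
        crop.ori_row - int(crop.dim_change_row),
        crop.ori_col - int(crop.dim_change_col),
    )
    full_even = np.zeros(even_shape, dtype=mask_small.dtype)
    r0, c0 = crop.cropped_left
    full_even[r0 : r0 + crop.cropped_row, c0 : c0 + crop.cropped_col] = crop_arr
    full = np.zeros((crop.ori_row, crop.ori_col), dtype=mask_small.dtype)
    full[int(crop.dim_change_row):, int(crop.dim_change_col):] = full_even
    return full


def enhance_clahe(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on the luminance
    channel of a colour fundus image (chroma untouched)."""
    cfg = cfg or PreprocessConfig()
    image = np.asarray(image)
    if image.ndim == 2:
        out = exposure.equalize_adapthist(
            image / 255.0, clip_limit=cfg.clahe_clip,
            kernel_size=max(8, image.shape[0] // cfg.clahe_tile),
        )
        return np.clip(np.rint(out * 255), 0, 255).astype(np.uint8)
    ycc = rgb2ycbcr(image[..., :3])
    y = (ycc[..., 0] - 16.0) / 219.0  # Y' range is [16, 235]
    y_eq = exposure.equalize_adapthist(
        np.clip(y, 0, 1), clip_limit=cfg.clahe_clip,
        kernel_size=max(8, image.shape[0] // cfg.clahe_tile),
    )
    ycc[..., 0] = y_eq * 219.0 + 16.0
    out = ycbcr2rgb(ycc)
    return np.clip(np.rint(out * 255), 0, 255).astype(np.uint8)


def enhance_lce(
    image: np.ndarray, fov: np.ndarray, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Local contrast enhancement: per-channel Gaussian high-pass inside the
    FOV, linearly rescaled and recentred at mid-grey.

    Vessels are locally darker than the surrounding retina, so subtracting a
    large-scale Gaussian background estimate and stretching the residual
    amplifies vessel/background contrast while flattening slow illumination
    gradients.  Background (outside-FOV) pixels are left untouched.
    """
    cfg = cfg or PreprocessConfig()
    image = np.asarray(image)
    fov = np.asarray(fov, dtype=bool)
    chans = image[..., None] if image.ndim == 2 else image[..., :3]
    out = image.copy()
    out_view = out[..., None] if image.ndim == 2 else out[..., :3]
    fov_f = fov.astype(np.float64)
    smooth_fov = ndi.gaussian_filter(fov_f, cfg.lce_sigma)
    for c in range(chans.shape[2]):
        chan = chans[..., c].astype(np.float64)
        # normalized convolution: background estimate from inside-FOV pixels only
        bg = ndi.gaussian_filter(chan * fov_f, cfg.lce_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            bg = np.where(smooth_fov > 1e-9, bg / np.maximum(smooth_fov, 1e-9), 0.0)
        hp = np.where(fov, chan - bg, 0.0)
        max_abs = np.abs(hp[fov]).max() if fov.any() else 0.0
        if max_abs > 1e-6:  # floor: a flat region must stay flat
            enhanced = 127.5 + 127.5 * hp / max_abs
        else:
            enhanced = np.full_like(hp, 127.5)
        out_view[..., c] = np.where(
            fov, np.clip(np.rint(enhanced), 0, 255), chans[..., c]
        ).astype(out.dtype)
    return out


def extend_fov_border(
    image: np.ndarray, fov: np.ndarray, width: int = 20
) -> np.ndarray:
    """Pad artificial retina-like intensities just outside the FOV border.

    Ring by ring, each outside-FOV pixel 8-adjacent to the already-extended
    region is replaced by the mean intensity of its neighbours inside that
    region.  Segmentation models see a smooth continuation instead of a hard
    black edge, which suppresses false-positive vessels along the FOV rim.
    Inside-FOV pixels are returned bit-identical.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    image = np.asarray(image)
    fov = np.asarray(fov, dtype=bool)
    chans = image[..., None].copy() if image.ndim == 2 else image[..., :3].copy()
    work = chans.astype(np.float64)
    region = fov.copy()
    kernel = np.ones((3, 3))
    for _ in range(width):
        ring = ndi.binary_dilation(region, structure=kernel.astype(bool)) & ~region
        if not ring.any():
            break
        counts = ndi.convolve(region.astype(np.float64), kernel, mode="constant")
        for c in range(work.shape[2]):
            sums = ndi.convolve(work[..., c] * region, kernel, mode="constant")
            vals = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
            work[..., c][ring] = vals[ring]
        region |= ring
    out = np.clip(np.rint(work), 0, 255).astype(image.dtype)
    if image.ndim == 2:
        out = out[..., 0]
    elif image.shape[-1] > 3:
        out = np.concatenate([out, image[..., 3:]], axis=-1)
    return out


def sauvola_binarize(
    prob: np.ndarray,
    fov: np.ndarray | None = None,
    cfg: PreprocessConfig | None = None,
) -> np.ndarray:
    """Binarize a soft vessel-probability map with Sauvola's local adaptive
    threshold ``t = m * (1 + k * (s / R - 1))``.

    The threshold tracks the local mean ``m`` and standard deviation ``s``
    (window ``sauvola_window``), so faint but locally salient thin vessels
    survive where a single global threshold would drop them.
    """
    cfg = cfg or PreprocessConfig()
    prob = np.asarray(prob, dtype=np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    w = cfg.sauvola_window
    if w % 2 == 0 or w < 3:
        raise ValueError("sauvola_window must be odd and >= 3")
    if w >= min(prob.shape):
        raise ValueError("sauvola_window must be smaller than the image")
    t = threshold_sauvola(prob, window_size=w, k=cfg.sauvola_k, r=cfg.sauvola_r)
    mask = prob > t
    if fov is not None:
        mask &= np.asarray(fov, dtype=bool)
    return mask
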