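"""Mask and per-image container I/O.

Rasters live in memory as numpy arrays indexed ``(row, col)``, 0-based.
The MATLAB-style container stores pixel index sets as 1-based column-major
linear indices; conversion between the two conventions happens only here,
at the I/O boundary.

Artery/vein masks are exchanged as RGB PNGs with an exact palette:
pure red = artery, pure blue = vein, pure green = crossing (pixels where an
artery and a vein overlap), black = background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import scipy.io

__all__ = [
    "AV_BACKGROUND",
    "AV_ARTERY",
    "AV_VEIN",
    "AV_CROSSING",
    "AV_PALETTE",
    "CropInfo",
    "Annotation",
    "RetaContainer",
    "read_mask",
    "write_mask",
    "read_container",
    "write_container",
    "linear_to_rowcol",
    "rowcol_to_linear",
    "binarize_av",
]

AV_BACKGROUND, AV_ARTERY, AV_VEIN, AV_CROSSING = 0, 1, 2, 3

# label -> RGB; exact colours, zero tolerance, so round-trips are lossless
AV_PALETTE = {
    AV_BACKGROUND: (0, 0, 0),
    AV_ARTERY: (255, 0, 0),
    AV_VEIN: (0, 0, 255),
    AV_CROSSING: (0, 255, 0),
}


def linear_to_rowcol(indices, shape):
    """Convert 1-based column-major linear indices to 0-based (row, col).

    This is the MATLAB ``ind2sub`` convention: index 1 is pixel (0, 0),
    index 2 is (1, 0) — indices run down columns first.
    """
    idx = np.asarray(indices, dtype=np.int64) - 1
    n_rows = shape[0]
    if idx.size and (idx.min() < 0 or idx.max() >= n_rows * shape[1]):
        raise ValueError("linear index out of bounds for shape %r" % (shape,))
    return idx % n_rows, idx // n_rows


def rowcol_to_linear(rows, cols, shape):
    """Inverse of :func:`linear_to_rowcol` (returns 1-based column-major)."""
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    return cols * shape[0] + rows + 1


def binarize_av(labels: np.ndarray) -> np.ndarray:
    """Binary vessel mask from an A/V label raster (any nonbackground label)."""
    return np.asarray(labels) != AV_BACKGROUND


def read_mask(path, kind: str = "binary") -> np.ndarray:
    """Read a mask PNG.

    Parameters
    ----------
    path : path-like
    kind : {"binary", "fov", "av"}
        ``binary``/``fov`` return a boolean raster (any nonzero pixel is
        foreground).  ``av`` decodes the red/blue/green palette or a paletted
        label image with values in {0..3}.
    """
    arr = iio.imread(path)
    if kind in ("binary", "fov"):
        if arr.ndim == 3:
            arr = arr[..., :3].max(axis=2)
        return arr > 0
    if kind != "av":
        raise ValueError("kind must be 'binary', 'fov' or 'av', got %r" % kind)
    if arr.ndim == 2:
        labels = arr.astype(np.uint8)
        bad = np.setdiff1d(np.unique(labels), list(AV_PALETTE))
        if bad.size:
            raise ValueError("label image has values outside {0,1,2,3}: %s" % bad)
        return labels
    rgb = arr[..., :3]
    labels = np.full(rgb.shape[:2], -1, dtype=np.int16)
    for label, colour in AV_PALETTE.items():
        labels[np.all(rgb == np.array(colour, dtype=rgb.dtype), axis=2)] = label
    if (labels < 0).any():
        rows, cols = np.nonzero(labels < 0)
        offending = {tuple(int(v) for v in rgb[r, c]) for r, c in zip(rows[:8], cols[:8])}
        raise ValueError(
            "A/V mask contains colours outside the red/blue/green/black "
            "convention: %s" % sorted(offending)
        )
    return labels.astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a mask losslessly as PNG (inverse of :func:`read_mask`).

    Boolean rasters become 0/255 greyscale; integer label rasters with values
    in {0..3} are encoded with the A/V palette.
    """
    mask = np.asarray(mask)
    path = Path(path)
    if mask.dtype == bool:
        iio.imwrite(path, (mask.astype(np.uint8) * 255), extension=".png")
        return
    labels = np.unique(mask)
    if np.setdiff1d(labels, list(AV_PALETTE)).size:
        raise ValueError("integer mask must only contain labels {0,1,2,3}")
    rgb = np.zeros(mask.shape + (3,), dtype=np.uint8)
    for label, colour in AV_PALETTE.items():
        rgb[mask == label] = colour
    iio.imwrite(path, rgb, extension=".png")


@dataclass
class CropInfo:
    """Cropping/resizing parameters linking a full-frame image to its
    cropped (and padded-to-square) counterpart.

    ``cropped_left``/``cropped_right`` are the inclusive (row, col) corners of
    the crop bounding box in the (possibly dimension-trimmed) original image.
    ``extension`` holds the black padding added on (top, bottom, left, right)
    to make the crop square.  ``dim_change_row``/``col`` record whether the
    first row/column of the odd-sized original was dropped.
    """

    ori_row: int
    ori_col: int
    cropped_row: int
    cropped_col: int
    cropped_left: tuple[int, int]
    cropped_right: tuple[int, int]
    extension: tuple[int, int, int, int] = (0, 0, 0, 0)
    dim_change_row: bool = False
    dim_change_col: bool = False
    target_dim: int = 1024

    def to_dict(self) -> dict:
        return {
            "ori_row": self.ori_row,
            "ori_col": self.ori_col,
            "cropped_row": self.cropped_row,
            "cropped_col": self.cropped_col,
            "cropped_left": list(self.cropped_left),
            "cropped_right": list(self.cropped_right),
            "extension": list(self.extension),
            "dim_change_row": self.dim_change_row,
            "dim_change_col": self.dim_change_col,
            "target_dim": self.target_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CropInfo":
        return cls(
            ori_row=int(d["ori_row"]),
            ori_col=int(d["ori_col"]),
            cropped_row=int(d["cropped_row"]),
            cropped_col=int(d["cropped_col"]),
            cropped_left=tuple(int(v) for v in d["cropped_left"]),
            cropped_right=tuple(int(v) for v in d["cropped_right"]),
            extension=tuple(int(v) for v in d["extension"]),
            dim_change_row=bool(d["dim_change_row"]),
            dim_change_col=bool(d["dim_change_col"]),
            target_dim=int(d.get("target_dim", 1024)),
        )


@dataclass
class Annotation:
    """One pixel-level annotation layer: a label string, its numeric
    category, and the sure/unsure pixel index sets (0-based row/col arrays)."""

    label: str
    category: int
    sure: tuple[np.ndarray, np.ndarray]
    unsure: tuple[np.ndarray, np.ndarray]


@dataclass
class RetaContainer:
    """Per-image container bundling the fundus image, its cropped and
    enhanced versions, FOV masks, crop parameters and annotations."""

    image: np.ndarray
    image_cropped: np.ndarray
    enh_clahe: np.ndarray
    enh_lce: np.ndarray
    fov_full: np.ndarray
    fov_cropped: np.ndarray
    crop: CropInfo
    annotations: list[Annotation] = field(default_factory=list)

    def validate(self) -> None:
        shape = self.image_cropped.shape[:2]
        if shape != (self.crop.cropped_row, self.crop.cropped_col):
            raise ValueError("cropped image shape disagrees with CropInfo")
        for arr, name in (
            (self.enh_clahe, "enh_clahe"),
            (self.enh_lce, "enh_lce"),
            (self.fov_cropped, "fov_cropped"),
        ):
            if arr.shape[:2] != shape:
                raise ValueError("%s shape disagrees with cropped image" % name)
        n = shape[0] * shape[1]
        for ann in self.annotations:
            for rows, cols in (ann.sure, ann.unsure):
                lin = rowcol_to_linear(rows, cols, shape)
                if lin.size and lin.max() > n:
                    raise ValueError("annotation index out of bounds")


_MANDATORY_MAT_FIELDS = (
    "I", "I_cropped", "enhG_cropped", "enhC_cropped",
    "mask_white_o", "mask_white", "dim_change", "pos_data", "annotations",
)


def write_container(container: RetaContainer, path) -> None:
    """Write a container, either as a MATLAB v5 ``.mat`` file (when the path
    ends in ``.mat``) or as the portable JSON + PNG bundle directory."""
    container.validate()
    path = Path(path)
    if path.suffix == ".mat":
        _write_mat(container, path)
    else:
        _write_bundle(container, path)


def read_container(path) -> RetaContainer:
    path = Path(path)
    if path.suffix == ".mat":
        return _read_mat(path)
    return _read_bundle(path)


def _annotation_to_mat(ann: Annotation, shape) -> dict:
    return {
        "label": ann.label,
        "category": float(ann.category),
        "sure_inds": rowcol_to_linear(*ann.sure, shape).astype(np.float64),
        "unsure_inds": rowcol_to_linear(*ann.unsure, shape).astype(np.float64),
    }


def _write_mat(container: RetaContainer, path: Path) -> None:
    c = container.crop
    shape = (c.cropped_row, c.cropped_col)
    mat = {
        "I": container.image,
        "I_cropped": container.image_cropped,
        "enhG_cropped": container.enh_clahe,
        "enhC_cropped": container.enh_lce,
        "mask_white_o": container.fov_full.astype(np.uint8),
        "mask_white": container.fov_cropped.astype(np.uint8),
        "dim_change": {
            "row": float(c.dim_change_row),
            "col": float(c.dim_change_col),
        },
        "pos_data": {
            "ori_row": float(c.ori_row),
            "ori_col": float(c.ori_col),
            "cropped_row": float(c.cropped_row),
            "cropped_col": float(c.cropped_col),
            # stored 1-based (y, x) per the MATLAB convention
            "cropped_left": np.array(c.cropped_left, dtype=np.float64) + 1,
            "cropped_right": np.array(c.cropped_right, dtype=np.float64) + 1,
            "extension": np.array(c.extension, dtype=np.float64),
            "row": float(c.ori_row - int(c.dim_change_row)),
            "col": float(c.ori_col - int(c.dim_change_col)),
        },
        "annotations": np.array(
            [_annotation_to_mat(a, shape) for a in container.annotations],
            dtype=object,
        ),
    }
    scipy.io.savemat(path, {"MAT": mat})


def _scalar(v) -> float:
    return float(np.asarray(v).ravel()[0])


def _read_mat(path: Path) -> RetaContainer:
    raw = scipy.io.loadmat(path, squeeze_me=True, struct_as_record=False)
    if "MAT" not in raw:
        raise ValueError("container mat file must hold a struct named 'MAT'")
    mat = raw["MAT"]
    for name in _MANDATORY_MAT_FIELDS:
        if not hasattr(mat, name):
            raise ValueError("container is missing mandatory field %r" % name)
    dim = mat.dim_change
    pos = mat.pos_data
    crop = CropInfo(
        ori_row=int(_scalar(pos.ori_row)),
        ori_col=int(_scalar(pos.ori_col)),
        cropped_row=int(_scalar(pos.cropped_row)),
        cropped_col=int(_scalar(pos.cropped_col)),
        cropped_left=tuple(int(v) - 1 for v in np.asarray(pos.cropped_left).ravel()),
        cropped_right=tuple(int(v) - 1 for v in np.asarray(pos.cropped_right).ravel()),
        extension=tuple(int(v) for v in np.asarray(pos.extension).ravel()),
        dim_change_row=bool(_scalar(dim.row)),
        dim_change_col=bool(_scalar(dim.col)),
    )
    shape = (crop.cropped_row, crop.cropped_col)
    annotations = []
    anns = np.atleast_1d(mat.annotations)
    for a in anns:
        if isinstance(a, np.ndarray) and a.size == 0:
            continue
        sure = np.asarray(getattr(a, "sure_inds", []), dtype=np.int64).ravel()
        unsure = np.asarray(getattr(a, "unsure_inds", []), dtype=np.int64).ravel()
        annotations.append(
            Annotation(
                label=str(a.label),
                category=int(_scalar(a.category)),
                sure=linear_to_rowcol(sure, shape),
                unsure=linear_to_rowcol(unsure, shape),
            )
        )
    image = np.asarray(mat.I)
    if crop.dim_change_row:
        image = image[1:]
    if crop.dim_change_col:
        image = image[:, 1:]
    container = RetaContainer(
        image=image,
        image_cropped=np.asarray(mat.I_cropped),
        enh_clahe=np.asarray(mat.enhG_cropped),
        enh_lce=np.asarray(mat.enhC_cropped),
        fov_full=np.asarray(mat.mask_white_o) > 0,
        fov_cropped=np.asarray(mat.mask_white) > 0,
        crop=crop,
        annotations=annotations,
    )
    container.validate()
    return container


_BUNDLE_RASTERS = ("image", "image_cropped", "enh_clahe", "enh_lce")


def _write_bundle(container: RetaContainer, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for name in _BUNDLE_RASTERS:
        iio.imwrite(path / f"{name}.png", getattr(container, name), extension=".png")
    write_mask(container.fov_full, path / "fov_full.png")
    write_mask(container.fov_cropped, path / "fov_cropped.png")
    shape = (container.crop.cropped_row, container.crop.cropped_col)
    meta = {
        "crop": container.crop.to_dict(),
        "annotations": [
            {
                "label": a.label,
                "category": a.category,
                "sure_inds": rowcol_to_linear(*a.sure, shape).tolist(),
                "unsure_inds": rowcol_to_linear(*a.unsure, shape).tolist(),
            }
            for a in container.annotations
        ],
    }
    (path / "container.json").write_text(json.dumps(meta, indent=1))


def _read_bundle(path: Path) -> RetaContainer:
    meta_path = path / "container.json"
    if not meta_path.exists():
        raise ValueError("not a container bundle (missing container.json): %s" % path)
    meta = json.loads(meta_path.read_text())
    crop = CropInfo.from_dict(meta["crop"])
    shape = (crop.cropped_row, crop.cropped_col)
    annotations = [
        Annotation(
            label=a["label"],
            category=int(a["category"]),
            sure=linear_to_rowcol(np.asarray(a["sure_inds"], dtype=np.int64), shape),
            unsure=linear_to_rowcol(np.asarray(a["unsure_inds"], dtype=np.int64), shape),
        )
        for a in meta["annotations"]
    ]
    container = RetaContainer(
        image=iio.imread(path / "image.png"),
        image_cropped=iio.imread(path / "image_cropped.png"),
        enh_clahe=iio.imread(path / "enh_clahe.png"),
        enh_lce=iio.imread(path / "enh_lce.png"),
        fov_full=read_mask(path / "fov_full.png", "fov"),
        fov_cropped=read_mask(path / "fov_cropped.png", "fov"),
        crop=crop,
        annotations=annotations,
    )
    container.validate()
    return container
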