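"""Slide-level preprocessing: tissue masks, overlapping patch grids, coverage
filtering, patch extraction and annotation-based patch labels.

Patches are square crops on a regular grid with a fixed fractional overlap
between neighbours (stride = floor(patch_size * (1 - overlap))).  Candidate
patches with less than a minimum fraction of tissue are discarded, so the
downstream feature extraction only sees crops dominated by tissue.

Coordinates are 0-based with a top-left origin; a patch occupies the half-open
square [x, x + size) x [y, y + size) in the pixel space of the extraction
magnification.  Partial tiles at the right/bottom edge are dropped rather than
clamped; the coverage filter would discard most of them anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage import morphology
from skimage.color import rgb2hsv
from skimage.transform import resize

NORMAL = "normal"
ABNORMAL = "abnormal"

#: saturation below which a pixel can never count as tissue, even if Otsu's
#: threshold on a nearly unstained slide falls lower
_MIN_TISSUE_SATURATION = 0.05
#: pixels darker than this value count as tissue regardless of saturation
#: (pen marks, heavy hematoxylin); background is bright and unsaturated
_DARK_VALUE = 0.25


@dataclass
class SlideMeta:
    """Identity and geometry of one whole-slide image."""

    wsi_id: str
    patient_id: str
    label: str
    width: int
    height: int
    magnification: float
    path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"slide {self.wsi_id!r}: dimensions must be positive")
        if not self.magnification or self.magnification <= 0:
            # mirrors excluding slides without a recorded objective power
            raise ValueError(f"slide {self.wsi_id!r}: magnification is required and must be > 0")


@dataclass
class PatchRecord:
    """One candidate patch: grid position, size and tissue coverage."""

    wsi_id: str
    x: int
    y: int
    size: int
    tissue_fraction: float | None = None
    gt_label: str | None = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.x, self.y)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.size / 2.0, self.y + self.size / 2.0)


@dataclass
class TissueMask:
    """Binary mask over a slide at a (usually reduced) scale.

    ``scale`` is mask pixels per slide pixel; mask dimensions are
    ``ceil(slide_dims * scale)``.  Nonzero marks tissue (or, for annotation
    masks, the annotated abnormal region).
    """

    array: np.ndarray
    scale: float
    wsi_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.scale <= 1.0):
            raise ValueError(f"mask scale must be in (0, 1], got {self.scale}")
        self.array = np.asarray(self.array).astype(bool)
        if self.array.ndim != 2:
            raise ValueError("mask array must be 2-D")


@dataclass
class PatchGridConfig:
    """Patching parameters: 1024 px tiles, 30% overlap, 75% minimum tissue
    coverage, at 20x objective power."""

    patch_size: int = 1024
    overlap: float = 0.30
    min_tissue: float = 0.75
    magnification: float = 20.0

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")
        if not (0.0 <= self.min_tissue <= 1.0):
            raise ValueError("min_tissue must be in [0, 1]")
        if self.stride < 1:
            raise ValueError("stride floor(patch_size * (1 - overlap)) must be >= 1")

    @property
    def stride(self) -> int:
        return math.floor(self.patch_size * (1.0 - self.overlap))


def compute_tissue_mask(
    image: np.ndarray,
    downscale: float = 1.0,
    wsi_id: str = "",
    closing_radius: int = 2,
    min_object_area: int = 64,
) -> TissueMask:
    """Segment tissue from background on an RGB slide image.

    Background on a scanned slide is near-white and unsaturated, while stained
    tissue is saturated (eosin pink, hematoxylin purple).  The mask is the
    saturation channel thresholded by Otsu's method (with a small absolute
    floor), plus very dark pixels (pen marks, dense stain); it is cleaned by
    binary closing and removal of small connected components.  An all-background
    image yields a valid all-zero mask.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    if not (0.0 < downscale <= 1.0):
        raise ValueError(f"downscale must be in (0, 1], got {downscale}")

    h, w = image.shape[:2]
    out_shape = (math.ceil(h * downscale), math.ceil(w * downscale))
    img = image.astype(np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    if out_shape != (h, w):
        img = resize(img, out_shape, anti_aliasing=True, preserve_range=True)

    hsv = rgb2hsv(img)
    sat, val = hsv[..., 1], hsv[..., 2]

    if sat.max() < _MIN_TISSUE_SATURATION:
        mask = np.zeros(out_shape, dtype=bool)
    else:
        from skimage.filters import threshold_otsu

        try:
            thr = threshold_otsu(sat)
        except ValueError:  # constant saturation
            thr = _MIN_TISSUE_SATURATION
        mask = sat >= max(thr, _MIN_TISSUE_SATURATION)
    mask |= val <= _DARK_VALUE

    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    if min_object_area > 0:
        mask = morphology.remove_small_objects(mask, max_size=min_object_area - 1)
    return TissueMask(array=mask, scale=downscale, wsi_id=wsi_id)


def generate_patch_grid(
    width: int, height: int, cfg: PatchGridConfig, wsi_id: str = ""
) -> list[PatchRecord]:
    """Lay an overlapping square grid over a ``width x height`` slide.

    Origins run over {0, s, 2s, ...} independently per axis with
    s = floor(patch_size * (1 - overlap)); only fully contained patches are
    emitted, in row-major order (y outer, x inner).  Dimensions smaller than
    the patch size yield an empty list.
    """
    if width < 0 or height < 0:
        raise ValueError("slide dimensions must be non-negative")
    p, s = cfg.patch_size, cfg.stride
    nx = (width - p) // s + 1 if width >= p else 0
    ny = (height - p) // s + 1 if height >= p else 0
    return [
        PatchRecord(wsi_id=wsi_id, x=ix * s, y=iy * s, size=p)
        for iy in range(ny)
        for ix in range(nx)
    ]


def _mask_footprint(mask: TissueMask, patch: PatchRecord) -> tuple[int, int, int, int]:
    """Map a patch footprint into mask coordinates with floor/ceil bounds."""
    sc = mask.scale
    x0 = math.floor(patch.x * sc)
    y0 = math.floor(patch.y * sc)
    x1 = min(math.ceil((patch.x + patch.size) * sc), mask.array.shape[1])
    y1 = min(math.ceil((patch.y + patch.size) * sc), mask.array.shape[0])
    return x0, y0, x1, y1


def _covered_fraction(mask: TissueMask, patch: PatchRecord) -> float:
    x0, y0, x1, y1 = _mask_footprint(mask, patch)
    area = (x1 - x0) * (y1 - y0)
    if area <= 0:
        return 0.0
    return float(mask.array[y0:y1, x0:x1].sum()) / float(area)


def filter_by_tissue(
    patches: Sequence[PatchRecord], mask: TissueMask, min_tissue: float = 0.75
) -> list[PatchRecord]:
    """Keep patches whose tissue coverage is at least ``min_tissue`` (inclusive).

    The tissue fraction is evaluated at mask resolution and recorded on every
    input patch; input order is preserved.
    """
    if not (0.0 <= min_tissue <= 1.0):
        raise ValueError("min_tissue must be in [0, 1]")
    for p in patches:
        if mask.wsi_id and p.wsi_id and mask.wsi_id != p.wsi_id:
            raise ValueError(
                f"mask belongs to slide {mask.wsi_id!r} but patch is from {p.wsi_id!r}"
            )
        p.tissue_fraction = _covered_fraction(mask, p)
    return [p for p in patches if p.tissue_fraction >= min_tissue]


def label_patches_from_annotation(
    patches: Sequence[PatchRecord],
    annotation: TissueMask | None,
    threshold: float = 0.5,
) -> list[PatchRecord]:
    """Assign ground-truth patch labels from a binary abnormal-region mask.

    A patch is labeled abnormal iff at least ``threshold`` of its area (default
    a minimum of 50%) overlaps the annotated region; the boundary is inclusive.
    All remaining patches are labeled normal.
    """
    if annotation is None:
        raise ValueError("an annotation mask is required for patch labeling")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    out = list(patches)
    for p in out:
        frac = _covered_fraction(annotation, p)
        p.gt_label = ABNORMAL if frac >= threshold else NORMAL
    return out


def load_slide_image(meta: SlideMeta, target_magnification: float | None = None) -> np.ndarray:
    """Read a slide image, resampling to the target objective power if needed.

    A native power above the target is downsampled by the ratio; a native power
    below the target is used as-is at its own scale (no upsampling).
    """
    if meta.path is None:
        raise ValueError(f"slide {meta.wsi_id!r} has no file path")
    try:
        with Image.open(meta.path) as im:
            arr = np.asarray(im.convert("RGB"))
    except (FileNotFoundError, OSError) as exc:
        raise OSError(f"cannot read slide image {meta.path!r}: {exc}") from exc
    if target_magnification and meta.magnification > target_magnification:
        factor = target_magnification / meta.magnification
        h = max(1, round(arr.shape[0] * factor))
        w = max(1, round(arr.shape[1] * factor))
        arr = resize(arr, (h, w), anti_aliasing=True, preserve_range=True).astype(np.uint8)
    return arr


def extract_patch_images(
    slide: SlideMeta,
    patches: Sequence[PatchRecord],
    image: np.ndarray | None = None,
) -> Iterator[np.ndarray]:
    """Yield one ``size x size x 3`` crop per record, in order.

    Crops are yielded lazily so memory stays bounded by one patch, not the
    slide.  ``image`` may supply an already loaded array (e.g. a resampled
    level); otherwise the slide file is read.
    """
    if image is None:
        if not patches:
            return
        image = load_slide_image(slide)
    image = np.asarray(image)
    h, w = image.shape[:2]
    for p in patches:
        if p.x < 0 or p.y < 0 or p.x + p.size > w or p.y + p.size > h:
            raise ValueError(
                f"patch ({p.x}, {p.y}) size {p.size} is out of bounds for a {w}x{h} slide"
            )
        yield image[p.y : p.y + p.size, p.x : p.x + p.size]


def read_manifest(path: str | Path) -> list[SlideMeta]:
    """Read a dataset manifest (CSV/TSV with columns wsi_id, patient_id, label,
    path, magnification and optional width/height)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"wsi_id", "patient_id", "label", "path", "magnification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    metas = []
    for row in df.itertuples(index=False):
        p = Path(str(row.path))
        if not p.is_absolute():
            p = path.parent / p
        width = int(getattr(row, "width", 0) or 0)
        height = int(getattr(row, "height", 0) or 0)
        if width <= 0 or height <= 0:
            with Image.open(p) as im:
                width, height = im.size
        metas.append(
            SlideMeta(
                wsi_id=str(row.wsi_id),
                patient_id=str(row.patient_id),
                label=str(row.label),
                width=width,
                height=height,
                magnification=float(row.magnification),
                path=p,
            )
        )
    return metas


def write_patch_table(patches: Sequence[PatchRecord], path: str | Path) -> None:
    """Write patches as TSV (wsi_id, x, y, size, tissue_fraction[, gt_label])."""
    rows = [
        {
            "wsi_id": p.wsi_id,
            "x": p.x,
            "y": p.y,
            "size": p.size,
            "tissue_fraction": p.tissue_fraction,
            **({"gt_label": p.gt_label} if p.gt_label is not None else {}),
        }
        for p in patches
    ]
    cols = ["wsi_id", "x", "y", "size", "tissue_fraction"]
    if any("gt_label" in r for r in rows):
        cols.append("gt_label")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_patch_table(path: str | Path) -> list[PatchRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PatchRecord(
            wsi_id=str(r.wsi_id),
            x=int(r.x),
            y=int(r.y),
            size=int(r.size),
            tissue_fraction=None if pd.isna(r.tissue_fraction) else float(r.tissue_fraction),
            gt_label=str(r.gt_label) if "gt_label" in df.columns and pd.notna(r.gt_label) else None,
        )
        for r in df.itertuples(index=False)
    ]
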