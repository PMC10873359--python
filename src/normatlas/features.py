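"""Patch feature extraction and the on-disk feature store.

The pipeline is feature-agnostic: any function mapping an RGB patch to a fixed
length vector can be registered as an extractor.  Two deterministic built-ins
ship with the package — the 24-dim RGB histogram used for mosaic color
clustering, and a toy seeded random projection of the downsampled grayscale
patch that stands in for a deep embedding in tests.  Deep networks (KimiaNet,
DINO-trained ViT/ResNet50) plug in through the same registry but are not
bundled.

The feature store is a directory of per-slide CSV tables plus a JSON manifest,
so stored features are language-agnostic and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from normatlas.slide_patching import PatchRecord

_TOY_PROJ_SEED = 20240216
_TOY_PROJ_SIDE = 16
_TOY_PROJ_DIM = 16


@dataclass
class FeatureBag:
    """A slide's identity plus its patches' feature vectors — the unit of
    indexing and search."""

    wsi_id: str
    patient_id: str
    label: str
    patches: list[PatchRecord]
    vectors: np.ndarray  # (n_patches, d)
    extractor_id: str

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim == 1:
            self.vectors = self.vectors.reshape(0, 0) if self.vectors.size == 0 else self.vectors
        if self.vectors.ndim != 2:
            n = len(self.patches)
            self.vectors = self.vectors.reshape(n, -1) if n else self.vectors.reshape(0, 0)
        if len(self.patches) != self.vectors.shape[0]:
            raise ValueError(
                f"bag {self.wsi_id!r}: {len(self.patches)} patches but "
                f"{self.vectors.shape[0]} vectors"
            )

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1]) if self.vectors.size else int(self.vectors.shape[1])

    def vector_map(self) -> dict[tuple[int, int], np.ndarray]:
        """Map (x, y) grid keys to feature vectors."""
        return {p.key: self.vectors[i] for i, p in enumerate(self.patches)}

    def subset(self, patches: Sequence[PatchRecord]) -> "FeatureBag":
        """Restrict the bag to the given patches (matched by grid key)."""
        index = {p.key: i for i, p in enumerate(self.patches)}
        rows = []
        for p in patches:
            if p.key not in index:
                raise KeyError(f"bag {self.wsi_id!r} has no vector for patch at {p.key}")
            rows.append(index[p.key])
        d = self.vectors.shape[1] if self.vectors.size else 0
        vectors = self.vectors[rows] if rows else np.empty((0, d))
        return FeatureBag(
            wsi_id=self.wsi_id,
            patient_id=self.patient_id,
            label=self.label,
            patches=list(patches),
            vectors=vectors,
            extractor_id=self.extractor_id,
        )


def _as_uint8_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    if np.issubdtype(image.dtype, np.floating):
        if image.size and image.max() <= 1.0:
            image = image * 255.0
        image = np.clip(image, 0, 255).astype(np.uint8)
    return image


def rgb_histogram(image: np.ndarray, bins_per_channel: int = 8) -> np.ndarray:
    """Concatenated per-channel RGB histogram, L1-normalized per channel.

    Equal-width bins over [0, 256); channels concatenated R, G, B so the
    default 8 bins give a 24-dim vector summing to 3.0.
    """
    if bins_per_channel < 2:
        raise ValueError("bins_per_channel must be >= 2")
    image = _as_uint8_rgb(image)
    n = image.shape[0] * image.shape[1]
    if n == 0:
        raise ValueError("empty image")
    parts = []
    for c in range(3):
        counts, _ = np.histogram(image[..., c], bins=bins_per_channel, range=(0, 256))
        parts.append(counts / n)
    return np.concatenate(parts)


def _toy_projection_matrix() -> np.ndarray:
    rng = np.random.default_rng(_TOY_PROJ_SEED)
    m = rng.standard_normal((_TOY_PROJ_SIDE * _TOY_PROJ_SIDE, _TOY_PROJ_DIM))
    return m / np.sqrt(m.shape[0])


_TOY_MATRIX = _toy_projection_matrix()


def toy_projection(image: np.ndarray) -> np.ndarray:
    """Seeded random projection of the block-averaged grayscale patch.

    A cheap deterministic stand-in embedding: the patch is reduced to a 16x16
    grayscale thumbnail by block averaging, flattened and projected with a
    fixed Gaussian matrix to 16 dims.
    """
    image = _as_uint8_rgb(image).astype(np.float64)
    gray = image.mean(axis=2) / 255.0
    h, w = gray.shape
    ys = np.linspace(0, h, _TOY_PROJ_SIDE + 1).astype(int)
    xs = np.linspace(0, w, _TOY_PROJ_SIDE + 1).astype(int)
    thumb = np.empty((_TOY_PROJ_SIDE, _TOY_PROJ_SIDE))
    for i in range(_TOY_PROJ_SIDE):
        for j in range(_TOY_PROJ_SIDE):
            block = gray[ys[i] : max(ys[i + 1], ys[i] + 1), xs[j] : max(xs[j + 1], xs[j] + 1)]
            thumb[i, j] = block.mean()
    return thumb.ravel() @ _TOY_MATRIX


EXTRACTORS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "rgb_hist8": rgb_histogram,
    "toy_proj": toy_projection,
}


def register_extractor(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a patch-feature extractor (e.g. an adapter around a deep net)."""
    EXTRACTORS[name] = fn


def extract_features(images: Sequence[np.ndarray], extractor: str) -> np.ndarray:
    """Apply a registered extractor to each image; returns an (n, d) array."""
    if extractor not in EXTRACTORS:
        raise KeyError(
            f"unknown extractor {extractor!r}; registered: {sorted(EXTRACTORS)}"
        )
    fn = EXTRACTORS[extractor]
    vectors = [np.asarray(fn(img), dtype=np.float64) for img in images]
    if not vectors:
        return np.empty((0, 0))
    dims = {v.shape for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"extractor {extractor!r} returned mixed dimensions: {dims}")
    return np.stack(vectors)


def write_feature_store(bags: Sequence[FeatureBag], path: str | Path) -> Path:
    """Write bags as a directory store: manifest.json + one CSV per slide.

    Per-slide columns: x, y, size, tissue_fraction, gt_label, f0..f{d-1}.
    All bags must share extractor_id and feature dimension.
    """
    bags = list(bags)
    extractor_ids = {b.extractor_id for b in bags}
    if len(extractor_ids) > 1:
        raise ValueError(f"mixed extractor ids in store: {sorted(extractor_ids)}")
    dims = {b.vectors.shape[1] for b in bags if b.n_patches > 0}
    if len(dims) > 1:
        raise ValueError(f"mixed feature dimensions in store: {sorted(dims)}")
    d = dims.pop() if dims else (bags[0].vectors.shape[1] if bags else 0)

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    slides = []
    for bag in bags:
        fname = f"{bag.wsi_id}.csv"
        cols: dict[str, object] = {
            "x": [p.x for p in bag.patches],
            "y": [p.y for p in bag.patches],
            "size": [p.size for p in bag.patches],
            "tissue_fraction": [p.tissue_fraction for p in bag.patches],
            "gt_label": [p.gt_label for p in bag.patches],
        }
        for j in range(d):
            cols[f"f{j}"] = bag.vectors[:, j] if bag.n_patches else []
        pd.DataFrame(cols).to_csv(path / fname, index=False)
        slides.append(
            {
                "wsi_id": bag.wsi_id,
                "patient_id": bag.patient_id,
                "label": bag.label,
                "file": fname,
                "n_patches": bag.n_patches,
            }
        )
    manifest = {
        "extractor_id": bags[0].extractor_id if bags else "",
        "dim": int(d),
        "slides": slides,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_feature_store(path: str | Path) -> list[FeatureBag]:
    """Read a feature store written by :func:`write_feature_store`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"feature store manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    d = int(manifest["dim"])
    bags = []
    for entry in manifest["slides"]:
        df = pd.read_csv(path / entry["file"])
        fcols = [f"f{j}" for j in range(d)]
        if any(c not in df.columns for c in fcols):
            raise ValueError(
                f"slide {entry['wsi_id']!r}: feature columns do not match manifest dim {d}"
            )
        patches = [
            PatchRecord(
                wsi_id=entry["wsi_id"],
                x=int(r.x),
                y=int(r.y),
                size=int(r.size),
                tissue_fraction=None if pd.isna(r.tissue_fraction) else float(r.tissue_fraction),
                gt_label=None if pd.isna(r.gt_label) else str(r.gt_label),
            )
            for r in df.itertuples(index=False)
        ]
        vectors = df[fcols].to_numpy(dtype=np.float64) if len(df) else np.empty((0, d))
        bags.append(
            FeatureBag(
                wsi_id=entry["wsi_id"],
                patient_id=entry["patient_id"],
                label=entry["label"],
                patches=patches,
                vectors=vectors,
                extractor_id=manifest["extractor_id"],
            )
        )
    return bags
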