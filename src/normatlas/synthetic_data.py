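"""Seeded synthetic inputs at two levels.

Feature level: Gaussian-mixture feature bags emulating the statistical premise
of the normal atlas — normal tissue occupies a few dense modes in feature
space, disease patches form a displaced mode, and nominally normal slides carry
a small fraction (default 5%) of far-outlier "artifact" vectors standing in for
tissue folds, pen marks and out-of-focus areas.  Every patch carries its true
normal/abnormal flag, so pruning and retrieval can be audited exactly.

Slide level: small textured RGB "slides" on a white background with smooth
tissue blobs, a planted lesion region of controlled relative area, and exact
ground-truth masks, to exercise the patching/masking/labeling path end to end.

All generators are pure functions of their config (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from normatlas.features import FeatureBag
from normatlas.slide_patching import ABNORMAL, NORMAL, PatchRecord, SlideMeta

_MAX_CENTER_TRIES = 500
_GRID_STRIDE = 716
_GRID_PATCH = 1024


@dataclass(frozen=True)
class ClassSpec:
    label: str
    n_wsis: int
    abnormal_fraction: float

    def __post_init__(self) -> None:
        if self.n_wsis < 1:
            raise ValueError("n_wsis must be >= 1")
        if not (0.0 <= self.abnormal_fraction <= 1.0):
            raise ValueError("abnormal_fraction must be in [0, 1]")


def _default_classes() -> tuple[ClassSpec, ...]:
    return (
        ClassSpec("normal", 20, 0.0),
        ClassSpec("lesion_a", 20, 0.6),
        ClassSpec("lesion_b", 20, 0.6),
    )


@dataclass
class FeatureSimConfig:
    """Conditions of the synthetic feature study: 16-dim features, three normal
    modes, an abnormal mode displaced 6 sigma per disease class, 5% artifact
    contamination in normal slides, three classes of 20 slides with 60 patches
    each.

    ``abnormal_spread`` scales the abnormal mode's standard deviation relative
    to the normal modes (default 3): abnormal morphology is heterogeneous, so
    its feature cloud is diffuse where normal tissue is dense — the property
    that makes it an anomaly to density- and isolation-based detectors alike.
    """

    d: int = 16
    n_normal_modes: int = 3
    sigma: float = 1.0
    delta: float = 6.0
    abnormal_spread: float = 3.0
    contamination: float = 0.05
    n_artifact_modes: int = 2
    classes: tuple[ClassSpec, ...] = field(default_factory=_default_classes)
    patches_per_wsi: int = 60
    wsis_per_patient: int = 1
    n_atlas_wsis: int = 20
    seed: int = 0
    extractor_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination < 0.5):
            raise ValueError("contamination must be in [0, 0.5)")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.abnormal_spread <= 0:
            raise ValueError("abnormal_spread must be > 0")
        if min(self.d, self.n_normal_modes, self.patches_per_wsi, self.wsis_per_patient) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_artifact_modes < 1:
            raise ValueError("n_artifact_modes must be >= 1")
        self.classes = tuple(
            c if isinstance(c, ClassSpec) else ClassSpec(*c) for c in self.classes
        )


def _normal_mode_centers(cfg: FeatureSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Place normal-mode centers compactly with pairwise separation >= 3 sigma.

    Normal histology is dense: the modes sit on a circle in a random 2-plane
    (random rotation, seeded) with adjacent modes exactly 3 sigma apart, the
    minimal separation the model assumes.  In one dimension the modes fall on
    a line at 3 sigma spacing.
    """
    m, d, s = cfg.n_normal_modes, cfg.d, cfg.sigma
    if m == 1:
        return rng.normal(0.0, s, size=(1, d))
    if d == 1:
        return (np.arange(m, dtype=float) * 3.0 * s).reshape(m, 1)
    plane, _ = np.linalg.qr(rng.normal(size=(d, 2)))
    radius = 1.5 * s / math.sin(math.pi / m)
    angles = 2.0 * math.pi * np.arange(m) / m + rng.uniform(0.0, 2.0 * math.pi)
    coords = np.stack([radius * np.cos(angles), radius * np.sin(angles)], axis=1)
    return coords @ plane.T


def _draw_centers(cfg: FeatureSimConfig, rng: np.random.Generator):
    """Draw normal-mode centers, one displaced abnormal center per disease
    class (delta sigma from its anchor mode, no closer to any other mode), and
    shared artifact-mode centers at least 10 sigma from every normal mode.

    Artifacts (pen ink, tissue folds, out-of-focus areas) look alike across
    slides, so artifact vectors cluster around a few modes common to the whole
    dataset rather than scattering independently.
    """
    m, d, s = cfg.n_normal_modes, cfg.d, cfg.sigma
    centers = _normal_mode_centers(cfg, rng)
    disease = [c for c in cfg.classes if c.abnormal_fraction > 0]
    abnormal: dict[str, np.ndarray] = {}
    for idx, spec in enumerate(disease):
        anchor = centers[idx % m]
        for _ in range(_MAX_CENTER_TRIES):
            u = rng.normal(size=d)
            u /= np.linalg.norm(u)
            cand = anchor + cfg.delta * s * u
            # the anchor must remain the nearest normal mode
            if all(
                np.linalg.norm(cand - centers[j]) >= cfg.delta * s - 1e-9
                for j in range(m)
            ):
                abnormal[spec.label] = cand
                break
        else:
            raise ValueError(
                f"cannot displace an abnormal mode by {cfg.delta} sigma away from "
                f"{m} normal modes in {d} dimensions"
            )
    artifact_centers = np.empty((cfg.n_artifact_modes, d))
    far_points = list(centers) + list(abnormal.values())
    for i in range(cfg.n_artifact_modes):
        for _ in range(_MAX_CENTER_TRIES):
            anchor = centers[rng.integers(0, m)]
            u = rng.normal(size=d)
            u /= np.linalg.norm(u)
            cand = anchor + 16.0 * s * u
            if min(np.linalg.norm(cand - p) for p in far_points) >= 10.0 * s:
                artifact_centers[i] = cand
                far_points.append(cand)
                break
        else:
            raise ValueError(
                f"cannot place artifact modes >= 10 sigma from all other modes "
                f"in {d} dimensions"
            )
    return centers, abnormal, artifact_centers


def _sample_normal(centers: np.ndarray, sigma: float, n: int, rng: np.random.Generator):
    modes = rng.integers(0, centers.shape[0], size=n)
    return centers[modes] + rng.normal(0.0, sigma, size=(n, centers.shape[1]))


def _sample_artifacts(
    artifact_centers: np.ndarray,
    normal_centers: np.ndarray,
    sigma: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Artifact vectors around the shared artifact modes, each a far outlier
    (>= 10 sigma from every normal mode)."""
    d = artifact_centers.shape[1]
    out = np.empty((n, d))
    for i in range(n):
        for _ in range(_MAX_CENTER_TRIES):
            mode = artifact_centers[rng.integers(0, artifact_centers.shape[0])]
            v = mode + rng.normal(0.0, sigma, size=d)
            if min(np.linalg.norm(v - c) for c in normal_centers) >= 10.0 * sigma:
                out[i] = v
                break
        else:
            raise ValueError("could not place an artifact vector >= 10 sigma out")
    return out


def _grid_records(wsi_id: str, n: int) -> list[PatchRecord]:
    gw = max(1, math.ceil(math.sqrt(n)))
    return [
        PatchRecord(
            wsi_id=wsi_id,
            x=(j % gw) * _GRID_STRIDE,
            y=(j // gw) * _GRID_STRIDE,
            size=_GRID_PATCH,
            tissue_fraction=1.0,
        )
        for j in range(n)
    ]


def _make_bag(
    wsi_id: str,
    patient_id: str,
    label: str,
    vectors: np.ndarray,
    gt: Sequence[str],
    extractor_id: str,
) -> FeatureBag:
    patches = _grid_records(wsi_id, vectors.shape[0])
    for p, g in zip(patches, gt):
        p.gt_label = g
    return FeatureBag(
        wsi_id=wsi_id,
        patient_id=patient_id,
        label=label,
        patches=patches,
        vectors=vectors,
        extractor_id=extractor_id,
    )


def simulate_feature_dataset(
    cfg: FeatureSimConfig,
) -> tuple[list[FeatureBag], list[FeatureBag]]:
    """Generate (atlas-training normal bags, labeled evaluation bags).

    Normal slides (training bags and "abnormal_fraction = 0" classes) draw
    patches from the normal mixture with ``round(contamination * n)`` artifact
    outliers; disease slides draw ``round(abnormal_fraction * n)`` patches from
    their class's displaced abnormal mode and the rest from the normal mixture.
    Every patch carries its true normal/abnormal flag and synthetic grid
    coordinates; patient ids group ``wsis_per_patient`` consecutive slides.
    """
    rng = np.random.default_rng(cfg.seed)
    centers, abnormal_centers, artifact_centers = _draw_centers(cfg, rng)
    n = cfg.patches_per_wsi
    n_art = round(cfg.contamination * n)

    def normal_slide_vectors() -> tuple[np.ndarray, list[str]]:
        clean = _sample_normal(centers, cfg.sigma, n - n_art, rng)
        gt = [NORMAL] * (n - n_art)
        if n_art:
            art = _sample_artifacts(artifact_centers, centers, cfg.sigma, n_art, rng)
            return np.vstack([clean, art]), gt + [ABNORMAL] * n_art
        return clean, gt

    normal_bags = [
        _make_bag(
            f"atlas{i:03d}", f"atlaspt{i // cfg.wsis_per_patient:03d}", NORMAL,
            *normal_slide_vectors(), cfg.extractor_id,
        )
        for i in range(cfg.n_atlas_wsis)
    ]

    labeled_bags: list[FeatureBag] = []
    patient_counter = 0
    slide_counter = 0
    for spec in cfg.classes:
        n_abn = round(spec.abnormal_fraction * n)
        for i in range(spec.n_wsis):
            if i % cfg.wsis_per_patient == 0:
                patient_counter += 1
            wsi_id = f"wsi{slide_counter:03d}"
            slide_counter += 1
            if n_abn == 0:
                vectors, gt = normal_slide_vectors()
            else:
                abn = abnormal_centers[spec.label] + rng.normal(
                    0.0, cfg.sigma * cfg.abnormal_spread, size=(n_abn, cfg.d)
                )
                nor = _sample_normal(centers, cfg.sigma, n - n_abn, rng)
                vectors = np.vstack([abn, nor])
                gt = [ABNORMAL] * n_abn + [NORMAL] * (n - n_abn)
            labeled_bags.append(
                _make_bag(
                    wsi_id, f"pt{patient_counter:03d}", spec.label,
                    vectors, gt, cfg.extractor_id,
                )
            )
    return normal_bags, labeled_bags


def simulate_holdout_vectors(
    cfg: FeatureSimConfig, n_normal: int = 1000, n_abnormal: int = 1000
) -> tuple[np.ndarray, list[str]]:
    """Held-out labeled vectors from the same mixture as the dataset with the
    same seed-derived centers, for patch-level atlas validation."""
    rng_centers = np.random.default_rng(cfg.seed)
    centers, abnormal_centers, _ = _draw_centers(cfg, rng_centers)
    rng = np.random.default_rng([cfg.seed, 1])
    X_norm = _sample_normal(centers, cfg.sigma, n_normal, rng)
    parts, labels = [X_norm], [NORMAL] * n_normal
    if n_abnormal:
        if not abnormal_centers:
            raise ValueError("no disease class defined; cannot draw abnormal vectors")
        keys = sorted(abnormal_centers)
        picks = rng.integers(0, len(keys), size=n_abnormal)
        abn = np.stack([abnormal_centers[keys[p]] for p in picks]) + rng.normal(
            0.0, cfg.sigma * cfg.abnormal_spread, size=(n_abnormal, cfg.d)
        )
        parts.append(abn)
        labels += [ABNORMAL] * n_abnormal
    return np.vstack(parts), labels


@dataclass
class SlideSimConfig:
    width: int = 3072
    height: int = 3072
    lesion_fraction: float = 0.3
    base_color: tuple[int, int, int] = (226, 160, 190)  # eosin-like pink
    lesion_color: tuple[int, int, int] = (148, 92, 164)  # denser purple
    noise_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("slide dimensions must be >= 1")
        if not (0.0 <= self.lesion_fraction <= 1.0):
            raise ValueError("lesion_fraction must be in [0, 1]")
        if self.lesion_fraction > 0.9:
            raise ValueError("lesion_fraction > 0.9 gives degenerate geometry")


def _smooth_blob_mask(cfg: SlideSimConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    # shape the blob at 1/8 scale; the upsampled result is the exact truth
    hs, ws = max(1, h // 8), max(1, w // 8)
    yy, xx = np.ogrid[0:hs, 0:ws]
    mask = np.zeros((hs, ws), dtype=bool)
    r0 = 0.22 * min(hs, ws)
    for _ in range(3):
        cy = rng.uniform(0.3 * hs, 0.7 * hs)
        cx = rng.uniform(0.3 * ws, 0.7 * ws)
        r = rng.uniform(0.8 * r0, 1.2 * r0)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    smooth = gaussian_filter(mask.astype(np.float32), sigma=min(hs, ws) / 50.0)
    up = resize(smooth, (h, w), order=1, anti_aliasing=False, preserve_range=True)
    return up > 0.5


def _correlated_noise(shape, scale: float, rng: np.random.Generator) -> np.ndarray:
    # draw at quarter resolution and upsample: spatially correlated and cheap
    small = tuple(max(1, s // 4) for s in shape[:2]) + tuple(shape[2:])
    raw = rng.normal(0.0, 1.0, size=small).astype(np.float32)
    smooth = gaussian_filter(raw, sigma=(1.0, 1.0) + (0.0,) * (raw.ndim - 2))
    sd = float(smooth.std()) or 1.0
    up = resize(smooth, shape, order=1, anti_aliasing=False, preserve_range=True)
    return (up / sd * scale).astype(np.float32)


def simulate_slide(cfg: SlideSimConfig):
    """Generate one textured slide image with exact ground-truth masks.

    Returns ``(image, tissue_truth, lesion_truth, meta)``; masks are boolean
    arrays at full resolution (scale 1.0).  The lesion is a disk-shaped region
    inside the tissue whose area relative to the tissue is tuned by bisection
    to ``lesion_fraction`` within about 5%.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    tissue = _smooth_blob_mask(cfg, rng)
    tissue_area = int(tissue.sum())
    if tissue_area == 0:
        raise ValueError("degenerate simulation: no tissue generated")

    lesion = np.zeros_like(tissue)
    if cfg.lesion_fraction > 0:
        ys, xs = np.nonzero(tissue)
        pick = rng.integers(0, len(ys))
        cy, cx = float(ys[pick]), float(xs[pick])
        yy, xx = np.ogrid[0:h, 0:w]
        dist2 = ((yy - cy) ** 2 + (xx - cx) ** 2).astype(np.float32)
        # the radius whose disk covers exactly the target fraction of tissue
        r2 = float(np.quantile(dist2[tissue], cfg.lesion_fraction))
        lesion = tissue & (dist2 <= r2)

    img = np.full((h, w, 3), 244.0, dtype=np.float32)
    img += _correlated_noise((h, w, 3), 2.0, rng)
    tissue_tex = _correlated_noise((h, w, 3), cfg.noise_scale, rng)
    lesion_tex = _correlated_noise((h, w, 3), cfg.noise_scale, rng)
    for c in range(3):
        chan = img[..., c]
        chan[tissue] = cfg.base_color[c] + tissue_tex[..., c][tissue]
        chan[lesion] = cfg.lesion_color[c] + lesion_tex[..., c][lesion]
    image = np.clip(img, 0, 255).astype(np.uint8)

    meta = SlideMeta(
        wsi_id=f"sim{cfg.seed:04d}",
        patient_id=f"simpt{cfg.seed:04d}",
        label="synthetic",
        width=w,
        height=h,
        magnification=20.0,
    )
    return image, tissue, lesion, meta
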