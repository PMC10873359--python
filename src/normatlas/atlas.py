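"""The normal atlas: a one-class classifier fitted on patch features from
known-normal slides, used to label unseen patch features normal (inlier) or
abnormal (outlier) and to prune mosaics.

Training data are assumed contaminated with a small fraction of non-normal
material (artifacts, tissue folds, pen marks, out-of-focus areas); the
one-class SVM's nu parameter bounds that fraction (default 5%), while Isolation
Forest infers its decision offset automatically.  Features are z-scored before
fitting — RBF kernels are scale-sensitive and embedding dimensions vary in
magnitude — and the normalization state travels with the atlas.

One atlas is fitted per organ/site on the pooled patch vectors of all normal
slides; it records the extractor id and refuses features from any other
extractor or dimension.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import IsolationForest
from sklearn.svm import OneClassSVM

from normatlas.features import FeatureBag
from normatlas.mosaic import MosaicSelection
from normatlas.slide_patching import ABNORMAL, NORMAL

METHOD_OCSVM = "ocsvm"
METHOD_IFOREST = "isolation_forest"


@dataclass
class AtlasConfig:
    method: str = METHOD_OCSVM
    nu: float = 0.05
    n_trees: int = 100
    max_samples: int = 256
    kernel_scale: str | float = "scale"
    standardize: bool = True
    seed: int = 0
    min_train: int = 50

    def __post_init__(self) -> None:
        if self.method not in (METHOD_OCSVM, METHOD_IFOREST):
            raise ValueError(
                f"method must be {METHOD_OCSVM!r} or {METHOD_IFOREST!r}, got {self.method!r}"
            )
        if not (0.0 < self.nu < 1.0):
            raise ValueError("nu must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class NormalAtlas:
    """A fitted one-class classifier plus its feature-normalization state."""

    config: AtlasConfig
    extractor_id: str
    feature_dim: int
    mean: np.ndarray | None
    scale: np.ndarray | None
    model: object
    n_training_vectors: int
    training_flagged_fraction: float

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            return X
        return (X - self.mean) / self.scale

    def classify(self, vectors: np.ndarray) -> list[str]:
        return classify_features(self, vectors)

    def save(self, path: str | Path) -> None:
        """Serialize the atlas (config + normalization + model) to one file."""
        payload = {
            "format": "normatlas.atlas/1",
            "config": asdict(self.config),
            "extractor_id": self.extractor_id,
            "feature_dim": self.feature_dim,
            "mean": self.mean,
            "scale": self.scale,
            "model": self.model,
            "n_training_vectors": self.n_training_vectors,
            "training_flagged_fraction": self.training_flagged_fraction,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path, expect_dim: int | None = None) -> "NormalAtlas":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != "normatlas.atlas/1":
            raise ValueError(f"{path}: not a normal-atlas file")
        if expect_dim is not None and payload["feature_dim"] != expect_dim:
            raise ValueError(
                f"atlas feature dim {payload['feature_dim']} does not match expected {expect_dim}"
            )
        return cls(
            config=AtlasConfig(**payload["config"]),
            extractor_id=payload["extractor_id"],
            feature_dim=payload["feature_dim"],
            mean=payload["mean"],
            scale=payload["scale"],
            model=payload["model"],
            n_training_vectors=payload["n_training_vectors"],
            training_flagged_fraction=payload["training_flagged_fraction"],
        )


def fit_atlas(normal_bags: Sequence[FeatureBag], cfg: AtlasConfig | None = None) -> NormalAtlas:
    """Fit a normal atlas on the pooled patch features of normal slides.

    No cleaning of the pool is attempted: the contamination assumption is
    handled by the one-class method itself (nu for the OC-SVM, the automatic
    offset for Isolation Forest).
    """
    cfg = cfg or AtlasConfig()
    bags = list(normal_bags)
    if not bags:
        raise ValueError("no training bags")
    extractor_ids = {b.extractor_id for b in bags}
    if len(extractor_ids) > 1:
        raise ValueError(f"mixed extractor ids in training bags: {sorted(extractor_ids)}")
    X = np.vstack([b.vectors for b in bags if b.n_patches > 0])
    if X.shape[0] < cfg.min_train:
        raise ValueError(
            f"need at least {cfg.min_train} training vectors, got {X.shape[0]}"
        )
    if not np.isfinite(X).all():
        raise ValueError("training features contain non-finite values")

    mean = scale = None
    Xs = X
    if cfg.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        Xs = (X - mean) / scale

    if cfg.method == METHOD_OCSVM:
        model = OneClassSVM(kernel="rbf", nu=cfg.nu, gamma=cfg.kernel_scale)
    else:
        model = IsolationForest(
            n_estimators=cfg.n_trees,
            max_samples=min(cfg.max_samples, Xs.shape[0]),
            contamination="auto",
            random_state=cfg.seed,
        )
    model.fit(Xs)
    flagged = float(np.mean(model.predict(Xs) == -1))
    return NormalAtlas(
        config=cfg,
        extractor_id=bags[0].extractor_id,
        feature_dim=X.shape[1],
        mean=mean,
        scale=scale,
        model=model,
        n_training_vectors=int(X.shape[0]),
        training_flagged_fraction=flagged,
    )


def classify_features(atlas: NormalAtlas, vectors: np.ndarray | Sequence[np.ndarray]) -> list[str]:
    """Label each feature vector normal (inlier) or abnormal (outlier)."""
    X = np.asarray(vectors, dtype=np.float64)
    if X.size == 0:
        return []
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != atlas.feature_dim:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match atlas dim {atlas.feature_dim}"
        )
    pred = atlas.model.predict(atlas._normalize(X))
    return [NORMAL if p == 1 else ABNORMAL for p in pred]


def prune_selection(
    selection: MosaicSelection, bag: FeatureBag, atlas: NormalAtlas
) -> MosaicSelection:
    """Remove mosaic patches the atlas labels normal.

    Only the mosaic-selected patches are classified.  The result may be empty:
    a slide whose entire mosaic looks normal is itself predicted normal
    downstream without any search.
    """
    if bag.extractor_id != atlas.extractor_id:
        raise ValueError(
            f"bag extractor {bag.extractor_id!r} does not match atlas "
            f"extractor {atlas.extractor_id!r}"
        )
    vec_of = bag.vector_map()
    missing = [p.key for p in selection.selected if p.key not in vec_of]
    if missing:
        raise KeyError(f"bag {bag.wsi_id!r} lacks vectors for selected patches {missing}")
    if not selection.selected:
        return MosaicSelection(
            wsi_id=selection.wsi_id,
            selected=[],
            cluster_of=dict(selection.cluster_of),
            pruned_flags={},
        )
    X = np.stack([vec_of[p.key] for p in selection.selected])
    labels = classify_features(atlas, X)
    flags = {p.key: lab for p, lab in zip(selection.selected, labels)}
    kept = [p for p, lab in zip(selection.selected, labels) if lab == ABNORMAL]
    return MosaicSelection(
        wsi_id=selection.wsi_id,
        selected=kept,
        cluster_of=dict(selection.cluster_of),
        pruned_flags=flags,
    )
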