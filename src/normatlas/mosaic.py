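"""Yottixel-style mosaic selection.

A slide's candidate patches are grouped into (by default) 9 clusters on their
RGB-histogram features, and 15% of each cluster is then picked in a spatially
homogeneous manner, so the mosaic covers every color-distinct tissue morphology
while spreading picks across the slide.  Spatial homogeneity is realized as a
second k-means on patch centers within each color cluster, keeping the member
nearest each spatial centroid.

Both clustering stages run on patches in canonical (y, x) order with a fixed
seed, which makes the selection deterministic and invariant to the order in
which patches are supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from normatlas.slide_patching import PatchRecord


@dataclass
class MosaicConfig:
    n_color_clusters: int = 9
    selection_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_color_clusters < 1:
            raise ValueError("n_color_clusters must be >= 1")
        if not (0.0 < self.selection_fraction <= 1.0):
            raise ValueError("selection_fraction must be in (0, 1]")


@dataclass
class MosaicSelection:
    """The subset of a slide's patches chosen as its mosaic."""

    wsi_id: str
    selected: list[PatchRecord]
    cluster_of: dict[tuple[int, int], int]
    pruned_flags: dict[tuple[int, int], str] | None = None


def _kmeans(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, tol=1e-4)
    return km.fit_predict(X)


def build_mosaic(
    patches: Sequence[PatchRecord],
    color_features: Sequence[np.ndarray] | np.ndarray,
    cfg: MosaicConfig,
) -> MosaicSelection:
    """Cluster patches by color feature, then pick a spatially spread fraction
    of each cluster.

    Per cluster of size n_c, m_c = max(1, ceil(selection_fraction * n_c))
    patches are chosen: k-means with k = m_c on patch centers, taking the
    member nearest each spatial centroid (ties broken by smaller (y, x)).
    """
    patches = list(patches)
    X = np.asarray(color_features, dtype=np.float64)
    if not patches:
        raise ValueError("cannot build a mosaic from an empty patch list")
    if X.ndim != 2 or X.shape[0] != len(patches):
        raise ValueError(
            f"{len(patches)} patches but color feature array of shape {X.shape}"
        )

    n = len(patches)
    # canonical order: clustering results must not depend on input order
    order = sorted(range(n), key=lambda i: (patches[i].y, patches[i].x))
    patches_sorted = [patches[i] for i in order]
    X = X[order]

    k = min(cfg.n_color_clusters, n)
    labels = _kmeans(X, k, cfg.seed) if k > 1 else np.zeros(n, dtype=int)

    selected: list[PatchRecord] = []
    for c in range(k):
        members = [i for i in range(n) if labels[i] == c]
        n_c = len(members)
        if n_c == 0:
            continue
        m_c = max(1, math.ceil(cfg.selection_fraction * n_c))
        if m_c >= n_c:
            selected.extend(patches_sorted[i] for i in members)
            continue
        centers = np.array([patches_sorted[i].center for i in members])
        sub = _kmeans(centers, m_c, cfg.seed) if m_c > 1 else np.zeros(n_c, dtype=int)
        centroids = np.array(
            [centers[sub == s].mean(axis=0) for s in range(m_c)]
        )
        for s in range(m_c):
            group = [j for j in range(n_c) if sub[j] == s]
            if not group:
                continue
            best = min(
                group,
                key=lambda j: (
                    float(np.linalg.norm(centers[j] - centroids[s])),
                    patches_sorted[members[j]].y,
                    patches_sorted[members[j]].x,
                ),
            )
            selected.append(patches_sorted[members[best]])

    selected.sort(key=lambda p: (p.y, p.x))
    cluster_of = {patches_sorted[i].key: int(labels[i]) for i in range(n)}
    return MosaicSelection(
        wsi_id=patches[0].wsi_id, selected=selected, cluster_of=cluster_of
    )


def mosaic_fraction(selection: MosaicSelection, total: int) -> float:
    """Fraction of a slide's patches retained by the mosaic."""
    if total <= 0:
        raise ValueError("total patch count must be positive")
    if total < len(selection.selected):
        raise ValueError("total patch count smaller than the selection")
    return len(selection.selected) / total
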