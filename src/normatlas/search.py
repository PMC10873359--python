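"""Indexing and search over feature bags.

A slide is indexed as the bag of feature vectors of its mosaic patches
(optionally atlas-pruned).  Slide-to-slide distance is the median of minimum
one-to-one Euclidean distances: for each query patch, the distance to its
nearest target patch; the median of those minima is the bag distance.  The
direction is query -> target (asymmetric); a symmetrized variant is available
behind a flag.  Retrieval is a linear scan with ascending distance, ties broken
lexicographically by wsi_id, and top-1/3/5 consensus labels.

A query slide whose mosaic was entirely pruned as normal is predicted "normal"
directly, with no distance computation; indexed slides left without vectors are
excluded from distance ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from normatlas.features import FeatureBag
from normatlas.slide_patching import NORMAL

DEFAULT_K = (1, 3, 5)


@dataclass
class WSIIndex:
    """Stored feature bags of the known slides, plus provenance."""

    entries: list[FeatureBag]
    extractor_id: str
    provenance: dict = field(default_factory=dict)

    @property
    def patients(self) -> set[str]:
        return {e.patient_id for e in self.entries}


@dataclass
class RetrievalResult:
    query_wsi_id: str
    neighbors: list[tuple[str, str, float]]  # (wsi_id, label, distance), ascending
    predictions: dict[int, str] = field(default_factory=dict)


def build_index(bags: Sequence[FeatureBag], provenance: dict | None = None) -> WSIIndex:
    """Assemble an index, validating unique ids and a uniform feature space.

    Bags with zero patches are kept as entries (their slide is known and
    labeled) but carry no vectors and never participate in distance ranking.
    """
    bags = list(bags)
    if not bags:
        raise ValueError("cannot build an empty index")
    ids = [b.wsi_id for b in bags]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate wsi_ids in index")
    extractor_ids = {b.extractor_id for b in bags}
    if len(extractor_ids) > 1:
        raise ValueError(f"mixed extractor ids in index: {sorted(extractor_ids)}")
    dims = {b.vectors.shape[1] for b in bags if b.n_patches > 0}
    if len(dims) > 1:
        raise ValueError(f"mixed feature dimensions in index: {sorted(dims)}")
    return WSIIndex(entries=bags, extractor_id=bags[0].extractor_id, provenance=provenance or {})


def _bag_vectors(bag: FeatureBag | np.ndarray) -> np.ndarray:
    X = bag.vectors if isinstance(bag, FeatureBag) else np.asarray(bag, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("bag distance requires a non-empty 2-D vector set")
    return X


def wsi_distance(
    query: FeatureBag | np.ndarray,
    target: FeatureBag | np.ndarray,
    symmetric: bool = False,
) -> float:
    """Median of minimum one-to-one Euclidean distances, query -> target.

    With ``symmetric=True`` the mean of both directions is returned instead.
    The even-count median is the arithmetic mean of the two central values.
    """
    Q, T = _bag_vectors(query), _bag_vectors(target)
    if Q.shape[1] != T.shape[1]:
        raise ValueError(f"dimension mismatch: {Q.shape[1]} vs {T.shape[1]}")
    D = cdist(Q, T)
    d_qt = float(np.median(D.min(axis=1)))
    if not symmetric:
        return d_qt
    d_tq = float(np.median(D.min(axis=0)))
    return 0.5 * (d_qt + d_tq)


def query_index(
    index: WSIIndex,
    query: FeatureBag,
    exclude_patient: str | None = None,
    k_values: Iterable[int] = DEFAULT_K,
    symmetric: bool = False,
) -> RetrievalResult:
    """Rank all eligible indexed slides by bag distance to the query.

    Entries from ``exclude_patient`` (leave-one-patient-out) and the query
    slide itself are excluded, as are vectorless entries.  Ties in distance
    break lexicographically by wsi_id.
    """
    eligible = [
        e
        for e in index.entries
        if e.wsi_id != query.wsi_id
        and (exclude_patient is None or e.patient_id != exclude_patient)
        and e.n_patches > 0
    ]
    if not eligible:
        raise ValueError("no eligible index entries for this query")
    ranked = sorted(
        (
            (wsi_distance(query, e, symmetric=symmetric), e.wsi_id, e.label)
            for e in eligible
        ),
        key=lambda t: (t[0], t[1]),
    )
    neighbors = [(wsi_id, label, dist) for dist, wsi_id, label in ranked]
    result = RetrievalResult(query_wsi_id=query.wsi_id, neighbors=neighbors)
    result.predictions = {k: predict_label(result, k) for k in k_values}
    return result


def predict_label(result: RetrievalResult | None, k: int) -> str:
    """Top-k consensus label.

    ``result=None`` encodes a query whose mosaic was entirely pruned as normal;
    such slides are labeled "normal" without any search.  Otherwise the
    majority label among the top-k neighbors wins; ties break in favour of the
    label whose best representative ranks highest (smallest distance).  With
    fewer than k neighbors the vote runs over what is available, with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if result is None:
        return NORMAL
    if not result.neighbors:
        raise ValueError("retrieval result has no neighbors")
    if len(result.neighbors) < k:
        warnings.warn(
            f"query {result.query_wsi_id!r}: only {len(result.neighbors)} neighbors "
            f"available for top-{k} vote",
            stacklevel=2,
        )
    top = result.neighbors[:k]
    counts: dict[str, int] = {}
    best_rank: dict[str, int] = {}
    for rank, (_, label, _) in enumerate(top):
        counts[label] = counts.get(label, 0) + 1
        best_rank.setdefault(label, rank)
    max_count = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == max_count]
    return min(tied, key=lambda lab: best_rank[lab])
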