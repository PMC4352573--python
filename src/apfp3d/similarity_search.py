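"""City-block-distance similarity search with a bit-sum hash index.

The city-block (Manhattan, L1) distance between two fingerprints obeys

    |sum(a) - sum(b)| <= CBD(a, b),

so a database sorted by total bit sum can be searched for nearest
neighbors by expanding outward from the query's sum position and
terminating once the sum-difference lower bound exceeds the current
k-th best distance.  This is the minimal data structure realizing the
"sum of bit values as hash function" principle and gives exact (not
approximate) k-NN and range queries.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .fingerprints import Fingerprint

__all__ = [
    "cbd",
    "tanimoto_scalar",
    "SumIndex",
    "RankedHits",
    "build_index",
    "knn",
    "range_query",
    "SumHashNeighbors",
]


def _check_compatible(a: Fingerprint, b: Fingerprint) -> None:
    if a.scheme != b.scheme:
        raise ValueError(f"scheme mismatch: {a.scheme!r} vs {b.scheme!r}")
    if len(a) != len(b):
        raise ValueError("fingerprint length mismatch")


def cbd(a: Fingerprint, b: Fingerprint) -> float:
    """City-block (L1) distance between two same-scheme fingerprints."""
    _check_compatible(a, b)
    return float(np.abs(np.asarray(a.values, dtype=float)
                        - np.asarray(b.values, dtype=float)).sum())


def tanimoto_scalar(a: Fingerprint, b: Fingerprint) -> float:
    """Scalar Tanimoto: sum(min) / sum(max); 1.0 for two all-zero vectors."""
    _check_compatible(a, b)
    av = np.asarray(a.values, dtype=float)
    bv = np.asarray(b.values, dtype=float)
    if np.any(av < 0) or np.any(bv < 0):
        raise ValueError("tanimoto_scalar requires non-negative values")
    denom = np.maximum(av, bv).sum()
    if denom == 0.0:
        return 1.0
    return float(np.minimum(av, bv).sum() / denom)


@dataclass
class SumIndex:
    """Fingerprint database sorted ascending by total bit sum."""

    vectors: np.ndarray          # (n, length), sorted rows
    ids: list                    # parallel mol_ids
    sums: np.ndarray             # per-row sums, non-decreasing
    scheme: str

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class RankedHits:
    """Ordered (mol_id, distance) results of a similarity query."""

    hits: list = field(default_factory=list)   # [(mol_id, distance), ...]
    query_id: str = ""
    scheme: str = ""

    def __len__(self) -> int:
        return len(self.hits)

    def ids(self) -> list:
        return [h[0] for h in self.hits]

    def distances(self) -> list:
        return [h[1] for h in self.hits]


def build_index(fps: Sequence[Fingerprint]) -> SumIndex:
    """Build a :class:`SumIndex` from same-scheme fingerprints.

    Entries are ordered by (sum, mol_id) so the index is independent
    of insertion order; duplicate mol_ids are rejected.
    """
    fps = list(fps)
    if not fps:
        raise ValueError("cannot index an empty fingerprint set")
    scheme = fps[0].scheme
    for fp in fps:
        if fp.scheme != scheme:
            raise ValueError(f"mixed schemes: {scheme!r} vs {fp.scheme!r}")
    ids = [fp.mol_id for fp in fps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mol_ids in index input")
    vectors = np.asarray([fp.values for fp in fps], dtype=float)
    sums = vectors.sum(axis=1)
    order = sorted(range(len(fps)), key=lambda i: (sums[i], ids[i]))
    return SumIndex(vectors=vectors[order], ids=[ids[i] for i in order],
                    sums=sums[order], scheme=scheme)


def _scan(index: SumIndex, query: Fingerprint, visit):
    """Expand outward from the query's sum position.

    ``visit(bound, row) -> keep_going`` is called for entries in order
    of increasing sum-difference bound; scanning a side stops when
    ``visit`` returns False for it.
    """
    qv = np.asarray(query.values, dtype=float)
    qsum = qv.sum()
    n = len(index)
    right = int(np.searchsorted(index.sums, qsum))
    left = right - 1
    go_left = go_right = True
    while (go_left and left >= 0) or (go_right and right < n):
        bl = qsum - index.sums[left] if (go_left and left >= 0) else np.inf
        br = index.sums[right] - qsum if (go_right and right < n) else np.inf
        if bl <= br:
            if not visit(bl, left):
                go_left = False
            left -= 1
        else:
            if not visit(br, right):
                go_right = False
            right += 1


def knn(index: SumIndex, query: Fingerprint, k: int) -> RankedHits:
    """Exact k nearest neighbors by CBD, using the sum-bound pruning.

    Returns all entries when ``k`` exceeds the index size.  Ties at
    the k-th distance are broken by ascending mol_id.
    """
    if query.scheme != index.scheme:
        raise ValueError(f"scheme mismatch: {query.scheme!r} vs {index.scheme!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    qv = np.asarray(query.values, dtype=float)
    heap: list = []  # max-heap on distance via negation
    candidates: list = []

    def visit(bound, row):
        kth = -heap[0] if len(heap) >= k else np.inf
        if bound > kth:
            return False
        d = float(np.abs(index.vectors[row] - qv).sum())
        candidates.append((d, index.ids[row]))
        if len(heap) < k:
            heapq.heappush(heap, -d)
        elif d < -heap[0]:
            heapq.heapreplace(heap, -d)
        return True

    _scan(index, query, visit)
    candidates.sort()
    return RankedHits(hits=[(mol_id, d) for d, mol_id in candidates[:k]],
                      query_id=query.mol_id, scheme=index.scheme)


def range_query(index: SumIndex, query: Fingerprint,
                max_cbd: float) -> RankedHits:
    """All entries with CBD <= ``max_cbd``, sorted by (distance, mol_id)."""
    if query.scheme != index.scheme:
        raise ValueError(f"scheme mismatch: {query.scheme!r} vs {index.scheme!r}")
    if max_cbd < 0:
        raise ValueError("max_cbd must be >= 0")
    qv = np.asarray(query.values, dtype=float)
    found: list = []

    def visit(bound, row):
        if bound > max_cbd:
            return False
        d = float(np.abs(index.vectors[row] - qv).sum())
        if d <= max_cbd:
            found.append((d, index.ids[row]))
        return True

    _scan(index, query, visit)
    found.sort()
    return RankedHits(hits=[(mol_id, d) for d, mol_id in found],
                      query_id=query.mol_id, scheme=index.scheme)


class SumHashNeighbors(BaseEstimator):
    """Exact CBD nearest-neighbor search over a fingerprint database.

    A scikit-learn-style estimator: ``fit`` ingests the database and
    builds the sum-sorted index; ``kneighbors`` and
    ``radius_neighbors`` answer queries with the sum-bound pruning.

    Parameters
    ----------
    n_neighbors : int, default=5
        Default k for :meth:`kneighbors`.

    Attributes
    ----------
    index_ : SumIndex
        The fitted sum-sorted database.
    scheme_ : str
        Scheme of the indexed fingerprints.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X: Sequence[Fingerprint], y=None):
        self.index_ = build_index(X)
        self.scheme_ = self.index_.scheme
        return self

    def kneighbors(self, query: Fingerprint,
                   n_neighbors: Optional[int] = None) -> RankedHits:
        return knn(self.index_, query, n_neighbors or self.n_neighbors)

    def radius_neighbors(self, query: Fingerprint, radius: float) -> RankedHits:
        return range_query(self.index_, query, radius)
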