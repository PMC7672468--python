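"""SOM-guided 2D embedding of events (EmbedSOM-style).

Unlike t-SNE or UMAP, which optimize a global layout, this embedding uses
the trained SOM as a guiding manifold: each event is placed in the 2D grid
coordinate system using only its k nearest codebook vectors. Events are
therefore embedded completely independently of each other — the
computation is embarrassingly parallel, runs directly on data shards, and
its total cost is linear in the number of events.

Placement of one event x works in three steps:

1. Find the k nearest codebook vectors (exact, via the spatial index).
2. Convert their data-space distances to nonnegative scores with a
   truncated-Gaussian decay of the rank-scaled distance r_i = d_i / d_ref,
   where d_ref is the distance of the (k+1)-th neighbor:
   s_i ∝ (exp(−r_i²/2σ²) − exp(−1/2σ²))₊^adjust, normalized to sum 1.
   The truncation pins the score to 0 exactly at the (k+1)-th neighbor,
   so the k-th used score approaches 0 as the neighborhood boundary is
   reached — the neighborhood is effectively compact and the embedding
   varies continuously as points cross neighbor-set boundaries.
3. For every pair (a, b) of scored neighbors, project x onto the line
   through W_a and W_b in data space; the embedded point e should project
   to the same relative position on the segment between the nodes' grid
   coordinates. Minimizing the score-weighted squared deviations over all
   pairs is a 2×2 linear solve per event.

If the selected neighbors are (near-)collinear in grid space the normal
matrix is singular; those events fall back to the score-weighted average
of the neighbors' grid coordinates and are counted in the returned
``Embedding.n_fallback``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import neighbors
from .fcs import SampleMatrix
from .som import Codebook

__all__ = ["EmbeddingConfig", "Embedding", "embed", "embed_distributed"]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Per-event embedding parameters.

    k: number of nearest codebook vectors used per event (2 ≤ k ≤ m).
    smooth: Gaussian bandwidth σ of the score decay, in units of the
        rank-scaled distance (larger → flatter scores → smoother, more
        averaged placement; the default keeps the placement local to the
        best matching unit).
    adjust: exponent sharpening (>1) or flattening (<1) the score falloff.
    """

    k: int = 16
    smooth: float = 0.3
    adjust: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be ≥ 2")
        if self.smooth <= 0:
            raise ValueError("smooth must be positive")
        if self.adjust <= 0:
            raise ValueError("adjust must be positive")


@dataclass
class Embedding:
    """n × 2 event coordinates in grid units (same origin as node_coords)."""

    coords: np.ndarray
    n_fallback: int = 0

    def to_csv(self, path, event_ids: Sequence | None = None) -> None:
        import pandas as pd

        ids = np.arange(len(self.coords)) if event_ids is None else event_ids
        pd.DataFrame({"event_id": ids,
                      "x": self.coords[:, 0],
                      "y": self.coords[:, 1]}).to_csv(path, index=False)


def _scores(dist: np.ndarray, ref: np.ndarray, config: EmbeddingConfig
            ) -> np.ndarray:
    """Rank-scaled truncated-Gaussian scores, normalized per event.

    ``ref`` is the per-event scale (distance of the neighbor just outside
    the used neighborhood, or of the farthest node when k = m).
    """
    ref = ref[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ref > 0, dist / ref, 0.0)
    inv2s2 = 1.0 / (2.0 * config.smooth**2)
    base = np.exp(-(r**2) * inv2s2) - np.exp(-inv2s2)
    s = np.clip(base, 0.0, None) ** config.adjust
    tot = s.sum(axis=1, keepdims=True)
    uniform = tot[:, 0] <= 0
    if np.any(uniform):
        s[uniform] = 1.0
        tot = s.sum(axis=1, keepdims=True)
    return s / tot


# relative determinant threshold below which the pairwise system is treated
# as degenerate (all scored neighbors collinear in grid space)
_DEGENERATE_DET = 1e-12


def embed(data: SampleMatrix | np.ndarray, codebook: Codebook,
          config: EmbeddingConfig | None = None,
          index_kind: str = "auto", chunk: int = 8192,
          dtype=np.float64) -> Embedding:
    """Embed events into the 2D grid coordinate system.

    Deterministic and per-event independent: permuting the input rows
    permutes the output rows and changes nothing else. ``dtype=np.float32``
    speeds up the neighbor scan and pair algebra on huge inputs.
    """
    config = config or EmbeddingConfig()
    X = data.values if isinstance(data, SampleMatrix) else np.atleast_2d(np.asarray(data))
    W = np.asarray(codebook.weights, dtype=dtype)
    m = codebook.m
    if X.shape[1] != codebook.d:
        raise ValueError(f"data dimension {X.shape[1]} != codebook {codebook.d}")
    if config.k > m:
        raise ValueError(f"k={config.k} exceeds codebook size m={m}")
    k = config.k
    grid_xy = codebook.grid.node_coords  # m × 2

    index = neighbors.build_index(W, kind=index_kind)

    # pairwise tables over nodes, reused by every chunk
    wdot = W @ W.T  # m × m
    wsq = np.diag(wdot).copy()

    ia, ib = np.triu_indices(k, k=1)  # pair slots within the k-neighborhood
    n = X.shape[0]
    out = np.empty((n, 2))
    n_fallback = 0

    kq = min(k + 1, m)  # one extra neighbor supplies the score scale
    for s0 in range(0, n, chunk):
        xc = np.asarray(X[s0 : s0 + chunk], dtype=dtype)
        nc = xc.shape[0]
        idx, dist = neighbors.knearest(index, xc, kq, dtype=dtype)
        ref = dist[:, -1]
        idx, dist = idx[:, :k], dist[:, :k]
        sc = _scores(dist, ref, config)

        xdotw = xc @ W.T  # nc × m; x·W_i for all nodes (cheap vs gathers)
        na, nb = idx[:, ia], idx[:, ib]  # nc × P node ids per pair
        # t = (x−W_a)·(W_b−W_a) / ‖W_b−W_a‖², all from precomputed dots
        xa = np.take_along_axis(xdotw, na, axis=1)
        xb = np.take_along_axis(xdotw, nb, axis=1)
        wab = wdot[na, nb]
        lsq = wsq[na] + wsq[nb] - 2.0 * wab  # ‖W_b−W_a‖²
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(lsq > 0, (xb - xa - wab + wsq[na]) / lsq, 0.5)

        ga, gb = grid_xy[na], grid_xy[nb]  # nc × P × 2
        u = gb - ga
        glen = np.sqrt(np.einsum("ijk,ijk->ij", u, u))
        with np.errstate(invalid="ignore", divide="ignore"):
            uhat = np.where(glen[..., None] > 0, u / glen[..., None], 0.0)
        # residual per pair, in grid units: û·e − (û·g_a + t·‖u‖)
        c = np.einsum("ijk,ijk->ij", uhat, ga) + t * glen
        w = sc[:, ia] * sc[:, ib]  # pair weights
        w = np.where(glen > 0, w, 0.0)  # identical grid nodes carry no info

        ux, uy = uhat[..., 0], uhat[..., 1]
        a11 = np.einsum("ij,ij->i", w * ux, ux)
        a12 = np.einsum("ij,ij->i", w * ux, uy)
        a22 = np.einsum("ij,ij->i", w * uy, uy)
        b1 = np.einsum("ij,ij->i", w * ux, c)
        b2 = np.einsum("ij,ij->i", w * uy, c)

        det = a11 * a22 - a12 * a12
        scale = (a11 + a22) ** 2
        ok = det > _DEGENERATE_DET * np.maximum(scale, 1e-300)

        ex = np.empty(nc)
        ey = np.empty(nc)
        with np.errstate(invalid="ignore", divide="ignore"):
            ex = (a22 * b1 - a12 * b2) / det
            ey = (a11 * b2 - a12 * b1) / det
        if not np.all(ok):
            # collinear (or zero-weight) neighborhoods: score-weighted
            # average of the neighbors' grid positions
            bad = ~ok
            gsel = grid_xy[idx[bad]]  # nb × k × 2
            fallback = np.einsum("ij,ijk->ik", sc[bad], gsel)
            ex[bad] = fallback[:, 0]
            ey[bad] = fallback[:, 1]
            n_fallback += int(bad.sum())
        out[s0 : s0 + nc, 0] = ex
        out[s0 : s0 + nc, 1] = ey

    if n_fallback:
        warnings.warn(
            f"{n_fallback} events had grid-collinear neighborhoods and were "
            "placed at their score-weighted node average",
            RuntimeWarning,
            stacklevel=2,
        )
    return Embedding(coords=out, n_fallback=n_fallback)


def embed_distributed(shards: Sequence[SampleMatrix | np.ndarray],
                      codebook: Codebook,
                      config: EmbeddingConfig | None = None,
                      index_kind: str = "auto",
                      n_workers: int = 1,
                      dtype=np.float64) -> list[Embedding]:
    """Embed each shard independently; concatenation equals a serial embed.

    The per-event computation is deterministic, so the shard split has no
    effect on any coordinate (bit-exact agreement).
    """
    from .sharding import distributed_map

    return distributed_map(
        lambda shard: embed(shard, codebook, config, index_kind=index_kind,
                            dtype=dtype),
        shards,
        n_workers=n_workers,
    )
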