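"""Batch self-organizing map training in matrix form.

The SOM is a single-layer network of m = xdim × ydim nodes on a 2D grid;
each node carries a weight vector (one row of the m × d "codebook" W).
Training fits the codebook to the data while preserving grid topology, so
nearest-node classification of events doubles as a FlowSOM-style clustering.

Two trainers are provided:

* :func:`train_batch_som` — the production path. Each epoch assigns every
  event to its nearest node (one pass over the data, accelerated by a
  spatial index rebuilt per epoch since the codebook is constant within an
  epoch), accumulates per-node sums S and counts c, and applies the
  neighborhood-smoothed update

      W_i ← (Σ_k Ĥ_ik S_k) / (Σ_k Ĥ_ik c_k),

  where Ĥ is the row-normalized kernel of pairwise grid distances. With
  Ĥ = I this is exactly one Lloyd k-means step. The per-node sums are plain
  additions, so the computation splits over data shards and reduces
  exactly — the basis of the distributed implementation in
  :mod:`cytosom.sharding`.

* :func:`train_online_som` — the classical per-event Kohonen rule
  W_i ← W_i + α(t)·h(t)⊙(x − W_i), kept as a slow reference for
  verification, not as a production path.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from . import neighbors
from .fcs import SampleMatrix

__all__ = [
    "SOMGrid",
    "Codebook",
    "TrainingSchedule",
    "NeighborhoodMatrix",
    "initialize_codebook",
    "neighborhood_matrix",
    "assign_nearest",
    "partial_update",
    "PartialUpdate",
    "apply_update",
    "batch_epoch",
    "train_batch_som",
    "train_online_som",
    "quantization_error",
]

Kernel = Literal["gaussian", "bubble"]


@dataclass(frozen=True)
class SOMGrid:
    """Rectangular 2D node lattice; node index = i·ydim + j for (i, j)."""

    xdim: int
    ydim: int

    def __post_init__(self) -> None:
        if self.xdim < 1 or self.ydim < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def m(self) -> int:
        return self.xdim * self.ydim

    @property
    def node_coords(self) -> np.ndarray:
        """m × 2 integer lattice positions, row-major over (i, j)."""
        i, j = np.divmod(np.arange(self.m), self.ydim)
        return np.column_stack([i, j]).astype(np.float64)

    def grid_distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between node positions (m × m)."""
        c = self.node_coords
        return cdist(c, c)


@dataclass
class Codebook:
    """The m × d node-weight matrix W on an explicit grid topology."""

    weights: np.ndarray
    grid: SOMGrid
    trained_epochs: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape[0] != self.grid.m:
            raise ValueError(
                f"{self.weights.shape[0]} weight rows for a "
                f"{self.grid.xdim}×{self.grid.ydim} grid"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("codebook weights must be finite")

    @property
    def m(self) -> int:
        return self.weights.shape[0]

    @property
    def d(self) -> int:
        return self.weights.shape[1]

    def to_csv(self, path: str | Path, columns: list[str] | None = None) -> None:
        """Export as CSV: grid_x, grid_y, then one column per weight dim."""
        import pandas as pd

        names = columns or [f"w{i}" for i in range(self.d)]
        coords = self.grid.node_coords.astype(int)
        df = pd.DataFrame(self.weights, columns=names)
        df.insert(0, "grid_y", coords[:, 1])
        df.insert(0, "grid_x", coords[:, 0])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Codebook":
        import pandas as pd

        df = pd.read_csv(path)
        xdim = int(df["grid_x"].max()) + 1
        ydim = int(df["grid_y"].max()) + 1
        w = df.drop(columns=["grid_x", "grid_y"]).to_numpy(dtype=np.float64)
        return cls(weights=w, grid=SOMGrid(xdim, ydim))


@dataclass(frozen=True)
class TrainingSchedule:
    """Epoch count plus neighborhood-radius decay (and α decay, online only).

    The radius is in grid units and decays linearly from ``radius_start``
    (default max(xdim, ydim)/2) to ``radius_end`` across epochs; Gaussian
    kernel by default, with a hard-cutoff "bubble" kernel as an option.
    """

    epochs: int = 30
    radius_start: float | None = None
    radius_end: float = 1.0
    kernel: Kernel = "gaussian"
    alpha_start: float = 0.1
    alpha_end: float = 0.01

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")
        if self.radius_start is not None and self.radius_start < self.radius_end:
            raise ValueError("radius_start must be ≥ radius_end")
        if self.radius_end <= 0:
            raise ValueError("radius_end must be positive")

    def start_radius(self, grid: SOMGrid) -> float:
        if self.radius_start is not None:
            return self.radius_start
        return max(max(grid.xdim, grid.ydim) / 2.0, self.radius_end)

    def radius_at(self, epoch: int, grid: SOMGrid) -> float:
        """Radius for 0-based ``epoch``, linear decay start → end."""
        r0 = self.start_radius(grid)
        if self.epochs == 1:
            return r0
        f = epoch / (self.epochs - 1)
        return r0 + (self.radius_end - r0) * f


@dataclass(frozen=True)
class NeighborhoodMatrix:
    """Row-stochastic grid-distance kernel Ĥ used to smooth node updates."""

    values: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("neighborhood matrix rows must sum to 1")


def neighborhood_matrix(grid: SOMGrid, radius: float, kernel: Kernel = "gaussian"
                        ) -> NeighborhoodMatrix:
    """Kernel of pairwise grid distances, rows normalized to sum 1.

    Gaussian: exp(−(d/r)²/2); bubble: indicator d ≤ r. A bubble kernel with
    r < 1 (or the r → 0 limit) degenerates to the identity, which turns a
    batch epoch into a plain Lloyd k-means step.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    D = grid.grid_distances()
    if kernel == "gaussian":
        H = np.exp(-0.5 * (D / radius) ** 2)
    elif kernel == "bubble":
        H = (D <= radius).astype(np.float64)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    H /= H.sum(axis=1, keepdims=True)
    return NeighborhoodMatrix(values=H, radius=radius)


def identity_neighborhood(grid: SOMGrid) -> NeighborhoodMatrix:
    """Ĥ = I: batch epochs degenerate to k-means Lloyd steps."""
    return NeighborhoodMatrix(values=np.eye(grid.m), radius=0.0)


def _data_values(data: SampleMatrix | np.ndarray) -> np.ndarray:
    if isinstance(data, SampleMatrix):
        return data.values
    return np.atleast_2d(np.asarray(data))


def initialize_codebook(data: SampleMatrix | np.ndarray, grid: SOMGrid,
                        seed: int | np.random.Generator = 0) -> Codebook:
    """Random-sampling initialization: m rows drawn from the data.

    Sampling is without replacement when the data has at least m rows (so a
    dataset of exactly m rows yields a permutation of itself), with
    replacement otherwise. Deterministic for a fixed seed.
    """
    X = _data_values(data)
    if X.shape[0] == 0:
        raise ValueError("cannot initialize a codebook from empty data")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    replace = X.shape[0] < grid.m
    rows = rng.choice(X.shape[0], size=grid.m, replace=replace)
    return Codebook(weights=np.asarray(X[rows], dtype=np.float64), grid=grid)


def assign_nearest(data: SampleMatrix | np.ndarray, codebook: Codebook,
                   index: neighbors.NeighborIndex | str = "auto",
                   dtype=np.float64) -> np.ndarray:
    """Label each event with its nearest node (lowest index among ties).

    ``dtype=np.float32`` trades the last bits of distance precision for a
    much faster scan on very large event matrices.
    """
    X = _data_values(data)
    if X.shape[1] != codebook.d:
        raise ValueError(
            f"data dimension {X.shape[1]} != codebook dimension {codebook.d}"
        )
    if isinstance(index, str):
        index = neighbors.build_index(codebook.weights, kind=index)
    return neighbors.assign_labels(X, index, dtype=dtype)


@dataclass
class PartialUpdate:
    """Per-node event sums and counts from one data shard.

    The combine operation is plain elementwise addition, which is what makes
    the distributed reduce exact (up to float summation order).
    """

    sums: np.ndarray  # m × d
    counts: np.ndarray  # m

    def __add__(self, other: "PartialUpdate") -> "PartialUpdate":
        return PartialUpdate(self.sums + other.sums, self.counts + other.counts)

    @classmethod
    def zero(cls, m: int, d: int) -> "PartialUpdate":
        return cls(np.zeros((m, d)), np.zeros(m))

    @property
    def nbytes(self) -> int:
        return self.sums.nbytes + self.counts.nbytes


def partial_update(X: np.ndarray, labels: np.ndarray, m: int,
                   chunk: int = 1 << 16) -> PartialUpdate:
    """Accumulate per-node sums/counts with compensated chunk summation.

    Events are reduced in fixed-size chunks via bincount; chunk results are
    Kahan-added into the accumulator so the result stays accurate (and
    shard-count-invariant to ~1e-15 relative) even for very long shards.
    """
    X = np.atleast_2d(X)
    n, d = X.shape
    sums = np.zeros((m, d))
    comp = np.zeros((m, d))
    counts = np.zeros(m)
    for s in range(0, n, chunk):
        lab = labels[s : s + chunk]
        xc = np.asarray(X[s : s + chunk], dtype=np.float64)
        part = np.zeros((m, d))
        for j in range(d):
            part[:, j] = np.bincount(lab, weights=xc[:, j], minlength=m)
        # Kahan step: sums += part with running compensation
        y = part - comp
        t = sums + y
        comp = (t - sums) - y
        sums = t
        counts += np.bincount(lab, minlength=m)
    return PartialUpdate(sums=sums, counts=counts)


def apply_update(codebook: Codebook, update: PartialUpdate,
                 H: NeighborhoodMatrix, literal_update: bool = False) -> Codebook:
    """Master-side smoothing: W_i ← (Ĥ·S)_i / (Ĥ·c)_i.

    Nodes whose smoothed count is zero (possible with a bubble kernel of
    sub-unit radius and empty clusters; impossible with a Gaussian kernel on
    nonempty data) keep their previous weights.

    ``literal_update=True`` evaluates W ← Ĥ·N·X without the count
    normalization — the un-normalized matrix form, for comparison only; it
    is not scale-correct when cluster sizes differ.
    """
    num = H.values @ update.sums
    if literal_update:
        return Codebook(weights=num, grid=codebook.grid,
                        trained_epochs=codebook.trained_epochs + 1)
    den = H.values @ update.counts
    ok = den > 0
    w = np.array(codebook.weights, copy=True)
    w[ok] = num[ok] / den[ok, None]
    return Codebook(weights=w, grid=codebook.grid,
                    trained_epochs=codebook.trained_epochs + 1)


def batch_epoch(data: SampleMatrix | np.ndarray, codebook: Codebook,
                H: NeighborhoodMatrix, index_kind: str = "auto",
                literal_update: bool = False) -> Codebook:
    """One full-data batch update of the codebook."""
    X = _data_values(data)
    labels = assign_nearest(X, codebook, index=index_kind)
    upd = partial_update(X, labels, codebook.m)
    return apply_update(codebook, upd, H, literal_update=literal_update)


def train_batch_som(data: SampleMatrix | np.ndarray, grid: SOMGrid,
                    schedule: TrainingSchedule | None = None,
                    seed: int = 0, index_kind: str = "auto",
                    n_shards: int = 1,
                    codebook: Codebook | None = None,
                    dtype=np.float64) -> Codebook:
    """Train a batch SOM for ``schedule.epochs`` passes over the data.

    ``n_shards`` splits the data into contiguous row blocks whose partial
    updates are reduced by addition before the master-side smoothing — the
    in-process equivalent of the distributed loop, and the result is
    independent of the shard count up to float summation order (~1e-15
    relative). Pass ``codebook`` to resume training instead of initializing.
    """
    schedule = schedule or TrainingSchedule()
    X = _data_values(data)
    if codebook is None:
        codebook = initialize_codebook(X, grid, seed)
    bounds = np.linspace(0, X.shape[0], n_shards + 1).astype(np.intp)
    for epoch in range(schedule.epochs):
        H = neighborhood_matrix(grid, schedule.radius_at(epoch, grid),
                                schedule.kernel)
        index = neighbors.build_index(codebook.weights, kind=index_kind)
        total = PartialUpdate.zero(codebook.m, codebook.d)
        for a, b in zip(bounds[:-1], bounds[1:]):
            labels = neighbors.assign_labels(X[a:b], index, dtype=dtype)
            total = total + partial_update(X[a:b], labels, codebook.m)
        codebook = apply_update(codebook, total, H)
    return codebook


def train_online_som(data: SampleMatrix | np.ndarray, grid: SOMGrid,
                     schedule: TrainingSchedule | None = None,
                     seed: int = 0, steps: int | None = None) -> Codebook:
    """Classical online Kohonen training (reference implementation).

    Each step draws one random event x, finds its best matching unit, and
    moves every node toward x proportionally to the neighborhood kernel
    centered on the BMU: W ← W + α(t)·h(t)⊙(x − W). α and the radius decay
    linearly over the steps. Slow by design; used to cross-check the batch
    trainer, not to train at scale.
    """
    schedule = schedule or TrainingSchedule()
    X = np.asarray(_data_values(data), dtype=np.float64)
    if X.shape[0] == 0:
        raise ValueError("cannot train on empty data")
    rng = np.random.default_rng(seed)
    codebook = initialize_codebook(X, grid, rng)
    W = codebook.weights
    n_steps = steps if steps is not None else schedule.epochs * X.shape[0]
    coords = grid.node_coords
    r0 = schedule.start_radius(grid)
    for t in range(n_steps):
        f = t / max(n_steps - 1, 1)
        alpha = schedule.alpha_start + (schedule.alpha_end - schedule.alpha_start) * f
        radius = r0 + (schedule.radius_end - r0) * f
        x = X[rng.integers(X.shape[0])]
        bmu = int(np.argmin(np.einsum("ij,ij->i", W - x, W - x)))
        gd = np.linalg.norm(coords - coords[bmu], axis=1)
        if schedule.kernel == "bubble":
            h = (gd <= radius).astype(np.float64)
        else:
            h = np.exp(-0.5 * (gd / radius) ** 2)
        W += alpha * h[:, None] * (x - W)
    return Codebook(weights=W, grid=grid, trained_epochs=schedule.epochs)


def quantization_error(data: SampleMatrix | np.ndarray, codebook: Codebook,
                       index_kind: str = "auto") -> float:
    """Mean Euclidean distance from each event to its nearest node."""
    X = _data_values(data)
    if X.shape[0] == 0:
        raise ValueError("quantization error of empty data is undefined")
    index = neighbors.build_index(codebook.weights, kind=index_kind)
    labels = neighbors.assign_labels(X, index)
    diff = np.asarray(X, dtype=np.float64) - codebook.weights[labels]
    return float(np.mean(np.sqrt(np.einsum("ij,ij->i", diff, diff))))
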