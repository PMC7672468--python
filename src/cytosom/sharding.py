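"""Balanced dataset slicing and MapReduce-style distributed training.

A multi-file cytometry dataset is treated as one long concatenated event
stream. :func:`plan_slices` cuts that stream into per-worker shards of
near-equal size; each shard is described by just four integers (first/last
file, first/last event index), so distributing the plan is essentially
free, and each worker extracts only its own byte range from the FCS files.

Materialized shards can be persisted to a shard store (a plain directory of
binary containers plus a JSON manifest) so repeated analyses skip the
slicing step.

The training loop itself is expressed through two high-order operations,
:func:`distributed_map` and :func:`distributed_mapreduce`, with a strict
contract: workers share no mutable state and only function results cross
the worker boundary. Per epoch the payload per worker is one codebook-sized
partial update — O(m·d) numbers regardless of shard size — which is what
lets the same loop scale from a laptop to a cluster fabric.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence, TypeVar

import numpy as np

from . import neighbors, som
from .fcs import FCSHeader, SampleMatrix, read_fcs_events, read_fcs_header

__all__ = [
    "SliceDescription",
    "ShardedDataset",
    "plan_slices",
    "materialize_slice",
    "save_shard",
    "load_shard",
    "distributed_map",
    "distributed_mapreduce",
    "distributed_train_epoch",
    "split_rows",
]

T = TypeVar("T")
R = TypeVar("R")


@dataclass(frozen=True)
class SliceDescription:
    """A contiguous range of the file-concatenated event stream.

    ``first_event`` is inclusive within ``first_file``; ``last_event`` is
    exclusive within ``last_file``. Four integers fully describe the shard.
    """

    first_file: int
    first_event: int
    last_file: int
    last_event: int

    def size(self, event_counts: Sequence[int]) -> int:
        if self.first_file == self.last_file:
            return self.last_event - self.first_event
        n = event_counts[self.first_file] - self.first_event
        n += sum(event_counts[f] for f in range(self.first_file + 1, self.last_file))
        return n + self.last_event

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "SliceDescription":
        return cls(**{k: int(v) for k, v in d.items()})


def plan_slices(event_counts: Sequence[int], n_slices: int) -> list[SliceDescription]:
    """Cut the concatenated event stream into ``n_slices`` balanced slices.

    Slice sizes are ⌈N/n⌉ or ⌊N/n⌋ (larger slices first), contiguous in
    file order, disjoint, and jointly covering every event exactly once.
    Empty slices occur only when N < n_slices.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be ≥ 1")
    counts = [int(c) for c in event_counts]
    if any(c < 0 for c in counts):
        raise ValueError("event counts must be nonnegative")
    total = sum(counts)
    base, extra = divmod(total, n_slices)
    sizes = [base + (1 if i < extra else 0) for i in range(n_slices)]
    cum = np.concatenate([[0], np.cumsum(counts)])

    def locate_start(g: int) -> tuple[int, int]:
        # file holding global index g (file starts claim their boundary)
        f = int(np.searchsorted(cum, g, side="right")) - 1
        f = min(f, len(counts) - 1) if counts else 0
        return f, g - int(cum[f])

    def locate_end(g: int) -> tuple[int, int]:
        # boundary at a file's end stays within that file (exclusive index)
        f = int(np.searchsorted(cum, g, side="left")) - 1
        f = max(f, 0)
        return f, g - int(cum[f])

    slices = []
    offset = 0
    for s in sizes:
        if s == 0:
            f, e = locate_start(min(offset, total))
            slices.append(SliceDescription(f, e, f, e))
            continue
        ff, fe = locate_start(offset)
        lf, le = locate_end(offset + s)
        slices.append(SliceDescription(ff, fe, lf, le))
        offset += s
    return slices


def materialize_slice(desc: SliceDescription, files: Sequence[str | Path],
                      headers: Sequence[FCSHeader] | None = None) -> SampleMatrix:
    """Extract a slice's events from its FCS files, in stream order.

    All touched files must agree on their channel set; a mismatch raises a
    schema error listing the differing channels.
    """
    if headers is None:
        headers = [read_fcs_header(f) for f in files]
    parts: list[SampleMatrix] = []
    for f in range(desc.first_file, desc.last_file + 1):
        first = desc.first_event if f == desc.first_file else 0
        last = desc.last_event if f == desc.last_file else headers[f].n_events
        parts.append(read_fcs_events(files[f], first, last, header=headers[f]))
    cols = parts[0].columns
    for p, part in zip(range(desc.first_file, desc.last_file + 1), parts):
        if part.columns != cols:
            raise ValueError(
                "channel mismatch across files: "
                f"{sorted(set(cols) ^ set(part.columns))} "
                f"(file index {p})"
            )
    values = np.concatenate([p.values for p in parts], axis=0)
    return SampleMatrix(values=values, columns=list(cols),
                        source={"slice": desc.to_json(),
                                "files": [str(f) for f in files]})


@dataclass
class ShardedDataset:
    """Bookkeeping for a sliced multi-file dataset and its shard store."""

    files: list[str]
    event_counts: list[int]
    slices: list[SliceDescription]
    shard_store: str | None = None

    @property
    def n_events(self) -> int:
        return sum(self.event_counts)


# ---------------------------------------------------------------------------
# shard store: directory of shard_<k>.bin + manifest.json


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _manifest_path(store: str | Path) -> Path:
    return Path(store) / "manifest.json"


def _read_manifest(store: str | Path) -> dict:
    p = _manifest_path(store)
    if p.exists():
        return json.loads(p.read_text())
    return {"shards": {}}


def save_shard(matrix: SampleMatrix, store: str | Path, shard_id: int,
               extra: dict | None = None) -> Path:
    """Persist a shard losslessly as raw binary + manifest entry.

    The array's own dtype is recorded (raw FCS data is float32; transformed
    matrices are float64), together with a checksum verified on load.
    """
    store = Path(store)
    store.mkdir(parents=True, exist_ok=True)
    vals = np.ascontiguousarray(matrix.values)
    payload = vals.tobytes()
    path = store / f"shard_{shard_id}.bin"
    path.write_bytes(payload)
    manifest = _read_manifest(store)
    entry = {
        "file": path.name,
        "dtype": vals.dtype.str,
        "shape": list(vals.shape),
        "columns": list(matrix.columns),
        "sha256": _sha256(payload),
    }
    if extra:
        entry.update(extra)
    manifest["shards"][str(shard_id)] = entry
    _manifest_path(store).write_text(json.dumps(manifest, indent=1))
    return path


def load_shard(store: str | Path, shard_id: int) -> SampleMatrix:
    """Load a previously saved shard, verifying its checksum."""
    store = Path(store)
    manifest = _read_manifest(store)
    entry = manifest["shards"].get(str(shard_id))
    if entry is None:
        raise FileNotFoundError(f"shard {shard_id} not present in {store}")
    path = store / entry["file"]
    if not path.exists():
        raise FileNotFoundError(f"missing shard file {path}")
    payload = path.read_bytes()
    if _sha256(payload) != entry["sha256"]:
        raise IOError(f"checksum mismatch for shard {shard_id} ({path})")
    vals = np.frombuffer(payload, dtype=np.dtype(entry["dtype"]))
    vals = vals.reshape(entry["shape"]).copy()
    return SampleMatrix(values=vals, columns=list(entry["columns"]),
                        source={"store": str(store), "shard_id": shard_id})


# ---------------------------------------------------------------------------
# high-order distributed operations


def distributed_map(fn: Callable[[T], R], shards: Sequence[T],
                    n_workers: int = 1) -> list[R]:
    """Apply a pure function to every shard; results ordered by shard id.

    With ``n_workers > 1`` the maps run in local worker processes; the
    contract (no shared mutable state, only ``fn`` results cross the
    boundary) is what ports the loop to any cluster fabric. Failures are
    re-raised with the shard id attached.
    """
    def run(i: int, shard: T) -> R:
        try:
            return fn(shard)
        except Exception as e:
            raise RuntimeError(f"worker failed on shard {i}: {e}") from e

    if n_workers > 1 and len(shards) > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=n_workers)(
            delayed(run)(i, s) for i, s in enumerate(shards)
        )
    return [run(i, s) for i, s in enumerate(shards)]


def distributed_mapreduce(fn: Callable[[T], R], combine: Callable[[R, R], R],
                          shards: Sequence[T], n_workers: int = 1) -> R:
    """Map over shards and fold the results with an associative combine.

    Equals the serial fold over shard order; ``combine`` must be
    associative and commutative up to floating-point reordering (partial
    codebook updates combine by plain addition).
    """
    results = distributed_map(fn, shards, n_workers=n_workers)
    if not results:
        raise ValueError("mapreduce over zero shards has no identity")
    acc = results[0]
    for r in results[1:]:
        acc = combine(acc, r)
    return acc


def split_rows(matrix: SampleMatrix | np.ndarray, n_shards: int
               ) -> list[np.ndarray]:
    """Split an in-memory event matrix into contiguous row shards."""
    X = matrix.values if isinstance(matrix, SampleMatrix) else np.asarray(matrix)
    bounds = np.linspace(0, X.shape[0], n_shards + 1).astype(np.intp)
    return [X[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def distributed_train_epoch(shards: Sequence[SampleMatrix | np.ndarray],
                            codebook: som.Codebook,
                            H: som.NeighborhoodMatrix,
                            index_kind: str = "auto",
                            n_workers: int = 1,
                            collect_stats: bool = False,
                            dtype=np.float64):
    """One broadcast → partial-update → reduce → smooth training epoch.

    Workers receive the (small) codebook, compute raw per-node sums and
    counts from their shard, and send only those back; the master reduces
    by addition and applies the Ĥ smoothing and count normalization
    centrally. With one shard this is exactly :func:`som.batch_epoch`.

    Returns the updated codebook, or ``(codebook, stats)`` when
    ``collect_stats`` is set; ``stats['payload_bytes']`` lists the
    per-worker reply sizes (O(m·d), independent of shard length).
    """
    neighbors_index = neighbors.build_index(codebook.weights, kind=index_kind)
    m, d = codebook.m, codebook.d

    def worker(shard) -> som.PartialUpdate:
        X = shard.values if isinstance(shard, SampleMatrix) else np.asarray(shard)
        if X.shape[0] == 0:
            return som.PartialUpdate.zero(m, d)
        labels = neighbors.assign_labels(X, neighbors_index, dtype=dtype)
        return som.partial_update(X, labels, m)

    updates = distributed_map(worker, shards, n_workers=n_workers)
    total = som.PartialUpdate.zero(m, d)
    for u in updates:
        total = total + u
    new_cb = som.apply_update(codebook, total, H)
    if collect_stats:
        stats = {"payload_bytes": [u.nbytes for u in updates],
                 "broadcast_bytes": codebook.weights.nbytes}
        return new_cb, stats
    return new_cb
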