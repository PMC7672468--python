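"""Synthetic cytometry datasets: labeled Gaussian mixtures written as FCS.

Real cytometry panels measure tens of markers over 10⁴–10⁹ events; cell
populations appear as roughly Gaussian blobs after the standard asinh
transform. The generator draws labeled events from a Gaussian mixture in
that transformed space and — when ``raw_scale`` is on — maps them back to
raw instrument intensities via sinh(x)·cofactor, so the asinh/z-scaling
preprocessing steps operate on realistically scaled data. Fixtures are
written as valid FCS 3.1 files (optionally several files of unequal sizes,
to exercise the slice planner) with truth labels alongside as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fcs import SampleMatrix, write_fcs

__all__ = ["Component", "MixtureSpec", "generate", "write_fixture_set",
           "well_separated_spec"]


@dataclass(frozen=True)
class Component:
    """One mixture component: population weight, mean, covariance."""

    weight: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=np.float64)
        object.__setattr__(self, "mean", mean)
        cov = np.asarray(self.cov, dtype=np.float64)
        if cov.ndim == 0:  # scalar → isotropic
            cov = np.eye(mean.size) * float(cov)
        object.__setattr__(self, "cov", cov)
        if self.weight <= 0:
            raise ValueError("component weights must be positive")
        if cov.shape != (mean.size, mean.size):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        evals = np.linalg.eigvalsh(cov)
        if evals.min() < -1e-10 * max(evals.max(), 1.0):
            raise ValueError("covariance must be positive semidefinite")


@dataclass(frozen=True)
class MixtureSpec:
    """A labeled Gaussian mixture over a marker panel."""

    n_events: int
    markers: list[str]
    components: list[Component]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be nonnegative")
        d = len(self.markers)
        for c in self.components:
            if c.mean.size != d:
                raise ValueError("component dimension does not match markers")
        total = sum(c.weight for c in self.components)
        if not np.isclose(total, 1.0):
            raise ValueError(f"component weights sum to {total}, not 1")

    @property
    def d(self) -> int:
        return len(self.markers)


def _sqrt_psd(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root (handles singular covariances)."""
    evals, evecs = np.linalg.eigh(cov)
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def generate(spec: MixtureSpec, raw_scale: bool = False,
             cofactor: float = 500.0) -> tuple[SampleMatrix, np.ndarray]:
    """Draw labeled events i.i.d. from the mixture; deterministic per seed.

    Returns the event matrix and the integer component label per event.
    With ``raw_scale`` the transformed-space draws x are mapped to raw
    intensities sinh(x)·cofactor, the inverse of the asinh preprocessing.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    labels = rng.choice(len(spec.components), size=spec.n_events, p=weights)
    X = np.empty((spec.n_events, spec.d))
    for k, comp in enumerate(spec.components):
        rows = np.flatnonzero(labels == k)
        z = rng.standard_normal((rows.size, spec.d))
        X[rows] = comp.mean + z @ _sqrt_psd(comp.cov).T
    if raw_scale:
        X = np.sinh(X) * cofactor
    matrix = SampleMatrix(values=X, columns=list(spec.markers),
                          source={"mixture_seed": spec.seed})
    return matrix, labels.astype(np.int64)


def well_separated_spec(n_events: int, n_populations: int, d: int,
                        separation: float = 6.0, sigma: float = 1.0,
                        seed: int = 0,
                        weights: Sequence[float] | None = None) -> MixtureSpec:
    """Spec with component means pairwise ≥ ``separation``·σ apart.

    Means are drawn near a sphere of radius ``separation``/√2 (in d
    dimensions random sphere points sit ~r√2 apart) and redrawn, growing
    the radius when needed, until the pairwise separation holds. This
    keeps separations in a moderate band (roughly 1–2× the target) the way
    real cytometry populations differ in a subset of markers, rather than
    scattering means arbitrarily far apart.
    """
    rng = np.random.default_rng(seed + 987_654)
    if weights is None:
        w = np.full(n_populations, 1.0 / n_populations)
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    target = separation * sigma
    radius = target / np.sqrt(2)
    means = None
    for attempt in range(2000):
        cand = rng.standard_normal((n_populations, d))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        cand *= radius * rng.uniform(0.85, 1.15, size=(n_populations, 1))
        diff = cand[:, None, :] - cand[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= target:
            means = cand
            break
        if attempt % 100 == 99:  # packing too tight at this radius
            radius *= 1.15
    if means is None:  # pragma: no cover - placement converges in practice
        raise RuntimeError("could not place well-separated component means")
    comps = [Component(weight=float(w[k]), mean=means[k],
                       cov=np.eye(d) * sigma**2)
             for k in range(n_populations)]
    markers = [f"Marker{i + 1}" for i in range(d)]
    return MixtureSpec(n_events=n_events, markers=markers,
                       components=comps, seed=seed)


def write_fixture_set(spec: MixtureSpec, n_files: int, directory: str | Path,
                      raw_scale: bool = False, cofactor: float = 500.0,
                      ) -> dict:
    """Write the mixture as ``n_files`` FCS files + truth.csv + manifest.

    File sizes are deliberately unequal (proportional to 1, 2, …, n_files)
    so downstream slice planning is exercised on uneven inputs. Returns the
    manifest dict (also written as ``manifest.json``).
    """
    if n_files < 1:
        raise ValueError("n_files must be ≥ 1")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix, labels = generate(spec, raw_scale=raw_scale, cofactor=cofactor)

    parts = np.arange(1, n_files + 1, dtype=np.float64)
    bounds = np.rint(np.cumsum(parts) / parts.sum() * spec.n_events).astype(int)
    bounds = np.concatenate([[0], bounds])
    bounds[-1] = spec.n_events

    files = []
    for i in range(n_files):
        a, b = int(bounds[i]), int(bounds[i + 1])
        path = directory / f"sample_{i:02d}.fcs"
        write_fcs(SampleMatrix(values=matrix.values[a:b],
                               columns=matrix.columns), path)
        files.append({"file": path.name, "n_events": b - a})

    truth_path = directory / "truth.csv"
    with open(truth_path, "w") as fh:
        fh.write("event_id,label\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i},{int(lab)}\n")

    manifest = {
        "n_events": spec.n_events,
        "markers": spec.markers,
        "seed": spec.seed,
        "raw_scale": raw_scale,
        "cofactor": cofactor,
        "n_components": len(spec.components),
        "component_weights": [c.weight for c in spec.components],
        "files": files,
        "truth": truth_path.name,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
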