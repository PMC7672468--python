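"""Shared fixtures: small synthetic datasets and trained codebooks.

Everything is generated at test time from fixed seeds; no binary fixtures
are checked in.
"""

from __future__ import annotations

import numpy as np
import pytest

from cytosom import fcs, simulate, som


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_matrix():
    """200 × 5 random SampleMatrix with plain channel names."""
    gen = np.random.default_rng(11)
    vals = gen.standard_normal((200, 5))
    return fcs.SampleMatrix(values=vals, columns=[f"ch{i}" for i in range(5)])


@pytest.fixture(scope="session")
def mixture_4pop():
    """4 well-separated populations, 10 markers, 8000 events + truth."""
    spec = simulate.well_separated_spec(8000, 4, 10, seed=3)
    matrix, labels = simulate.generate(spec)
    return spec, matrix, labels


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A 3-file FCS fixture set (uneven sizes) with truth labels."""
    directory = tmp_path_factory.mktemp("fixture_set")
    spec = simulate.well_separated_spec(6000, 5, 8, seed=7)
    manifest = simulate.write_fixture_set(spec, 3, directory)
    return directory, spec, manifest


@pytest.fixture(scope="session")
def spread_codebook():
    """10×10 codebook trained on one broad Gaussian blob.

    Training on a single blob yields smoothly spread, pairwise-distinct
    node vectors — the geometry under which the embedding fixed-point
    property is well defined.
    """
    gen = np.random.default_rng(7)
    X = gen.standard_normal((20_000, 10))
    grid = som.SOMGrid(10, 10)
    schedule = som.TrainingSchedule(epochs=15)
    return som.train_batch_som(X, grid, schedule, seed=5), X
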