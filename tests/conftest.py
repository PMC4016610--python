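"""Shared fixtures and small geometric helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from foldspace import DistanceMatrix


def point_set_distances(
    n: int, q: int, rng: np.random.Generator, scale: float = 5.0
) -> tuple[np.ndarray, DistanceMatrix]:
    """Random points in q dimensions and their exact Euclidean distances."""
    coords = rng.normal(0.0, scale, size=(n, q))
    ids = [f"e{i}" for i in range(n)]
    return coords, DistanceMatrix(ids=ids, values=squareform(pdist(coords)))


def dense_matrix(values, ids=None) -> DistanceMatrix:
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"e{i}" for i in range(values.shape[0])]
    return DistanceMatrix(ids=list(ids), values=values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
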