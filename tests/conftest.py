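"""Shared fixtures and independent oracles for the test suite.

The oracle functions here are deliberately literal, loop-based
transcriptions of the defining formulas (entropy weights, within-class sums
of squares, brute-force k-means), kept independent of the package's
vectorized implementations so the tests compare two separate routes.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from cjindex import IndicatorMatrix, default_schema


# ---------------------------------------------------------------- oracles

def entropy_weights_literal(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Literal transcription of the entropy-weight formulas.

    P_ij = Y_ij / sum_i Y_ij;  e_j = -(1/ln m) sum_i P_ij ln P_ij (0 ln 0 = 0);
    w_j = (1 - e_j) / sum_j (1 - e_j).  All-zero columns get e_j = 1.
    """
    m, n = Y.shape
    e = []
    for j in range(n):
        col_sum = sum(Y[i, j] for i in range(m))
        if col_sum == 0:
            e.append(1.0)
            continue
        s = 0.0
        for i in range(m):
            p = Y[i, j] / col_sum
            if p > 0:
                s += p * math.log(p)
        e.append(-s / math.log(m))
    e = np.array(e)
    d = 1.0 - e
    return d / d.sum(), e


def kmeans_inertia_bruteforce(X: np.ndarray, k: int) -> float:
    """Minimum within-cluster sum of squares over every assignment of the
    points to k (non-empty) clusters.  Exponential; for tiny n only."""
    n = len(X)
    best = np.inf
    for assign in product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        a = np.array(assign)
        inertia = 0.0
        for c in range(k):
            seg = X[a == c]
            inertia += float(np.sum((seg - seg.mean(axis=0)) ** 2))
        best = min(best, inertia)
    return best


def match_centroids(found: np.ndarray, planted: np.ndarray) -> np.ndarray:
    """Greedy-free optimal matching of recovered to planted centroids;
    returns per-coordinate absolute errors of the matched pairs."""
    from scipy.optimize import linear_sum_assignment

    cost = np.linalg.norm(found[:, None, :] - planted[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return np.abs(found[rows] - planted[cols])


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def linear_schema():
    return default_schema("linear")


@pytest.fixture
def areal_schema():
    return default_schema("areal")


@pytest.fixture
def toy_matrix(linear_schema):
    """3 linear units with distinct, finite indicator values."""
    rng = np.random.default_rng(42)
    X = rng.uniform(1.0, 9.0, size=(3, 9))
    return IndicatorMatrix(["u1", "u2", "u3"], linear_schema, X)


@pytest.fixture
def toy_csv(tmp_path, toy_matrix):
    from cjindex import write_indicator_table

    path = tmp_path / "toy.csv"
    write_indicator_table(toy_matrix, path)
    return path


def square_geojson(unit_ids) -> dict:
    """Synthetic unit-square geometries keyed by unit_id (test stand-in)."""
    features = []
    for i, uid in enumerate(unit_ids):
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[i, 0], [i + 1, 0], [i + 1, 1], [i, 1], [i, 0]]],
            },
            "properties": {"unit_id": str(uid)},
        })
    return {"type": "FeatureCollection", "features": features}
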