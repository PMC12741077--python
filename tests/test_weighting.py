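"""Normalization and entropy weighting: hand examples, degenerate cases,
and equivalence with a literal transcription of the defining formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cjindex as cj
from cjindex.schema import Dimension, group_codes
from cjindex.weighting import (
    NormalizedMatrix,
    entropy_weights,
    weights_per_dimension,
)

from conftest import entropy_weights_literal


def _matrix_from_columns(schema, columns):
    """Build an IndicatorMatrix whose first columns are given, rest random."""
    rng = np.random.default_rng(0)
    m = len(next(iter(columns.values())))
    X = rng.uniform(0.0, 1.0, size=(m, len(schema)))
    codes = [s.code for s in schema]
    for code, col in columns.items():
        X[:, codes.index(code)] = col
    return cj.IndicatorMatrix([f"u{i}" for i in range(m)], schema, X)


def _normalized(Y: np.ndarray) -> NormalizedMatrix:
    frame = pd.DataFrame(Y, columns=[f"c{j}" for j in range(Y.shape[1])])
    return NormalizedMatrix(frame, polarities={})


class TestNormalize:
    def test_positive_and_negative_columns(self, linear_schema):
        mat = _matrix_from_columns(
            linear_schema, {"C1": [2.0, 4.0, 10.0], "C2": [2.0, 4.0, 10.0]}
        )
        norm = cj.normalize(mat)
        np.testing.assert_allclose(norm.Y["C1"], [0.0, 0.25, 1.0])  # positive
        np.testing.assert_allclose(norm.Y["C2"], [1.0, 0.75, 0.0])  # negative

    def test_constant_column_flagged_zero(self, linear_schema):
        mat = _matrix_from_columns(linear_schema, {"C3": [5.0, 5.0, 5.0]})
        norm = cj.normalize(mat)
        assert norm.constant_columns == ["C3"]
        np.testing.assert_array_equal(norm.Y["C3"], 0.0)

    def test_output_in_unit_interval_with_extremes_attained(self, toy_matrix):
        norm = cj.normalize(toy_matrix)
        Y = norm.Y.to_numpy()
        assert Y.min() >= 0.0 and Y.max() <= 1.0
        np.testing.assert_allclose(Y.min(axis=0), 0.0, atol=1e-15)
        np.testing.assert_allclose(Y.max(axis=0), 1.0, rtol=1e-15)

    def test_explicit_bounds_used(self, linear_schema):
        mat = _matrix_from_columns(linear_schema, {"C1": [0.25, 0.5, 0.75]})
        norm = cj.normalize(mat, bounds={"C1": (0.0, 1.0)})
        np.testing.assert_allclose(norm.Y["C1"], [0.25, 0.5, 0.75])

    def test_single_unit_rejected(self, linear_schema):
        mat = cj.IndicatorMatrix(["only"], linear_schema, np.ones((1, 9)))
        with pytest.raises(cj.InputError):
            cj.normalize(mat)


class TestEntropyWeights:
    def test_hand_example(self):
        # one maximally dispersed column, one constant: all weight to the first
        wv = entropy_weights(_normalized(np.array([[1.0, 0.5], [0.0, 0.5]])))
        assert wv.entropies["c0"] == pytest.approx(0.0, abs=1e-12)
        assert wv.entropies["c1"] == pytest.approx(1.0, abs=1e-12)
        assert wv.weights["c0"] == pytest.approx(1.0, abs=1e-12)
        assert wv.weights["c1"] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_columns_fall_back_to_uniform(self):
        wv = entropy_weights(_normalized(np.zeros((3, 4))))
        assert wv.degenerate
        np.testing.assert_allclose(list(wv.weights.values()), 0.25)

    def test_single_unit_rejected(self):
        with pytest.raises(cj.InputError):
            entropy_weights(_normalized(np.array([[0.4, 0.6]])))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_simplex_and_oracle_equivalence(self, seed):
        """Weights are a probability vector and match the literal formulas."""
        rng = np.random.default_rng(seed)
        Y = rng.uniform(0.0, 1.0, size=(5, 3))
        wv = entropy_weights(_normalized(Y))
        w = np.array(list(wv.weights.values()))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        w_ref, e_ref = entropy_weights_literal(Y)
        np.testing.assert_allclose(w, w_ref, atol=1e-12)
        np.testing.assert_allclose(list(wv.entropies.values()), e_ref, atol=1e-12)

    def test_scale_invariance_of_raw_columns(self, linear_schema):
        """Affine rescaling (positive slope) of a raw column changes nothing."""
        rng = np.random.default_rng(3)
        X = rng.uniform(1.0, 5.0, size=(6, 9))
        mat1 = cj.IndicatorMatrix([f"u{i}" for i in range(6)], linear_schema, X)
        X2 = X.copy()
        X2[:, 0] = 7.5 * X2[:, 0] + 100.0
        mat2 = cj.IndicatorMatrix([f"u{i}" for i in range(6)], linear_schema, X2)
        w1 = weights_per_dimension(mat1)
        w2 = weights_per_dimension(mat2)
        for dim in cj.DIMENSIONS:
            np.testing.assert_allclose(
                list(w1[dim].weights.values()),
                list(w2[dim].weights.values()),
                atol=1e-12,
            )

    def test_permutation_equivariance(self, toy_matrix):
        perm = [2, 0, 1]
        mat_p = cj.IndicatorMatrix(
            [toy_matrix.units[i] for i in perm],
            toy_matrix.schema,
            toy_matrix.X[perm],
        )
        norm, norm_p = cj.normalize(toy_matrix), cj.normalize(mat_p)
        np.testing.assert_allclose(
            norm.Y.to_numpy()[perm], norm_p.Y.to_numpy(), atol=1e-15
        )
        w = entropy_weights(norm)
        w_p = entropy_weights(norm_p)
        np.testing.assert_allclose(
            list(w.weights.values()), list(w_p.weights.values()), atol=1e-15
        )


class TestWeightsPerDimension:
    @pytest.mark.parametrize(
        "space_type,sizes", [("linear", (4, 3, 2)), ("areal", (2, 3, 2))]
    )
    def test_group_sizes(self, space_type, sizes):
        sc = cj.preset(f"{space_type}_reference", seed=1)
        _, truth = cj.generate_scores(sc)
        mat = cj.backfill_indicators(truth)
        by_dim = weights_per_dimension(mat)
        got = tuple(len(by_dim[d].weights) for d in cj.DIMENSIONS)
        assert got == sizes
        for d in cj.DIMENSIONS:
            assert sum(by_dim[d].weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_columns_share_weight(self, linear_schema):
        """Symmetry: identical recognition columns get equal weights."""
        rng = np.random.default_rng(8)
        X = rng.uniform(0.0, 1.0, size=(8, 9))
        codes = [s.code for s in linear_schema]
        rec = group_codes(linear_schema, Dimension.RECOGNITION)
        base = X[:, codes.index(rec[0])]
        for code in rec[1:]:
            X[:, codes.index(code)] = base
        # same polarity for all recognition columns so duplicates stay identical
        mat = cj.IndicatorMatrix([f"u{i}" for i in range(8)], linear_schema, X)
        by_dim = weights_per_dimension(
            mat, polarities={c: "negative" for c in rec}
        )
        w = list(by_dim[Dimension.RECOGNITION].weights.values())
        np.testing.assert_allclose(w, 1.0 / len(rec), atol=1e-12)

    def test_whole_table_mode_renormalizes(self, toy_matrix):
        by_dim = weights_per_dimension(toy_matrix, mode="whole_table")
        for d in cj.DIMENSIONS:
            assert sum(by_dim[d].weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_reference_weights_injectable(self, linear_schema):
        ref = cj.reference_weights(linear_schema)
        assert ref[Dimension.PROCEDURAL].weights["C8"] == pytest.approx(0.623, abs=1e-9)
        for d in cj.DIMENSIONS:
            assert sum(ref[d].weights.values()) == pytest.approx(1.0, abs=1e-12)
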