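"""Indicator schema contents and table/result round-trips."""

import json

import numpy as np
import pandas as pd
import pytest

import cjindex as cj
from cjindex.io import read_geometries, write_results
from cjindex.schema import Dimension, Polarity, group_codes

from conftest import square_geojson


class TestDefaultSchema:
    @pytest.mark.parametrize(
        "space_type,n_total,per_dim",
        [("linear", 9, (4, 3, 2)), ("areal", 7, (2, 3, 2))],
    )
    def test_structure(self, space_type, n_total, per_dim):
        schema = cj.default_schema(space_type)
        assert len(schema) == n_total
        codes = [s.code for s in schema]
        assert len(set(codes)) == len(codes)
        sizes = tuple(len(group_codes(schema, d)) for d in cj.DIMENSIONS)
        assert sizes == per_dim

    @pytest.mark.parametrize("space_type", ["linear", "areal"])
    def test_reference_weights_sum_to_one_per_dimension(self, space_type):
        schema = cj.default_schema(space_type)
        for dim in cj.DIMENSIONS:
            total = sum(s.reference_weight for s in schema if s.dimension is dim)
            assert total == pytest.approx(1.0, abs=1e-3)

    def test_published_weight_fixtures(self):
        linear = {s.code: s.reference_weight for s in cj.default_schema("linear")}
        assert (linear["C8"], linear["C9"]) == (0.623, 0.377)
        areal = {s.code: s.reference_weight for s in cj.default_schema("areal")}
        assert (areal["C10"], areal["C11"]) == (0.648, 0.352)

    def test_default_polarities(self):
        pol = {s.name: s.polarity for s in cj.default_schema("linear")}
        pol.update({s.name: s.polarity for s in cj.default_schema("areal")})
        assert pol["Sky View Factor"] is Polarity.POSITIVE
        assert pol["Green View Index"] is Polarity.POSITIVE
        assert pol["Vegetation Coverage"] is Polarity.POSITIVE
        assert pol["Housing Prices"] is Polarity.POSITIVE
        assert pol["Indoor Cooling Facilities"] is Polarity.POSITIVE
        assert pol["Street Canyon Ratio"] is Polarity.NEGATIVE
        assert pol["Land Surface Temperature"] is Polarity.NEGATIVE
        assert pol["Population Aggregation"] is Polarity.NEGATIVE
        assert pol["Proportion of Sensitive Population"] is Polarity.NEGATIVE


class TestLoadIndicatorTable:
    def test_round_trip_exact(self, toy_csv, toy_matrix):
        loaded = cj.load_indicator_table(toy_csv)
        assert loaded.m == 3 and loaded.n == 9
        assert loaded.units == toy_matrix.units
        np.testing.assert_allclose(loaded.X, toy_matrix.X, rtol=1e-12)

    def test_missing_column_names_it(self, toy_csv, tmp_path):
        df = pd.read_csv(toy_csv).drop(columns=["C4"])
        bad = tmp_path / "missing.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(cj.SchemaError, match="C4"):
            cj.load_indicator_table(bad)

    def test_unknown_column_rejected(self, toy_csv, tmp_path):
        df = pd.read_csv(toy_csv)
        df["C99"] = 1.0
        bad = tmp_path / "unknown.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(cj.SchemaError, match="C99"):
            cj.load_indicator_table(bad)

    def test_mixed_space_types_rejected(self, toy_csv, tmp_path):
        df = pd.read_csv(toy_csv)
        df.loc[1, "space_type"] = "areal"
        bad = tmp_path / "mixed.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(cj.InputError, match="mixed"):
            cj.load_indicator_table(bad)

    def test_non_numeric_cell_reports_coordinates(self, toy_csv, tmp_path):
        df = pd.read_csv(toy_csv, dtype=str)
        df.loc[2, "C7"] = "oops"
        bad = tmp_path / "nonnum.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(cj.ParseError, match=r"C7"):
            cj.load_indicator_table(bad)

    def test_synthetic_preset_row_count(self, tmp_path):
        sc = cj.preset("linear_reference", seed=0)
        _, truth = cj.generate_scores(sc)
        matrix = cj.backfill_indicators(truth)
        path = tmp_path / "linear.csv"
        cj.write_indicator_table(matrix, path)
        loaded = cj.load_indicator_table(path)
        assert loaded.m == sc.m == sum(sc.counts)

    def test_nonfinite_matrix_rejected(self, linear_schema):
        X = np.ones((2, 9))
        X[0, 3] = np.nan
        with pytest.raises(cj.InputError, match="non-finite"):
            cj.IndicatorMatrix(["a", "b"], linear_schema, X)


class TestWriteResults:
    @pytest.fixture
    def small_run(self, tmp_path):
        cfg = cj.RunConfig(preset_name="areal_reference", seed=5,
                           out_dir=str(tmp_path / "out"))
        return cj.run_pipeline(cfg)

    def test_csv_and_report_written(self, small_run):
        df = pd.read_csv(small_run["results_csv"])
        assert len(df) == 54
        assert {"unit_id", "dj", "rj", "pj", "cji", "level_cji",
                "cluster", "deficit_label"} <= set(df.columns)
        with open(small_run["report_json"]) as fh:
            report = json.load(fh)
        assert report["typology"]["total"] == 54

    def test_level_proportions_sum_to_100(self, small_run):
        with open(small_run["report_json"]) as fh:
            report = json.load(fh)
        for block in report["levels"].values():
            assert sum(block["proportions_pct"].values()) == pytest.approx(100.0, abs=0.01)

    def test_geojson_feature_per_unit(self, tmp_path):
        sc = cj.preset("areal_reference", seed=5)
        _, truth = cj.generate_scores(sc)
        geo = square_geojson(truth.scores.index)
        gpath = tmp_path / "units.geojson"
        gpath.write_text(json.dumps(geo))
        cfg = cj.RunConfig(preset_name="areal_reference", seed=5,
                           geojson=str(gpath), out_dir=str(tmp_path / "out"))
        manifest = cj.run_pipeline(cfg)
        with open(manifest["geojson"]) as fh:
            doc = json.load(fh)
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == 54
        props = doc["features"][0]["properties"]
        assert "cji" in props and "unit_id" in props

    def test_id_mismatch_raises(self):
        from cjindex.pipeline import assemble_results

        cfg = cj.RunConfig(preset_name="areal_reference", seed=5)
        sc = cj.preset("areal_reference", seed=5)
        _, truth = cj.generate_scores(sc)
        matrix = cj.backfill_indicators(truth)
        norm = cj.normalize(matrix)
        scores = cj.compute_scores(norm, cj.reference_weights(matrix.schema))
        from cjindex.pipeline import classify_scores
        levels, _ = classify_scores(scores, 5, None)
        typ = cj.kmeans_partition(scores, k=4, seed=1, restarts=5)
        levels_bad = levels.iloc[:-1]
        with pytest.raises(cj.ConsistencyError):
            assemble_results(scores, levels_bad, typ, "areal")

    def test_rerun_byte_identical(self, tmp_path):
        cfg = cj.RunConfig(preset_name="areal_reference", seed=9,
                           out_dir=str(tmp_path / "out"))
        m1 = cj.run_pipeline(cfg)
        first = {k: open(m1[k], "rb").read()
                 for k in ("results_csv", "report_json")}
        m2 = cj.run_pipeline(cfg)
        for key, blob in first.items():
            with open(m2[key], "rb") as fh:
                assert fh.read() == blob
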