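"""Reading and writing indicator tables and result artifacts.

The canonical exchange format is CSV (comma-delimited, UTF-8, decimal
point): one row per spatial unit, a ``unit_id`` column, a ``space_type``
column, and one column per indicator code.  Geometries travel separately as
an RFC 7946 GeoJSON FeatureCollection whose features carry a ``unit_id``
property; geometry handling is strictly pass-through (no CRS transforms).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError, ParseError, SchemaError
from .schema import (
    IndicatorMatrix,
    IndicatorSpec,
    SpaceType,
    default_schema,
    schema_codes,
)

logger = logging.getLogger(__name__)

#: float format used for all CSV output — 17 significant digits give an
#: exact binary round-trip of scores and raw indicators through text.
CSV_FLOAT_FORMAT = "%.17g"

_META_COLUMNS = {"unit_id", "space_type"}


def load_indicator_table(
    path: str | Path,
    schema: list[IndicatorSpec] | None = None,
) -> IndicatorMatrix:
    """Load and validate a per-unit indicator CSV for one space type.

    Parameters
    ----------
    path
        Delimited text file with a header naming ``unit_id``, ``space_type``
        and the indicator codes.
    schema
        Indicator specs to validate against; defaults to the built-in schema
        of the file's (single) space type.

    Raises
    ------
    InputError
        If the file mixes space types, or contains no rows.
    SchemaError
        If an indicator column is missing or an unknown column is present.
    ParseError
        If a cell is non-numeric (reported with row/column coordinates).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "unit_id" not in raw.columns or "space_type" not in raw.columns:
        raise SchemaError("input must have 'unit_id' and 'space_type' columns")
    n_read = len(raw)
    if n_read == 0:
        raise InputError(f"{path}: no data rows")

    space_types = set(raw["space_type"])
    if len(space_types) != 1:
        raise InputError(
            f"{path}: mixed space types in one table: {sorted(space_types)}"
        )
    space_type = SpaceType(space_types.pop())
    if schema is None:
        schema = default_schema(space_type)
    if schema[0].space_type is not space_type:
        raise InputError(
            f"{path}: table is {space_type.value!r} but schema is "
            f"{schema[0].space_type.value!r}"
        )

    codes = schema_codes(schema)
    missing = [c for c in codes if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing indicator column(s): {', '.join(missing)}")
    unknown = [c for c in raw.columns if c not in _META_COLUMNS and c not in codes]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s): {', '.join(unknown)}")

    # Drop rows with empty cells (logged), then parse the rest strictly.
    value_block = raw[codes]
    empty_mask = (value_block == "").any(axis=1)
    n_dropped = int(empty_mask.sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with empty cells", path, n_dropped)
    kept = raw.loc[~empty_mask]
    if kept.empty:
        raise InputError(f"{path}: all {n_read} rows had empty cells")

    X = np.empty((len(kept), len(codes)), dtype=float)
    for j, code in enumerate(codes):
        col = pd.to_numeric(kept[code], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            row_label = kept.loc[bad[0], "unit_id"]
            raise ParseError(
                f"{path}: non-numeric value {kept.loc[bad[0], code]!r} at "
                f"row {bad[0] + 2} (unit {row_label!r}), column {code!r}"
            )
        X[:, j] = col.to_numpy(float)

    matrix = IndicatorMatrix(list(kept["unit_id"]), schema, X)
    logger.info(
        "%s: read %d rows, dropped %d, loaded %d %s units",
        path, n_read, n_dropped, matrix.m, space_type.value,
    )
    return matrix


def write_indicator_table(matrix: IndicatorMatrix, path: str | Path) -> Path:
    """Write an indicator matrix back to the canonical CSV dialect."""
    path = Path(path)
    frame = matrix.to_frame().reset_index()
    frame.insert(1, "space_type", matrix.space_type.value)
    frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    return path


def read_geometries(path: str | Path) -> dict[str, dict[str, Any]]:
    """Read a GeoJSON FeatureCollection keyed by the ``unit_id`` property.

    Returns a mapping unit_id -> feature (geometry kept verbatim, CRS member
    preserved by the caller via :func:`attach_geometries`).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise InputError(f"{path}: not a GeoJSON FeatureCollection")
    features: dict[str, dict[str, Any]] = {}
    for feat in doc.get("features", []):
        uid = (feat.get("properties") or {}).get("unit_id")
        if uid is None:
            raise InputError(f"{path}: feature without a 'unit_id' property")
        features[str(uid)] = feat
    # remember any top-level foreign members (e.g. legacy "crs") verbatim
    extras = {k: v for k, v in doc.items() if k not in ("type", "features")}
    if extras:
        features["__collection_extras__"] = extras  # type: ignore[assignment]
    return features


def attach_geometries(
    results: pd.DataFrame,
    geometries: dict[str, dict[str, Any]],
) -> dict[str, Any]:
    """Build a FeatureCollection with result columns as feature properties."""
    extras = geometries.get("__collection_extras__", {})
    missing = [u for u in results.index if u not in geometries]
    if missing:
        raise ConsistencyError(
            f"no geometry for unit(s): {', '.join(map(str, missing[:5]))}"
            + ("..." if len(missing) > 5 else "")
        )
    features = []
    for uid, row in results.iterrows():
        feat = geometries[str(uid)]
        props = dict(feat.get("properties") or {})
        props.update({"unit_id": str(uid), **_jsonify(row.to_dict())})
        features.append(
            {"type": "Feature", "geometry": feat.get("geometry"), "properties": props}
        )
    doc: dict[str, Any] = {"type": "FeatureCollection", "features": features}
    doc.update(extras)
    return doc


def _jsonify(obj: Any) -> Any:
    """Coerce numpy scalars / containers into plain JSON-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_results(
    results: pd.DataFrame,
    report: dict[str, Any],
    out_dir: str | Path,
    geometries: dict[str, dict[str, Any]] | None = None,
    prefix: str = "results",
) -> dict[str, str]:
    """Write the per-unit results CSV, the JSON report and optional GeoJSON.

    ``results`` is indexed by unit_id; ``report`` is the machine-readable
    run report (weights, breaks, typology, proportions).  Returns a manifest
    mapping artifact names to file paths.  Output is deterministic: keys are
    sorted and no timestamps are written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    csv_path = out_dir / f"{prefix}.csv"
    results.reset_index().to_csv(csv_path, index=False, float_format=CSV_FLOAT_FORMAT)
    manifest["results_csv"] = str(csv_path)

    json_path = out_dir / f"{prefix}_report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["report_json"] = str(json_path)

    if geometries is not None:
        geo_path = out_dir / f"{prefix}.geojson"
        doc = attach_geometries(results, geometries)
        with open(geo_path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, sort_keys=True)
            fh.write("\n")
        manifest["geojson"] = str(geo_path)

    return manifest
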