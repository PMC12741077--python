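"""Indicator schemas for linear and areal outdoor cooling spaces.

The assessment uses two separate indicator systems: *linear* cooling spaces
(streets) are described by nine indicators C1-C9, *areal* cooling spaces
(parks, squares) by seven indicators C10-C16.  Each indicator belongs to one
of three justice dimensions:

* **distributive** — physical heat exposure and mitigation resources
  (sky view factor, street canyon ratio, green view index, vegetation
  coverage, land surface temperature);
* **recognition** — demographic and socioeconomic sensitivity (population
  aggregation, proportion of sensitive population, housing prices);
* **procedural** — access to adaptive services (indoor cooling facilities,
  medical facilities).

Each indicator carries a *polarity*: positive indicators increase justice as
they grow (more greenery, more facilities), negative indicators decrease it
(hotter surfaces, more crowding).  The published per-dimension entropy
weights of the original Fuzhou study are stored as ``reference_weight``
fixtures; they are never used in computation unless a run explicitly asks
for fixed weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, SchemaError


class SpaceType(str, Enum):
    LINEAR = "linear"
    AREAL = "areal"


class Dimension(str, Enum):
    DISTRIBUTIVE = "distributive"
    RECOGNITION = "recognition"
    PROCEDURAL = "procedural"


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


#: Canonical dimension order used everywhere (score triples, centroids, ...).
DIMENSIONS: tuple[Dimension, ...] = (
    Dimension.DISTRIBUTIVE,
    Dimension.RECOGNITION,
    Dimension.PROCEDURAL,
)


@dataclass(frozen=True)
class IndicatorSpec:
    """Metadata for a single raw indicator column."""

    code: str
    name: str
    space_type: SpaceType
    dimension: Dimension
    polarity: Polarity
    reference_weight: float | None = None

    def with_polarity(self, polarity: Polarity) -> "IndicatorSpec":
        return replace(self, polarity=polarity)


# (code, name, dimension, polarity, reference weight)
_LINEAR_ROWS = [
    ("C1", "Sky View Factor", Dimension.DISTRIBUTIVE, Polarity.POSITIVE, 0.190),
    ("C2", "Street Canyon Ratio", Dimension.DISTRIBUTIVE, Polarity.NEGATIVE, 0.550),
    ("C3", "Green View Index", Dimension.DISTRIBUTIVE, Polarity.POSITIVE, 0.131),
    ("C4", "Land Surface Temperature", Dimension.DISTRIBUTIVE, Polarity.NEGATIVE, 0.129),
    ("C5", "Population Aggregation", Dimension.RECOGNITION, Polarity.NEGATIVE, 0.187),
    ("C6", "Proportion of Sensitive Population", Dimension.RECOGNITION, Polarity.NEGATIVE, 0.527),
    ("C7", "Housing Prices", Dimension.RECOGNITION, Polarity.POSITIVE, 0.286),
    ("C8", "Indoor Cooling Facilities", Dimension.PROCEDURAL, Polarity.POSITIVE, 0.623),
    ("C9", "Medical Facilities", Dimension.PROCEDURAL, Polarity.POSITIVE, 0.377),
]

_AREAL_ROWS = [
    ("C10", "Vegetation Coverage", Dimension.DISTRIBUTIVE, Polarity.POSITIVE, 0.648),
    ("C11", "Land Surface Temperature", Dimension.DISTRIBUTIVE, Polarity.NEGATIVE, 0.352),
    ("C12", "Population Aggregation", Dimension.RECOGNITION, Polarity.NEGATIVE, 0.390),
    ("C13", "Proportion of Sensitive Population", Dimension.RECOGNITION, Polarity.NEGATIVE, 0.399),
    ("C14", "Housing Prices", Dimension.RECOGNITION, Polarity.POSITIVE, 0.211),
    ("C15", "Indoor Cooling Facilities", Dimension.PROCEDURAL, Polarity.POSITIVE, 0.533),
    ("C16", "Medical Facilities", Dimension.PROCEDURAL, Polarity.POSITIVE, 0.467),
]


def default_schema(space_type: SpaceType | str) -> list[IndicatorSpec]:
    """Return the built-in indicator schema for one space type.

    The reference weights within each (space type, dimension) block sum to 1
    (to the printed precision of three decimals).
    """
    space_type = SpaceType(space_type)
    rows = _LINEAR_ROWS if space_type is SpaceType.LINEAR else _AREAL_ROWS
    return [
        IndicatorSpec(code, name, space_type, dim, pol, w)
        for code, name, dim, pol, w in rows
    ]


def schema_codes(schema: list[IndicatorSpec]) -> list[str]:
    return [s.code for s in schema]


def group_codes(schema: list[IndicatorSpec], dimension: Dimension) -> list[str]:
    return [s.code for s in schema if s.dimension is dimension]


def validate_schema(schema: list[IndicatorSpec]) -> None:
    """Check schema invariants: unique codes, single space type, non-empty
    dimension groups, reference weights summing to 1 per group when present."""
    codes = schema_codes(schema)
    if len(set(codes)) != len(codes):
        raise SchemaError("duplicate indicator codes in schema")
    space_types = {s.space_type for s in schema}
    if len(space_types) != 1:
        raise SchemaError("schema mixes space types")
    for dim in DIMENSIONS:
        group = [s for s in schema if s.dimension is dim]
        if not group:
            raise SchemaError(f"dimension {dim.value!r} has no indicators")
        weights = [s.reference_weight for s in group]
        if all(w is not None for w in weights):
            total = float(np.sum(weights))
            if abs(total - 1.0) > 1e-3:
                raise SchemaError(
                    f"reference weights for {dim.value!r} sum to {total}, not 1"
                )


def polarity_map(
    schema: list[IndicatorSpec],
    overrides: dict[str, Polarity | str] | None = None,
) -> dict[str, Polarity]:
    """Per-code polarity, with optional overrides (config-driven)."""
    pol = {s.code: s.polarity for s in schema}
    for code, p in (overrides or {}).items():
        if code not in pol:
            raise SchemaError(f"polarity override for unknown indicator {code!r}")
        pol[code] = Polarity(p)
    return pol


class IndicatorMatrix:
    """An m x n matrix of raw indicator values for one space type.

    Rows are spatial units (in input order), columns follow the schema's
    indicator order.  Values must be finite; per-column minima and maxima are
    cached for normalization.
    """

    def __init__(
        self,
        units: list[str],
        schema: list[IndicatorSpec],
        X: np.ndarray,
    ) -> None:
        validate_schema(schema)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape != (len(units), len(schema)):
            raise InputError(
                f"X has shape {X.shape}, expected ({len(units)}, {len(schema)})"
            )
        if len(set(units)) != len(units):
            raise InputError("duplicate unit ids")
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise InputError(
                f"non-finite value at unit {units[bad[0]]!r}, "
                f"indicator {schema[bad[1]].code!r}"
            )
        self.units = list(units)
        self.schema = list(schema)
        self.X = X
        self.col_min = X.min(axis=0)
        self.col_max = X.max(axis=0)

    @property
    def m(self) -> int:
        return len(self.units)

    @property
    def n(self) -> int:
        return len(self.schema)

    @property
    def codes(self) -> list[str]:
        return schema_codes(self.schema)

    @property
    def space_type(self) -> SpaceType:
        return self.schema[0].space_type

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=pd.Index(self.units, name="unit_id"),
                            columns=self.codes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, schema: list[IndicatorSpec]) -> "IndicatorMatrix":
        codes = schema_codes(schema)
        missing = [c for c in codes if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing indicator column(s): {', '.join(missing)}")
        return cls(list(frame.index.astype(str)), schema, frame[codes].to_numpy(float))


def dimension_name(dimension: Dimension | str) -> str:
    """Human-readable dimension name used in typology labels."""
    return {
        Dimension.DISTRIBUTIVE: "Distributive",
        Dimension.RECOGNITION: "Recognition",
        Dimension.PROCEDURAL: "Procedural",
    }[Dimension(dimension)]


def parse_space_type(value: str) -> SpaceType:
    try:
        return SpaceType(value)
    except ValueError as exc:
        raise ConfigError(f"unknown space type {value!r}") from exc
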