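"""Polarity-aware min-max normalization and entropy weighting.

Normalization maps each raw indicator column onto [0, 1] so that larger
values always mean *more justice*:

* positive polarity:  ``Y = (X - Xmin) / (Xmax - Xmin)``
* negative polarity:  ``Y = (Xmax - X) / (Xmax - Xmin)``

The entropy weight method then assigns each indicator an objective weight
that grows with the dispersion of its normalized column: with column shares
``P_ij = Y_ij / sum_i Y_ij``, the information entropy is
``e_j = -(1/ln m) * sum_i P_ij ln P_ij`` (with 0*ln 0 = 0) and the weight is
``w_j = (1 - e_j) / sum_j (1 - e_j)``.  A column with no variation carries
no information (e_j = 1) and receives zero weight.

Weights are computed independently within each justice dimension, mirroring
the per-dimension weight blocks of the published indicator system; a
whole-table mode is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, InputError, SchemaError
from .schema import (
    DIMENSIONS,
    Dimension,
    IndicatorMatrix,
    IndicatorSpec,
    Polarity,
    group_codes,
    polarity_map,
)

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Normalized indicator values Y in [0, 1], plus provenance."""

    Y: pd.DataFrame                      # units x codes
    polarities: dict[str, Polarity]
    constant_columns: list[str] = field(default_factory=list)
    bounds: dict[str, tuple[float, float]] | None = None

    @property
    def units(self) -> list[str]:
        return list(self.Y.index)

    @property
    def codes(self) -> list[str]:
        return list(self.Y.columns)


def normalize(
    matrix: IndicatorMatrix,
    polarities: dict[str, Polarity | str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> NormalizedMatrix:
    """Min-max normalize each column by its polarity.

    Parameters
    ----------
    matrix
        Raw indicator matrix (m >= 2 units).
    polarities
        Optional per-code polarity overrides; defaults to the schema's.
    bounds
        Optional explicit per-code (min, max) normalization bounds.  By
        default the empirical column min/max are used; explicit bounds allow
        scoring against fixed reference ranges (e.g. when re-scoring
        synthetic data whose generating ranges are known).

    Constant columns (max == min) map to all zeros and are flagged in
    ``constant_columns``.
    """
    if matrix.m < 2:
        raise InputError("normalization needs at least two units")
    pol = polarity_map(matrix.schema, polarities)
    Y = np.empty_like(matrix.X)
    constant: list[str] = []
    for j, spec in enumerate(matrix.schema):
        x = matrix.X[:, j]
        if bounds is not None and spec.code in bounds:
            lo, hi = bounds[spec.code]
            if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
                raise ConfigError(f"invalid bounds for {spec.code!r}: ({lo}, {hi})")
        else:
            lo, hi = matrix.col_min[j], matrix.col_max[j]
        span = hi - lo
        if span == 0.0:
            Y[:, j] = 0.0
            constant.append(spec.code)
            logger.warning("indicator %s is constant; normalized to 0", spec.code)
            continue
        if pol[spec.code] is Polarity.POSITIVE:
            Y[:, j] = (x - lo) / span
        else:
            Y[:, j] = (hi - x) / span
    frame = pd.DataFrame(Y, index=pd.Index(matrix.units, name="unit_id"),
                         columns=matrix.codes)
    used_bounds = None
    if bounds:
        used_bounds = {
            c: (float(lo), float(hi))
            for c, (lo, hi) in bounds.items()
            if c in matrix.codes
        }
    return NormalizedMatrix(frame, pol, constant, used_bounds)


@dataclass
class WeightVector:
    """Entropy weights w_j and entropies e_j for one indicator group."""

    weights: dict[str, float]
    entropies: dict[str, float]
    group: str = ""
    degenerate: bool = False

    @property
    def codes(self) -> list[str]:
        return list(self.weights)

    def as_array(self, codes: list[str] | None = None) -> np.ndarray:
        codes = codes if codes is not None else self.codes
        return np.array([self.weights[c] for c in codes], dtype=float)


def entropy_weights(
    normalized: NormalizedMatrix,
    codes: list[str] | None = None,
    group: str = "",
) -> WeightVector:
    """Entropy weights over a (subset of) normalized columns.

    All-zero columns receive entropy 1 and weight 0.  If *every* column is
    degenerate the weights fall back to uniform with ``degenerate=True`` so
    downstream aggregation never divides by zero.
    """
    codes = codes if codes is not None else normalized.codes
    if not codes:
        raise SchemaError("empty indicator group")
    missing = [c for c in codes if c not in normalized.Y.columns]
    if missing:
        raise ConsistencyError(f"group codes not in matrix: {', '.join(missing)}")
    Y = normalized.Y[codes].to_numpy(float)
    m = Y.shape[0]
    if m < 2:
        raise InputError("entropy is undefined for a single unit (ln m = 0)")

    col_sums = Y.sum(axis=0)
    entropies = np.ones(len(codes))
    for j, total in enumerate(col_sums):
        if total <= 0.0:
            continue  # all-zero column: e_j = 1
        p = Y[:, j] / total
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0.0, p * np.log(p), 0.0)
        entropies[j] = -plogp.sum() / np.log(m)
    # guard tiny negative rounding; entropy is bounded by [0, 1]
    entropies = np.clip(entropies, 0.0, 1.0)

    divergence = 1.0 - entropies
    total_div = divergence.sum()
    if total_div <= 1e-15:
        logger.warning("all indicators degenerate in group %r; uniform weights", group)
        w = np.full(len(codes), 1.0 / len(codes))
        return WeightVector(dict(zip(codes, w)), dict(zip(codes, entropies)),
                            group, degenerate=True)
    w = divergence / total_div
    return WeightVector(
        dict(zip(codes, map(float, w))),
        dict(zip(codes, map(float, entropies))),
        group,
        degenerate=False,
    )


def weights_per_dimension(
    matrix: IndicatorMatrix,
    polarities: dict[str, Polarity | str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    mode: str = "per_dimension",
) -> dict[Dimension, WeightVector]:
    """Entropy weights computed within each justice dimension.

    ``mode="whole_table"`` estimates entropy weights jointly over all
    columns and renormalizes within each dimension (sensitivity-analysis
    variant); the default matches the per-dimension block structure of the
    published weight tables.
    """
    normalized = normalize(matrix, polarities, bounds)
    return weights_per_dimension_from_normalized(normalized, matrix.schema, mode)


def weights_per_dimension_from_normalized(
    normalized: NormalizedMatrix,
    schema: list[IndicatorSpec],
    mode: str = "per_dimension",
) -> dict[Dimension, WeightVector]:
    if mode not in ("per_dimension", "whole_table"):
        raise ConfigError(f"unknown weighting mode {mode!r}")
    out: dict[Dimension, WeightVector] = {}
    if mode == "whole_table":
        full = entropy_weights(normalized, group="whole_table")
        for dim in DIMENSIONS:
            codes = group_codes(schema, dim)
            if not codes:
                raise SchemaError(f"dimension {dim.value!r} has no indicators")
            sub = np.array([full.weights[c] for c in codes])
            total = sub.sum()
            if total <= 1e-15:
                sub = np.full(len(codes), 1.0 / len(codes))
                degenerate = True
            else:
                sub = sub / total
                degenerate = False
            out[dim] = WeightVector(
                dict(zip(codes, map(float, sub))),
                {c: full.entropies[c] for c in codes},
                group=dim.value,
                degenerate=degenerate or full.degenerate,
            )
        return out
    for dim in DIMENSIONS:
        codes = group_codes(schema, dim)
        if not codes:
            raise SchemaError(f"dimension {dim.value!r} has no indicators")
        out[dim] = entropy_weights(normalized, codes, group=dim.value)
    return out


def reference_weights(schema: list[IndicatorSpec]) -> dict[Dimension, WeightVector]:
    """The schema's stored reference weights as injectable WeightVectors.

    Renormalized exactly to sum 1 within each dimension (the printed values
    carry three decimals).  Used for the fixed-weight pipeline mode and for
    synthetic-data back-filling.
    """
    out: dict[Dimension, WeightVector] = {}
    for dim in DIMENSIONS:
        specs = [s for s in schema if s.dimension is dim]
        if any(s.reference_weight is None for s in specs):
            raise ConfigError(
                f"schema has no reference weights for dimension {dim.value!r}"
            )
        w = np.array([s.reference_weight for s in specs], dtype=float)
        w = w / w.sum()
        out[dim] = WeightVector(
            {s.code: float(x) for s, x in zip(specs, w)},
            {s.code: float("nan") for s in specs},
            group=dim.value,
        )
    return out
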