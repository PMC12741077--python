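"""Criterion-layer justice indices and the composite Climate Justice Index.

Each justice dimension k gets a per-unit criterion index
``C_k(i) = sum_j Y_ij * w_j`` over that dimension's indicators; the three
criterion indices (DJ = distributive, RJ = recognition, PJ = procedural)
are combined linearly into the Climate Justice Index

    CJI_i = alpha * DJ_i + beta * RJ_i + gamma * PJ_i,

with nonnegative weights summing to 1 so CJI stays in [0, 1] and levels are
comparable across runs.  Higher CJI means a more just spatial unit.  The
dimension weights default to 1/3 each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError
from .schema import DIMENSIONS, Dimension
from .weighting import NormalizedMatrix, WeightVector

#: Per-unit score column names, in canonical dimension order, plus composite.
SCORE_COLUMNS = ("dj", "rj", "pj")
_DIM_TO_COLUMN = dict(zip(DIMENSIONS, SCORE_COLUMNS))

EQUAL_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclass
class JusticeScores:
    """Per-unit DJ/RJ/PJ criterion indices and composite CJI."""

    table: pd.DataFrame                 # index unit_id; columns dj, rj, pj, cji
    weights_used: tuple[float, float, float]

    @property
    def units(self) -> list[str]:
        return list(self.table.index)

    def triples(self) -> pd.DataFrame:
        """The (dj, rj, pj) block used for clustering."""
        return self.table[list(SCORE_COLUMNS)]


def criterion_index(normalized: NormalizedMatrix, weights: WeightVector) -> pd.Series:
    """Weighted sum of normalized indicators over one dimension's columns."""
    missing = [c for c in weights.codes if c not in normalized.Y.columns]
    if missing:
        raise ConsistencyError(
            f"weights refer to absent column(s): {', '.join(missing)}"
        )
    Y = normalized.Y[weights.codes].to_numpy(float)
    w = weights.as_array()
    return pd.Series(Y @ w, index=normalized.Y.index, name=weights.group or "score")


def validate_cji_weights(alpha: float, beta: float, gamma: float) -> None:
    if min(alpha, beta, gamma) < 0:
        raise ConfigError("CJI weights must be nonnegative")
    if abs(alpha + beta + gamma - 1.0) > 1e-9:
        raise ConfigError(
            f"CJI weights must sum to 1 (got {alpha + beta + gamma})"
        )


def climate_justice_index(
    dj: pd.Series | np.ndarray,
    rj: pd.Series | np.ndarray,
    pj: pd.Series | np.ndarray,
    alpha: float = EQUAL_WEIGHTS[0],
    beta: float = EQUAL_WEIGHTS[1],
    gamma: float = EQUAL_WEIGHTS[2],
) -> pd.Series | np.ndarray:
    """CJI = alpha*DJ + beta*RJ + gamma*PJ (weights on the unit simplex)."""
    validate_cji_weights(alpha, beta, gamma)
    return alpha * dj + beta * rj + gamma * pj


def compute_scores(
    normalized: NormalizedMatrix,
    weights_by_dimension: dict[Dimension, WeightVector],
    alpha: float = EQUAL_WEIGHTS[0],
    beta: float = EQUAL_WEIGHTS[1],
    gamma: float = EQUAL_WEIGHTS[2],
) -> JusticeScores:
    """All three criterion indices plus the composite CJI for one table."""
    validate_cji_weights(alpha, beta, gamma)
    cols = {}
    for dim in DIMENSIONS:
        if dim not in weights_by_dimension:
            raise ConsistencyError(f"missing weights for dimension {dim.value!r}")
        cols[_DIM_TO_COLUMN[dim]] = criterion_index(
            normalized, weights_by_dimension[dim]
        )
    table = pd.DataFrame(cols)
    table.index.name = "unit_id"
    table["cji"] = climate_justice_index(
        table["dj"], table["rj"], table["pj"], alpha, beta, gamma
    )
    return JusticeScores(table, (alpha, beta, gamma))
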