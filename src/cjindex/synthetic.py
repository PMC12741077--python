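"""Synthetic spatial-unit generator emulating the Fuzhou study structure.

The original per-unit indicator data are not publicly available, so this
module generates tables with the statistical structure the analysis
assumes: two space-type populations (linear street units and areal
park/square units), per-unit justice-score triples drawn from a planted
mixture of four deficit clusters (Gaussian noise around fixed centroids,
clipped to [0, 1]), and — via :func:`backfill_indicators` — raw indicator
columns that are exactly consistent with a given weight vector and the
polarity-aware normalization, so the full pipeline can be validated
end-to-end against known ground truth.

The reference presets plant the cluster centroids and exact member counts
reported for the Fuzhou case study (linear: counts 108/84/76/19; areal:
13/11/11/19), with default noise sd 0.05.  (The published linear typology
table is internally inconsistent — its counts sum to 287 while its printed
total is 279; the preset follows the per-cluster counts.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .schema import (
    DIMENSIONS,
    Dimension,
    IndicatorMatrix,
    IndicatorSpec,
    Polarity,
    SpaceType,
    default_schema,
    group_codes,
)
from .scoring import SCORE_COLUMNS
from .weighting import WeightVector

logger = logging.getLogger(__name__)

#: Plausible raw ranges per indicator code, used only to back-transform
#: normalized values into raw columns (units: SVF/GVI/coverage as fractions,
#: canyon ratio H/W, LST in deg C, aggregation as a 0-100 activity index,
#: sensitive share as a fraction, prices in CNY/m^2, facilities as counts).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "C1": (0.05, 0.95),     # Sky View Factor
    "C2": (0.2, 3.0),       # Street Canyon Ratio (H/W)
    "C3": (0.0, 0.6),       # Green View Index
    "C4": (28.0, 45.0),     # Land Surface Temperature
    "C5": (0.0, 100.0),     # Population Aggregation
    "C6": (0.05, 0.45),     # Proportion of Sensitive Population
    "C7": (8000.0, 60000.0),  # Housing Prices
    "C8": (0.0, 40.0),      # Indoor Cooling Facilities
    "C9": (0.0, 25.0),      # Medical Facilities
    "C10": (0.0, 0.9),      # Vegetation Coverage
    "C11": (28.0, 45.0),    # Land Surface Temperature
    "C12": (0.0, 100.0),    # Population Aggregation
    "C13": (0.05, 0.45),    # Proportion of Sensitive Population
    "C14": (8000.0, 60000.0),  # Housing Prices
    "C15": (0.0, 40.0),     # Indoor Cooling Facilities
    "C16": (0.0, 25.0),     # Medical Facilities
}

# Planted mixtures reproducing the published typology tables:
# per-cluster (DJ, RJ, PJ) centroids and exact member counts.
LINEAR_CENTROIDS = np.array([
    [0.280, 0.213, 0.946],   # distributive & recognition deficit
    [0.362, 0.733, 0.938],   # distributive deficit
    [0.408, 0.425, 0.934],   # justice-balanced
    [0.279, 0.339, 0.429],   # systemic deficit
])
LINEAR_COUNTS = (108, 84, 76, 19)

AREAL_CENTROIDS = np.array([
    [0.874, 0.894, 0.912],   # all-dimension fulfilled
    [0.721, 0.372, 0.661],   # recognition deficit
    [0.457, 0.754, 0.747],   # distributive deficit
    [0.208, 0.192, 0.355],   # systemic deficit
])
AREAL_COUNTS = (13, 11, 11, 19)

DEFAULT_NOISE_SD = 0.05

PRESET_NAMES = ("linear_reference", "areal_reference", "null", "custom")


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario."""

    space_type: SpaceType
    m: int
    k: int
    centroids: np.ndarray                       # k x 3, in [0, 1]
    counts: tuple[int, ...] | None = None       # exact planted sizes
    proportions: tuple[float, ...] | None = None
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    indicator_backfill: bool = True
    minmax: dict[str, tuple[float, float]] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        self.space_type = SpaceType(self.space_type)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (self.k, 3):
            raise ConfigError(
                f"centroids shape {self.centroids.shape} != ({self.k}, 3)"
            )
        if np.any(self.centroids < 0) or np.any(self.centroids > 1):
            raise ConfigError("centroids must lie in [0, 1]^3")
        if self.m < self.k:
            raise ConfigError(f"m={self.m} < k={self.k}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.counts is not None:
            if len(self.counts) != self.k or sum(self.counts) != self.m:
                raise ConfigError("counts must have length k and sum to m")
            self.proportions = tuple(c / self.m for c in self.counts)
        if self.proportions is not None:
            if abs(sum(self.proportions) - 1.0) > 1e-9:
                raise ConfigError("mixture proportions must sum to 1")
        else:
            self.proportions = tuple(1.0 / self.k for _ in range(self.k))
        if not self.minmax:
            self.minmax = {
                s.code: DEFAULT_RANGES[s.code]
                for s in default_schema(self.space_type)
            }


@dataclass
class SyntheticTruth:
    """Ground truth accompanying one generated table."""

    config: ScenarioConfig
    cluster: pd.Series                  # unit_id -> planted cluster id
    scores: pd.DataFrame                # unit_id x (dj, rj, pj), post-clip
    Y: pd.DataFrame | None = None       # planted normalized indicators
    seed: int = 0


def preset(
    name: str,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    **overrides,
) -> ScenarioConfig:
    """Named scenario configurations.

    ``linear_reference`` / ``areal_reference`` plant the published linear
    and areal typologies (m=279 and m=54, k=4, exact counts); ``null`` is a
    single homogeneous cluster used for ANOVA calibration.  ``custom``
    requires explicit parameters via ``overrides``.
    """
    if name == "linear_reference":
        cfg = dict(space_type=SpaceType.LINEAR, m=sum(LINEAR_COUNTS), k=4,
                   centroids=LINEAR_CENTROIDS, counts=LINEAR_COUNTS)
    elif name == "areal_reference":
        cfg = dict(space_type=SpaceType.AREAL, m=54, k=4,
                   centroids=AREAL_CENTROIDS, counts=AREAL_COUNTS)
    elif name == "null":
        cfg = dict(space_type=SpaceType.LINEAR, m=279, k=1,
                   centroids=np.array([[0.5, 0.5, 0.5]]), counts=(279,))
    elif name == "custom":
        cfg = {}
    else:
        raise ConfigError(
            f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
        )
    cfg.update(overrides)
    cfg.setdefault("name", name)
    return ScenarioConfig(seed=seed, noise_sd=noise_sd, **cfg)


def _unit_ids(config: ScenarioConfig) -> list[str]:
    prefix = "LS" if config.space_type is SpaceType.LINEAR else "AS"
    width = max(4, len(str(config.m)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(config.m)]


def generate_scores(config: ScenarioConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw per-unit (DJ, RJ, PJ) triples from the planted mixture.

    Cluster sizes are exact when ``counts`` is given (multinomial draws from
    ``proportions`` otherwise); unit order is a seeded permutation so the
    table is not sorted by cluster.  Noise is Gaussian per coordinate,
    clipped to [0, 1]; sd 0 reproduces the centroids exactly.
    """
    rng = np.random.default_rng(config.seed)
    if config.counts is not None:
        labels = np.repeat(np.arange(config.k), config.counts)
    else:
        labels = rng.choice(config.k, size=config.m, p=config.proportions)
    labels = labels[rng.permutation(config.m)]
    scores = config.centroids[labels]
    if config.noise_sd > 0:
        scores = scores + rng.normal(0.0, config.noise_sd, size=scores.shape)
        scores = np.clip(scores, 0.0, 1.0)
    index = pd.Index(_unit_ids(config), name="unit_id")
    table = pd.DataFrame(scores, index=index, columns=list(SCORE_COLUMNS))
    truth = SyntheticTruth(
        config=config,
        cluster=pd.Series(labels, index=index, name="planted_cluster"),
        scores=table.copy(),
        seed=config.seed,
    )
    return table, truth


def backfill_indicators(
    truth: SyntheticTruth,
    schema: list[IndicatorSpec] | None = None,
    weights: dict[Dimension, WeightVector] | None = None,
    jitter_sd: float = 0.05,
) -> IndicatorMatrix:
    """Synthesize raw indicator columns consistent with planted scores.

    For each unit and dimension with target score C, the base solution sets
    every normalized indicator in the group to C (so the weighted sum is C
    exactly for any weights summing to 1).  Optional jitter is drawn in the
    weight vector's zero-sum directions and scaled to stay inside [0, 1],
    leaving the weighted sum within numerical precision of C; units whose
    base solution sits on the [0, 1] boundary keep the unjittered solution.
    Raw values are then obtained by inverting the polarity-appropriate
    min-max normalization over the configured (min, max) ranges.

    The planted normalized matrix is stored on ``truth.Y``.
    """
    config = truth.config
    if schema is None:
        schema = default_schema(config.space_type)
    if weights is None:
        from .weighting import reference_weights
        weights = reference_weights(schema)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    codes = [s.code for s in schema]
    Y = pd.DataFrame(0.0, index=truth.scores.index, columns=codes)
    n_skipped = 0
    for dim, col in zip(DIMENSIONS, SCORE_COLUMNS):
        gcodes = group_codes(schema, dim)
        w = weights[dim].as_array(gcodes)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"injected weights for {dim.value!r} sum to {w.sum()}, not 1"
            )
        C = truth.scores[col].to_numpy(float)
        block = np.tile(C[:, None], (1, len(gcodes)))
        if jitter_sd > 0 and len(gcodes) > 1:
            u = rng.normal(0.0, jitter_sd, size=block.shape)
            # project each row onto the zero-sum subspace: (u . w) w / (w . w)
            z = u - np.outer(u @ w, w) / float(w @ w)
            # largest per-row scale t in [0, 1] keeping block + t z in [0, 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                up_room = np.where(z > 0, (1.0 - block) / z, np.inf)
                dn_room = np.where(z < 0, -block / z, np.inf)
            t = np.minimum(1.0, np.minimum(up_room, dn_room).min(axis=1))
            infeasible = ~(t > 0)
            n_skipped += int(infeasible.sum())
            t = np.where(infeasible, 0.0, t)
            block = block + t[:, None] * z
        Y[gcodes] = block
    if n_skipped:
        logger.warning(
            "jitter skipped for %d unit-dimension(s) at the [0, 1] boundary",
            n_skipped,
        )

    X = pd.DataFrame(index=Y.index, columns=codes, dtype=float)
    for spec in schema:
        lo, hi = config.minmax[spec.code]
        y = Y[spec.code].to_numpy(float)
        if spec.polarity is Polarity.POSITIVE:
            X[spec.code] = lo + y * (hi - lo)
        else:
            X[spec.code] = hi - y * (hi - lo)
    truth.Y = Y
    return IndicatorMatrix(list(Y.index), schema, X.to_numpy(float))
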