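"""End-to-end orchestration: simulate/load -> weights -> scores -> levels ->
typology -> report.

`run_pipeline` executes every stage of the assessment with one seeded
configuration and writes a per-unit results CSV, a machine-readable JSON
report (weights, entropies, break points, level proportions, typology
centroids/counts, ANOVA F/p) and, when geometries are supplied, a GeoJSON
with the same properties.  Re-running with the same config and seed
produces byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as cjio
from .classify import (
    DEFAULT_LEVELS,
    assign_levels,
    jenks_breaks,
    level_summary,
)
from .errors import CJIndexError, ConfigError, ConsistencyError
from .schema import (
    DIMENSIONS,
    Dimension,
    IndicatorMatrix,
    default_schema,
)
from .scoring import SCORE_COLUMNS, JusticeScores, compute_scores
from .synthetic import PRESET_NAMES, backfill_indicators, generate_scores, preset
from .typology import (
    DEFAULT_RESTARTS,
    DEFAULT_THETA,
    ClusterTypology,
    kmeans_partition,
)
from .weighting import (
    WeightVector,
    normalize,
    reference_weights,
    weights_per_dimension_from_normalized,
)

logger = logging.getLogger(__name__)

SCORE_VECTORS = (*SCORE_COLUMNS, "cji")


@dataclass
class RunConfig:
    """Fully validated configuration of one pipeline run."""

    # input: either a CSV path or a synthetic preset
    input_csv: str | None = None
    geojson: str | None = None
    preset_name: str | None = None
    noise_sd: float = 0.05
    # weighting
    weight_mode: str = "entropy"            # "entropy" | "fixed"
    fixed_weights_file: str | None = None   # JSON {code: weight}; default = schema reference
    weighting_scope: str = "per_dimension"  # | "whole_table"
    polarity_overrides: dict[str, str] = field(default_factory=dict)
    norm_bounds: str = "empirical"          # | "configured" (synthetic ranges)
    # composite index
    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0
    gamma: float = 1.0 / 3.0
    # classification
    jenks_k: int = 5
    level_labels: tuple[str, ...] | None = None
    # typology
    cluster_k: int = 4
    restarts: int = DEFAULT_RESTARTS
    theta: float = DEFAULT_THETA
    label_mode: str = "absolute"
    standardize: bool = False
    # run control
    seed: int = 20250101
    out_dir: str = "results"
    prefix: str = "results"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.preset_name is None):
            raise ConfigError("exactly one of input_csv or preset_name is required")
        if self.preset_name is not None and self.preset_name not in PRESET_NAMES:
            raise ConfigError(f"unknown preset {self.preset_name!r}")
        if self.weight_mode not in ("entropy", "fixed"):
            raise ConfigError(f"unknown weight mode {self.weight_mode!r}")
        if self.norm_bounds not in ("empirical", "configured"):
            raise ConfigError(f"unknown norm_bounds {self.norm_bounds!r}")
        if self.norm_bounds == "configured" and self.preset_name is None:
            raise ConfigError("norm_bounds='configured' requires a synthetic preset")


def load_fixed_weights(
    path: str | Path, schema
) -> dict[Dimension, WeightVector]:
    """Read injected weights from a JSON file mapping code -> weight.

    Weights are grouped by the schema's dimensions and renormalized to sum
    to 1 within each group.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    out: dict[Dimension, WeightVector] = {}
    for dim in DIMENSIONS:
        specs = [s for s in schema if s.dimension is dim]
        missing = [s.code for s in specs if s.code not in raw]
        if missing:
            raise ConfigError(
                f"{path}: missing weight(s) for {', '.join(missing)}"
            )
        w = np.array([float(raw[s.code]) for s in specs])
        if np.any(w < 0) or w.sum() <= 0:
            raise ConfigError(f"{path}: weights for {dim.value!r} invalid")
        w = w / w.sum()
        out[dim] = WeightVector(
            {s.code: float(x) for s, x in zip(specs, w)},
            {s.code: float("nan") for s in specs},
            group=dim.value,
        )
    return out


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage's name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, CJIndexError):
                raise CJIndexError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, CJIndexError):
                exc.args = (f"stage {name!r}: {exc.args[0]}",) + exc.args[1:]
            return False

    return _Ctx()


def classify_scores(
    scores: JusticeScores, k: int, labels: tuple[str, ...] | None
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Jenks levels for each score vector (DJ, RJ, PJ, CJI) separately.

    If a score vector has fewer distinct values than k (e.g. noise-free
    synthetic data), k is reduced to the number of distinct values for that
    vector, with a warning.
    """
    level_cols = {}
    level_report: dict[str, Any] = {}
    for col in SCORE_VECTORS:
        v = scores.table[col]
        u = int(pd.unique(v.round(15)).size)
        k_eff = min(k, int(np.unique(v.to_numpy()).size))
        if k_eff < k:
            logger.warning(
                "score %r has only %d distinct values; using k=%d", col, u, k_eff
            )
        use_labels = labels
        if use_labels is None:
            use_labels = DEFAULT_LEVELS if k == 5 else None
        if use_labels is not None and k_eff < len(use_labels):
            use_labels = tuple(use_labels[:k_eff])
        bs = jenks_breaks(v.to_numpy(), k_eff, use_labels)
        lv = assign_levels(v, bs)
        level_cols[f"level_{col}"] = lv
        level_report[col] = {
            "k": bs.k,
            "breaks": [float(b) for b in bs.breaks],
            "sdcm": bs.objective,
            **level_summary(lv, bs.labels),
        }
    return pd.DataFrame(level_cols, index=scores.table.index), level_report


def assemble_results(
    scores: JusticeScores,
    levels: pd.DataFrame,
    typology: ClusterTypology,
    space_type: str,
) -> pd.DataFrame:
    """Join per-unit scores, levels and cluster membership; ids must agree."""
    for other, what in ((levels.index, "levels"), (typology.assignment.index, "typology")):
        if not scores.table.index.equals(other):
            raise ConsistencyError(f"unit ids of scores and {what} differ")
    results = scores.table.copy()
    results.insert(0, "space_type", space_type)
    results = results.join(levels)
    results["cluster"] = typology.assignment
    results["deficit_label"] = [
        typology.labels[int(c)] for c in typology.assignment
    ]
    return results


def make_report(
    config: RunConfig,
    matrix: IndicatorMatrix,
    weights: dict[Dimension, WeightVector],
    scores: JusticeScores,
    level_report: dict[str, Any],
    typology: ClusterTypology,
) -> dict[str, Any]:
    """Machine-readable run report mirroring the published table formats:
    per-dimension level proportions, comprehensive level counts, and the
    typology block (per-cluster centroids, counts, total, ANOVA F/p)."""
    cfg = asdict(config)
    cfg["level_labels"] = list(config.level_labels) if config.level_labels else None
    return {
        "config": cfg,
        "space_type": matrix.space_type.value,
        "m": matrix.m,
        "indicators": [s.code for s in matrix.schema],
        "weights": {
            "mode": config.weight_mode,
            "scope": config.weighting_scope,
            "by_dimension": {
                dim.value: {
                    "weights": weights[dim].weights,
                    "entropies": weights[dim].entropies,
                    "degenerate": weights[dim].degenerate,
                }
                for dim in DIMENSIONS
            },
        },
        "cji_weights": {
            "alpha": scores.weights_used[0],
            "beta": scores.weights_used[1],
            "gamma": scores.weights_used[2],
        },
        "levels": level_report,
        "typology": {
            "k": typology.k,
            "counts": typology.counts,
            "total": typology.m,
            "centroids": typology.centroids.to_dict(orient="index"),
            "labels": {str(c): lab for c, lab in typology.labels.items()},
            "anova": {
                dim: {"F": f, "p": p} for dim, (f, p) in typology.anova.items()
            },
            "inertia": typology.inertia,
            "seed": typology.seed,
            "restarts": typology.restarts,
        },
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write artifacts; returns a manifest dict
    with the report inline and the paths of all files written."""
    truth = None
    bounds = None

    with _stage("input"):
        if config.preset_name is not None:
            scenario = preset(
                config.preset_name, seed=config.seed, noise_sd=config.noise_sd
            )
            _, truth = generate_scores(scenario)
            schema = default_schema(scenario.space_type)
            matrix = backfill_indicators(truth, schema, reference_weights(schema))
            if config.norm_bounds == "configured":
                bounds = scenario.minmax
        else:
            matrix = cjio.load_indicator_table(config.input_csv)
            schema = matrix.schema
        geometries = (
            cjio.read_geometries(config.geojson) if config.geojson else None
        )

    with _stage("normalize"):
        normalized = normalize(matrix, config.polarity_overrides or None, bounds)

    with _stage("weights"):
        if config.weight_mode == "entropy":
            weights = weights_per_dimension_from_normalized(
                normalized, schema, config.weighting_scope
            )
        elif config.fixed_weights_file:
            weights = load_fixed_weights(config.fixed_weights_file, schema)
        else:
            weights = reference_weights(schema)

    with _stage("score"):
        scores = compute_scores(
            normalized, weights, config.alpha, config.beta, config.gamma
        )

    with _stage("classify"):
        levels, level_report = classify_scores(
            scores, config.jenks_k, config.level_labels
        )

    with _stage("typology"):
        typology = kmeans_partition(
            scores,
            k=config.cluster_k,
            seed=config.seed,
            restarts=config.restarts,
            standardize=config.standardize,
            theta=config.theta,
            label_mode=config.label_mode,
        )

    with _stage("report"):
        results = assemble_results(
            scores, levels, typology, matrix.space_type.value
        )
        report = make_report(
            config, matrix, weights, scores, level_report, typology
        )
        manifest = cjio.write_results(
            results, report, config.out_dir, geometries, prefix=config.prefix
        )
        if truth is not None:
            truth_path = Path(config.out_dir) / f"{config.prefix}_truth.csv"
            truth_df = truth.scores.copy()
            truth_df["planted_cluster"] = truth.cluster
            truth_df.reset_index().to_csv(
                truth_path, index=False, float_format=cjio.CSV_FLOAT_FORMAT
            )
            manifest["truth_csv"] = str(truth_path)

    manifest["report"] = report
    return manifest
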