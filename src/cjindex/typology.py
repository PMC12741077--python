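"""Deficit typology: K-means over (DJ, RJ, PJ) triples, ANOVA, labeling.

Spatial units are clustered on their three justice scores (k-means++, best
of many restarts) to identify recurring deficit patterns.  One-way ANOVA
per dimension checks that the clusters actually differ; each cluster is
then labeled by which dimensions fall below a deficit threshold — e.g. a
cluster whose distributive and recognition centroids are low but whose
procedural centroid is high becomes a "Distributive & Recognition Justice
Deficit" type, and a cluster low on all three is a "Systemic Justice
Deficit".

Clusters are reported in descending size order so typology tables are
stable across runs; the labeling rule is explicit configuration (absolute
threshold by default, relative-to-column-mean as an alternative) because
verbal typologies in the literature are rarely derivable from one rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import ConfigError, InputError
from .schema import DIMENSIONS, dimension_name

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20250101
DEFAULT_RESTARTS = 50
DEFAULT_THETA = 0.5

FULFILLED_LABEL = "All-Dimension Justice Fulfilled"
SYSTEMIC_LABEL = "Systemic Justice Deficit"

_SCORE_COLUMNS = ("dj", "rj", "pj")


@dataclass
class ClusterTypology:
    """Result of clustering + validation + labeling for one space type."""

    k: int
    assignment: pd.Series               # unit_id -> cluster id (0..k-1)
    centroids: pd.DataFrame             # k rows x (dj, rj, pj)
    counts: list[int]
    inertia: float
    seed: int
    restarts: int
    anova: dict[str, tuple[float, float]] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return int(sum(self.counts))


def _as_triples(scores) -> pd.DataFrame:
    if hasattr(scores, "triples"):
        scores = scores.triples()
    df = pd.DataFrame(scores)
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"score table lacks column(s): {', '.join(missing)}")
    return df[list(_SCORE_COLUMNS)]


def kmeans_partition(
    scores,
    k: int = 4,
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
    standardize: bool = False,
    theta: float = DEFAULT_THETA,
    label_mode: str = "absolute",
) -> ClusterTypology:
    """Cluster per-unit (DJ, RJ, PJ) triples into k deficit types.

    Runs k-means++ with ``restarts`` independent initializations and keeps
    the lowest-inertia solution; deterministic given ``seed``.  Clusters are
    renumbered in descending size order (ties broken by descending centroid
    mean).  ANOVA per dimension and deficit labels are attached.

    ``standardize=True`` z-scores each dimension before clustering (the
    scores are already on [0, 1], so this is off by default); centroids are
    always reported on the original score scale.
    """
    df = _as_triples(scores)
    m = len(df)
    if not (m >= k >= 2):
        raise ConfigError(f"need m >= k >= 2 (m={m}, k={k})")
    X = df.to_numpy(float)
    fit_X = X
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        fit_X = (X - X.mean(axis=0)) / sd

    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        random_state=int(seed) % (2**31),
    ).fit(fit_X)
    raw_assign = km.labels_

    # report centroids on the raw score scale as member means
    raw_centroids = np.vstack(
        [X[raw_assign == c].mean(axis=0) for c in range(k)]
    )
    raw_counts = np.bincount(raw_assign, minlength=k)

    # descending size order; deterministic tie-break by centroid mean then values
    order = sorted(
        range(k),
        key=lambda c: (-raw_counts[c], -raw_centroids[c].mean(), tuple(-raw_centroids[c])),
    )
    relabel = {old: new for new, old in enumerate(order)}
    assignment = pd.Series(
        [relabel[c] for c in raw_assign], index=df.index, name="cluster"
    )
    centroids = pd.DataFrame(
        raw_centroids[order], columns=list(_SCORE_COLUMNS),
        index=pd.RangeIndex(k, name="cluster"),
    )
    counts = [int(raw_counts[c]) for c in order]

    typ = ClusterTypology(
        k=k,
        assignment=assignment,
        centroids=centroids,
        counts=counts,
        inertia=float(km.inertia_),
        seed=int(seed),
        restarts=int(restarts),
    )
    typ.anova = anova_table(df, assignment)
    typ.labels = label_typology(typ, theta=theta, mode=label_mode)
    return typ


def anova_by_cluster(values, assignment) -> tuple[float, float]:
    """One-way ANOVA of one dimension's values across clusters.

    F = (SSB / (k-1)) / (SSW / (m-k)), p from the F(k-1, m-k) distribution.
    A perfectly separated grouping (SSW = 0 with SSB > 0) is reported as
    F = +inf, p = 0 with a warning; identical groups give F = 0, p = 1.
    """
    v = np.asarray(values, dtype=float).ravel()
    a = np.asarray(assignment).ravel()
    if len(v) != len(a):
        raise InputError("values and assignment lengths differ")
    clusters = np.unique(a)
    k, m = len(clusters), len(v)
    if k < 2:
        raise InputError("ANOVA needs at least two clusters")
    if m - k < 1:
        raise InputError("ANOVA needs a positive error degree of freedom")
    grand = v.mean()
    ssb = 0.0
    ssw = 0.0
    for c in clusters:
        seg = v[a == c]
        ssb += seg.size * (seg.mean() - grand) ** 2
        ssw += float(np.sum((seg - seg.mean()) ** 2))
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        logger.warning("zero within-cluster variance; F reported as +inf")
        return float("inf"), 0.0
    F = (ssb / (k - 1)) / (ssw / (m - k))
    p = float(stats.f.sf(F, k - 1, m - k))
    return float(F), p


def anova_table(scores, assignment) -> dict[str, tuple[float, float]]:
    """Per-dimension (F, p) for the three justice scores."""
    df = _as_triples(scores)
    return {
        dim.value: anova_by_cluster(df[col], assignment)
        for dim, col in zip(DIMENSIONS, _SCORE_COLUMNS)
    }


def label_typology(
    typology: ClusterTypology,
    theta: float | dict[str, float] = DEFAULT_THETA,
    mode: str = "absolute",
) -> dict[int, str]:
    """Deficit labels from cluster centroids.

    A dimension is *deficient* in a cluster when its centroid is below the
    threshold: an absolute value (default 0.5, optionally per dimension) or,
    with ``mode="relative"``, the across-cluster mean of that dimension's
    centroid column.  All three deficient -> systemic deficit; none ->
    fulfilled; otherwise the deficient dimensions are named.  The label
    function depends only on centroid values, so it is invariant to cluster
    reordering.
    """
    if mode not in ("absolute", "relative"):
        raise ConfigError(f"unknown labeling mode {mode!r}")
    cent = typology.centroids
    if mode == "relative":
        thresholds = cent.mean(axis=0)
    elif isinstance(theta, dict):
        thresholds = pd.Series(
            {col: float(theta[dim.value]) for dim, col in zip(DIMENSIONS, _SCORE_COLUMNS)}
        )
    else:
        thresholds = pd.Series({col: float(theta) for col in _SCORE_COLUMNS})

    labels: dict[int, str] = {}
    for cid, row in cent.iterrows():
        deficient = [
            dim for dim, col in zip(DIMENSIONS, _SCORE_COLUMNS)
            if row[col] < thresholds[col]
        ]
        if len(deficient) == len(DIMENSIONS):
            labels[int(cid)] = SYSTEMIC_LABEL
        elif not deficient:
            labels[int(cid)] = FULFILLED_LABEL
        else:
            names = " & ".join(dimension_name(d) for d in deficient)
            labels[int(cid)] = f"{names} Justice Deficit"
    return labels
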