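"""Jenks natural-breaks classification of score vectors into ordered levels.

Jenks (Fisher's) natural breaks is the optimal contiguous partition of a
sorted 1-D variable into k classes minimizing the sum of squared deviations
from class means (SDCM).  ``jenks_breaks`` solves it exactly by dynamic
programming over the *distinct* values (so heavy ties can never straddle a
class boundary or empty a class); ``jenks_oracle`` is an independent
exhaustive-enumeration check for small inputs.

Conventions, stated explicitly because implementations differ:

* class intervals are right-closed — a value equal to a break belongs to
  the lower class;
* SDCM ties are broken toward the partition whose first class is smallest
  (lexicographically smallest class sizes);
* default is k=5 with levels Low / Lower / Medium / Higher / High, "Low"
  meaning least justice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ClassificationError, ConfigError

logger = logging.getLogger(__name__)

DEFAULT_LEVELS: tuple[str, ...] = ("Low", "Lower", "Medium", "Higher", "High")


@dataclass
class BreakSet:
    """A fitted k-class natural-breaks partition."""

    k: int
    breaks: np.ndarray          # ascending class upper bounds, length k
    objective: float            # SDCM of the induced partition
    labels: tuple[str, ...]
    fitted_min: float
    fitted_max: float

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        if len(self.breaks) != self.k:
            raise ClassificationError("breaks length must equal k")
        if np.any(np.diff(self.breaks) <= 0):
            raise ClassificationError("breaks must be strictly ascending")
        if len(self.labels) != self.k:
            raise ConfigError("labels length must equal k")


def _prepare(values, k: int, labels) -> tuple[np.ndarray, tuple[str, ...]]:
    v = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ClassificationError("values must be finite")
    if k < 2:
        raise ConfigError(f"class count k={k} must be >= 2")
    if labels is None:
        labels = DEFAULT_LEVELS if k == 5 else tuple(f"L{i+1}" for i in range(k))
    if len(labels) != k:
        raise ConfigError("labels length must equal k")
    return v, tuple(labels)


def _sdcm_terms(uniq: np.ndarray, counts: np.ndarray):
    """Prefix sums giving the weighted SSE of any contiguous value range."""
    cw = np.concatenate(([0.0], np.cumsum(counts)))
    cwx = np.concatenate(([0.0], np.cumsum(counts * uniq)))
    cwx2 = np.concatenate(([0.0], np.cumsum(counts * uniq * uniq)))

    def sse(i: int, j: int) -> float:  # half-open [i, j) over unique values
        w = cw[j] - cw[i]
        s = cwx[j] - cwx[i]
        return max(0.0, (cwx2[j] - cwx2[i]) - s * s / w)

    return sse


def jenks_breaks(values, k: int, labels=None) -> BreakSet:
    """Optimal k-class natural breaks of a real vector (exact DP).

    Requires at least k distinct values.  Runs in O(k * u^2) for u distinct
    values, which is instantaneous at the few-hundred-unit scale this
    pipeline works at.
    """
    v, labels = _prepare(values, k, labels)
    uniq, counts = np.unique(v, return_counts=True)
    u = len(uniq)
    if u < k:
        raise ClassificationError(
            f"need at least k={k} distinct values, got {u}"
        )
    sse = _sdcm_terms(uniq, counts.astype(float))

    # best[c][i] = minimal SDCM of partitioning uniq[i:] into c classes
    best = np.full((k + 1, u + 1), np.inf)
    best[1, :u] = [sse(i, u) for i in range(u)]
    for c in range(2, k + 1):
        # last admissible start leaves c-1 values for the remaining classes
        for i in range(u - c + 1):
            ends = np.arange(i + 1, u - c + 2)
            costs = np.array([sse(i, e) + best[c - 1, e] for e in ends])
            best[c, i] = costs.min()

    # Reconstruct left to right, picking the smallest feasible class end at
    # each step: this yields the lexicographically smallest class sizes
    # among all SDCM-optimal partitions.
    bounds: list[int] = []
    i = 0
    for c in range(k, 1, -1):
        for e in range(i + 1, u - c + 2):
            if sse(i, e) + best[c - 1, e] == best[c, i]:
                bounds.append(e)
                i = e
                break
    breaks = np.array([uniq[b - 1] for b in bounds] + [uniq[-1]])
    objective = float(best[k, 0])
    return BreakSet(k, breaks, objective, labels, float(uniq[0]), float(uniq[-1]))


def jenks_oracle(values, k: int, labels=None, max_n: int = 15) -> BreakSet:
    """Exhaustive-enumeration natural breaks for small n (test oracle).

    Enumerates every contiguous partition of the sorted values into k
    non-empty classes (skipping partitions that would split tied values,
    which no threshold classification can realize) and returns the
    SDCM-minimal one under the same smallest-first-class tie rule.
    """
    v, labels = _prepare(values, k, labels)
    n = len(v)
    if n > max_n:
        raise ClassificationError(f"oracle refuses n={n} > {max_n}")
    if len(np.unique(v)) < k:
        raise ClassificationError(f"need at least k={k} distinct values")
    sv = np.sort(v)
    best_obj = np.inf
    best_bounds: tuple[int, ...] | None = None
    for bounds in combinations(range(1, n), k - 1):
        if any(sv[b - 1] == sv[b] for b in bounds):
            continue  # splits a tie: not realizable by thresholds
        edges = (0, *bounds, n)
        obj = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            seg = sv[a:b]
            obj += float(np.sum((seg - seg.mean()) ** 2))
        # combinations() is lexicographic, so strict improvement keeps the
        # smallest-first-class optimum
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_bounds = bounds
    assert best_bounds is not None
    breaks = np.array([sv[b - 1] for b in best_bounds] + [sv[-1]])
    return BreakSet(k, breaks, best_obj, labels, float(sv[0]), float(sv[-1]))


def assign_levels(values, breakset: BreakSet) -> pd.Series | np.ndarray:
    """Map each value to its level label (right-closed class intervals).

    Values outside the fitted [min, max] range are assigned to the nearest
    end class with a warning.
    """
    index = values.index if isinstance(values, pd.Series) else None
    v = np.asarray(values, dtype=float).ravel()
    below = v < breakset.fitted_min
    above = v > breakset.fitted_max
    if below.any() or above.any():
        logger.warning(
            "%d value(s) outside fitted range [%g, %g]; clamped to end classes",
            int(below.sum() + above.sum()), breakset.fitted_min, breakset.fitted_max,
        )
    # side="left": v equal to a break lands on that break's own class
    idx = np.searchsorted(breakset.breaks, v, side="left")
    idx = np.clip(idx, 0, breakset.k - 1)
    out = np.array([breakset.labels[i] for i in idx], dtype=object)
    if index is not None:
        return pd.Series(out, index=index, name="level")
    return out


def sdcm_of_partition(values, breakset: BreakSet) -> float:
    """Recompute the SDCM induced by a BreakSet on data (invariant check)."""
    v = np.asarray(values, dtype=float).ravel()
    idx = np.clip(np.searchsorted(breakset.breaks, v, side="left"), 0, breakset.k - 1)
    total = 0.0
    for c in range(breakset.k):
        seg = v[idx == c]
        if seg.size:
            total += float(np.sum((seg - seg.mean()) ** 2))
    return total


def level_summary(levels, labels: tuple[str, ...]) -> dict[str, dict[str, float]]:
    """Counts and percentage shares per level, in level order."""
    levels = pd.Series(np.asarray(levels, dtype=object))
    m = len(levels)
    counts = {lab: int((levels == lab).sum()) for lab in labels}
    return {
        "counts": counts,
        "proportions_pct": {lab: 100.0 * c / m for lab, c in counts.items()},
    }
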