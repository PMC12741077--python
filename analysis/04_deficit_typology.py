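#!/usr/bin/env python
"""Cluster units into deficit types and validate with ANOVA.

K-means (k=4, 50 restarts) on the per-unit (DJ, RJ, PJ) triples, one-way
ANOVA per dimension across the clusters, and threshold-based deficit
labels.  Prints the typology table (centroids, counts, labels, F/p) and
compares the recovered partition with the planted ground truth.
"""

import sys
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cjindex.typology import kmeans_partition

SEED = 20250101
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    for name in ("linear_reference", "areal_reference"):
        table = pd.read_csv(OUT / f"{name}_scores.csv", index_col="unit_id")
        truth = pd.read_csv(OUT / f"{name}_truth.csv", index_col="unit_id")
        typ = kmeans_partition(table, k=4, seed=SEED, restarts=50)
        ari = adjusted_rand_score(truth["planted_cluster"], typ.assignment)
        print(f"{name}: k={typ.k}, inertia={typ.inertia:.4f}, "
              f"ARI vs planted={ari:.3f}")
        for cid in range(typ.k):
            c = typ.centroids.loc[cid]
            print(f"  cluster {cid}: n={typ.counts[cid]:<4d} "
                  f"DJ={c['dj']:.3f} RJ={c['rj']:.3f} PJ={c['pj']:.3f}  "
                  f"{typ.labels[cid]}")
        for dim, (F, p) in typ.anova.items():
            print(f"  ANOVA {dim}: F={F:.1f}, p={p:.2e}")
        out = typ.assignment.to_frame()
        out["deficit_label"] = [typ.labels[int(c)] for c in typ.assignment]
        path = OUT / f"{name}_typology.csv"
        out.reset_index().to_csv(path, index=False)
        print(f"  -> {path.name}")


if __name__ == "__main__":
    main()
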