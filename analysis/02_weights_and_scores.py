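#!/usr/bin/env python
"""Estimate entropy weights and per-unit justice scores.

Loads the simulated indicator tables, normalizes each indicator by its
polarity, estimates entropy weights within each justice dimension, and
computes per-unit DJ/RJ/PJ criterion indices and the equal-weight composite
Climate Justice Index.  Prints the estimated weights next to the published
reference weights and writes score tables under results/analysis/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import cjindex as cj
from cjindex.io import CSV_FLOAT_FORMAT
from cjindex.weighting import weights_per_dimension_from_normalized

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    for name in ("linear_reference", "areal_reference"):
        matrix = cj.load_indicator_table(OUT / f"{name}_indicators.csv")
        normalized = cj.normalize(matrix)
        weights = weights_per_dimension_from_normalized(normalized, matrix.schema)
        scores = cj.compute_scores(normalized, weights)
        path = OUT / f"{name}_scores.csv"
        scores.table.reset_index().to_csv(path, index=False,
                                          float_format=CSV_FLOAT_FORMAT)
        ref = {s.code: s.reference_weight for s in matrix.schema}
        print(f"{name}: entropy weights (reference in parentheses)")
        for dim in cj.DIMENSIONS:
            parts = ", ".join(
                f"{code}={w:.3f} ({ref[code]:.3f})"
                for code, w in weights[dim].weights.items()
            )
            print(f"  {dim.value:<13s} {parts}")
        print(f"  mean CJI {scores.table['cji'].mean():.3f} -> {path.name}")


if __name__ == "__main__":
    main()
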