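#!/usr/bin/env python
"""Classify justice scores into five Jenks natural-breaks levels.

Fits Jenks breaks separately per space type and per score vector (each
criterion index and the composite CJI), prints the per-level percentage
shares in the style of the published proportion tables, and writes the
level assignments under results/analysis/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cjindex.classify import assign_levels, jenks_breaks, level_summary

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SCORES = ("dj", "rj", "pj", "cji")


def main() -> None:
    for name in ("linear_reference", "areal_reference"):
        table = pd.read_csv(OUT / f"{name}_scores.csv", index_col="unit_id")
        levels = {}
        print(f"{name}: level shares (%) per score")
        header = None
        rows = {}
        for col in SCORES:
            bs = jenks_breaks(table[col].to_numpy(), 5)
            lv = assign_levels(table[col], bs)
            levels[f"level_{col}"] = lv
            shares = level_summary(lv, bs.labels)["proportions_pct"]
            header = header or list(shares)
            rows[col] = shares
        print("  " + " ".join(f"{h:>8s}" for h in ["score"] + header))
        for col, shares in rows.items():
            cells = " ".join(f"{shares[h]:8.2f}" for h in header)
            print(f"  {col:>8s} {cells}")
        path = OUT / f"{name}_levels.csv"
        pd.DataFrame(levels).reset_index().to_csv(path, index=False)
        print(f"  -> {path.name}")


if __name__ == "__main__":
    main()
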