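#!/usr/bin/env python
"""Trending ability: four-quadrant concordance and the four-zone error grid.

Builds consecutive-change pairs from results/cohort.csv, reports the 4Q
concordance rate (10% central exclusion) and zone percentages pooled and
for the two densely measured phases, and writes the 4Q figure.
"""

import json
from pathlib import Path

from coagree import delta_pairs, error_grid, four_quadrant, read_cohort
from coagree.plots import plot_trending

root = Path(__file__).resolve().parents[1] / "results"
cohort = read_cohort(root / "cohort.csv")
deltas = delta_pairs(cohort)
print(f"{len(deltas)} consecutive-change pairs "
      f"({cohort.n_measurements} rows − {cohort.n_patients} patients)")

results = {}
for label in ("all", "distal_anastomoses", "icu_pre_extubation",
              "baseline", "aortic_side_clamp"):
    subset = deltas if label == "all" else [d for d in deltas if d.phase == label]
    if not subset:
        results[label] = {"n_deltas": 0, "note": "no delta pairs"}
        continue
    fq = four_quadrant(subset, exclusion=10.0, mode="percent")
    grid = error_grid(subset, min_n=30)
    entry = {
        "n_deltas": len(subset),
        "concordance_rate": fq.concordance_rate,
        "n_excluded": fq.n_excluded,
    }
    if grid.reported:
        entry["zone_percentages"] = list(grid.zone_percentages)
    else:
        entry["zone_percentages"] = None
        entry["note"] = f"error grid suppressed: n={grid.n_deltas} < {grid.min_n}"
    results[label] = entry
    zp = (" / ".join(f"{z:.1f}%" for z in grid.zone_percentages)
          if grid.reported else "suppressed (too few pairs)")
    print(f"  {label:22s} n={len(subset):4d}  "
          f"concordance {fq.concordance_rate:5.1f}%  zones 1-4: {zp}")

(root / "trending.json").write_text(json.dumps(results, indent=2) + "\n")
plot_trending(deltas, four_quadrant(deltas, exclusion=10.0),
              root / "four_quadrant.png")
print(f"wrote {root / 'trending.json'} and four_quadrant.png")
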