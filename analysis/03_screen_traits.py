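#!/usr/bin/env python
"""Outlier-filter the trait table and screen traits with Kruskal–Wallis.

Reads results/traits.csv (from 02), removes tail observations outside
5%/95% quantile-regression lines per trait cell, then tests every
(trait, view) for treatment and variety effects.  Image traits are
flagged at p < 0.005.  Writes results/screening.csv and
results/outlier_report.csv.
"""

from pathlib import Path

import pandas as pd

from shootpheno.shape_traits import TRAIT_NAMES
from shootpheno.stats import (
    build_screening_tables,
    quantile_outlier_filter,
    to_long_table,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    traits = pd.read_csv(RESULTS / "traits.csv")
    long = to_long_table(traits, TRAIT_NAMES)
    filtered, report = quantile_outlier_filter(long)
    report.lines.to_csv(RESULTS / "outlier_report.csv", index=False)
    print(f"outlier filter removed {report.n_removed} of {len(long)} "
          f"trait observations (taus {report.taus})")

    screening = build_screening_tables(filtered)
    screening.to_csv(RESULTS / "screening.csv", index=False)
    sig = screening[screening["significant"]]
    print(f"{len(sig)}/{len(screening)} screening rows significant")
    treat = screening[screening["grouping"] == "treatment"]
    print("treatment screening (vertical view):")
    cols = ["trait_name", "H", "p_value", "significant"]
    print(treat[treat["view"] == "vertical"][cols].round(4).to_string(index=False))
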