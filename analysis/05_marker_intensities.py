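#!/usr/bin/env python
"""Imaging marker-intensity statistics: IQR outlier removal, max-scaling,
Wilcoxon shift tests between timepoints, SA-b-gal positive fractions and
pairwise marker correlations.
"""

from pathlib import Path

import numpy as np

from senkit import io, markers_img as mi

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    table = io.read_marker_table(BASE / "data" / "markers.csv")
    cleaned = mi.remove_outliers(table, factor=1.5)
    n_removed = int(cleaned[mi.marker_columns(cleaned)].isna().sum().sum())
    print(f"IQR filter removed {n_removed} intensity values")

    scaled = mi.max_scale(cleaned)
    for marker in ("p21", "p16", "SA_b_gal", "BrdU"):
        stat, p = mi.marker_shift_test(scaled, marker, "T0", "T2")
        print(f"{marker:9s} T0 vs T2: U={stat:9.0f}  p={p:.3g}")

    t0 = scaled.loc[scaled["timepoint"] == "T0", "SA_b_gal"].dropna()
    threshold = float(np.quantile(t0, 0.99))
    fracs = {tp: mi.positive_fraction(
        scaled.loc[scaled["timepoint"] == tp, "SA_b_gal"].dropna(),
        threshold) for tp in ("T0", "T1", "T2")}
    print("SA-b-gal positive fractions (threshold = T0 99th pct):",
          {k: f"{v:.1f}%" for k, v in fracs.items()})

    corr = mi.marker_correlations(scaled, "T2")
    corr.to_csv(BASE / "marker_correlations_T2.tsv", sep="\t")
    print("T2 marker Spearman correlations -> "
          "results/marker_correlations_T2.tsv")


if __name__ == "__main__":
    main()
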