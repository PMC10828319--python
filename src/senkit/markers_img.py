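"""Statistics for single-cell imaging marker intensities.

The pipeline order is fixed: per-marker, per-timepoint IQR outlier removal,
then max-scaling of each marker by its global (all-timepoints) maximum, then
shift tests / positivity fractions / pairwise correlations on the scaled
values.  Outlier removal is grouped within timepoints so that genuine
senescence-associated shifts between timepoints are not themselves deleted
as outliers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

ID_COLUMNS = ("cell_id", "timepoint")


def iqr_filter(values, factor: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence outlier removal: keep values within quartiles +- factor*IQR.

    Quartiles use type-7 (linear) interpolation.  Returns (kept values,
    boolean outlier mask aligned with the input).  Empty input yields empty
    output.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values, np.zeros(0, dtype=bool)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    outlier = (values < lo) | (values > hi)
    return values[~outlier], outlier


def marker_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def remove_outliers(table: pd.DataFrame, factor: float = 1.5,
                    per_timepoint: bool = True) -> pd.DataFrame:
    """Apply the IQR filter per marker (within each timepoint by default).

    Flagged entries are set to NaN so that each marker keeps its own
    filtering without dropping whole cells.
    """
    out = table.copy()
    for marker in marker_columns(table):
        groups = out.groupby("timepoint").groups.items() if per_timepoint \
            else [("all", out.index)]
        for _, idx in groups:
            vals = out.loc[idx, marker].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            _, outlier = iqr_filter(vals[ok], factor)
            bad = np.asarray(idx)[ok][outlier]
            out.loc[bad, marker] = np.nan
    return out


def max_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each marker by its maximum across all timepoints.

    Expects outlier filtering to have been applied already.  Errors on a
    marker whose intensities are all zero (or all missing).
    """
    out = table.copy()
    for marker in marker_columns(table):
        m = out[marker].max(skipna=True)
        if not np.isfinite(m) or m == 0:
            raise ValueError(f"marker {marker!r}: all-zero or all-missing "
                             "intensities, cannot scale")
        out[marker] = out[marker] / m
    return out


def marker_shift_test(table: pd.DataFrame, marker: str, tp_a: str, tp_b: str,
                      ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of a marker between two timepoints.

    Exact null distribution for small untied samples, tie-corrected normal
    approximation otherwise (scipy's ``method='auto'``).
    """
    if marker not in table.columns:
        raise ValueError(f"unknown marker {marker!r}")
    tps = set(table["timepoint"])
    for tp in (tp_a, tp_b):
        if tp not in tps:
            raise ValueError(f"unknown timepoint {tp!r}")
    a = table.loc[table["timepoint"] == tp_a, marker].dropna().to_numpy()
    b = table.loc[table["timepoint"] == tp_b, marker].dropna().to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 cells per group")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 50 and no_ties) \
        else "asymptotic"
    stat, p = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(stat), float(p)


def positive_fraction(values, threshold: float) -> float:
    """Percentage of values strictly above the threshold."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean(values > threshold))


def marker_correlations(table: pd.DataFrame, timepoint: str,
                        markers: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman correlations of marker intensities at a timepoint.

    Symmetric with unit diagonal; entries for constant markers are NaN
    (undefined rank correlation).
    """
    sub = table[table["timepoint"] == timepoint]
    if len(sub) < 3:
        raise ValueError("need >= 3 cells at the timepoint")
    cols = list(markers) if markers is not None else marker_columns(table)
    corr = sub[cols].corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    for c in cols:  # constant marker: undefined, reported missing
        if sub[c].nunique(dropna=True) <= 1:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
            corr.loc[c, c] = np.nan
    return corr
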