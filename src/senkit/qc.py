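"""Droplet cell calling and gene filtering.

Cell calling follows the knee-free quantile heuristic: take the library
sizes of the top ``expected_cells`` barcodes, compute their upper quantile
(default the 99th percentile, type-7 / linear interpolation), and call every
barcode whose total UMI count strictly exceeds 10% of that quantile.

Gene filtering removes genes detected (count > 0) in less than a given
fraction of all cells (default 10%, strict "less than"); genes detected in
zero cells are always removed.
"""

from __future__ import annotations

from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


def call_cells(profile: Mapping[str, int] | pd.Series, expected_cells: int,
               upper_quantile: float = 0.99, fraction: float = 0.10,
               ) -> set[str]:
    """Call cell-containing barcodes from a barcode -> total-UMI profile.

    Threshold = ``fraction`` x (``upper_quantile``-quantile of the library
    sizes of the top ``expected_cells`` barcodes).  Barcodes with count
    strictly greater than the threshold are called.  If ``expected_cells``
    exceeds the number of barcodes, the quantile is taken over all barcodes.
    """
    profile = pd.Series(profile)
    if profile.empty:
        raise ValueError("empty barcode profile")
    if (profile < 0).any():
        raise ValueError("negative UMI counts")
    if profile.sum() == 0:
        raise ValueError("all-zero barcode profile")
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")

    top = np.sort(profile.to_numpy())[::-1][:expected_cells]
    t = np.quantile(top, upper_quantile)  # linear interpolation (type 7)
    threshold = fraction * t
    return set(profile.index[profile > threshold])


def filter_genes(adata: ad.AnnData, min_cell_fraction: float = 0.10,
                 ) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove genes detected in less than ``min_cell_fraction`` of cells.

    Returns the filtered matrix and a before/after dimension report (a
    count-matrix census: features x samples, overall and per timepoint /
    replicate when those labels are present).
    """
    if not (0 <= min_cell_fraction <= 1):
        raise ValueError("min_cell_fraction must be in [0, 1]")
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    X = adata.X
    if sp.issparse(X):
        detected = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        detected = (np.asarray(X) > 0).sum(axis=0)
    frac = detected / adata.n_obs
    keep = (frac >= min_cell_fraction) & (detected > 0)
    filtered = adata[:, keep].copy()

    rows = [{"stage": "original", "features": adata.n_vars,
             "samples": adata.n_obs, "group": "all"},
            {"stage": "filtered", "features": filtered.n_vars,
             "samples": filtered.n_obs, "group": "all"}]
    for col in ("timepoint", "replicate"):
        if col in adata.obs:
            for level, n in adata.obs[col].value_counts().sort_index().items():
                rows.append({"stage": "filtered", "features": filtered.n_vars,
                             "samples": int(n), "group": f"{col}={level}"})
    report = pd.DataFrame(rows)
    return filtered, report
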