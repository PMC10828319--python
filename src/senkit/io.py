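"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as CellRanger-style Matrix Market triplets
(``matrix.mtx`` with genes as rows and cells as columns, plus
``features.tsv`` / ``barcodes.tsv``) together with a ``cell_metadata.tsv``
carrying timepoint / replicate / cluster labels.  In memory everything is an
:class:`anndata.AnnData` with cells as observations.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

METADATA_COLUMNS = ("timepoint", "replicate", "cluster")


def write_count_matrix(adata: ad.AnnData, outdir: str | os.PathLike) -> Path:
    """Write an AnnData as MTX + features/barcodes/cell_metadata TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(np.asarray(X))
    # genes x cells on disk, CellRanger orientation
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo(), field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    meta = adata.obs.copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)
    return outdir


def read_count_matrix(indir: str | os.PathLike) -> ad.AnnData:
    """Read a count-matrix directory written by :func:`write_count_matrix`."""
    indir = Path(indir)
    X = scipy.io.mmread(str(indir / "matrix.mtx")).tocsr()  # genes x cells
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    adata = ad.AnnData(X=X.T.tocsr(),
                       obs=pd.DataFrame(index=barcodes.astype(str)),
                       var=pd.DataFrame(index=features.astype(str)))
    meta_path = indir / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"barcode": str})
        meta = meta.set_index("barcode").reindex(adata.obs_names)
        for col in meta.columns:
            adata.obs[col] = meta[col].values
    return adata


def write_ppi(edges: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a two-column gene-symbol PPI edge list as TSV (no header)."""
    edges.iloc[:, :2].to_csv(path, sep="\t", header=False, index=False)


def read_ppi(path: str | os.PathLike) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                        names=["gene_a", "gene_b"], dtype=str)
    return edges


def write_marker_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, index=False)


def read_marker_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(truth, path: str | os.PathLike) -> None:
    """Serialize a SimTruth record (see :mod:`senkit.syndata`) to JSON."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
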