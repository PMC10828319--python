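"""Synthetic data generators with ground-truth records.

Every downstream stage of the pipeline (QC, distribution-shape fitting,
PPI-constrained networks, imaging-marker statistics, lineage inference) is
exercised against data produced here, so each generator returns both the
data and a :class:`SimTruth` describing exactly what was planted.

The count generators emulate a droplet scRNA-seq design of three timepoints
(T0/T1/T2) x three biological replicates (R1/R2/R3): per-gene UMI counts are
drawn from one of four count families — Poisson (P), zero-inflated Poisson
(ZIP), negative binomial (NB) and zero-inflated negative binomial (ZINB) —
with replicate effects acting multiplicatively on the mean (a log-link
covariate).  The NB parameterisation is mean ``mu`` and size ``theta`` with
variance ``mu + mu**2 / theta``; zero inflation ``pi`` is a point mass at
zero on top of the count component.

Determinism: every generator is a pure function of its parameters and the
``seed``; RNG streams are namespaced per gene / entity so that adding
entities does not perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

FAMILIES = ("P", "ZIP", "NB", "ZINB")
TIMEPOINTS = ("T0", "T1", "T2")
REPLICATES = ("R1", "R2", "R3")

_INFLATED = {"ZIP", "ZINB"}
_DISPERSED = {"NB", "ZINB"}


@dataclass
class SimTruth:
    """Ground truth for one generator call: what was planted, and the seed."""

    kind: str
    seed: int
    records: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "seed": self.seed, "records": self.records}


@dataclass
class ShapeSpec:
    """Planted per-gene count model across timepoints.

    ``families``, ``mu``, ``theta`` and ``pi`` are per-timepoint sequences
    (``theta``/``pi`` entries are None where the family has no such
    parameter).  ``replicate_effects`` multiply the mean per replicate.
    """

    gene: str
    families: Sequence[str]
    mu: Sequence[float]
    theta: Sequence[float | None] | None = None
    pi: Sequence[float | None] | None = None
    replicate_effects: Sequence[float] = (1.0, 1.0, 1.0)
    cells_per_group: int = 100

    def __post_init__(self):
        T = len(self.families)
        if self.theta is None:
            self.theta = [None] * T
        if self.pi is None:
            self.pi = [None] * T
        if not (len(self.mu) == len(self.theta) == len(self.pi) == T):
            raise ValueError("families, mu, theta, pi must have equal length")
        for t, fam in enumerate(self.families):
            if fam not in FAMILIES:
                raise ValueError(f"unknown family {fam!r}")
            if self.mu[t] < 0:
                raise ValueError("mu must be >= 0")
            th, p = self.theta[t], self.pi[t]
            if fam in _DISPERSED:
                if th is None or th <= 0:
                    raise ValueError(f"{fam} requires theta > 0")
            elif th is not None:
                raise ValueError(f"theta given for family {fam}")
            if fam in _INFLATED:
                if p is None or not (0 <= p < 1):
                    raise ValueError(f"{fam} requires 0 <= pi < 1")
            elif p is not None:
                raise ValueError(f"pi given for family {fam}")
        if self.cells_per_group < 1:
            raise ValueError("cells_per_group must be >= 1")


def _draw_counts(rng: np.random.Generator, family: str, mu: float,
                 theta: float | None, pi: float | None, n: int) -> np.ndarray:
    if family in ("NB", "ZINB"):
        base = (rng.negative_binomial(theta, theta / (theta + mu), n)
                if mu > 0 else np.zeros(n, dtype=np.int64))
    else:
        base = rng.poisson(mu, n)
    if family in _INFLATED:
        base = np.where(rng.random(n) < pi, 0, base)
    return base.astype(np.int64)


def gen_shape_counts(specs: Sequence[ShapeSpec], seed: int,
                     timepoints: Sequence[str] = TIMEPOINTS,
                     replicates: Sequence[str] = REPLICATES,
                     ) -> tuple[ad.AnnData, SimTruth]:
    """Draw a UMI count matrix from planted per-gene count families.

    Each gene's counts at timepoint ``t`` and replicate ``r`` come from its
    planted family with mean ``mu[t] * replicate_effects[r]``.  Returns an
    AnnData (cells x genes, sparse) with ``timepoint`` and ``replicate``
    obs columns, and the SimTruth holding every spec.
    """
    if len(specs) == 0:
        raise ValueError("need at least one ShapeSpec")
    n_group = {s.cells_per_group for s in specs}
    if len(n_group) != 1:
        raise ValueError("all specs must share cells_per_group")
    n_group = n_group.pop()
    n_t, n_r = len(timepoints), len(replicates)
    n_cells = n_group * n_t * n_r

    tp_labels = np.repeat(list(timepoints), n_r * n_group)
    rep_labels = np.tile(np.repeat(list(replicates), n_group), n_t)

    cols = []
    for g_idx, spec in enumerate(specs):
        if len(spec.families) != n_t:
            raise ValueError(f"spec {spec.gene}: expected {n_t} timepoints")
        rng = np.random.default_rng([seed, g_idx])
        y = np.empty(n_cells, dtype=np.int64)
        pos = 0
        for t in range(n_t):
            for r in range(n_r):
                mu_tr = spec.mu[t] * spec.replicate_effects[r]
                y[pos:pos + n_group] = _draw_counts(
                    rng, spec.families[t], mu_tr, spec.theta[t],
                    spec.pi[t], n_group)
                pos += n_group
        cols.append(y)
    X = sp.csr_matrix(np.column_stack(cols))

    obs = pd.DataFrame({"timepoint": tp_labels, "replicate": rep_labels},
                       index=[f"CELL{i:06d}" for i in range(n_cells)])
    var = pd.DataFrame(index=[s.gene for s in specs])
    adata = ad.AnnData(X=X, obs=obs, var=var)

    truth = SimTruth(kind="shape_counts", seed=seed, records={
        s.gene: {"families": list(s.families), "mu": list(s.mu),
                 "theta": list(s.theta), "pi": list(s.pi),
                 "replicate_effects": list(s.replicate_effects)}
        for s in specs})
    return adata, truth


def gen_droplet_profile(n_real: int, n_ambient: int, real_depth: float,
                        ambient_depth: float, seed: int,
                        depth_cv: float = 0.25,
                        ) -> tuple[pd.Series, SimTruth]:
    """Simulate per-barcode total UMI counts with an ambient tail.

    Real barcodes draw Poisson counts around ``real_depth`` (with a
    log-normal depth jitter of coefficient ``depth_cv``), ambient barcodes
    around ``ambient_depth``.  Truth labels each barcode real/ambient.
    """
    if real_depth <= 0 or (n_ambient > 0 and ambient_depth <= 0):
        raise ValueError("depths must be positive")
    rng = np.random.default_rng([seed, 0])
    sigma = np.sqrt(np.log1p(depth_cv ** 2))
    labels = {}
    counts = {}
    for i in range(n_real):
        bc = f"REAL{i:06d}"
        lam = real_depth * np.exp(rng.normal(-sigma ** 2 / 2, sigma))
        counts[bc] = int(rng.poisson(lam))
        labels[bc] = "real"
    for i in range(n_ambient):
        bc = f"AMB{i:06d}"
        lam = ambient_depth * np.exp(rng.normal(-sigma ** 2 / 2, sigma))
        counts[bc] = int(rng.poisson(lam))
        labels[bc] = "ambient"
    profile = pd.Series(counts, name="total_umis")
    truth = SimTruth(kind="droplet_profile", seed=seed,
                     records={"labels": labels})
    return profile, truth


def gen_ppi_expression(n_genes: int, planted_modules: Sequence[tuple[int, float]],
                       n_cells: int, seed: int, ppi_m: int = 2,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Expression matrix with planted correlated modules plus a scale-free PPI.

    Genes inside a planted module share a latent factor with the given
    loading, so within-module pairs are strongly rank-correlated;
    background genes are independent Gaussians.  The PPI is a
    preferential-attachment (Barabasi-Albert) graph augmented with every
    within-module pair, so the module structure is discoverable through
    PPI-constrained correlation.

    Returns (expression genes x cells, PPI edge list, truth).
    """
    sizes = [s for s, _ in planted_modules]
    if any(s < 2 for s in sizes):
        raise ValueError("module size must be >= 2")
    if sum(sizes) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    genes = [f"G{i:05d}" for i in range(n_genes)]

    rng = np.random.default_rng([seed, 1])
    expr = np.empty((n_genes, n_cells))
    membership = {g: None for g in genes}
    pos = 0
    for m_idx, (size, loading) in enumerate(planted_modules):
        if not (0 <= loading <= 1):
            raise ValueError("loading must be in [0, 1]")
        latent = rng.normal(size=n_cells)
        for g in range(pos, pos + size):
            noise = rng.normal(size=n_cells)
            expr[g] = loading * latent + np.sqrt(1 - loading ** 2) * noise
            membership[genes[g]] = m_idx
        pos += size
    for g in range(pos, n_genes):
        expr[g] = rng.normal(size=n_cells)

    G = nx.barabasi_albert_graph(n_genes, ppi_m,
                                 seed=int(np.random.default_rng([seed, 2])
                                          .integers(2 ** 31)))
    G = nx.relabel_nodes(G, dict(enumerate(genes)))
    s = 0
    for size, _ in planted_modules:
        for i in range(s, s + size):
            for j in range(i + 1, s + size):
                G.add_edge(genes[i], genes[j])
        s += size

    edges = pd.DataFrame(sorted((min(a, b), max(a, b)) for a, b in G.edges()),
                         columns=["gene_a", "gene_b"])
    expr_df = pd.DataFrame(expr, index=genes,
                           columns=[f"CELL{i:05d}" for i in range(n_cells)])
    truth = SimTruth(kind="ppi_expression", seed=seed, records={
        "membership": membership,
        "modules": [{"size": s_, "loading": l_} for s_, l_ in planted_modules]})
    return expr_df, edges, truth


def gen_marker_table(n_cells_per_timepoint: int,
                     marker_shifts: Mapping[str, Sequence[float]],
                     outlier_frac: float, seed: int, sigma: float = 0.2,
                     timepoints: Sequence[str] = TIMEPOINTS,
                     ) -> tuple[pd.DataFrame, SimTruth]:
    """Per-cell imaging marker intensities with timepoint shifts and outliers.

    Intensities are log-normal: marker ``m`` at timepoint ``t`` has
    log-location ``marker_shifts[m][t]`` and log-scale ``sigma``.  A fraction
    ``outlier_frac`` of cells per marker is replaced by extreme values above
    10x the marker's 99th percentile; those entries are flagged in truth.
    """
    if not (0 <= outlier_frac <= 0.2):
        raise ValueError("outlier_frac must be in [0, 0.2]")
    for m, locs in marker_shifts.items():
        if len(locs) != len(timepoints):
            raise ValueError(f"marker {m}: need one location per timepoint")
        if any(l < 0 for l in locs):
            raise ValueError(f"marker {m}: shift locations must be >= 0")

    n_total = n_cells_per_timepoint * len(timepoints)
    table = pd.DataFrame({
        "cell_id": [f"IMG{i:06d}" for i in range(n_total)],
        "timepoint": np.repeat(list(timepoints), n_cells_per_timepoint),
    })
    outliers: list[dict] = []
    for m_idx, (marker, locs) in enumerate(marker_shifts.items()):
        rng = np.random.default_rng([seed, 10 + m_idx])
        vals = np.concatenate([
            np.exp(rng.normal(loc, sigma, n_cells_per_timepoint))
            for loc in locs])
        n_out = int(round(outlier_frac * n_total))
        if n_out:
            q99 = np.quantile(vals, 0.99)
            idx = rng.choice(n_total, n_out, replace=False)
            vals[idx] = q99 * rng.uniform(12.0, 20.0, n_out)
            outliers.extend({"cell_id": table["cell_id"][i], "marker": marker}
                            for i in sorted(idx))
        table[marker] = vals
    truth = SimTruth(kind="marker_table", seed=seed, records={
        "shifts": {m: list(l) for m, l in marker_shifts.items()},
        "outliers": outliers, "sigma": sigma})
    return table, truth


def gen_lineage_counts(cluster_tree: Mapping, cells_per_cluster: int,
                       noise_sd: float, seed: int,
                       ) -> tuple[ad.AnnData, SimTruth]:
    """Counts for cells scattered around cluster centroids joined by a tree.

    ``cluster_tree`` is a mapping with keys ``centroids`` (cluster id ->
    vector of per-gene log-means), ``edges`` (list of cluster-id pairs) and
    ``root``.  Cells are Gaussian perturbations of their cluster centroid in
    log space, mapped to counts by exponentiating and Poisson sampling — so
    log-normalisation downstream approximately recovers the geometry.
    """
    centroids = {str(k): np.asarray(v, dtype=float)
                 for k, v in cluster_tree["centroids"].items()}
    if len(centroids) < 2:
        raise ValueError("need at least 2 clusters")
    mats = list(centroids.values())
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            if np.allclose(mats[i], mats[j]):
                raise ValueError("duplicate centroids")
    cluster_ids = sorted(centroids)
    n_genes = len(mats[0])

    rows, clusters = [], []
    for c_idx, cid in enumerate(cluster_ids):
        rng = np.random.default_rng([seed, 100 + c_idx])
        latent = centroids[cid] + rng.normal(0.0, noise_sd,
                                             (cells_per_cluster, n_genes))
        rows.append(rng.poisson(np.exp(latent)))
        clusters.extend([cid] * cells_per_cluster)
    X = sp.csr_matrix(np.vstack(rows).astype(np.int64))
    obs = pd.DataFrame({"cluster": clusters},
                       index=[f"CELL{i:06d}" for i in range(X.shape[0])])
    var = pd.DataFrame(index=[f"G{i:05d}" for i in range(n_genes)])
    adata = ad.AnnData(X=X, obs=obs, var=var)

    truth = SimTruth(kind="lineage_counts", seed=seed, records={
        "edges": [list(map(str, e)) for e in cluster_tree["edges"]],
        "root": str(cluster_tree["root"]),
        "centroids": {k: v.tolist() for k, v in centroids.items()}})
    return adata, truth
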