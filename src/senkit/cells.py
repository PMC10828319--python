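"""Cell-level analyses: normalization, marker-gene ranking, cell-cycle
scoring, PCA embedding, and a simplified MST cluster lineage with pseudotime.

Normalization is depth-relative log transformation
``ln(1 + count * scale / cell_depth)`` (scale 1e4).  Marker genes are ranked
one group versus the rest by Wilcoxon rank-sum with a natural-log
fold-change computed on de-logged means (pseudocount 1) and Bonferroni
correction over all genes tested; the retention thresholds are
``|logFC| > 0.25`` and adjusted p < 0.001.  Cell-cycle phases follow the
expression-matched control-gene scoring scheme: each cell's S and G2M score
is the mean expression of the phase gene set minus the mean of control genes
drawn from the same average-expression bins; G1 when both scores are <= 0,
otherwise the larger score wins.

Lineage inference deliberately stops at the first stage of tree-based
trajectory methods: a Euclidean minimum spanning tree over cluster centroids
in PC space, lineages as root-to-leaf paths, and per-cell pseudotime as the
arc length from the root centroid to the cell's projection onto its
cluster's incident tree segment.  No principal-curve smoothing is applied;
conclusions are therefore topology-level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def lognormalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Depth-normalized log counts: ``ln(1 + count * scale / depth)``."""
    X = _dense(adata.X).astype(float)
    depth = X.sum(axis=1)
    if np.any(depth <= 0):
        raise ValueError("zero-depth cell(s) present")
    norm = np.log1p(X * (scale / depth[:, None]))
    out = adata.copy()
    out.X = norm
    return out


@dataclass
class DERecord:
    gene: str
    group: str
    log_fc: float
    p_value: float
    p_adjusted: float
    direction: str


def rank_markers(norm: ad.AnnData, labels, group,
                 logfc_min: float = 0.25, padj_max: float = 0.001,
                 ) -> list[DERecord]:
    """One-vs-rest Wilcoxon marker ranking with logFC/Bonferroni thresholds.

    ``logFC = ln((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))``;
    Bonferroni over all genes tested; records kept when ``|logFC| >
    logfc_min`` and adjusted p < ``padj_max``, sorted by |logFC| descending.
    """
    labels = np.asarray(labels)
    mask = labels == group
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("need >= 3 cells on each side")
    X = _dense(norm.X)
    x_in, x_out = X[mask], X[~mask]
    with np.errstate(over="ignore"):
        mean_in = np.expm1(x_in).mean(axis=0)
        mean_out = np.expm1(x_out).mean(axis=0)
    log_fc = np.log((mean_in + 1) / (mean_out + 1))
    res = mannwhitneyu(x_in, x_out, alternative="two-sided", axis=0)
    p = np.asarray(res.pvalue)
    n_tests = X.shape[1]
    p_adj = np.minimum(1.0, p * n_tests)
    keep = (np.abs(log_fc) > logfc_min) & (p_adj < padj_max)
    order = np.argsort(-np.abs(log_fc))
    records = [DERecord(gene=norm.var_names[i], group=str(group),
                        log_fc=float(log_fc[i]), p_value=float(p[i]),
                        p_adjusted=float(p_adj[i]),
                        direction="up" if log_fc[i] > 0 else "down")
               for i in order if keep[i]]
    return records


def marker_summary(records_by_group: dict[str, list[DERecord]],
                   labels, top: int = 5) -> pd.DataFrame:
    """Per-group marker counts (up/down) and top markers by |logFC|."""
    labels = np.asarray(labels)
    rows = []
    for group, recs in records_by_group.items():
        ups = sum(1 for r in recs if r.direction == "up")
        rows.append({
            "group": group,
            "n_cells": int((labels == group).sum()),
            "n_markers": len(recs), "n_up": ups, "n_down": len(recs) - ups,
            "top_markers": ", ".join(r.gene for r in recs[:top])})
    return pd.DataFrame(rows)


@dataclass
class PhaseScore:
    cell: str
    s_score: float
    g2m_score: float
    phase: str


def cell_cycle_scores(norm: ad.AnnData, s_genes: Sequence[str],
                      g2m_genes: Sequence[str], n_bins: int = 24,
                      n_ctrl: int = 100, seed: int = 0) -> list[PhaseScore]:
    """Score S and G2M phase per cell against expression-matched controls.

    Genes are binned by average expression into ``n_bins`` quantile bins;
    for each phase gene ``n_ctrl`` control genes are drawn (with
    replacement) from its bin.  Score = mean(phase genes) - mean(controls).
    Phase is G1 when both scores are <= 0, otherwise the argmax.
    """
    for name, gl in (("s_genes", s_genes), ("g2m_genes", g2m_genes)):
        if len(gl) == 0:
            raise ValueError(f"{name} is empty")
    X = _dense(norm.X)
    var_index = {g: i for i, g in enumerate(norm.var_names)}
    avg = X.mean(axis=0)
    ranks = pd.qcut(pd.Series(avg).rank(method="first"), q=n_bins,
                    labels=False).to_numpy()
    bins: dict[int, np.ndarray] = {b: np.where(ranks == b)[0]
                                   for b in range(n_bins)}
    rng = np.random.default_rng(seed)

    def score_set(gene_list):
        idx = [var_index[g] for g in gene_list if g in var_index]
        if not idx:
            raise ValueError("gene list has no overlap with the matrix")
        in_set = np.zeros(X.shape[1], dtype=bool)
        in_set[idx] = True
        ctrl = []
        for gi in idx:
            pool = bins[ranks[gi]]
            pool = pool[~in_set[pool]]  # controls never come from the set
            if len(pool) == 0:
                pool = np.where(~in_set)[0]
            ctrl.append(rng.choice(pool, size=min(n_ctrl, len(pool)),
                                   replace=True))
        ctrl = np.unique(np.concatenate(ctrl))
        return X[:, idx].mean(axis=1) - X[:, ctrl].mean(axis=1)

    s = score_set(s_genes)
    g2m = score_set(g2m_genes)
    out = []
    eps = 1e-12  # absorb float-summation noise in the degenerate flat case
    for i, cell in enumerate(norm.obs_names):
        if s[i] <= eps and g2m[i] <= eps:
            phase = "G1"
        else:
            phase = "S" if s[i] >= g2m[i] else "G2M"
        out.append(PhaseScore(cell=cell, s_score=float(s[i]),
                              g2m_score=float(g2m[i]), phase=phase))
    return out


@dataclass
class Embedding:
    coords: np.ndarray                  # cells x n_pcs
    explained_variance_ratio: np.ndarray
    components: np.ndarray              # n_pcs x genes


def pca_embed(norm: ad.AnnData, n_pcs: int = 20) -> Embedding:
    """Centred PCA of the normalized matrix with deterministic signs.

    Each component's sign is fixed by making its largest-magnitude loading
    positive.  Errors when ``n_pcs`` exceeds the matrix rank.
    """
    X = _dense(norm.X)
    if n_pcs > min(X.shape):
        raise ValueError("n_pcs exceeds matrix dimensions")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(X)
    sv = pca.singular_values_
    if sv[0] > 0 and np.any(sv < 1e-10 * sv[0]):
        raise ValueError("n_pcs exceeds the rank of the data")
    comps = pca.components_
    flip = np.sign(comps[np.arange(n_pcs),
                         np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    return Embedding(coords=coords * flip, components=comps * flip[:, None],
                     explained_variance_ratio=pca.explained_variance_ratio_)


@dataclass
class LineageTree:
    centroids: dict                     # cluster id -> centroid (PC space)
    edges: list                         # MST edges as (cluster, cluster)
    root: str
    lineages: list                      # root-to-leaf cluster paths
    pseudotime: pd.Series               # per cell, >= 0
    cluster_pseudotime: dict = field(default_factory=dict)


def mst_lineage(embedding: np.ndarray, labels, root,
                cell_names: Sequence[str] | None = None) -> LineageTree:
    """Cluster lineage from a minimum spanning tree over centroids.

    Lineages are the root-to-leaf paths of the Euclidean MST over cluster
    centroids.  A cell's pseudotime is the tree arc length from the root
    centroid to the cell's orthogonal projection (clamped to the segment)
    onto the incident tree edge of its cluster nearest to the cell.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    root = str(root)
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    if root not in clusters:
        raise ValueError(f"unknown root cluster {root!r}")
    if embedding.shape[0] < 2:
        raise ValueError("singleton embedding")

    centroids = {c: embedding[labels == c].mean(axis=0) for c in clusters}
    C = np.array([centroids[c] for c in clusters])
    D = np.linalg.norm(C[:, None] - C[None, :], axis=-1)
    mst = minimum_spanning_tree(D).toarray()
    T = nx.Graph()
    T.add_nodes_from(clusters)
    for i, j in zip(*np.nonzero(mst)):
        T.add_edge(clusters[i], clusters[j], weight=float(D[i, j]))

    dist_root = nx.single_source_dijkstra_path_length(T, root)
    parent = {root: None}
    for node in nx.bfs_tree(T, root).nodes():
        for child in T.neighbors(node):
            if child not in parent:
                parent[child] = node
    leaves = [c for c in clusters if T.degree(c) == 1 and c != root]
    if not leaves:  # root itself is the only leaf (2-cluster tree edge case)
        leaves = [c for c in clusters if c != root]
    lineages = [[str(c) for c in nx.shortest_path(T, root, leaf)]
                for leaf in leaves]

    names = list(cell_names) if cell_names is not None \
        else list(range(len(labels)))
    pt = np.zeros(len(labels))
    for c in clusters:
        idx = np.where(labels == c)[0]
        segs = []
        for nbr in T.neighbors(c):
            # orient each incident segment from the endpoint closer to root
            u, v = (nbr, c) if dist_root[nbr] <= dist_root[c] else (c, nbr)
            segs.append((centroids[u], centroids[v], dist_root[u]))
        if not segs:
            pt[idx] = dist_root[c]
            continue
        cells = embedding[idx]
        best_d = np.full(len(idx), np.inf)
        best_pt = np.zeros(len(idx))
        for p0, p1, base in segs:
            d01 = p1 - p0
            L = np.linalg.norm(d01)
            t = np.clip((cells - p0) @ d01 / (L ** 2), 0.0, 1.0)
            proj = p0 + t[:, None] * d01
            d = np.linalg.norm(cells - proj, axis=1)
            better = d < best_d
            best_d[better] = d[better]
            best_pt[better] = base + t[better] * L
        pt[idx] = best_pt
    return LineageTree(centroids=centroids,
                       edges=[tuple(sorted(e)) for e in T.edges()],
                       root=root, lineages=lineages,
                       pseudotime=pd.Series(pt, index=names,
                                            name="pseudotime"),
                       cluster_pseudotime=dist_root)
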