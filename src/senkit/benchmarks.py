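"""End-to-end benchmark runs on synthetic data with known ground truth.

Each function generates its own inputs with the study's design (sample
sizes, family parameters, planting strengths), runs the corresponding
pipeline stage, and returns the measured performance.  They are shared by
the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cells, markers_img, netmod, qc, shapes, syndata


def shape_identification(n_genes_per_family: int = 100, n_cells: int = 2000,
                         n_boot: int = 100, alpha: float = 0.05,
                         seed: int = 0) -> dict:
    """Accuracy of assign_shape on genes with known planted families.

    Families and parameters: P(mu=3), NB(mu=5, theta=0.5),
    ZINB(pi=0.4, mu=8, theta=2), each at ``n_cells`` cells.
    """
    planted = [("P", dict(families=["P"], mu=[3.0])),
               ("NB", dict(families=["NB"], mu=[5.0], theta=[0.5])),
               ("ZINB", dict(families=["ZINB"], mu=[8.0], theta=[2.0],
                             pi=[0.4]))]
    out = {}
    for f_idx, (family, kwargs) in enumerate(planted):
        specs = [syndata.ShapeSpec(f"{family}{i:03d}",
                                   cells_per_group=n_cells, **kwargs)
                 for i in range(n_genes_per_family)]
        adata, _ = syndata.gen_shape_counts(specs, seed=seed * 10 + f_idx,
                                            timepoints=("T0",),
                                            replicates=("R1",))
        X = np.asarray(adata.X.todense())
        hits = 0
        for j in range(n_genes_per_family):
            a = shapes.assign_shape(
                X[:, j], alpha=alpha, n_boot=n_boot,
                seed=int(np.random.default_rng(
                    [seed, f_idx, j]).integers(2 ** 31)))
            hits += a.family == family
        out[family] = 100.0 * hits / n_genes_per_family
    return out


def zinb_recovery(n_cells: int = 5000, seed: int = 0) -> dict:
    """ZINB parameter recovery: pi=0.3, mu=5, theta=2 at ``n_cells``."""
    spec = syndata.ShapeSpec("g", families=["ZINB"], mu=[5.0], theta=[2.0],
                             pi=[0.3], cells_per_group=n_cells)
    adata, _ = syndata.gen_shape_counts([spec], seed=seed,
                                        timepoints=("T0",),
                                        replicates=("R1",))
    y = np.asarray(adata.X.todense()).ravel()
    fit = shapes.fit_family(y, family="ZINB")
    return {"pi_hat": float(fit.pi), "mu_hat": float(fit.mu[0]),
            "theta_hat": float(fit.theta), "n": n_cells}


def droplet_calling(n_real: int = 100, n_ambient: int = 1000,
                    real_depth: float = 1000.0, ambient_depth: float = 10.0,
                    seed: int = 0) -> dict:
    """Recall / false-positive rate of the quantile cell caller."""
    profile, truth = syndata.gen_droplet_profile(
        n_real, n_ambient, real_depth, ambient_depth, seed=seed)
    called = qc.call_cells(profile, expected_cells=n_real)
    real = {b for b, l in truth.records["labels"].items() if l == "real"}
    return {"recall_pct": 100.0 * len(called & real) / len(real),
            "fpr_pct": 100.0 * len(called - real) / max(n_ambient, 1),
            "n_called": len(called)}


def _bifurcation_tree(seed: int, n_genes: int = 30, sep: float = 2.0):
    # orthonormal branch directions: guarantees the planted Y really is the
    # minimum spanning tree of the latent centroids (tips are sqrt(2) x sep
    # apart while planted edges are sep).  Spreading the branches over 30
    # genes at a baseline of 2.5 log-counts keeps each cluster's total
    # expression nearly equal, so depth normalization does not shear the
    # geometry
    rng = np.random.default_rng([seed, 1])
    dirs = np.linalg.qr(rng.normal(size=(n_genes, 3))).Q.T
    base = np.full(n_genes, 2.5)
    centroids = {"root": base,
                 "A": base + sep * dirs[0],
                 "B": base + sep * dirs[0] + sep * dirs[1],
                 "C": base + sep * dirs[0] + sep * dirs[2]}
    return {"centroids": centroids,
            "edges": [("root", "A"), ("A", "B"), ("A", "C")],
            "root": "root"}


def lineage_recovery(n_seeds: int = 100, cells_per_cluster: int = 50,
                     noise_sd: float = 0.2, seed: int = 0) -> dict:
    """Fraction of seeds on which the planted bifurcation is recovered.

    Each run plants a Y-shaped 4-cluster lineage with centroid separation
    10x the per-gene noise, simulates counts, embeds with PCA and checks
    that the centroid MST matches the planted topology and that mean
    pseudotime is monotone along every lineage.
    """
    recovered = monotone = 0
    for i in range(n_seeds):
        tree_spec = _bifurcation_tree(seed * n_seeds + i)
        adata, truth = syndata.gen_lineage_counts(
            tree_spec, cells_per_cluster, noise_sd, seed=seed * n_seeds + i)
        norm = cells.lognormalize(adata)
        emb = cells.pca_embed(norm, n_pcs=4)
        tree = cells.mst_lineage(emb.coords, norm.obs["cluster"], "root",
                                 cell_names=norm.obs_names)
        planted = sorted(tuple(sorted(e)) for e in truth.records["edges"])
        if sorted(tree.edges) == planted:
            recovered += 1
            labels = norm.obs["cluster"].to_numpy()
            ok = True
            for lineage in tree.lineages:
                pts = [tree.pseudotime[labels == c].mean() for c in lineage]
                ok &= all(a < b for a, b in zip(pts, pts[1:]))
            monotone += ok
    return {"recovery_pct": 100.0 * recovered / n_seeds,
            "monotone_pct": 100.0 * monotone / max(recovered, 1),
            "n_seeds": n_seeds}


def null_de_control(n_runs: int = 100, n_genes: int = 500,
                    cells_per_group: int = 200, seed: int = 0) -> dict:
    """Type-I control of the marker filter on no-signal simulations."""
    clean = 0
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        counts = rng.poisson(2.0, (2 * cells_per_group, n_genes))
        import anndata as ad
        adata = ad.AnnData(
            X=counts.astype(float),
            var=pd.DataFrame(index=[f"g{j}" for j in range(n_genes)]))
        norm = cells.lognormalize(adata)
        labels = np.array(["a"] * cells_per_group + ["b"] * cells_per_group)
        if not cells.rank_markers(norm, labels, "a"):
            clean += 1
    return {"zero_marker_runs_pct": 100.0 * clean / n_runs,
            "n_runs": n_runs}


def marker_shift_benchmark(n_cells_per_timepoint: int = 500,
                           seed: int = 0) -> dict:
    """Planted +1 log-unit shift: outlier removal and Wilcoxon detection."""
    shifts = {"p21": [1.0, 1.5, 2.0]}
    table, truth = syndata.gen_marker_table(
        n_cells_per_timepoint, shifts, outlier_frac=0.05, seed=seed)
    cleaned = markers_img.remove_outliers(table, factor=1.5)
    removed = sum(
        np.isnan(cleaned.loc[cleaned["cell_id"] == o["cell_id"],
                             o["marker"]].iloc[0])
        for o in truth.records["outliers"])
    scaled = markers_img.max_scale(cleaned)
    _, p = markers_img.marker_shift_test(scaled, "p21", "T0", "T2")
    return {"outliers_removed_pct":
            100.0 * removed / max(len(truth.records["outliers"]), 1),
            "shift_p_value": p}


def module_recovery(n_genes: int = 80, module_size: int = 10,
                    loading: float = 0.8, n_cells: int = 500,
                    seed: int = 0) -> dict:
    """Jaccard overlap of the best MCODE module with the planted module."""
    expr, ppi, truth = syndata.gen_ppi_expression(
        n_genes, [(module_size, loading)], n_cells=n_cells, seed=seed)
    G = netmod.correlation_graph(expr, ppi, rho_min=0.5)
    mods = netmod.mcode_modules(G)
    planted = {g for g, m in truth.records["membership"].items() if m == 0}
    if not mods:
        return {"jaccard": 0.0, "n_modules": 0}
    best = max(mods, key=lambda m: len(m.nodes & planted))
    jacc = len(best.nodes & planted) / len(best.nodes | planted)
    return {"jaccard": float(jacc), "n_modules": len(mods)}
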