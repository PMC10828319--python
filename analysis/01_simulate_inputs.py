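#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Emulates the study design — three timepoints (T0/T1/T2) x three biological
replicates, per-gene counts from the four count families with some genes
switching family across timepoints, a droplet barcode profile with an
ambient tail, an expression matrix with a planted co-expression module plus
a scale-free PPI, an imaging-marker table with timepoint shifts, and a
Y-shaped cluster lineage.  Everything lands under results/data/ with its
ground truth alongside.
"""

from pathlib import Path

from senkit import benchmarks, io, syndata

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def shape_specs():
    """48 genes: stable P/NB/ZIP/ZINB plus switching genes.

    Replicate effects (1.0, 1.2, 0.8) emulate biological-replicate
    variation on the mean.
    """
    reps = (1.0, 1.2, 0.8)
    specs = []
    for i in range(12):
        specs.append(syndata.ShapeSpec(
            f"STBL_P{i:02d}", families=["P"] * 3, mu=[3.0, 3.5, 2.5],
            replicate_effects=reps, cells_per_group=120))
    for i in range(12):
        specs.append(syndata.ShapeSpec(
            f"STBL_NB{i:02d}", families=["NB"] * 3, mu=[5.0, 6.0, 4.0],
            theta=[0.8] * 3, replicate_effects=reps, cells_per_group=120))
    for i in range(8):
        specs.append(syndata.ShapeSpec(
            f"SWCH_PNBP{i:02d}", families=["P", "NB", "P"],
            mu=[4.0, 5.0, 4.0], theta=[None, 0.5, None],
            replicate_effects=reps, cells_per_group=120))
    for i in range(8):
        specs.append(syndata.ShapeSpec(
            f"SWCH_PNBZ{i:02d}", families=["P", "NB", "ZIP"],
            mu=[4.0, 6.0, 5.0], theta=[None, 0.5, None],
            pi=[None, None, 0.45], replicate_effects=reps,
            cells_per_group=120))
    for i in range(8):
        specs.append(syndata.ShapeSpec(
            f"STBL_ZINB{i:02d}", families=["ZINB"] * 3, mu=[8.0, 8.0, 8.0],
            theta=[2.0] * 3, pi=[0.4, 0.4, 0.4], replicate_effects=reps,
            cells_per_group=120))
    return specs


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    adata, truth = syndata.gen_shape_counts(shape_specs(), seed=SEED)
    io.write_count_matrix(adata, OUT / "shapes")
    io.write_truth(truth, OUT / "shapes" / "truth.json")
    print(f"shapes: {adata.n_vars} genes x {adata.n_obs} cells "
          f"(3 timepoints x 3 replicates)")

    profile, truth = syndata.gen_droplet_profile(
        n_real=100, n_ambient=1000, real_depth=1000, ambient_depth=10,
        seed=SEED)
    profile.to_csv(OUT / "barcode_profile.tsv", sep="\t", header=False)
    io.write_truth(truth, OUT / "droplet_truth.json")
    print(f"droplets: {len(profile)} barcodes (100 real + 1000 ambient)")

    expr, ppi, truth = syndata.gen_ppi_expression(
        n_genes=80, planted_modules=[(10, 0.8)], n_cells=500, seed=SEED)
    expr.to_csv(OUT / "network_expression.tsv", sep="\t")
    io.write_ppi(ppi, OUT / "ppi.tsv")
    io.write_truth(truth, OUT / "network_truth.json")
    print(f"network: {expr.shape[0]} genes x {expr.shape[1]} cells, "
          f"{len(ppi)} PPI edges, one planted 10-gene module")

    shifts = {"p21": [1.0, 1.5, 2.0], "p16": [1.0, 1.2, 1.6],
              "SA_b_gal": [0.5, 1.0, 2.2], "BrdU": [2.0, 1.5, 1.0],
              "DNA": [3.0, 3.0, 3.1]}
    table, truth = syndata.gen_marker_table(
        n_cells_per_timepoint=500, marker_shifts=shifts, outlier_frac=0.05,
        seed=SEED)
    io.write_marker_table(table, OUT / "markers.csv")
    io.write_truth(truth, OUT / "markers_truth.json")
    print(f"markers: {len(table)} cells x {len(shifts)} markers "
          f"(5% injected outliers)")

    tree_spec = benchmarks._bifurcation_tree(SEED)
    adata, truth = syndata.gen_lineage_counts(tree_spec, 60, 0.2, seed=SEED)
    io.write_count_matrix(adata, OUT / "lineage")
    io.write_truth(truth, OUT / "lineage" / "truth.json")
    print(f"lineage: {adata.n_obs} cells in 4 clusters (Y topology)")


if __name__ == "__main__":
    main()
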