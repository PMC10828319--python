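import numpy as np
import pytest

from senkit import syndata


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def marker_fixture():
    """Imaging-marker table with a planted +1 log-unit p21 shift and 5%
    injected outliers (500 cells per timepoint)."""
    shifts = {"p21": [1.0, 1.5, 2.0], "p16": [1.0, 1.2, 1.6],
              "SA_b_gal": [0.5, 1.0, 2.2], "BrdU": [2.0, 1.5, 1.0],
              "DNA": [3.0, 3.0, 3.1]}
    table, truth = syndata.gen_marker_table(
        n_cells_per_timepoint=500, marker_shifts=shifts,
        outlier_frac=0.05, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def bifurcation_tree():
    """Y-shaped 4-cluster lineage: root -> A -> (B, C), separation 10x noise,
    orthonormal branch directions so the planted Y is the latent MST."""
    d = 30
    rng = np.random.default_rng(7)
    dirs = np.linalg.qr(rng.normal(size=(d, 3))).Q.T
    base = np.full(d, 2.5)
    centroids = {
        "root": base,
        "A": base + 2.0 * dirs[0],
        "B": base + 2.0 * dirs[0] + 2.0 * dirs[1],
        "C": base + 2.0 * dirs[0] + 2.0 * dirs[2],
    }
    return {"centroids": centroids,
            "edges": [("root", "A"), ("A", "B"), ("A", "C")],
            "root": "root"}
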