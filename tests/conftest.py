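import numpy as np
import pytest
from scipy import io as spio
from scipy import sparse

from countshapes import CellDesign, CountMatrix, random_spec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    counts = np.array([[1, 0, 2], [0, 3, 4]])
    return CountMatrix(["g1", "g2"], ["c1", "c2", "c3"], counts)


def write_10x_dir(directory, matrix: CountMatrix, transpose=False):
    """Write a CountMatrix as a 10X-style MTX triplet (plain text)."""
    directory.mkdir(parents=True, exist_ok=True)
    m = matrix.counts.T if transpose else matrix.counts
    spio.mmwrite(str(directory / "matrix.mtx"), sparse.coo_matrix(m))
    (directory / "barcodes.tsv").write_text("\n".join(matrix.cells) + "\n")
    (directory / "features.tsv").write_text(
        "\n".join(f"{g}\t{g}\tGene Expression" for g in matrix.genes) + "\n"
    )
    return directory


@pytest.fixture
def tenx_writer():
    return write_10x_dir


@pytest.fixture(scope="session")
def simulated_small():
    """60-gene, 500-cell dataset with known labels (15 genes per family)."""
    rng = np.random.default_rng(777)
    spec = random_spec(rng, n_per_family=15, n_cells=500, seed=777)
    matrix, design, truth = simulate_dataset(spec)
    return matrix, design, truth


def two_condition_dataset(seed_a=101, seed_b=202, n_per_family=10, n_cells=400,
                          switch_families=None):
    """Two-condition dataset; condition B optionally re-labels some genes'
    generative family to create known shape switches."""
    rng = np.random.default_rng(seed_a)
    spec_a = random_spec(rng, n_per_family=n_per_family, n_cells=n_cells,
                         seed=seed_a, condition="A")
    genes_b = spec_a.genes.copy()
    if switch_families:
        for gene, fam in switch_families.items():
            i = genes_b.index[genes_b["gene"] == gene][0]
            genes_b.loc[i, "family"] = fam
            if fam in ("NB", "ZINB") and np.isnan(genes_b.loc[i, "phi"]):
                genes_b.loc[i, "phi"] = 1.0
            if fam in ("ZIP", "ZINB") and np.isnan(genes_b.loc[i, "omega"]):
                genes_b.loc[i, "omega"] = 0.4
    from countshapes import SimulationSpec

    spec_b = SimulationSpec(genes=genes_b, n_cells=n_cells, seed=seed_b, condition="B")
    mat_a, des_a, truth_a = simulate_dataset(spec_a)
    mat_b, des_b, truth_b = simulate_dataset(spec_b)

    import pandas as pd

    cells_a = [f"A_{c}" for c in mat_a.cells]
    cells_b = [f"B_{c}" for c in mat_b.cells]
    matrix = CountMatrix(
        list(mat_a.genes), cells_a + cells_b,
        np.hstack([mat_a.counts, mat_b.counts]),
    )
    table = pd.concat([
        des_a.table.set_axis(cells_a), des_b.table.set_axis(cells_b),
    ])
    design = CellDesign(table, condition="condition")
    truth = truth_a.merge(truth_b, on="gene", suffixes=("_A", "_B"))
    return matrix, design, truth
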