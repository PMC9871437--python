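import numpy as np
import pandas as pd
import pytest

from countshapes import (
    CellDesign,
    CountMatrix,
    SimulationSpec,
    classification_metrics,
    random_spec,
    simulate_dataset,
    subsample_cells,
)


class TestSimulator:
    def test_same_seed_identical(self):
        spec = random_spec(np.random.default_rng(1), n_per_family=5, n_cells=200, seed=9)
        m1, d1, t1 = simulate_dataset(spec)
        m2, d2, t2 = simulate_dataset(spec)
        np.testing.assert_array_equal(m1.counts, m2.counts)
        pd.testing.assert_frame_equal(d1.table, d2.table)

    def test_poisson_gene_moment(self):
        genes = pd.DataFrame(
            [{"gene": "g0", "family": "P", "beta0": np.log(0.01), "phi": np.nan,
              "omega": np.nan}]
        )
        sizes = np.full(3000, 1000.0)
        spec = SimulationSpec(genes=genes, n_cells=3000, seed=4, library_sizes=sizes)
        matrix, _, _ = simulate_dataset(spec)
        mean = matrix.counts[0].mean()
        se = np.sqrt(10 / 3000)  # Poisson variance 10 per cell
        assert abs(mean - 10.0) < 3 * se

    def test_zinb_zero_mass(self):
        phi, omega = 2.0, 0.4
        genes = pd.DataFrame(
            [{"gene": "g0", "family": "ZINB", "beta0": np.log(5.0 / 1000), "phi": phi,
              "omega": omega}]
        )
        sizes = np.full(4000, 1000.0)
        spec = SimulationSpec(genes=genes, n_cells=4000, seed=5, library_sizes=sizes)
        matrix, _, _ = simulate_dataset(spec)
        nb_zero = (phi / (phi + 5.0)) ** phi
        expected = omega + (1 - omega) * nb_zero
        observed = np.mean(matrix.counts[0] == 0)
        assert observed == pytest.approx(expected, abs=3 * np.sqrt(expected / 4000) + 0.01)

    def test_empirical_library_resampling(self):
        empirical = np.array([100.0, 200.0, 400.0])
        spec = SimulationSpec(
            genes=pd.DataFrame([{"gene": "g0", "family": "P", "beta0": -3.0}]),
            n_cells=500, seed=6, library_sizes=empirical,
        )
        _, design, _ = simulate_dataset(spec)
        assert set(design.table["library_size"]) <= set(empirical)

    def test_truth_labels_match_spec(self):
        spec = random_spec(np.random.default_rng(2), n_per_family=3, n_cells=50, seed=1)
        _, _, truth = simulate_dataset(spec)
        assert truth["true_family"].value_counts().to_dict() == {
            "P": 3, "NB": 3, "ZIP": 3, "ZINB": 3
        }


class TestMetrics:
    def test_perfect_prediction(self):
        labels = ["P", "NB", "ZIP", "ZINB"] * 5
        cm = classification_metrics(labels, labels)
        for fam in ("P", "NB", "ZIP", "ZINB"):
            assert cm.metric(fam, "accuracy") == 1.0
            assert cm.metric(fam, "sensitivity") == 1.0
            assert cm.metric(fam, "specificity") == 1.0

    def test_printed_formula_values(self):
        # one family with TP=90, FN=10, TN=280, FP=20
        truth = ["P"] * 100 + ["NB"] * 300
        pred = ["P"] * 90 + ["NB"] * 10 + ["NB"] * 280 + ["P"] * 20
        cm = classification_metrics(truth, pred)
        assert cm.metric("P", "accuracy") == pytest.approx(0.925)
        assert cm.metric("P", "sensitivity") == pytest.approx(0.900)
        assert cm.metric("P", "specificity") == pytest.approx(280 / 300, abs=1e-9)
        assert cm.metric("P", "specificity") == pytest.approx(0.9333, abs=1e-4)

    def test_constant_predictor(self):
        truth = ["P", "NB", "ZIP", "ZINB"]
        pred = ["P"] * 4
        cm = classification_metrics(truth, pred)
        assert cm.metric("P", "sensitivity") == 1.0
        assert cm.metric("P", "specificity") == 0.0

    def test_counts_partition_total(self):
        rng = np.random.default_rng(0)
        fams = np.array(["P", "NB", "ZIP", "ZINB"])
        truth = rng.choice(fams, 200)
        pred = rng.choice(fams, 200)
        cm = classification_metrics(truth, pred)
        for fam in fams:
            row = cm.table.loc[fam]
            assert row["TP"] + row["FP"] + row["TN"] + row["FN"] == 200

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(["P"], ["FAILED"])


def make_typed_design(sizes_by_type):
    rows, cells = [], []
    i = 0
    for ctype, sizes in sizes_by_type.items():
        for s in sizes:
            cells.append(f"c{i}")
            rows.append({"condition": "A", "cell_type": ctype, "library_size": s})
            i += 1
    table = pd.DataFrame(rows, index=cells)
    matrix = CountMatrix(["g1"], cells, np.ones((1, len(cells)), dtype=int))
    return matrix, CellDesign(table, covariates=["cell_type"])


class TestSubsampling:
    def test_random_per_type_and_clamping(self):
        matrix, design = make_typed_design(
            {"T": np.full(50, 100.0), "B": np.full(5, 100.0)}
        )
        cells = subsample_cells(matrix, design, "random", per_type=10,
                                cell_type="cell_type", seed=0)
        types = design.table.loc[cells, "cell_type"]
        assert (types == "T").sum() == 10
        assert (types == "B").sum() == 5  # clamped to type size

    def test_proportion_largest_remainder(self):
        matrix, design = make_typed_design(
            {"T": np.full(70, 10.0), "B": np.full(20, 10.0), "NK": np.full(10, 10.0)}
        )
        cells = subsample_cells(matrix, design, "proportion", n_target=50,
                                cell_type="cell_type", seed=1)
        assert len(cells) == 50
        counts = design.table.loc[cells, "cell_type"].value_counts()
        for ctype, frac in [("T", 0.7), ("B", 0.2), ("NK", 0.1)]:
            assert abs(counts.get(ctype, 0) - frac * 50) <= 1

    def test_kernel_constant_density_is_uniform(self):
        matrix, design = make_typed_design({"T": np.full(40, 500.0)})
        cells = subsample_cells(matrix, design, "kernel", per_type=10,
                                cell_type="cell_type", seed=2)
        assert len(cells) == 10 and len(set(cells)) == 10

    def test_kernel_flattens_bimodal_depth(self):
        """With 80/20 cells at log10 depth 2.5/4.0, density weighting should
        pull the sampled shares toward 50/50."""
        rng = np.random.default_rng(3)
        shares = []
        for seed in range(40):
            lows = 10 ** (2.5 + 0.05 * rng.standard_normal(160))
            highs = 10 ** (4.0 + 0.05 * rng.standard_normal(40))
            matrix, design = make_typed_design({"T": np.concatenate([lows, highs])})
            cells = subsample_cells(matrix, design, "kernel", per_type=50,
                                    cell_type="cell_type", seed=seed)
            low_share = (design.table.loc[cells, "library_size"] < 1000).mean()
            shares.append(low_share)
        assert abs(np.mean(shares) - 0.5) < abs(0.8 - 0.5)
        assert np.mean(shares) < 0.7  # clearly flatter than the 80/20 source
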