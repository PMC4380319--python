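"""Weight extraction (dual sum), standardization, ordering, log-odds matrix."""

import warnings

import numpy as np
import pandas as pd
import pytest

from varinterp.interpret import (
    AA_PROPERTY_ORDER,
    LogOddsMatrix,
    extract_weights,
    heatmap_emit,
    log_odds_matrix,
    order_rows_cols,
    primal_weights,
    standardize_weights,
    weight_table,
    WeightTable,
)
from varinterp.features import FeatureMatrix
from varinterp.io import VariantRecord
from varinterp.models import TrainingConfig, train_subset

from conftest import matrix, separable_toy


class TestExtractWeights:
    def test_two_point_symmetric_toy(self):
        # first coordinate symmetric within each class -> carries no signal
        X = np.array([[0.5, 1.0], [0.5, -1.0], [-0.5, 1.0], [-0.5, -1.0]])
        y = np.array([1, 0, 1, 0])
        model = train_subset(matrix(X), y, TrainingConfig(seed=0, probability=False))
        w = extract_weights(model)
        assert abs(w[1]) > 100 * abs(w[0])
        assert w[1] > 0  # class 1 sits at positive second coordinate

    def test_dual_sum_equals_primal(self):
        M, y = separable_toy(n=80, seed=3)
        model = train_subset(M, y, TrainingConfig(seed=0))
        w_dual, w_primal = extract_weights(model), primal_weights(model)
        assert np.abs(w_dual - w_primal).max() <= 1e-6 * np.abs(w_primal).max()

    def test_rbf_model_not_interpretable(self):
        M, y = separable_toy()
        model = train_subset(M, y, TrainingConfig.rbf(seed=0, probability=False))
        with pytest.raises(ValueError):
            extract_weights(model)


class TestStandardizeWeights:
    def test_hand_computed_example(self):
        z = standardize_weights(np.array([1.0, 2.0, 3.0]))
        assert z == pytest.approx([-1.22474487, 0.0, 1.22474487])

    def test_idempotent_on_standardized_vector(self):
        z = standardize_weights(np.array([0.3, -1.2, 2.0, -0.5]))
        assert np.abs(standardize_weights(z) - z).max() < 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            standardize_weights(np.array([1.0, 1.0, 1.0]))


class TestWeightTable:
    def train_pair(self):
        M, y = separable_toy(n=60, seed=1)
        cfg = TrainingConfig(seed=0, probability=False)
        return {
            "A": train_subset(M, y, cfg, key="A"),
            "C": train_subset(M, 1 - y, cfg, key="C"),
        }

    def test_rows_standardized_over_retained_features(self):
        models = self.train_pair()
        table = weight_table(models)
        for _, row in table.df.iterrows():
            vals = row.dropna().to_numpy()
            assert abs(vals.mean()) < 1e-9 and abs(vals.std() - 1) < 1e-9

    def test_dropped_features_masked(self):
        # give one model an extra constant column so it is dropped there
        M, y = separable_toy(n=60, seed=1)
        df = M.df.copy()
        df[("x", "f2")] = 1.0
        cfg = TrainingConfig(seed=0, probability=False)
        models = {
            "A": train_subset(FeatureMatrix(df), y, cfg, key="A"),
            "C": train_subset(M, y, cfg, key="C"),
        }
        table = weight_table(models)
        assert np.isnan(table.df.loc["A", ("x", "f2")])
        assert ("x", "f2") not in [c for c in models["A"].retained_features]

    def test_category_mismatch_rejected(self):
        M, y = separable_toy(n=60, seed=1)
        other = FeatureMatrix(M.df.rename(columns={"x": "y"}, level=0))
        cfg = TrainingConfig(seed=0, probability=False)
        models = {
            "A": train_subset(M, y, cfg, key="A"),
            "B": train_subset(other, y, cfg, key="B"),
        }
        with pytest.raises(ValueError):
            weight_table(models)


class TestOrdering:
    def make_table(self):
        df = pd.DataFrame(
            [[1.0, 1.0, -1.0], [0.9, 0.9, -0.9], [-1.0, -1.0, 1.0]],
            index=["D", "A", "C"],
            columns=pd.MultiIndex.from_tuples(
                [("x", "p"), ("x", "q"), ("x", "r")]
            ),
        )
        return WeightTable(df)

    def test_identical_columns_cluster_adjacent(self):
        ordered = order_rows_cols(self.make_table(), "cluster")
        cols = [c[1] for c in ordered.df.columns]
        assert abs(cols.index("p") - cols.index("q")) == 1

    def test_aa_property_mode_is_pure_permutation(self):
        table = self.make_table()
        ordered = order_rows_cols(table, "aa_property")
        assert sorted(ordered.df.index) == sorted(table.df.index)
        assert ordered.df.index.tolist() == ["D", "A", "C"]  # property order D<A<C
        np.testing.assert_array_equal(
            np.sort(ordered.df.to_numpy().ravel()), np.sort(table.df.to_numpy().ravel())
        )

    def test_single_row_cluster_identity(self):
        df = self.make_table().df.iloc[:1]
        ordered = order_rows_cols(WeightTable(df), "cluster")
        assert ordered.df.index.tolist() == df.index.tolist()


class TestLogOdds:
    def make_variants(self, counts):
        """counts: {(ref, mut, label): n}"""
        variants = []
        i = 0
        for (ref, mut, label), n in counts.items():
            for _ in range(n):
                i += 1
                variants.append(VariantRecord("P1", i + 1, ref, mut, label=label))
        return variants

    def test_hand_computed_cell(self):
        # d=2, n=1 with D=4, N=4 and c=0 -> log((2/4)/(1/4)) = log 2
        variants = self.make_variants(
            {
                ("D", "E", 1): 2, ("A", "V", 1): 2,
                ("D", "E", 0): 1, ("A", "V", 0): 3,
            }
        )
        lom = log_odds_matrix(variants, pseudocount=0.0)
        assert lom.df.loc["D", "E"] == pytest.approx(np.log(2))

    def test_equal_relative_frequency_gives_zero(self):
        variants = self.make_variants({("D", "E", 1): 2, ("D", "E", 0): 2})
        lom = log_odds_matrix(variants, pseudocount=0.0)
        assert lom.df.loc["D", "E"] == pytest.approx(0.0)

    def test_label_swap_negates_matrix(self):
        variants = self.make_variants(
            {("D", "E", 1): 3, ("A", "V", 1): 1, ("D", "G", 0): 2, ("A", "V", 0): 2}
        )
        swapped = [v.with_label(1 - v.label) for v in variants]
        a = log_odds_matrix(variants).df.to_numpy()
        b = log_odds_matrix(swapped).df.to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_mask_complements_reachable_pairs(self):
        variants = self.make_variants({("D", "E", 1): 1, ("A", "V", 0): 1})
        lom = log_odds_matrix(variants)
        n_masked = int(lom.mask.to_numpy().sum())
        assert n_masked == 380 - 150 + 20  # unreachable pairs + diagonal

    def test_single_class_rejected(self):
        variants = self.make_variants({("D", "E", 1): 2})
        with pytest.raises(ValueError):
            log_odds_matrix(variants)


class TestHeatmapEmit:
    def test_writes_tsv_and_png(self, tmp_path):
        df = pd.DataFrame(
            [[1.0, np.nan], [-0.5, 0.2]],
            index=["A", "C"],
            columns=pd.MultiIndex.from_tuples([("x", "p"), ("x", "q")]),
        )
        tsv, png = heatmap_emit(WeightTable(df), tmp_path / "weights")
        assert tsv.exists() and png.exists()
        text = tsv.read_text()
        assert "NA" in text and "x:p" in text
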