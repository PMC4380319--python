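"""Feature encodings: values against hand-computed oracles, plus invariants."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from varinterp import features
from varinterp.features import (
    FeatureMatrix,
    WindowSpec,
    apply_scaler,
    assemble,
    conservation_features,
    domain_features,
    drop_constant_columns,
    physchem_features,
    standardize,
    substitution_features,
    surrounding_features,
)
from varinterp.genetic_code import AMINO_ACIDS, reachable_mutants
from varinterp.io import MsaColumn, PfamAnnotation, ScaleSet, VariantRecord

AA = st.sampled_from(AMINO_ACIDS)


def V(pos, ref, mut, pid="P1"):
    return VariantRecord(pid, pos, ref, mut)


class TestSubstitution:
    def test_reference_minus_one_mutant_plus_one(self):
        x = substitution_features(V(5, "D", "G"))
        assert x[AMINO_ACIDS.index("D")] == -1
        assert x[AMINO_ACIDS.index("G")] == 1
        assert np.count_nonzero(x) == 2

    @given(ref=AA, mut=AA)
    def test_vector_sums_to_zero(self, ref, mut):
        if ref == mut:
            return
        assert substitution_features(V(5, ref, mut)).sum() == 0

    def test_non_standard_letter_rejected(self):
        with pytest.raises(ValueError):
            substitution_features(V(5, "B", "G"))


class TestSurrounding:
    def test_poly_alanine_window_counts(self):
        seq = "A" * 30
        x = surrounding_features(V(10, "A", "V"), seq, WindowSpec(19, include_center=False))
        assert x[AMINO_ACIDS.index("A")] == 18 and x.sum() == 18

    def test_center_included_by_default(self):
        seq = "A" * 30
        x = surrounding_features(V(10, "A", "V"), seq)
        assert x.sum() == 19

    def test_truncation_at_sequence_start(self):
        seq = "A" * 30
        x = surrounding_features(V(1, "A", "V"), seq)
        assert x.sum() == 10  # positions 1..10

    @given(pos=st.integers(1, 32))
    def test_counts_sum_to_realized_window(self, toy_proteins, pos):
        seq = toy_proteins["P2"]
        v = V(pos, seq[pos - 1], "G" if seq[pos - 1] != "G" else "A", "P2")
        x = surrounding_features(v, seq)
        lo, hi = max(1, pos - 9), min(len(seq), pos + 9)
        assert x.sum() == hi - lo + 1


class TestConservation:
    def test_hand_counted_frequencies(self):
        col = MsaColumn(Counter("AAAV"), n_proteins=5)
        f = conservation_features(V(3, "A", "V"), col)
        assert f.tolist() == [0.75, 0.25, 5.0, 4.0]

    def test_query_only_column(self):
        col = MsaColumn(Counter("A"), n_proteins=1)
        f = conservation_features(V(3, "A", "V"), col)
        assert f[0] == 1.0 and f[1] == 0.0

    def test_empty_column_degenerate(self):
        col = MsaColumn(Counter(), n_proteins=4)
        f = conservation_features(V(3, "A", "V"), col)
        assert f.tolist() == [0.0, 0.0, 4.0, 0.0]

    def test_n_proteins_denominator_option(self):
        col = MsaColumn(Counter("AAAV"), n_proteins=8)
        f = conservation_features(V(3, "A", "V"), col, denominator="n_proteins")
        assert f[0] == pytest.approx(3 / 8)


class TestPhyschem:
    SCALES = ScaleSet(
        names=("s1",),
        values={"s1": {aa: float(i) / 10 for i, aa in enumerate(AMINO_ACIDS)}},
    )

    def test_zero_distance_when_mutant_observed(self):
        col = MsaColumn(Counter("AW"), n_proteins=2)
        assert physchem_features(V(3, "A", "W"), col, self.SCALES).tolist() == [0.0]

    def test_min_distance_to_single_residue(self):
        scales = ScaleSet(names=("s1",), values={"s1": {**{a: 0.0 for a in AMINO_ACIDS}, "W": 2.0, "G": 0.0}})
        col = MsaColumn(Counter("G"), n_proteins=1)
        assert physchem_features(V(3, "G", "W"), col, scales).tolist() == [2.0]

    def test_min_over_observed_residues(self):
        values = {a: 10.0 for a in AMINO_ACIDS}
        values.update({"A": 1.0, "V": 1.5, "L": 1.4})
        scales = ScaleSet(names=("s1",), values={"s1": values})
        col = MsaColumn(Counter("AV"), n_proteins=2)
        d = physchem_features(V(3, "A", "L"), col, scales)
        assert d[0] == pytest.approx(0.1)

    def test_empty_column_is_zero(self):
        col = MsaColumn(Counter(), n_proteins=3)
        assert physchem_features(V(3, "A", "W"), col, self.SCALES).tolist() == [0.0]


class TestDomain:
    def test_domain_span_membership(self):
        anns = [PfamAnnotation("P1", 10, 80, "domain")]
        assert domain_features(V(50, "A", "V"), anns).tolist() == [0.0, 1.0, 0.0]

    def test_no_annotations(self):
        assert domain_features(V(50, "A", "V"), []).tolist() == [0.0, 0.0, 0.0]

    def test_overlapping_family_and_clan(self):
        anns = [
            PfamAnnotation("P1", 40, 60, "family"),
            PfamAnnotation("P1", 30, 70, "clan-member", "CL1"),
        ]
        assert domain_features(V(50, "A", "V"), anns).tolist() == [1.0, 0.0, 1.0]


class TestAssemble:
    def test_column_blocks_and_row_order(self, toy_resources):
        seq = toy_resources.proteins["P2"]
        variants = [V(5, seq[4], "K", "P2"), V(7, seq[6], "R", "P2")]
        M, excluded = assemble(variants, toy_resources)
        assert not excluded
        cats = [c for c, _ in M.df.columns]
        assert cats == sorted(cats, key=list(features.CATEGORIES).index)
        assert list(M.df.index) == [v.variant_id for v in variants]
        assert M.df.shape == (2, 20 + 20 + 4 + len(toy_resources.scales) + 3)

    def test_permutation_equivariant_in_rows(self, toy_resources):
        seq = toy_resources.proteins["P2"]
        variants = [V(5, seq[4], "K", "P2"), V(7, seq[6], "R", "P2"), V(10, seq[9], "R", "P2")]
        M1, _ = assemble(variants, toy_resources)
        M2, _ = assemble(variants[::-1], toy_resources)
        pd.testing.assert_frame_equal(M1.df, M2.df.iloc[::-1])

    def test_missing_msa_reported(self, toy_resources):
        v = VariantRecord("GHOST", 3, "A", "V")
        M, excluded = assemble(
            [v], features.Resources({"GHOST": "MAV"}, {}, {}, toy_resources.scales)
        )
        assert len(M) == 0 and "no MSA" in excluded[0]

    def test_physchem_zero_whenever_mutant_frequency_positive(self, small_dataset):
        M = small_dataset.true_features
        f_mut = M.df[("conservation", "f_mut")].to_numpy()
        phys = M.category("physchem").values
        assert np.all(phys[f_mut > 0].sum(axis=1) == 0)


class TestConstantRemovalAndScaling:
    def test_serine_subset_removes_methods_feature_list(self):
        # build the substitution block for every serine variant the genetic
        # code admits; S itself plus the unreachable D,E,H,K,M,Q,V must drop
        variants = [V(5, "S", m) for m in sorted(reachable_mutants("S"))]
        rows = np.array([substitution_features(v) for v in variants])
        df = pd.DataFrame(
            rows,
            index=[v.variant_id for v in variants],
            columns=pd.MultiIndex.from_tuples([("substitution", a) for a in AMINO_ACIDS]),
        )
        _, dropped = drop_constant_columns(FeatureMatrix(df))
        assert {name for _, name in dropped} == set("S") | set("DEHKMQV")

    def test_no_constant_columns_is_identity(self):
        df = pd.DataFrame(
            {("x", "a"): [0.0, 1.0], ("x", "b"): [1.0, 0.0]},
        )
        M2, dropped = drop_constant_columns(FeatureMatrix(df))
        assert dropped == [] and M2.df.equals(df)

    def test_all_constant_matrix_rejected(self):
        df = pd.DataFrame({("x", "a"): [1.0, 1.0]})
        with pytest.raises(ValueError):
            drop_constant_columns(FeatureMatrix(df))

    def test_population_sd_hand_example(self):
        df = pd.DataFrame({("x", "a"): [0.0, 2.0]})
        scaled, scaler = standardize(FeatureMatrix(df))
        assert scaled.df[("x", "a")].tolist() == [-1.0, 1.0]
        assert scaler.loc["mean", ("x", "a")] == 1.0 and scaler.loc["sd", ("x", "a")] == 1.0

    def test_restandardizing_is_identity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=pd.MultiIndex.from_tuples([("x", c) for c in "abc"]))
        once, _ = standardize(FeatureMatrix(df))
        twice, _ = standardize(once)
        assert np.abs(twice.df.to_numpy() - once.df.to_numpy()).max() < 1e-12

    def test_standardized_moments(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.exponential(size=(100, 2)), columns=pd.MultiIndex.from_tuples([("x", "a"), ("x", "b")]))
        scaled, _ = standardize(FeatureMatrix(df))
        assert np.abs(scaled.df.mean()).max() < 1e-9
        assert np.abs(scaled.df.std(ddof=0) - 1).max() < 1e-9

    def test_scaler_reapplied_verbatim_and_mismatch_rejected(self):
        df = pd.DataFrame({("x", "a"): [0.0, 2.0, 4.0]})
        _, scaler = standardize(FeatureMatrix(df))
        test = FeatureMatrix(pd.DataFrame({("x", "a"): [6.0]}))
        out = apply_scaler(test, scaler)
        assert out.df.iloc[0, 0] == pytest.approx((6.0 - 2.0) / np.sqrt(8 / 3))
        with pytest.raises(ValueError):
            apply_scaler(FeatureMatrix(pd.DataFrame({("x", "zz"): [1.0]})), scaler)
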