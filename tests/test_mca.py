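"""Indicator encoding, Burt matrix and the correspondence-analysis SVD."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from mcakm import mca
from mcakm.mca import (
    build_burt,
    encode_indicator,
    fit_ca,
    fit_mca,
    inertia_profile,
    select_dimensions,
)


from _oracles import assert_equal_up_to_sign, brute_force_ca


class TestEncodeIndicator:
    def test_table1_shape_row_sums_and_column_sums(self, table1_cohort):
        X = encode_indicator(table1_cohort)
        assert X.n_columns == 33 and X.n_variables == 16
        assert np.all(X.values.sum(axis=1) == 16)
        j_male = X.column_labels.index(("sex", "Male"))
        assert X.values[:, j_male].sum() == 520

    def test_two_row_binary_identity_pattern(self):
        df = pd.DataFrame({"a": ["Yes", "No"]})
        X = encode_indicator(df)
        assert X.values.shape == (2, 2)
        assert X.values.sum() == 2 and np.all(X.values.sum(axis=1) == 1)

    def test_single_observed_level_rejected(self):
        df = pd.DataFrame({"a": ["Yes", "No"], "flat": ["x", "x"]})
        with pytest.raises(ValueError, match="flat"):
            encode_indicator(df)

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"a": ["Yes", None, "No"]})
        with pytest.raises(ValueError, match="missing"):
            encode_indicator(df)


class TestBurt:
    def test_complete_factorial_off_diagonal_block(self):
        df = pd.DataFrame({"a": ["x", "x", "y", "y"], "b": ["u", "v", "u", "v"]})
        B = build_burt(encode_indicator(df))
        assert np.array_equal(B[:2, 2:], np.ones((2, 2)))

    def test_diagonal_blocks_are_level_counts(self, table1_cohort):
        X = encode_indicator(table1_cohort)
        B = build_burt(X)
        j_male = X.column_labels.index(("sex", "Male"))
        assert B[j_male, j_male] == 520
        sex = X.variable_index["sex"]
        assert np.allclose(B[sex, sex], np.diag(np.diag(B[sex, sex])))

    def test_trace_equals_rows_times_variables(self, random_table):
        df = random_table(n_rows=25, n_vars=3, seed=7)
        X = encode_indicator(df)
        assert np.trace(build_burt(X)) == 25 * 3


class TestFitMca:
    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_random_tables(self, random_table, seed):
        df = random_table(n_rows=10 * (seed + 1), n_vars=2 + seed % 4, seed=seed)
        X = encode_indicator(df)
        model = fit_mca(X)
        F, G, evals = brute_force_ca(X.values)
        d = model.n_dimensions
        assert np.allclose(model.eigenvalues, evals[:d], atol=1e-10)
        assert_equal_up_to_sign(model.F, F[:, :d])
        assert_equal_up_to_sign(model.G, G[:, :d])

    def test_independent_table_has_zero_inertia(self):
        table = np.outer([1, 2, 3], [2, 5, 3])  # rank-1: P = r c' exactly
        model = fit_ca(table)
        assert model.n_dimensions == 0
        assert model.total_inertia < 1e-20
        assert model.F.shape[1] == 0 and model.G.shape[1] == 0

    def test_indicator_total_inertia_closed_form(self, table1_cohort, random_table):
        for df in (table1_cohort, random_table(n_rows=40, n_vars=5, seed=3)):
            X = encode_indicator(df)
            model = fit_mca(X)
            J, K = X.n_columns, X.n_variables
            assert model.total_inertia == pytest.approx(J / K - 1, abs=1e-8)
            assert model.total_inertia == pytest.approx(model.eigenvalues.sum(), abs=1e-8)

    def test_burt_eigenvalues_are_squared_indicator_eigenvalues(self, random_table):
        X = encode_indicator(random_table(n_rows=20, n_vars=3, seed=1))
        ind = fit_mca(X, basis="indicator")
        burt = fit_mca(X, basis="burt")
        d = min(ind.n_dimensions, burt.n_dimensions)
        assert np.allclose(burt.eigenvalues[:d], ind.eigenvalues[:d] ** 2, atol=1e-8)

    def test_duplicated_category_gives_identical_g_rows(self):
        df = pd.DataFrame(
            {
                "a": ["x", "x", "y", "y", "x", "y"],
                "b": ["x", "x", "y", "y", "x", "y"],  # duplicate of a
                "c": ["u", "v", "u", "v", "v", "u"],
            }
        )
        model = fit_mca(encode_indicator(df))
        labels = model.column_labels
        for level in ("x", "y"):
            i = labels.index(("a", level))
            j = labels.index(("b", level))
            assert np.allclose(model.G[i], model.G[j], atol=1e-8)

    def test_masses_center_the_coordinates(self, table1_cohort):
        model = fit_mca(encode_indicator(table1_cohort))
        assert np.allclose(model.c @ model.G, 0, atol=1e-8)
        assert np.allclose(model.r @ model.F, 0, atol=1e-8)
        assert np.all(np.diff(model.singular_values) <= 1e-12)
        assert np.allclose(model.eigenvalues, model.singular_values**2, atol=1e-10)

    def test_barycentric_transition_relation(self, random_table):
        model = fit_mca(encode_indicator(random_table(n_rows=30, n_vars=4, seed=9)))
        # G = Dc^{-1} P' F Delta^{-1}
        G_from_F = (model.P.T @ model.F) / model.c[:, None] / model.singular_values
        assert np.allclose(G_from_F, model.G, atol=1e-8)

    def test_row_permutation_leaves_g_unchanged(self, random_table):
        df = random_table(n_rows=20, n_vars=3, seed=5)
        perm = np.random.default_rng(0).permutation(len(df))
        m1 = fit_mca(encode_indicator(df))
        m2 = fit_mca(encode_indicator(df.iloc[perm].reset_index(drop=True)))
        assert np.allclose(m1.G, m2.G, atol=1e-8)
        assert np.allclose(m1.F[perm], m2.F, atol=1e-8)

    def test_zero_mass_column_rejected(self):
        with pytest.raises(ValueError, match="zero column mass"):
            fit_ca(np.array([[1.0, 0.0], [2.0, 0.0]]))


class TestInertiaProfile:
    def test_full_cumulative_is_one(self, random_table):
        model = fit_mca(encode_indicator(random_table(seed=2)))
        profile = inertia_profile(model)
        assert profile.cumulative[-1] == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(profile.cumulative) >= -1e-12)

    def test_subset_point_inertias_sum_to_retained_eigenvalues(self, random_table):
        model = fit_mca(encode_indicator(random_table(n_rows=35, n_vars=4, seed=6)))
        for d in (1, 2, model.n_dimensions):
            profile = inertia_profile(model, subset_dims=d)
            lam = model.eigenvalues[:d].sum()
            assert profile.column_point_inertias.sum() == pytest.approx(lam, abs=1e-8)
            assert profile.row_point_inertias.sum() == pytest.approx(lam, abs=1e-8)

    def test_column_point_inertias_match_chi_square_decomposition(self, random_table):
        df = random_table(n_rows=30, n_vars=3, seed=12)
        model = fit_mca(encode_indicator(df))
        profile = inertia_profile(model)
        # direct chi-squared contribution of each column of the table
        expected = ((model.P - np.outer(model.r, model.c)) ** 2 / np.outer(model.r, model.c)).sum(0)
        assert np.allclose(profile.column_point_inertias, expected, atol=1e-8)

    def test_rank2_single_axis_share(self):
        # 3x3 table with exactly two non-trivial axes
        table = np.array([[10, 2, 3], [2, 8, 1], [3, 1, 9]], dtype=float)
        model = fit_ca(table)
        assert model.n_dimensions == 2
        profile = inertia_profile(model, subset_dims=1)
        lam = model.eigenvalues
        assert profile.cumulative[0] == pytest.approx(lam[0] / lam.sum(), abs=1e-12)


class TestSelectDimensions:
    def test_threshold_one_keeps_all_axes(self, random_table):
        model = fit_mca(encode_indicator(random_table(seed=4)))
        profile = inertia_profile(model)
        assert select_dimensions(profile, threshold=1.0) == model.n_dimensions
        assert select_dimensions(profile, rule="all") == model.n_dimensions

    def test_smallest_dimension_reaching_threshold(self):
        table = np.array([[10, 2, 3], [2, 8, 1], [3, 1, 9]], dtype=float)
        profile = inertia_profile(fit_ca(table))
        share1 = profile.proportions[0]
        assert select_dimensions(profile, threshold=share1 - 0.01) == 1
        assert select_dimensions(profile, threshold=share1 + 0.01) == 2

    def test_planted_structure_needs_multiple_axes(self, table1_cohort):
        from mcakm import synthetic

        spec = synthetic.cohort_preset("table1_planted", seed=3)
        model = fit_mca(encode_indicator(synthetic.generate_cohort(spec)))
        d = select_dimensions(inertia_profile(model), threshold=0.8)
        assert d >= 2
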