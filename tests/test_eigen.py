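"""Dual eigen-analysis: SVD identities, polarization, contrasts, accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dualeigen as de
from dualeigen.eigen import decompose


class TestDecompose:
    def test_constant_matrix_rank1_closed_form(self):
        s, g, c = 4, 10, 2.5
        d = decompose(np.full((s, g), c))
        assert d.n_components == 1
        assert d.lam(0) == pytest.approx(c * np.sqrt(s * g), rel=1e-12)
        np.testing.assert_allclose(d.u(0), np.full(s, 1 / np.sqrt(s)), rtol=1e-12)

    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(0)
        E = rng.normal(8, 1, (4, 20))
        d = decompose(E)
        np.testing.assert_allclose(d.reconstruct(), E, atol=1e-8 * np.abs(E).max())
        U = d.sample_eigenvectors
        V = d.gene_eigenvectors
        np.testing.assert_allclose(U @ U.T, np.eye(len(U)), atol=1e-8)
        np.testing.assert_allclose(V @ V.T, np.eye(len(V)), atol=1e-8)
        assert np.all(np.diff(d.singular_values) <= 0)

    def test_singular_values_match_gram_eigenvalues(self):
        # brute-force eigendecomposition of E E^T as the independent oracle
        rng = np.random.default_rng(1)
        E = rng.normal(0, 1, (3, 5))
        d = decompose(E)
        eigvals = np.sort(np.linalg.eigvalsh(E @ E.T))[::-1]
        np.testing.assert_allclose(d.singular_values**2, eigvals, rtol=1e-8)

    def test_non_finite_rejected(self):
        E = np.ones((3, 5))
        E[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            decompose(E)


class TestBaseline:
    def test_constant_matrix_cv_zero(self):
        cv, flag = de.baseline_cv(decompose(np.full((5, 12), 3.0)))
        assert cv == pytest.approx(0.0, abs=1e-10)
        assert flag

    def test_synthetic_shift_sd_005_gives_cv_below_2pct(self, small_dataset):
        A, B, *_ = small_dataset
        for profile in (A, B):
            cv, flag = de.baseline_cv(decompose(profile))
            assert cv < 2.0
            assert flag

    def test_contrast_gap_zero_for_exact_contrast(self):
        s, g = 6, 40
        u1 = np.array([1, -1, 1, -1, 1, -1]) / np.sqrt(6)
        rng = np.random.default_rng(2)
        v1 = rng.normal(size=g)
        v1 -= v1.mean()  # orthogonal to the constant baseline gene vector
        v1 /= np.linalg.norm(v1)
        E = 5.0 + 0.8 * np.outer(u1, v1)
        d = decompose(E)
        assert de.empirical_contrast_gap(d, 1) < 1e-10

    def test_contrast_gap_bounded_by_baseline_deviation(self, small_dataset):
        A, *_ = small_dataset
        d = decompose(A)
        cv, _ = de.baseline_cv(d)
        gap = de.empirical_contrast_gap(d, 1)
        # |sum u_k| = |<u_k, 1 - sqrt(s) u_0>| <= ||1 - sqrt(s) u_0|| ~ sqrt(s) CV
        assert gap <= np.sqrt(A.n_samples) * cv / 100.0

    def test_gap_on_baseline_is_an_error(self, small_dataset):
        A, *_ = small_dataset
        with pytest.raises(ValueError, match="baseline"):
            de.empirical_contrast_gap(decompose(A), 0)


class TestPolarize:
    @pytest.fixture()
    def toy(self):
        u1 = np.array([-0.6, -0.2, 0.3, 0.5])
        u1 = u1 / np.linalg.norm(u1)
        rng = np.random.default_rng(3)
        v1 = rng.normal(size=30)
        v1 /= np.linalg.norm(v1)
        E = 7.0 + 1.3 * np.outer(u1, v1)
        return decompose(E), u1

    def test_reference_at_positive_pole_keeps_sign(self, toy):
        d, u1 = toy
        ref = [False, False, True, True]
        pol = de.polarize(d, 1, ref)
        assert not pol.flipped
        assert np.sign(pol.u @ u1) > 0

    def test_negative_reference_flips_u_and_v_together(self, toy):
        d, u1 = toy
        before = np.outer(d.u(1), d.v(1))
        pol = de.polarize(d, 1, [True, True, False, False])
        assert pol.flipped
        assert pol.u[np.array([True, True, False, False])].mean() > 0
        np.testing.assert_allclose(np.outer(pol.u, pol.v), before, atol=1e-12)

    def test_sorted_loadings_are_a_permutation(self, toy):
        d, _ = toy
        pol = de.polarize(d, 1, [False, False, True, True])
        assert sorted(pol.sorted_loadings["loading"]) == sorted(pol.u)
        assert np.all(np.diff(pol.sorted_loadings["loading"]) <= 0)

    def test_empty_reference_rejected(self, toy):
        d, _ = toy
        with pytest.raises(ValueError, match="empty"):
            de.polarize(d, 1, [False] * 4)


class TestContrastTest:
    def test_fully_separated_3v3_one_sided_exact(self):
        # 1 / C(6,3) = 0.05 by enumeration
        p = de.contrast_test(
            np.array([5.0, 6, 7, 1, 2, 3]), np.array([1, 1, 1, 0, 0, 0], bool),
            sided="greater",
        )
        assert p == pytest.approx(0.05, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        p = de.contrast_test(
            np.array([1.0, 2, 3, 1, 2, 3]), np.array([1, 1, 1, 0, 0, 0], bool)
        )
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            de.contrast_test(np.arange(4.0), np.zeros(4, bool))

    def test_null_permutation_p_uniform(self):
        rng = np.random.default_rng(4)
        loadings = rng.normal(size=20)
        labels = np.array([True] * 10 + [False] * 10)
        ps = np.sort([de.contrast_test(loadings, rng.permutation(labels))
                      for _ in range(2000)])
        # exact p-values are discrete, hence super-uniform: the ecdf may not
        # exceed the uniform cdf beyond Monte-Carlo slack
        ecdf = np.arange(1, 2001) / 2000
        d_plus = np.max(ecdf - ps)
        assert d_plus < 0.04
        assert abs(ps.mean() - 0.5) < 0.05


class TestSumOfSquares:
    def _planted(self, amps, seed=5):
        # exact SVD structure: u's orthogonal to 1_s and each other, v's
        # orthogonal to 1_g and each other
        rng = np.random.default_rng(seed)
        s, g = 8, 60
        E = np.full((s, g), 6.0)
        us, vs = [np.ones(s) / np.sqrt(s)], [np.ones(g) / np.sqrt(g)]
        for a in amps:
            u = rng.normal(size=s)
            for prev in us:
                u -= (u @ prev) * prev
            u /= np.linalg.norm(u)
            us.append(u)
            v = rng.normal(size=g)
            for prev in vs:
                v -= (v @ prev) * prev
            v /= np.linalg.norm(v)
            vs.append(v)
            E += a * np.outer(u, v)
        return decompose(E)

    def test_single_component_explains_everything(self):
        ss = de.sum_of_squares(self._planted([2.0]))
        assert ss.top_proportion(1) == pytest.approx(1.0, rel=1e-10)

    def test_per_gene_squares_sum_to_lambda1_sq(self, small_dataset):
        A, *_ = small_dataset
        d = decompose(A)
        ss = de.sum_of_squares(d)
        assert ss.per_gene_ss1.sum() == pytest.approx(d.lam(1) ** 2, rel=1e-8)

    def test_contrast_total_equals_frobenius_sq(self, small_dataset):
        A, *_ = small_dataset
        d = decompose(A)
        ss = de.sum_of_squares(d)
        lam_sq_total = float(ss.table["lambda_sq"].sum())
        assert lam_sq_total == pytest.approx(ss.frobenius_sq, rel=1e-8)
        assert ss.table["proportion"].sum() == pytest.approx(1.0, rel=1e-10)

    def test_two_components_closed_form_proportions(self):
        a, b = 3.0, 1.5
        ss = de.sum_of_squares(self._planted([a, b]))
        props = ss.table["proportion"].values[:2]
        np.testing.assert_allclose(props, [a**2 / (a**2 + b**2), b**2 / (a**2 + b**2)],
                                   rtol=1e-8)


class TestTimecourse:
    def test_identical_groups_give_zero_vectors(self):
        rng = np.random.default_rng(6)
        block = rng.normal(8, 1, (6, 15))
        E = np.vstack([block, block])  # group2 identical to group1
        prof = de.ExpressionProfile(
            E, [f"g{j}" for j in range(15)], [f"s{i}" for i in range(12)]
        )
        groups = ["a"] * 6 + ["b"] * 6
        times = [1, 1, 2, 2, 3, 3] * 2
        diff = de.timecourse_differential(prof, groups, times, group_order=("a", "b"))
        np.testing.assert_allclose(diff.values, 0, atol=1e-12)

    def test_design_yields_one_vector_per_timepoint(self, small_dataset):
        A, *_ = small_dataset
        diff = de.timecourse_differential(
            A, A.metadata["group"], A.metadata["week"], group_order=("DS", "CTL")
        )
        assert diff.shape == (A.n_genes, 5)
        assert list(diff.columns) == [4, 6, 8, 16, 24]

    def test_planted_difference_recovered(self, small_dataset, program_vector):
        A, _, _, _, truth = small_dataset
        diff = de.timecourse_differential(
            A, A.metadata["group"], A.metadata["week"], group_order=("DS", "CTL")
        )
        q = program_vector(A, truth)
        # planted pattern: +-ramp(t) per group, rms-normalized; the DS-CTL
        # difference at the last week is 2 * amplitude * pattern_height * q
        pat = truth.patterns_a["shared_program"]
        height = pat.max()  # DS loading at the last week
        expected = 2 * 2.0 * height
        got = diff.loc[np.asarray(q) > 0, 24].mean()
        assert got == pytest.approx(expected, abs=4 * 0.5 / np.sqrt(3 * 100))

    def test_missing_cell_is_named(self):
        prof = de.ExpressionProfile(
            np.zeros((3, 5)), [f"g{j}" for j in range(5)], ["a", "b", "c"]
        )
        with pytest.raises(ValueError, match="w2"):
            de.timecourse_differential(prof, ["x", "x", "y"], ["w1", "w2", "w1"])


class TestStratify:
    def test_paper_thresholds_region_definition(self):
        res = de.stratify([0.0], [0.03], threshold_x=-0.01, threshold_y=0.025)
        assert res["table"]["region"].iloc[0] == "I"
        assert res["thresholds"] == {"x": -0.01, "y": 0.025}

    def test_all_flagged_in_region_iv(self):
        x = np.array([-0.5, -0.3, -0.2])
        y = np.array([-0.1, -0.2, -0.3])
        res = de.stratify(x, y, -0.01, 0.025, flags=np.ones(3, bool))
        assert res["flagged_outside_IV"] == 0.0
        assert res["summary"]["IV"]["count"] == 3

    def test_region_counts_and_covariate_means(self):
        x = np.array([0.1, -0.1, 0.1, -0.1])
        y = np.array([0.1, 0.1, -0.1, -0.1])
        cov = np.array([48.0, 40.0, 42.0, 34.0])
        res = de.stratify(x, y, 0.0, 0.0, flags=x > 0, covariate=cov)
        assert [res["summary"][r]["count"] for r in "I II III IV".split()] == [1, 1, 1, 1]
        assert res["summary"]["I"]["covariate_mean"] == 48.0
        assert res["summary"]["IV"]["covariate_mean"] == 34.0
        assert res["flagged_outside_IV"] == 1.0
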