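import numpy as np
import pytest
from scipy import linalg

from gmkit import (
    LandmarkError,
    bgpca,
    covariance_metric,
    cva_on_pcs,
    generalized_variance_ratio,
    gpa,
    mahalanobis_distance,
    pca,
    qda_loocv_classify,
    relative_eigenanalysis,
    sample_mardia_dryden,
    total_variance,
)
from gmkit.ordination import _pooled_within_cov
from gmkit.simulate import grid_template


def random_spd(dim, rng):
    A = rng.normal(size=(dim, dim))
    return A @ A.T + dim * np.eye(dim)


class TestPca:
    def test_matches_svd_of_centered_data(self, rng):
        X = rng.normal(size=(10, 6))
        res = pca(X)
        s = np.linalg.svd(X - X.mean(0), compute_uv=False)
        np.testing.assert_allclose(res.eigenvalues, s ** 2 / 9, atol=1e-10)
        # score variances equal eigenvalues; axes orthonormal
        np.testing.assert_allclose(res.scores.var(axis=0, ddof=1)[:6],
                                   res.eigenvalues[:6], atol=1e-10)
        np.testing.assert_allclose(res.axes.T @ res.axes, np.eye(6), atol=1e-10)

    def test_isotropic_eigenvalues_similar(self, rng):
        X = rng.normal(size=(4000, 2))
        res = pca(X)
        assert res.eigenvalues[0] / res.eigenvalues[1] < 1.15

    def test_rank_one_data(self, rng):
        u = rng.normal(size=6)
        X = np.outer(rng.normal(size=9), u)
        res = pca(X)
        assert res.eigenvalues[0] > 1e-10
        assert np.all(res.eigenvalues[1:] < 1e-10 * res.eigenvalues[0])

    def test_constant_data_rejected(self):
        with pytest.raises(LandmarkError):
            pca(np.ones((5, 3)))


class TestBgpca:
    def test_two_groups_axis_is_mean_difference(self, rng):
        X = rng.normal(size=(30, 8))
        g = np.array(["A"] * 15 + ["B"] * 15)
        res = bgpca(X, g)
        d = X[g == "A"].mean(0) - X[g == "B"].mean(0)
        d /= np.linalg.norm(d)
        assert abs(res.axes[:, 0] @ d) == pytest.approx(1.0, abs=1e-10)
        # scores along the axis are exactly the projections on that vector
        proj = (X - res.center) @ res.axes[:, 0]
        np.testing.assert_allclose(res.scores[:, 0], proj, atol=1e-12)

    def test_identical_group_means_zero_variance(self, rng):
        X = rng.normal(size=(10, 4))
        X2 = np.vstack([X, X])
        g = ["A"] * 10 + ["B"] * 10
        res = bgpca(X2, g)
        assert res.eigenvalues.max() < 1e-12

    def test_cross_validation_removes_spurious_separation(self):
        tmpl = grid_template(5, 5)
        sample = sample_mardia_dryden(tmpl, n=40, sigma=0.02, seed=21)
        sup = gpa(sample)
        g = np.array(["A"] * 20 + ["B"] * 20)

        def separation(scores):
            a, b = scores[g == "A", 0], scores[g == "B", 0]
            return abs(a.mean() - b.mean()) / np.sqrt(0.5 * (a.var() + b.var()))

        naive = separation(bgpca(sup.flat(), g).scores)
        cv = separation(bgpca(sup.flat(), g, cross_validate=True).scores)
        assert naive > 1.0          # spurious separation of identical groups
        assert cv < 0.5 * naive     # largely removed by cross-validation

    def test_single_group_rejected(self, rng):
        with pytest.raises(LandmarkError):
            bgpca(rng.normal(size=(6, 3)), ["A"] * 6)


class TestCva:
    def test_isotropic_within_matches_bgpca_direction(self, rng):
        d = np.r_[np.ones(4), np.zeros(4)]
        X = rng.normal(size=(400, 8))
        g = np.array(["A"] * 200 + ["B"] * 200)
        X[g == "B"] += d
        cv = cva_on_pcs(X, g, n_pcs=8)
        bg = bgpca(X, g)
        cos = abs(cv.axes[:, 0] @ bg.axes[:, 0]) / np.linalg.norm(cv.axes[:, 0])
        assert cos > 0.97

    def test_identical_groups_artificially_separated(self):
        # as n_pcs approaches n - g, CVA separates three samples drawn from
        # one distribution almost completely
        tmpl = grid_template(5, 5)
        sample = sample_mardia_dryden(tmpl, n=30, sigma=0.02, seed=22)
        sup = gpa(sample)
        g = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        cv = cva_on_pcs(sup.flat(), g, n_pcs=26)
        for ga, gb in (("A", "B"), ("A", "C"), ("B", "C")):
            a = cv.scores[g == ga][:, :2]
            b = cv.scores[g == gb][:, :2]
            gap = np.linalg.norm(a.mean(0) - b.mean(0))
            spread = np.sqrt(a.var(axis=0).sum() + b.var(axis=0).sum())
            assert gap > 2.0 * spread  # essentially disjoint clusters

    def test_two_groups_match_fisher_discriminant(self, rng):
        X = rng.normal(size=(60, 5)) @ rng.normal(size=(5, 5))
        g = np.array(["A"] * 30 + ["B"] * 30)
        X[g == "B"] += rng.normal(size=5)
        cv = cva_on_pcs(X, g, n_pcs=5)
        base = pca(X)
        Y = base.scores[:, :5]
        W = _pooled_within_cov(Y, g, ["A", "B"])
        d = Y[g == "A"].mean(0) - Y[g == "B"].mean(0)
        fisher = linalg.solve(W, d)
        fisher_coord = base.axes[:, :5] @ fisher
        cos = abs(cv.axes[:, 0] @ fisher_coord) / (
            np.linalg.norm(cv.axes[:, 0]) * np.linalg.norm(fisher_coord)
        )
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_affine_invariance_of_scores(self, rng):
        X = rng.normal(size=(40, 4))
        g = np.array(["A"] * 20 + ["B"] * 20)
        X[g == "B", 0] += 2.0
        cv1 = cva_on_pcs(X, g, n_pcs=4)
        T = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        cv2 = cva_on_pcs(X @ T, g, n_pcs=4)
        r = np.corrcoef(cv1.scores[:, 0], cv2.scores[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)


class TestMahalanobis:
    def test_identity_covariance_is_euclidean(self):
        d = mahalanobis_distance([1, 2, 3], [0, 0, 3], np.eye(3))
        assert d == pytest.approx(np.sqrt(5))

    def test_affine_invariance(self, rng):
        ma, mb = rng.normal(size=(2, 4))
        cov = random_spd(4, rng)
        base = mahalanobis_distance(ma, mb, cov)
        T = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        trans = mahalanobis_distance(ma @ T, mb @ T, T.T @ cov @ T)
        assert trans == pytest.approx(base, rel=1e-8)

    def test_two_variable_worked_case(self):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        d = np.array([1.0, -1.0])
        expected = np.sqrt(d @ np.linalg.inv(cov) @ d)
        assert mahalanobis_distance(d, [0, 0], cov) == pytest.approx(expected)

    def test_monotone_in_pc_count(self):
        # dimensionality artifact: distance between identical-distribution
        # group means grows as PCs are added
        tmpl = grid_template(5, 5)
        sample = sample_mardia_dryden(tmpl, n=50, sigma=0.02, seed=23)
        sup = gpa(sample)
        g = np.array(["A"] * 25 + ["B"] * 25)
        base = pca(sup.flat())
        ds = []
        for m in (2, 5, 10, 20):
            Y = base.scores[:, :m]
            W = _pooled_within_cov(Y, g, ["A", "B"])
            ds.append(mahalanobis_distance(Y[g == "A"].mean(0),
                                           Y[g == "B"].mean(0), W))
        assert all(np.diff(ds) >= -1e-9)


class TestQda:
    def test_separated_clusters_perfect(self, rng):
        X = np.vstack([rng.normal(size=(15, 4)), rng.normal(size=(15, 4)) + 10])
        g = ["A"] * 15 + ["B"] * 15
        rep = qda_loocv_classify(X, g, n_pcs=2)
        assert rep.overall_rate == 1.0
        assert rep.confusion.values.sum() == 30

    def test_small_toy_matches_hand_computed_densities(self):
        X = np.array([[0.0], [0.2], [0.4], [1.9], [2.0], [2.4], [2.2]])
        g = np.array(["A", "A", "A", "B", "B", "B", "B"])
        rep = qda_loocv_classify(X, g, n_pcs=1)
        # hand check one fold: leave out case 3 (value 1.9)
        rest = np.delete(X[:, 0], 3)
        grest = np.delete(g, 3)
        centered = rest - rest.mean()
        a = centered[grest == "A"]
        b = centered[grest == "B"]
        x = X[3, 0] - rest.mean()
        ll_a = -0.5 * (np.log(a.var(ddof=1)) + (x - a.mean()) ** 2 / a.var(ddof=1))
        ll_b = -0.5 * (np.log(b.var(ddof=1)) + (x - b.mean()) ** 2 / b.var(ddof=1))
        expected = "A" if ll_a > ll_b else "B"
        pred_rate_b = rep.confusion.loc["B", expected]
        assert pred_rate_b >= 1  # the left-out B case went where the math says

    def test_group_too_small_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(LandmarkError):
            qda_loocv_classify(X, ["A"] * 3 + ["B"] * 3, n_pcs=3)


class TestRelativeEigen:
    def test_equal_matrices_all_ones(self, rng):
        C = random_spd(4, rng)
        rel = relative_eigenanalysis(C, C)
        np.testing.assert_allclose(rel.eigenvalues, 1.0, atol=1e-10)

    def test_scaled_matrix_constant_ratio(self, rng):
        C = random_spd(4, rng)
        rel = relative_eigenanalysis(2 * C, C)
        np.testing.assert_allclose(rel.eigenvalues, 2.0, atol=1e-10)

    def test_affine_invariance(self, rng):
        A, B = random_spd(5, rng), random_spd(5, rng)
        rel = relative_eigenanalysis(A, B)
        T = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        rel2 = relative_eigenanalysis(T.T @ A @ T, T.T @ B @ T)
        assert np.linalg.norm(rel.log_eigenvalues - rel2.log_eigenvalues) < 1e-8

    def test_extremes_bound_directional_ratios(self, rng):
        A, B = random_spd(3, rng), random_spd(3, rng)
        rel = relative_eigenanalysis(A, B)
        for _ in range(200):
            v = rng.normal(size=3)
            ratio = (v @ A @ v) / (v @ B @ v)
            assert rel.eigenvalues[-1] - 1e-9 <= ratio <= rel.eigenvalues[0] + 1e-9

    def test_singular_denominator_rejected(self, rng):
        A = random_spd(3, rng)
        B = np.zeros((3, 3))
        with pytest.raises(LandmarkError):
            relative_eigenanalysis(A, B)


class TestGeneralizedVariance:
    def test_product_identity(self, rng):
        A, B = random_spd(4, rng), random_spd(4, rng)
        rel = relative_eigenanalysis(A, B)
        gv = generalized_variance_ratio(A, B)
        assert np.prod(rel.eigenvalues) == pytest.approx(gv, rel=1e-8)

    def test_diagonal_matrices(self):
        A = np.diag([2.0, 3.0])
        B = np.diag([1.0, 6.0])
        assert generalized_variance_ratio(A, B) == pytest.approx(1.0)

    def test_equal_matrices_unity(self, rng):
        C = random_spd(3, rng)
        assert generalized_variance_ratio(C, C) == pytest.approx(1.0)


class TestCovarianceMetric:
    def test_zero_iff_equal_and_symmetric(self, rng):
        A, B = random_spd(3, rng), random_spd(3, rng)
        assert covariance_metric(A, A) == pytest.approx(0, abs=1e-8)
        assert covariance_metric(A, B) == pytest.approx(covariance_metric(B, A),
                                                        rel=1e-8)

    def test_triangle_inequality_random_triples(self, rng):
        for _ in range(50):
            A, B, C = (random_spd(3, rng) for _ in range(3))
            dab = covariance_metric(A, B)
            dbc = covariance_metric(B, C)
            dac = covariance_metric(A, C)
            assert dac <= dab + dbc + 1e-9


class TestTotalVariance:
    def test_equals_eigenvalue_sum_and_trace(self, rng):
        X = rng.normal(size=(40, 5))
        tv = total_variance(X)
        assert tv == pytest.approx(pca(X).eigenvalues.sum(), rel=1e-10)
        assert tv == pytest.approx(np.trace(np.cov(X, rowvar=False)), rel=1e-10)

    def test_identity_covariance_dimension(self, rng):
        X = rng.normal(size=(20000, 5))
        assert total_variance(X) == pytest.approx(5.0, rel=0.05)
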