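import numpy as np
import pandas as pd
import pytest

from gmkit import (
    LandmarkError,
    canonical_correlation,
    pc_sensitivity_curve,
    pls_two_block,
    reduced_rank_regression,
    regression_scores,
    shape_regression,
    shape_vector_angle,
)


class TestShapeRegression:
    def test_noise_free_exact_recovery(self, rng):
        x = rng.normal(size=30)
        beta = rng.normal(size=10)
        mu = rng.normal(size=10)
        Y = mu + np.outer(x, beta)
        res = shape_regression(Y, pd.DataFrame({"x": x}), "x")
        np.testing.assert_allclose(res.coefficients[:, 0], beta, atol=1e-10)
        np.testing.assert_allclose(res.intercept, mu, atol=1e-9)
        assert res.multivariate_r2 == pytest.approx(1.0, abs=1e-10)

    def test_uncorrelated_predictor_near_zero_r2(self, rng):
        Y = rng.normal(size=(300, 8))
        x = rng.normal(size=300)
        res = shape_regression(Y, pd.DataFrame({"x": x}), "x")
        assert res.multivariate_r2 < 0.05

    def test_noisy_recovery_cosine(self, rng):
        n, q = 200, 20
        beta = rng.normal(size=q)
        beta /= np.linalg.norm(beta)
        x = rng.normal(size=n)
        Y = np.outer(x, beta) + rng.normal(0, 0.2, size=(n, q))
        res = shape_regression(Y, pd.DataFrame({"x": x}), "x")
        c = res.coefficients[:, 0]
        assert abs(c @ beta) / np.linalg.norm(c) > 0.95

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(LandmarkError):
            shape_regression(rng.normal(size=(10, 4)),
                             pd.DataFrame({"x": np.ones(10)}), "x")

    def test_multivariate_r2_is_variance_weighted_mean(self, rng):
        Y = rng.normal(size=(50, 6)) @ rng.normal(size=(6, 6))
        x = rng.normal(size=50)
        Y[:, 0] += 2 * x
        res = shape_regression(Y, pd.DataFrame({"x": x}), "x")
        Yc = Y - Y.mean(0)
        var = Yc.var(axis=0)
        r2_per = np.array([
            np.corrcoef(Y[:, j], x)[0, 1] ** 2 for j in range(6)
        ])
        weighted = (r2_per * var).sum() / var.sum()
        assert res.multivariate_r2 == pytest.approx(weighted, rel=1e-8)


class TestRegressionScores:
    def test_noise_free_scores_perfectly_correlated(self, rng):
        x = rng.normal(size=25)
        beta = rng.normal(size=6)
        Y = np.outer(x, beta)
        res = shape_regression(Y, pd.DataFrame({"x": x}), "x")
        r = np.corrcoef(res.scores[:, 0], x)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert res.score_r2[0] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_variation_leaves_scores_unchanged(self, rng):
        x = rng.normal(size=25)
        beta = np.r_[np.ones(3), np.zeros(3)]
        Y = np.outer(x, beta)
        res = shape_regression(Y, pd.DataFrame({"x": x}), "x")
        ortho = np.outer(rng.normal(size=25), np.r_[np.zeros(3), np.ones(3)])
        s2 = regression_scores(res, Y + ortho)
        np.testing.assert_allclose(s2[:, 0], res.scores[:, 0], atol=1e-10)

    def test_matches_dot_product_recomputation(self, rng):
        Y = rng.normal(size=(20, 5))
        x = rng.normal(size=20)
        res = shape_regression(Y, pd.DataFrame({"x": x}), "x")
        c = res.coefficients[:, 0]
        expected = (Y - Y.mean(0)) @ (c / np.linalg.norm(c))
        np.testing.assert_allclose(res.scores[:, 0], expected, atol=1e-12)


class TestShapeVectorAngle:
    def test_parallel_orthogonal_and_oracle(self, rng):
        v = rng.normal(size=6)
        assert shape_vector_angle(v, 2 * v) == pytest.approx(0, abs=1e-5)
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 3.0])
        assert shape_vector_angle(a, b) == pytest.approx(90.0)
        u, w = rng.normal(size=(2, 9))
        expected = np.degrees(np.arccos(u @ w / np.linalg.norm(u) / np.linalg.norm(w)))
        assert shape_vector_angle(u, w) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(LandmarkError):
            shape_vector_angle(np.zeros(3), np.ones(3))


def _signal_noise_data(rng, n=150, qsig=10, qnoise=30):
    """x loads equally on 10 orthogonal directions whose residual variance
    decreases, plus pure-noise directions of low variance."""
    q = qsig + qnoise
    x = rng.normal(size=n)
    data = np.zeros((n, q))
    resid_sd = np.linspace(2.0, 0.8, qsig)
    for i in range(qsig):
        data[:, i] = 0.8 * x + resid_sd[i] * rng.normal(size=n)
    data[:, qsig:] = 0.3 * rng.normal(size=(n, qnoise))
    # rotate so signal is spread over coordinates (PCs must find it)
    Q, _ = np.linalg.qr(rng.normal(size=(q, q)))
    return data @ Q, x


class TestPcSensitivity:
    def test_identical_vectors_zero_angle_curve(self, rng):
        x = rng.normal(size=60)
        beta = rng.normal(size=8)
        Y = np.outer(x, beta) + rng.normal(0, 1e-6, size=(60, 8))
        Y = np.vstack([Y, Y])
        groups = ["a"] * 60 + ["b"] * 60
        cov = pd.DataFrame({"x": np.r_[x, x]})
        curve = pc_sensitivity_curve("angle", Y, cov, "x", [2, 4, 6],
                                     groups=groups)
        for _, ang in curve:
            assert ang < 1e-3

    def test_r2_statistics_diverge_beyond_signal_dimension(self, rng):
        data, x = _signal_noise_data(rng)
        cov = pd.DataFrame({"x": x})
        ms = [2, 6, 10, 20, 30, 39]
        mr = dict(pc_sensitivity_curve("multivariate_r2", data, cov, "x", ms))
        sr = dict(pc_sensitivity_curve("score_r2", data, cov, "x", ms))
        # multivariate R2 peaks near the signal dimension, then declines
        assert max(mr[2], mr[6], mr[10]) > mr[30] > mr[39] - 1e-12
        assert mr[10] > mr[39]
        # score R2 keeps creeping up as noise PCs are added
        assert sr[39] >= sr[10] - 1e-9
        assert sr[39] >= sr[2]

    def test_angle_curve_grows_with_noise_pcs(self, rng):
        # two groups share the same true coefficient vector; extra PCs add
        # independently estimated noise, inflating the angle
        beta = rng.normal(size=40)
        beta /= np.linalg.norm(beta)
        rows, labs, xs = [], [], []
        for g in ("a", "b"):
            x = rng.normal(size=80)
            rows.append(np.outer(x, beta) + rng.normal(0, 0.7, size=(80, 40)))
            labs += [g] * 80
            xs.append(x)
        Y = np.vstack(rows)
        cov = pd.DataFrame({"x": np.concatenate(xs)})
        curve = dict(pc_sensitivity_curve("angle", Y, cov, "x",
                                          [2, 10, 25, 40], groups=labs))
        assert curve[40] > curve[2]


class TestPls:
    def test_first_pair_matches_grid_search(self, rng):
        X = rng.normal(size=(40, 2))
        Y = X @ np.array([[1.0, 0.3], [0.2, 0.8]]) + rng.normal(0, 0.5, (40, 2))
        res = pls_two_block(X, Y)
        best = 0.0
        for a1 in np.radians(np.arange(0, 180, 1.0)):
            a = np.array([np.cos(a1), np.sin(a1)])
            for a2 in np.radians(np.arange(0, 180, 1.0)):
                b = np.array([np.cos(a2), np.sin(a2)])
                best = max(best, abs(np.cov(X @ a, Y @ b)[0, 1]))
        assert res.statistics[0] >= best - 1e-6
        assert res.statistics[0] == pytest.approx(best, rel=1e-3)

    def test_identical_blocks_first_sv_is_top_eigenvalue(self, rng):
        X = rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4))
        res = pls_two_block(X, X)
        top = np.linalg.eigvalsh(np.cov(X, rowvar=False)).max()
        assert res.statistics[0] == pytest.approx(top, rel=1e-8)

    def test_prewhitened_blocks_equalize_all_three_methods(self, rng):
        X = rng.normal(size=(200, 3))
        Y = X @ rng.normal(size=(3, 3)) + rng.normal(0, 0.5, size=(200, 3))

        def whiten(Z):
            Zc = Z - Z.mean(0)
            C = np.cov(Zc, rowvar=False)
            evals, evecs = np.linalg.eigh(C)
            return Zc @ evecs @ np.diag(evals ** -0.5) @ evecs.T

        Xw, Yw = whiten(X), whiten(Y)
        pls = pls_two_block(Xw, Yw)
        rrr = reduced_rank_regression(Xw, Yw)
        cca = canonical_correlation(Xw, Yw)
        for other in (rrr, cca):
            for j in range(3):
                cos = abs(pls.x_coefficients[:, j] @ other.x_coefficients[:, j])
                assert cos == pytest.approx(1.0, abs=1e-6)

    def test_singular_values_inflate_with_variable_count(self, rng):
        # pure noise: the maximized covariance grows as variables are added
        n = 60
        svs = []
        for q in (5, 10, 20, 40):
            X = rng.normal(size=(n, q))
            Y = rng.normal(size=(n, q))
            svs.append(pls_two_block(X, Y).statistics[0])
        assert all(np.diff(svs) > 0)


class TestRrr:
    def test_univariate_scores_slope_equals_ols(self, rng):
        x = rng.normal(size=80)
        y = 2.5 * x + rng.normal(0, 0.5, 80)
        res = reduced_rank_regression(x[:, None], y[:, None])
        xs, ys = res.x_scores[:, 0], res.y_scores[:, 0]
        slope = (xs @ ys) / (xs @ xs)
        ols = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(ols, rel=1e-8)

    def test_temperature_construction_contrasts_pls_and_rrr(self, rng):
        # min/max temperature correlated 0.9; shape responds weakly to the
        # average and strongly to the (low-variance) difference
        n = 500
        t1 = rng.normal(size=n)
        t2 = 0.9 * t1 + np.sqrt(1 - 0.81) * rng.normal(size=n)
        y = 0.3 * (t1 + t2) + 1.0 * (t1 - t2) + rng.normal(0, 0.3, n)
        X = np.column_stack([t1, t2])
        pls = pls_two_block(X, y[:, None])
        rrr = reduced_rank_regression(X, y[:, None])
        assert pls.x_coefficients[0, 0] * pls.x_coefficients[1, 0] > 0  # average
        assert rrr.x_coefficients[0, 0] * rrr.x_coefficients[1, 0] < 0  # difference

    def test_standardized_slope_beats_random_directions(self, rng):
        X = rng.normal(size=(120, 4))
        y = X @ rng.normal(size=4) + rng.normal(0, 1.0, 120)
        res = reduced_rank_regression(X, y[:, None])
        s0 = res.statistics[0]
        yc = y - y.mean()
        n = len(y)
        for _ in range(1000):
            a = rng.normal(size=4)
            xa = X @ a
            xa -= xa.mean()
            slope = abs(xa @ yc / (n - 1)) / np.sqrt(xa @ xa / (n - 1))
            assert slope <= s0 + 1e-9

    def test_x_invariance_rrr_not_pls(self, rng):
        X = rng.normal(size=(100, 3))
        Y = X @ rng.normal(size=(3, 2)) + rng.normal(0, 0.5, size=(100, 2))
        T = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        r1 = reduced_rank_regression(X, Y)
        r2 = reduced_rank_regression(X @ T, Y)
        # RRR latent scores invariant to a nonsingular x transform
        cor = abs(np.corrcoef(r1.x_scores[:, 0], r2.x_scores[:, 0])[0, 1])
        assert cor == pytest.approx(1.0, abs=1e-8)
        assert r1.statistics[0] == pytest.approx(r2.statistics[0], rel=1e-8)
        p1 = pls_two_block(X, Y)
        p2 = pls_two_block(X @ T, Y)
        assert abs(p1.statistics[0] - p2.statistics[0]) > 1e-3  # PLS is not


class TestCca:
    def test_noiseless_linear_map_perfect_correlation(self, rng):
        X = rng.normal(size=(50, 3))
        Y = X @ rng.normal(size=(3, 3))
        res = canonical_correlation(X, Y)
        assert res.statistics[0] == pytest.approx(1.0, abs=1e-8)

    def test_independent_blocks_near_zero(self, rng):
        n = 800
        res = canonical_correlation(rng.normal(size=(n, 2)),
                                    rng.normal(size=(n, 2)))
        assert res.statistics[0] < 2 / np.sqrt(n) * 2.5

    def test_matches_statsmodels(self, rng):
        from statsmodels.multivariate.cancorr import CanCorr

        X = rng.normal(size=(60, 3))
        Y = X @ rng.normal(size=(3, 2)) + rng.normal(0, 0.8, size=(60, 2))
        res = canonical_correlation(X, Y)
        ref = CanCorr(Y, X).cancorr
        np.testing.assert_allclose(res.statistics, ref, atol=1e-8)

    def test_small_toy_matches_grid_search(self, rng):
        X = rng.normal(size=(30, 3))
        Y = X[:, :2] @ rng.normal(size=(2, 2)) + rng.normal(0, 0.6, size=(30, 2))
        res = canonical_correlation(X, Y)
        best = 0.0
        for a1 in np.linspace(0, np.pi, 40):
            for a2 in np.linspace(0, np.pi, 40):
                a = np.array([np.sin(a1) * np.cos(a2), np.sin(a1) * np.sin(a2),
                              np.cos(a1)])
                for b1 in np.radians(np.arange(0, 180, 2.0)):
                    b = np.array([np.cos(b1), np.sin(b1)])
                    r = abs(np.corrcoef(X @ a, Y @ b)[0, 1])
                    best = max(best, r)
        assert res.statistics[0] >= best - 1e-6

    def test_invariance_to_transforms_of_both_blocks(self, rng):
        X = rng.normal(size=(80, 3))
        Y = X @ rng.normal(size=(3, 3)) + rng.normal(0, 0.7, size=(80, 3))
        Tx = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        Ty = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        r1 = canonical_correlation(X, Y)
        r2 = canonical_correlation(X @ Tx, Y @ Ty)
        np.testing.assert_allclose(r1.statistics, r2.statistics, atol=1e-8)

    def test_statistics_non_increasing(self, rng):
        X = rng.normal(size=(70, 4))
        Y = rng.normal(size=(70, 4)) + X @ rng.normal(size=(4, 4)) * 0.3
        for res in (pls_two_block(X, Y), reduced_rank_regression(X, Y),
                    canonical_correlation(X, Y)):
            assert np.all(np.diff(res.statistics) <= 1e-10)
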