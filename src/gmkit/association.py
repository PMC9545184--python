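"""Associating shape with external variables.

Shape regression fits ordinary least squares of *all* shape (or form)
coordinates jointly on external predictors; the coefficient vector is
itself a shape pattern that can be visualized as a deformation. Two R²
statistics with very different behavior are exposed: the multivariate R²
(fraction of total shape variance explained — shrinks as noise dimensions
are added) and the regression-score R² (between predictor and the
projection of the data onto the coefficient vector — inflates as
dimensions are added). ``pc_sensitivity_curve`` traces either statistic,
or the angle between two coefficient vectors, as a function of the number
of retained PCs, since none of them is stable under dimension choice.

The two-block latent-variable trio differs only in the criterion the first
pair of latent variables maximizes: covariance (PLS), regression slope of
the y-latent on the x-latent (reduced rank regression), or correlation
(CCA). All three are singular value decompositions of differently whitened
cross-covariance matrices; PLS needs no inversion, RRR needs a nonsingular
x covariance, CCA nonsingular covariance in both blocks, which is what the
``x_pcs`` / ``y_pcs`` reduction provides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .ordination import pca
from .superimpose import Superimposition
from .types import LandmarkError


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, Superimposition):
        return data.flat()
    return np.atleast_2d(np.asarray(data, float))


@dataclass
class ShapeRegressionResult:
    """Joint OLS of all coordinates on external predictors."""

    coefficients: np.ndarray      # (q, c) one column per predictor
    intercept: np.ndarray         # (q,)
    multivariate_r2: float
    score_r2: np.ndarray          # (c,) per predictor
    scores: np.ndarray            # (n, c) regression scores
    predictor_names: list

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        return self.intercept + x @ self.coefficients.T


def shape_regression(data, covariates, predictors) -> ShapeRegressionResult:
    """Regress all shape/form coordinates on one or more predictors.

    ``data`` is a Superimposition or an (n, q) matrix; ``covariates`` a
    DataFrame with the predictor columns (numeric); ``predictors`` the
    column name(s). Per-coordinate OLS, reported jointly: the multivariate
    R² is the explained fraction of total shape variance; the score R² is
    the squared correlation between each predictor and its regression
    score (the data projected on the normalized coefficient vector).
    """
    Y = _as_matrix(data)
    if isinstance(predictors, str):
        predictors = [predictors]
    X = np.column_stack([np.asarray(covariates[p], float) for p in predictors])
    n, c = X.shape
    if n != Y.shape[0]:
        raise LandmarkError("covariate table and data have different case counts")
    if n <= c + 1:
        raise LandmarkError("too few cases for the requested predictors")
    if np.any(X.std(axis=0) == 0):
        raise LandmarkError("constant predictor")
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    intercept, coefs = beta[0], beta[1:].T   # coefs: (q, c)
    resid = Y - Xd @ beta
    Yc = Y - Y.mean(axis=0)
    sst = (Yc ** 2).sum()
    r2 = float(1.0 - (resid ** 2).sum() / sst) if sst > 0 else 0.0
    scores = regression_scores_matrix(Y, coefs)
    score_r2 = np.array([
        np.corrcoef(scores[:, j], X[:, j])[0, 1] ** 2 for j in range(c)
    ])
    return ShapeRegressionResult(coefficients=coefs, intercept=intercept,
                                 multivariate_r2=r2, score_r2=score_r2,
                                 scores=scores, predictor_names=list(predictors))


def regression_scores_matrix(Y: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Centered data projected on each normalized coefficient vector."""
    Yc = Y - Y.mean(axis=0)
    coefs = np.atleast_2d(coefs.T).T
    norms = np.linalg.norm(coefs, axis=0)
    if np.any(norms == 0):
        raise LandmarkError("zero coefficient vector has no regression score")
    return Yc @ (coefs / norms)


def regression_scores(result: ShapeRegressionResult, data) -> np.ndarray:
    """Regression scores ('net partial predictor') of a fitted result on data."""
    return regression_scores_matrix(_as_matrix(data), result.coefficients)


def shape_vector_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two coefficient/shape vectors, in [0, 180]."""
    v1 = np.asarray(v1, float).ravel()
    v2 = np.asarray(v2, float).ravel()
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise LandmarkError("zero vector has no direction")
    c = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def pc_sensitivity_curve(statistic: str, data, covariates, predictor: str,
                         m_range, groups=None):
    """Recompute an association statistic on an increasing number of PCs.

    ``statistic``:
      - ``"multivariate_r2"`` / ``"score_r2"``: the regression R² statistics
        of ``shape_regression`` computed on the first m PC scores;
      - ``"angle"``: the angle between the two per-group coefficient
        vectors (``groups`` must label exactly two groups; the PCA is
        computed on the pooled data).

    Returns a list of (m, value) pairs. m values beyond the data rank are
    dropped with a warning.
    """
    import warnings

    Y = _as_matrix(data)
    base = pca(Y)
    rank = int(np.sum(base.eigenvalues > 1e-12 * base.eigenvalues[0]))
    out = []
    for m in m_range:
        if m > rank:
            warnings.warn(f"m={m} exceeds data rank {rank}; truncating curve",
                          RuntimeWarning)
            break
        S = base.scores[:, :m]
        if statistic == "angle":
            g = np.asarray(groups)
            labs = list(dict.fromkeys(g))
            if len(labs) != 2:
                raise LandmarkError("angle curve needs exactly two groups")
            vecs = []
            for lab in labs:
                sel = g == lab
                res = shape_regression(S[sel], covariates[sel].reset_index(drop=True),
                                       predictor)
                vecs.append(res.coefficients[:, 0])
            out.append((m, shape_vector_angle(vecs[0], vecs[1])))
        else:
            res = shape_regression(S, covariates, predictor)
            if statistic == "multivariate_r2":
                out.append((m, res.multivariate_r2))
            elif statistic == "score_r2":
                out.append((m, float(res.score_r2[0])))
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
    return out


@dataclass
class LatentPairResult:
    """Paired latent axes from PLS, RRR or CCA.

    ``x_coefficients`` / ``y_coefficients``: columns per latent pair;
    ``statistics``: the per-pair maximized quantity (covariance, slope, or
    correlation), non-increasing; ``x_scores`` / ``y_scores``: latent
    variable values.
    """

    method: str
    x_coefficients: np.ndarray
    y_coefficients: np.ndarray
    statistics: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray


def _centered_blocks(x_block, y_block):
    X = _as_matrix(x_block)
    Y = _as_matrix(y_block)
    if X.shape[0] != Y.shape[0]:
        raise LandmarkError("blocks must have the same number of cases")
    if X.shape[0] < 3:
        raise LandmarkError("need at least 3 cases")
    return X - X.mean(axis=0), Y - Y.mean(axis=0)


def _sign_align(res: LatentPairResult) -> LatentPairResult:
    # sign convention: positive covariance of each x-latent with the first x variable
    for j in range(res.x_coefficients.shape[1]):
        s = res.x_coefficients[0, j]
        if s == 0:
            s = res.x_coefficients[np.argmax(np.abs(res.x_coefficients[:, j])), j]
        if s < 0:
            res.x_coefficients[:, j] *= -1
            res.y_coefficients[:, j] *= -1
            res.x_scores[:, j] *= -1
            res.y_scores[:, j] *= -1
    return res


def pls_two_block(x_block, y_block) -> LatentPairResult:
    """Two-block partial least squares: latent pairs maximizing covariance.

    SVD of the cross-covariance matrix; singular values are the latent
    covariances (descending); coefficient vectors are unit norm, so each
    x-coefficient vector is proportional to the covariances of the x
    variables with the y latent variable. Needs no matrix inversion.
    """
    Xc, Yc = _centered_blocks(x_block, y_block)
    n = Xc.shape[0]
    Sxy = Xc.T @ Yc / (n - 1)
    if not np.any(Sxy):
        import warnings

        warnings.warn("zero cross-covariance: PLS axes are arbitrary", RuntimeWarning)
    U, s, Vt = np.linalg.svd(Sxy, full_matrices=False)
    res = LatentPairResult(method="pls", x_coefficients=U, y_coefficients=Vt.T,
                           statistics=s, x_scores=Xc @ U, y_scores=Yc @ Vt.T)
    return _sign_align(res)


def _reduce(Xc: np.ndarray, m) -> tuple:
    """PCA-reduce a centered block to m components; returns (scores, basis)."""
    if m is None:
        return Xc, np.eye(Xc.shape[1])
    res = pca(Xc)
    m = int(m)
    rank = int(np.sum(res.eigenvalues > 1e-10 * res.eigenvalues[0]))
    if m > rank:
        raise LandmarkError(f"requested {m} PCs but rank is {rank}")
    return res.scores[:, :m], res.axes[:, :m]


def _invsqrt(C: np.ndarray, name: str) -> np.ndarray:
    evals, evecs = np.linalg.eigh(C)
    if evals.min() <= 1e-10 * max(evals.max(), 1e-300):
        raise LandmarkError(f"singular {name} covariance; reduce with PCs first")
    return evecs @ np.diag(evals ** -0.5) @ evecs.T


def reduced_rank_regression(x_block, y_block, x_pcs=None) -> LatentPairResult:
    """Latent pairs maximizing the regression slope of y-latent on x-latent.

    Computed as the SVD of Sxx^(-1/2) Sxy on the (optionally PC-reduced)
    x basis: x coefficients are proportional to *partial* (multiple)
    regression coefficients, y coefficients to covariances. The reported
    per-pair statistic is the slope with the x latent standardized to unit
    variance (the convention under which "maximal slope" is well defined).
    Requires a nonsingular x covariance — many more cases than retained x
    variables.
    """
    Xc, Yc = _centered_blocks(x_block, y_block)
    Xr, xbasis = _reduce(Xc, x_pcs)
    n = Xr.shape[0]
    Sxx = Xr.T @ Xr / (n - 1)
    Sxy = Xr.T @ Yc / (n - 1)
    W = _invsqrt(Sxx, "x")
    U, s, Vt = np.linalg.svd(W @ Sxy, full_matrices=False)
    a = W @ U                      # x weights on reduced basis (slope-maximizing)
    a = a / np.linalg.norm(a, axis=0)
    b = Vt.T
    xs = Xr @ a
    ys = Yc @ b
    # the maximized statistic: regression slope of the y latent on the x
    # latent with the x latent standardized to unit variance (the slope is
    # only scale-well-defined under that normalization); equals the
    # singular values of the half-whitened cross-covariance
    res = LatentPairResult(method="rrr", x_coefficients=xbasis @ a,
                           y_coefficients=b, statistics=s,
                           x_scores=xs, y_scores=ys)
    return _sign_align(res)


def canonical_correlation(x_block, y_block, x_pcs=None, y_pcs=None) -> LatentPairResult:
    """Latent pairs maximizing correlation (CCA).

    SVD of the doubly whitened cross-covariance Sxx^(-1/2) Sxy Syy^(-1/2);
    singular values are the canonical correlations in [0, 1], descending.
    Both blocks must be nonsingular, hence the PC reduction options.
    """
    Xc, Yc = _centered_blocks(x_block, y_block)
    Xr, xbasis = _reduce(Xc, x_pcs)
    Yr, ybasis = _reduce(Yc, y_pcs)
    n = Xr.shape[0]
    Sxx = Xr.T @ Xr / (n - 1)
    Syy = Yr.T @ Yr / (n - 1)
    Sxy = Xr.T @ Yr / (n - 1)
    Wx = _invsqrt(Sxx, "x")
    Wy = _invsqrt(Syy, "y")
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy, full_matrices=False)
    a = Wx @ U
    b = Wy @ Vt.T
    a = a / np.linalg.norm(a, axis=0)
    b = b / np.linalg.norm(b, axis=0)
    res = LatentPairResult(method="cca", x_coefficients=xbasis @ a,
                           y_coefficients=ybasis @ b,
                           statistics=np.clip(s, 0.0, 1.0),
                           x_scores=Xr @ a, y_scores=Yr @ b)
    return _sign_align(res)
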