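"""Ordination and variance comparison for high-dimensional shape data.

PCA, between-group PCA (with the leave-one-out cross-validation that
alleviates its spurious-separation artifact), CVA on a reduced PC basis,
Mahalanobis distance, leave-one-out quadratic classification, and the
relative-eigenvalue machinery for comparing two covariance matrices
(variance ratios, generalized variance, the log-relative-eigenvalue
metric).

A central caution these tools carry with them: when the variable count
approaches the case count, within-group scatter can be rotated away, so
bgPCA and especially CVA will separate even identically distributed groups.
The cross-validated variants and the chance-level classification tests in
this package exist to make that artifact visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .types import LandmarkError

logger = logging.getLogger(__name__)


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    axes = axes.copy()
    for j in range(axes.shape[1]):
        i = np.argmax(np.abs(axes[:, j]))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    return axes


@dataclass
class OrdinationResult:
    """Axes (columns, in coordinate space), scores, and explained variance."""

    method: str
    axes: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    center: np.ndarray
    groups: np.ndarray = None
    cross_validated: bool = False

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues

    def backtransform(self, score_row: np.ndarray) -> np.ndarray:
        """Map a point in score space back to coordinate space."""
        score_row = np.asarray(score_row, float)
        return self.center + self.axes[:, : score_row.size] @ score_row


def pca(data: np.ndarray) -> OrdinationResult:
    """Principal component analysis of an (n, q) data matrix.

    Eigendecomposition of the sample covariance (n-1 denominator), axes in
    descending eigenvalue order. Score variances equal the eigenvalues.
    """
    X = np.asarray(data, float)
    n = X.shape[0]
    if n < 2:
        raise LandmarkError("PCA needs at least two cases")
    center = X.mean(axis=0)
    Xc = X - center
    if not np.any(Xc):
        raise LandmarkError("constant data: PCA undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evals = s ** 2 / (n - 1)
    axes = _fix_signs(Vt.T)
    scores = Xc @ axes
    return OrdinationResult(method="pca", axes=axes, scores=scores,
                            eigenvalues=evals, center=center)


def _group_means(X, groups):
    labels = pd.unique(np.asarray(groups))
    means = np.stack([X[np.asarray(groups) == g].mean(axis=0) for g in labels])
    return labels, means


def bgpca(data: np.ndarray, groups, cross_validate: bool = False,
          weighted: bool = False) -> OrdinationResult:
    """Between-group PCA: the PCs of the group means, with all cases projected.

    By default each group mean counts equally ("PCs of the group means");
    ``weighted=True`` weights means by group size. With two groups, the
    single axis is the normalized difference of the two group means.

    ``cross_validate=True`` computes each case's score after removing that
    case from its own group's mean (leave-one-out), which largely removes
    the spurious separation bgPCA produces when q is large relative to n.
    """
    X = np.asarray(data, float)
    groups = np.asarray(groups)
    labels, means = _group_means(X, groups)
    if len(labels) < 2:
        raise LandmarkError("between-group PCA needs at least two groups")
    if weighted:
        w = np.array([(groups == g).sum() for g in labels], float)
        grand = (means * w[:, None]).sum(axis=0) / w.sum()
        M = (means - grand) * np.sqrt(w[:, None] / w.sum())
    else:
        grand = means.mean(axis=0)
        M = means - grand
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    nax = min(len(labels) - 1, M.shape[1])
    axes = _fix_signs(Vt[:nax].T)
    evals = (s[:nax] ** 2) / max(len(labels) - 1, 1)
    if cross_validate:
        scores = np.empty((X.shape[0], nax))
        for i in range(X.shape[0]):
            mask = np.ones(X.shape[0], bool)
            mask[i] = False
            li, mi = _group_means(X[mask], groups[mask])
            if weighted:
                wi = np.array([(groups[mask] == g).sum() for g in li], float)
                gi = (mi * wi[:, None]).sum(axis=0) / wi.sum()
                Mi = (mi - gi) * np.sqrt(wi[:, None] / wi.sum())
            else:
                gi = mi.mean(axis=0)
                Mi = mi - gi
            _, si, Vti = np.linalg.svd(Mi, full_matrices=False)
            ax_i = _fix_signs(Vti[:nax].T)
            scores[i] = (X[i] - gi) @ ax_i
    else:
        scores = (X - grand) @ axes
    return OrdinationResult(method="bgpca", axes=axes, scores=scores,
                            eigenvalues=evals, center=grand, groups=groups,
                            cross_validated=cross_validate)


def _pooled_within_cov(scores, groups, labels):
    n, q = scores.shape
    S = np.zeros((q, q))
    for g in labels:
        sub = scores[np.asarray(groups) == g]
        sub = sub - sub.mean(axis=0)
        S += sub.T @ sub
    return S / (n - len(labels))


def cva_on_pcs(data: np.ndarray, groups, n_pcs: int) -> OrdinationResult:
    """Canonical variate analysis on the first ``n_pcs`` PC scores.

    Maximizes between-group relative to pooled within-group variance by a
    generalized eigendecomposition on the reduced basis; axes are
    back-transformed to coordinate space for visualization. CV scores have
    unit pooled within-group variance per axis. With isotropic within-group
    variation CVA, bgPCA and the mean-difference vector coincide; with
    n_pcs approaching n the method separates even identical groups — use
    with the dimension warnings in mind.
    """
    X = np.asarray(data, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise LandmarkError("CVA needs at least two groups")
    n, q = X.shape
    n_pcs = int(n_pcs)
    if n_pcs > min(n - len(labels), q):
        raise LandmarkError(f"n_pcs={n_pcs} exceeds usable dimensions")
    base = pca(X)
    Y = base.scores[:, :n_pcs]
    _, means = _group_means(Y, groups)
    grand = means.mean(axis=0)
    B = (means - grand).T @ (means - grand) / (len(labels) - 1)
    W = _pooled_within_cov(Y, groups, labels)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as e:
        raise LandmarkError(
            f"singular within-group covariance on {n_pcs} PCs; use fewer PCs"
        ) from e
    order = np.argsort(evals)[::-1][: len(labels) - 1]
    evals = np.clip(evals[order], 0, None)
    A = evecs[:, order]
    # normalize so CV scores have unit pooled within-group variance
    wvar = np.einsum("ij,jk,ki->i", A.T, W, A)
    A = A / np.sqrt(wvar)
    scores = (Y - Y.mean(axis=0)) @ A
    axes_coord = _fix_signs(base.axes[:, :n_pcs] @ A)
    scores = scores * np.sign(
        np.einsum("ij,ij->j", base.axes[:, :n_pcs] @ A, axes_coord)
    )
    return OrdinationResult(method="cva", axes=axes_coord, scores=scores,
                            eigenvalues=evals, center=base.center, groups=groups)


def mahalanobis_distance(mean_a, mean_b, pooled_cov) -> float:
    """Mahalanobis distance between two group means.

    The mean difference measured relative to within-group variance along
    its direction; invariant to any nonsingular linear transform applied
    consistently to means and covariance.
    """
    d = np.asarray(mean_a, float) - np.asarray(mean_b, float)
    cov = np.asarray(pooled_cov, float)
    try:
        sol = linalg.solve(cov, d, assume_a="pos")
    except linalg.LinAlgError as e:
        raise LandmarkError(f"singular covariance: {e}") from e
    return float(np.sqrt(d @ sol))


@dataclass
class ClassificationReport:
    """Confusion table and correct-classification rates from cross-validation."""

    confusion: pd.DataFrame
    rates: pd.Series
    overall_rate: float
    scheme: str = "loocv"


def qda_loocv_classify(data: np.ndarray, groups, n_pcs: int) -> ClassificationReport:
    """Leave-one-out quadratic classification on the first ``n_pcs`` PCs.

    For each left-out case the PCA and the per-group Gaussian densities
    (separate covariances, equal priors) are recomputed from the remaining
    cases; the case is assigned to the group with the highest density
    (ties to the lower group index). For two groups drawn from one
    distribution the expected rate is 0.5.
    """
    X = np.asarray(data, float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    n = X.shape[0]
    n_pcs = int(n_pcs)
    for g in labels:
        if (groups == g).sum() <= n_pcs + 1:
            raise LandmarkError(
                f"group {g!r} has too few cases for QDA on {n_pcs} PCs"
            )
    pred = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        fold = pca(X[mask])
        Y = fold.scores[:, :n_pcs]
        yi = (X[i] - fold.center) @ fold.axes[:, :n_pcs]
        best, best_ll = None, -np.inf
        for g in labels:
            sub = Y[groups[mask] == g]
            mu = sub.mean(axis=0)
            cov = np.cov(sub, rowvar=False).reshape(n_pcs, n_pcs)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise LandmarkError(f"singular within-group covariance for group {g!r}")
            d = yi - mu
            ll = -0.5 * (logdet + d @ linalg.solve(cov, d, assume_a="pos"))
            if ll > best_ll:
                best, best_ll = g, ll
        pred[i] = best
    confusion = pd.crosstab(pd.Series(groups, name="true"),
                            pd.Series(pred, name="predicted"),
                            dropna=False).reindex(index=labels, columns=labels,
                                                  fill_value=0)
    correct = pred == groups
    rates = pd.Series({g: correct[groups == g].mean() for g in labels})
    return ClassificationReport(confusion=confusion, rates=rates,
                                overall_rate=float(correct.mean()))


@dataclass
class RelativeEigenResult:
    """Relative eigenvalues/-vectors of one covariance matrix w.r.t. another."""

    eigenvalues: np.ndarray       # descending variance ratios a : b
    eigenvectors: np.ndarray      # columns, in the analysis basis
    log_eigenvalues: np.ndarray


def relative_eigenanalysis(cov_a: np.ndarray, cov_b: np.ndarray) -> RelativeEigenResult:
    """Directions maximizing/minimizing the variance ratio between two groups.

    Generalized eigendecomposition of (cov_a, cov_b); eigenvalues are the
    variance ratios a:b along the eigenvectors, in descending order, the
    first and last being the largest and smallest achievable ratios. The
    ratios are invariant under any common nonsingular transform of both
    matrices. Singular ``cov_b`` requires prior dimension reduction.
    """
    A = np.asarray(cov_a, float)
    B = np.asarray(cov_b, float)
    _check_nonsingular(B, "cov_b")
    evals, evecs = linalg.eigh(A, B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    if np.any(evals <= 0):
        _check_nonsingular(A, "cov_a")
        evals = np.clip(evals, np.finfo(float).tiny, None)
    return RelativeEigenResult(eigenvalues=evals, eigenvectors=evecs[:, order],
                               log_eigenvalues=np.log(evals))


def _check_nonsingular(C, name):
    evals = np.linalg.eigvalsh(C)
    if evals.min() <= 1e-12 * max(evals.max(), 1e-300):
        raise LandmarkError(
            f"{name} is singular on this basis; reduce dimensions (e.g. PCA) first"
        )


def generalized_variance_ratio(cov_a: np.ndarray, cov_b: np.ndarray) -> float:
    """det(cov_a)/det(cov_b): the ratio of generalized variances.

    Equals the product of the relative eigenvalues.
    """
    A = np.asarray(cov_a, float)
    B = np.asarray(cov_b, float)
    _check_nonsingular(A, "cov_a")
    _check_nonsingular(B, "cov_b")
    sa, la = np.linalg.slogdet(A)
    sb, lb = np.linalg.slogdet(B)
    return float(np.exp(la - lb))


def covariance_metric(cov_a: np.ndarray, cov_b: np.ndarray) -> float:
    """Affine-invariant distance between covariance matrices:
    sqrt(sum of squared log relative eigenvalues). Zero iff equal;
    symmetric (log eigenvalues negate when the roles swap)."""
    rel = relative_eigenanalysis(cov_a, cov_b)
    return float(np.sqrt((rel.log_eigenvalues ** 2).sum()))


def total_variance(data: np.ndarray) -> float:
    """Trace of the sample covariance = sum of all PCA eigenvalues."""
    X = np.asarray(data, float)
    Xc = X - X.mean(axis=0)
    return float((Xc ** 2).sum() / (X.shape[0] - 1))


def default_n_pcs(data: np.ndarray, threshold: float = 0.90) -> int:
    """Smallest PC count reaching ``threshold`` cumulative variance.

    A crude programmatic default only — inspect the scree plot; automatic
    dimension choices hide exactly the artifacts this module warns about.
    """
    res = pca(data)
    cum = np.cumsum(res.explained_variance_ratio)
    m = int(np.searchsorted(cum, threshold) + 1)
    logger.warning("default_n_pcs chose m=%d (%.1f%% variance); verify on the scree plot",
                   m, 100 * cum[m - 1])
    return m
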