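"""Spatial-scale analysis of shape variation.

Partial warps order non-affine shape variation by spatial scale: warps
with small bending-energy eigenvalue are large-scale patterns, warps with
large eigenvalue are localized ones, so 1/lambda serves as a measure of
spatial scale. Plotting per-warp score variance against 1/lambda on log-log
axes summarizes how shape variance is distributed across scales. Under the
self-similar shape distribution the variance is the same at every scale,
which corresponds to a slope of 1 for 2D landmarks and 2 for 3D landmarks;
steeper slopes indicate coordinated (large-scale dominated) variation,
shallower slopes compensatory (local) variation. Isotropic landmark noise
(Mardia-Dryden) has a flat spectrum: slope 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ordination import RelativeEigenResult, relative_eigenanalysis
from .superimpose import gpa
from .thinplate import BendingEnergyModel, bending_energy_matrix, partial_warp_scores
from .types import LandmarkError, LandmarkSample, make_sample


def self_similar_exponent(k: int) -> int:
    """Reference exponent s with score variance ~ lambda^-s under
    self-similarity: 1 in 2D, 2 in 3D."""
    return 1 if k == 2 else 2


@dataclass
class ScaleSpectrum:
    """Per-partial-warp variance (summed over coordinate axes) with its
    bending-energy eigenvalue, plus the fitted log-log slope."""

    variances: np.ndarray
    eigenvalues: np.ndarray
    slope: float
    slope_se: float
    intercept: float
    k: int


def partial_warp_variance_spectrum(be_model: BendingEnergyModel, sup) -> ScaleSpectrum:
    """Variance of each partial warp's scores, paired with its eigenvalue.

    Scores are summed over the k coordinate axes per warp; the slope is
    fitted by :func:`scale_slope`.
    """
    scores = partial_warp_scores(be_model, sup)
    n, _ = scores.shape
    k = be_model.k
    per_axis = scores.reshape(n, be_model.n_warps, k)
    variances = per_axis.var(axis=0, ddof=1).sum(axis=1)
    slope, se, intercept = _loglog_fit(variances, be_model.eigenvalues)
    return ScaleSpectrum(variances=variances, eigenvalues=be_model.eigenvalues,
                         slope=slope, slope_se=se, intercept=intercept, k=k)


def _loglog_fit(variances, eigenvalues):
    keep = variances > 0
    if keep.sum() < len(variances):
        import warnings

        warnings.warn(f"dropping {len(variances) - int(keep.sum())} zero-variance warps "
                      "from the log-log fit", RuntimeWarning)
    v = variances[keep]
    lam = eigenvalues[keep]
    if v.size < 3:
        raise LandmarkError("need at least 3 positive-variance warps for a slope")
    # average ties in lambda first (repeated eigenvalues are one scale)
    order = np.argsort(lam)
    lam, v = lam[order], v[order]
    uniq, inv = np.unique(np.round(np.log(lam), 10), return_inverse=True)
    lam_u = np.exp(uniq)
    v_u = np.array([v[inv == i].mean() for i in range(len(uniq))])
    res = stats.linregress(np.log(1.0 / lam_u), np.log(v_u))
    return float(res.slope), float(res.stderr), float(res.intercept)


def scale_slope(spectrum: ScaleSpectrum):
    """(slope, standard error) of log variance on log(1/lambda).

    Slope above the self-similar value (1 in 2D, 2 in 3D) flags coordinated
    variation, below it compensatory variation; 0 is isotropic noise.
    """
    return spectrum.slope, spectrum.slope_se


def relative_intrinsic_warps(sup, be_model: BendingEnergyModel, n_pcs: int = None,
                             exponent: float = None) -> RelativeEigenResult:
    """Relative eigenanalysis of non-affine shape variation against the
    self-similar reference.

    The observed per-warp score covariance is contrasted with the diagonal
    self-similar expectation 1/lambda^s (s = 1 in 2D, 2 in 3D, overridable
    via ``exponent``); eigenvalues are variances relative to the
    self-similar expectation and the leading eigenvector is the non-affine
    pattern most in excess of it. Invariant to uniform rescaling of all
    lambda. ``n_pcs`` restricts the analysis to the first (largest-scale)
    warps.
    """
    scores = partial_warp_scores(be_model, sup)
    k = be_model.k
    s_exp = self_similar_exponent(k) if exponent is None else exponent
    lam = np.repeat(be_model.eigenvalues, k)
    if n_pcs is not None:
        m = int(n_pcs) * k
        scores = scores[:, :m]
        lam = lam[:m]
    cov = np.cov(scores, rowvar=False)
    ref = np.diag(lam ** (-float(s_exp)))
    ref /= np.exp(np.mean(np.log(np.diag(ref))))  # normalize scale of the reference
    return relative_eigenanalysis(cov, ref)


def per_cell_nonaffine_variance(sample: LandmarkSample, rows: int, cols: int,
                                cell: int) -> float:
    """Mean size-standardized non-affine shape variance of square cells of
    side ``cell`` in a rows x cols grid sample.

    Each cell is read at its four corner landmarks (so cells of every size
    have the same landmark count and differ only in physical scale),
    superimposed on its own in shape mode, and the summed partial-warp
    score variance recorded; the mean over all cell positions is returned.
    Under isotropic landmark noise the value drops with cell size (the
    larger centroid size absorbs the same coordinate noise); under a
    self-similar distribution it is scale-free: equal across cell sizes.
    """
    arr = sample.as_array()
    if arr.shape[1] != rows * cols:
        raise LandmarkError("sample does not match the stated grid")
    index = np.arange(rows * cols).reshape(rows, cols)
    out = []
    for r0 in range(rows - cell):
        for c0 in range(cols - cell):
            sub = [index[r0, c0], index[r0, c0 + cell],
                   index[r0 + cell, c0], index[r0 + cell, c0 + cell]]
            subsample = make_sample(arr[:, sub, :])
            sup = gpa(subsample, mode="shape")
            bem = bending_energy_matrix(sup.mean_shape)
            spec_scores = partial_warp_scores(bem, sup)
            out.append(float(spec_scores.var(axis=0, ddof=1).sum()))
    return float(np.mean(out))


def landmark_distance_covariance_trend(sample: LandmarkSample,
                                       reference: np.ndarray = None) -> float:
    """Spearman rank correlation between inter-landmark distance (at the
    mean) and the covariance of the landmarks' displacements.

    Negative under a self-similar distribution (nearby landmarks co-vary
    more strongly than distant ones). With ``reference`` given,
    displacements are taken directly from it; otherwise the sample is
    superimposed first (which adds the usual Procrustes-induced
    covariances to the picture).
    """
    if reference is not None:
        arr = sample.as_array()
        n, p, k = arr.shape
        flatr = arr - np.asarray(reference, float)
        mu = np.asarray(reference, float)
    else:
        sup = gpa(sample, mode="shape")
        n, p, k = sup.aligned.shape
        flatr = sup.aligned - sup.mean_shape
        mu = sup.mean_shape
    dists, covs = [], []
    for i in range(p):
        for j in range(i + 1, p):
            dists.append(np.linalg.norm(mu[i] - mu[j]))
            c = np.mean(np.einsum("na,na->n", flatr[:, i, :], flatr[:, j, :]))
            covs.append(c)
    rho = stats.spearmanr(dists, covs).statistic
    return float(rho)
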