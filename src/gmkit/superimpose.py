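"""Generalized Procrustes Analysis and the shape / form coordinate systems.

Shape coordinates are landmark coordinates after standardizing location,
scale (to unit centroid size) and orientation; Boas coordinates standardize
location and orientation only, and are obtained here by re-multiplying shape
coordinates by centroid size (equivalently, skipping the scaling step).
Size-shape (form) coordinates augment the shape coordinates by log centroid
size, giving p*k + 1 form variables.

All rotations are proper (determinant +1); reflections are never introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import LandmarkConfiguration, LandmarkError, LandmarkSample, make_sample


def centroid_size(config) -> float:
    """Root summed squared distance of the landmarks from their centroid.

    Scales linearly with uniform scaling of the configuration.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs == 0.0:
        raise LandmarkError("degenerate configuration: all landmarks coincide (CS = 0)")
    return cs


def _coords(x) -> np.ndarray:
    return x.coords if isinstance(x, LandmarkConfiguration) else np.asarray(x, float)


def optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (k x k, det +1) minimizing ||moving @ R - target||.

    Both inputs must already be centered. Degenerate (rank < k-1) inputs
    leave the rotation underdetermined and raise an error.
    """
    k = moving.shape[1]
    H = moving.T @ target
    U, s, Vt = np.linalg.svd(H)
    if np.sum(s > 1e-12 * max(s[0], 1e-300)) < k - 1:
        raise LandmarkError("degenerate configuration: rotation underdetermined")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.eye(k)
    D[-1, -1] = d
    return U @ D @ Vt


def opa_align(moving, target, scale: bool = True):
    """Ordinary Procrustes alignment of one configuration onto another.

    Centers both, optionally scales ``moving`` to the target's centroid
    size, and rotates (proper rotation only) to minimize the summed squared
    landmark differences.

    Returns
    -------
    aligned : (p, k) ndarray
        ``moving`` after translation / scaling / rotation, positioned on the
        centered target.
    residual : float
        Root summed squared difference to the centered target.
    """
    X = _coords(moving)
    Y = _coords(target)
    if X.shape != Y.shape:
        raise LandmarkError(f"incongruent configurations: {X.shape} vs {Y.shape}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if scale:
        Xc = Xc * (centroid_size(Yc) / centroid_size(Xc))
    R = optimal_rotation(Xc, Yc)
    aligned = Xc @ R
    residual = float(np.sqrt(((aligned - Yc) ** 2).sum()))
    return aligned, residual


@dataclass
class Superimposition:
    """Result of a Generalized Procrustes Analysis.

    Attributes
    ----------
    aligned : (n, p, k) ndarray
        Superimposed coordinates (centered; unit centroid size in shape
        mode, original centroid size in boas mode).
    mean_shape : (p, k) ndarray
        Consensus configuration.
    centroid_sizes : (n,) ndarray
        Original centroid sizes.
    mode : str
        ``"shape"`` or ``"boas"``.
    sample : LandmarkSample
        The input sample (for ids, names and covariates).
    """

    aligned: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    mode: str
    sample: LandmarkSample
    n_iterations: int = 0
    converged: bool = True
    objective_trace: np.ndarray = None

    @property
    def n(self):
        return self.aligned.shape[0]

    @property
    def p(self):
        return self.aligned.shape[1]

    @property
    def k(self):
        return self.aligned.shape[2]

    def flat(self) -> np.ndarray:
        """(n, p*k) matrix of aligned coordinates."""
        return self.aligned.reshape(self.n, -1)

    def aligned_sample(self) -> LandmarkSample:
        """The superimposed coordinates as a LandmarkSample."""
        return self.sample.with_coords(self.aligned)


def gpa(sample: LandmarkSample, mode: str = "shape", tol: float = 1e-10,
        max_iter: int = 100, subset=None) -> Superimposition:
    """Generalized Procrustes Analysis.

    Iteratively aligns all configurations to their consensus: translate to a
    common centroid, scale to unit centroid size (shape mode), and rotate to
    minimize summed squared differences. The summed squared deviation from
    the consensus is non-increasing across iterations; iteration stops when
    its change falls below ``tol``. The final consensus (and with it the
    whole sample) is rotated to optimally align with the first configuration
    so the output orientation is reproducible.

    ``mode="boas"`` returns form-space coordinates: the shape-mode result
    re-multiplied row-wise by the original centroid sizes.

    ``subset`` optionally names landmark indices used to *estimate* the
    superimposition; all landmarks are transformed.
    """
    if mode not in ("shape", "boas"):
        raise ValueError(f"mode must be 'shape' or 'boas', got {mode!r}")
    if sample.n < 2:
        raise LandmarkError("GPA needs at least two configurations")
    X = sample.as_array().copy()
    n, p, k = X.shape
    sel = np.arange(p) if subset is None else np.asarray(subset, int)

    # center and scale on the registration subset
    sizes = np.empty(n)
    for i in range(n):
        X[i] -= X[i, sel].mean(axis=0)
        sizes[i] = centroid_size(X[i, sel])
        X[i] /= sizes[i]

    consensus = X[0].copy()
    trace = []
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            R = optimal_rotation(X[i, sel], consensus[sel])
            X[i] = X[i] @ R
        consensus = X.mean(axis=0)
        consensus = consensus / centroid_size(consensus[sel])
        obj = float(((X - consensus) ** 2).sum())
        trace.append(obj)
        if prev - obj < tol:
            converged = True
            break
        prev = obj
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations", RuntimeWarning)

    # polish to a self-consistent fixed point: the tangent-space rank
    # statements require rotations optimal w.r.t. the final consensus to
    # near machine precision, beyond the objective-change stopping rule
    for _ in range(30):
        for i in range(n):
            R = optimal_rotation(X[i, sel], consensus[sel])
            X[i] = X[i] @ R
        new_consensus = X.mean(axis=0)
        new_consensus = new_consensus / centroid_size(new_consensus[sel])
        shift = float(np.abs(new_consensus - consensus).max())
        consensus = new_consensus
        if shift < 1e-13:
            break

    # reproducible orientation: rotate everything so the consensus optimally
    # matches configuration 1
    first = sample.configurations[0].coords
    firstc = first[sel] - first[sel].mean(axis=0)
    R = optimal_rotation(consensus[sel], firstc / centroid_size(firstc))
    consensus = consensus @ R
    X = X @ R

    if mode == "boas":
        X = X * sizes[:, None, None]
        consensus = X.mean(axis=0)

    return Superimposition(
        aligned=X, mean_shape=consensus, centroid_sizes=sizes, mode=mode,
        sample=sample, n_iterations=it, converged=converged,
        objective_trace=np.asarray(trace),
    )


def size_shape_coordinates(sup: Superimposition) -> np.ndarray:
    """Form coordinates: shape coordinates augmented by log centroid size.

    Returns an (n, p*k + 1) matrix whose last column is ln(centroid size).
    Reconstructing a form from a point of this space rescales the shape part
    by exp(log cs), see :func:`form_from_size_shape`.
    """
    if sup.mode != "shape":
        raise LandmarkError("size-shape coordinates require a shape-mode superimposition")
    return np.column_stack([sup.flat(), np.log(sup.centroid_sizes)])


def form_from_size_shape(point: np.ndarray, k: int) -> np.ndarray:
    """Reconstruct a (p, k) form from one row of size-shape coordinates."""
    point = np.asarray(point, float)
    shape, logcs = point[:-1], point[-1]
    return shape.reshape(-1, k) * np.exp(logcs)


def procrustes_distance(a, b, mode: str = "shape") -> float:
    """Procrustes distance between two configurations.

    Root summed squared distance between corresponding landmarks after
    superimposition: both configurations centered, scaled to unit centroid
    size (``mode="shape"``) or kept at their own size (``mode="form"``),
    and optimally rotated. Symmetric; zero iff the configurations are
    identical up to the standardized transformations.
    """
    A = _coords(a)
    B = _coords(b)
    if A.shape != B.shape:
        raise LandmarkError("incongruent configurations")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    if mode == "shape":
        Ac = Ac / centroid_size(Ac)
        Bc = Bc / centroid_size(Bc)
    elif mode != "form":
        raise ValueError("mode must be 'shape' or 'form'")
    R = optimal_rotation(Ac, Bc)
    return float(np.sqrt(((Ac @ R - Bc) ** 2).sum()))


def _rotation_generators(k: int):
    gens = []
    for a in range(k):
        for b in range(a + 1, k):
            J = np.zeros((k, k))
            J[a, b], J[b, a] = 1.0, -1.0
            gens.append(J)
    return gens


def tangent_basis_nuisance(mean_shape: np.ndarray, mode: str = "shape") -> np.ndarray:
    """Orthonormal basis (rows) of the nuisance directions at the consensus.

    Rotation generators applied to the mean, plus (shape mode) the scaling
    direction along the mean itself. Translations are already absent from
    centered coordinates.
    """
    k = mean_shape.shape[1]
    vecs = [(mean_shape @ J.T).ravel() for J in _rotation_generators(k)]
    if mode == "shape":
        vecs.append(mean_shape.ravel())
    B = np.asarray(vecs)
    # orthonormalize
    Q, _ = np.linalg.qr(B.T)
    return Q.T[: len(vecs)]


def tangent_coordinates(sup: Superimposition):
    """Mean-centered tangent-space residuals and their numerical rank.

    Aligned coordinates are centered at the consensus and orthogonally
    projected onto the tangent plane of the pre-form/pre-shape space at the
    consensus (removing the residual components along the rotation
    generators and, in shape mode, the consensus scaling direction). The
    resulting matrix has rank at most p*k - 4 (2D shape), p*k - 7 (3D
    shape), or one more in boas mode where scale is a real degree of
    freedom.

    Returns
    -------
    residuals : (n, p*k) ndarray
    rank : int
        Numerical rank (singular values below 1e-8 of the largest count as
        zero).
    """
    flat = sup.flat()
    centered = flat - flat.mean(axis=0)
    nuis = tangent_basis_nuisance(sup.mean_shape, sup.mode)
    centered = centered - (centered @ nuis.T) @ nuis
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size and s[0] > 0:
        rank = int(np.sum(s > 1e-8 * s[0]))
    else:
        rank = 0
    return centered, rank
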