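"""Thin-plate splines: interpolation, bending energy, partial warps.

The TPS is the standard smooth interpolant between two landmark
configurations. Its bending energy is a quadratic form in the landmark
displacements that is zero exactly for affine (uniform) differences and
weights localized differences — displacements of closely adjacent
landmarks — more heavily than large-scale ones. The eigenvectors of the
bending-energy matrix with nonzero eigenvalue are the *partial warps*, an
orthonormal, spatial-scale-ordered basis for the non-affine part of shape
variation; eigenvalues are ascending, so the first partial warps are the
largest-scale (smallest bending energy) patterns.

Kernels: U(r) = r^2 log r in 2D, U(r) = r in 3D. Any consistent positive
rescaling of the kernel rescales all eigenvalues equally and cancels in
every ratio or regression computed from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superimpose import Superimposition, tangent_basis_nuisance
from .types import LandmarkConfiguration, LandmarkError


def _coords(x) -> np.ndarray:
    return x.coords if isinstance(x, LandmarkConfiguration) else np.asarray(x, float)


def tps_kernel(r: np.ndarray, k: int) -> np.ndarray:
    """Radial basis kernel: r^2 log r (k=2, with U(0)=0) or -r (k=3).

    The 3D sign makes the bending form positive semidefinite; any
    consistent sign/scale choice cancels in every eigenvalue ratio.
    """
    r = np.asarray(r, float)
    if k == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r * r * np.log(np.where(r > 0, r, 1.0)), 0.0)
        return out
    return -r


def _kernel_matrix(source: np.ndarray) -> np.ndarray:
    k = source.shape[1]
    d = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=-1)
    return tps_kernel(d, k)


def _bordered_system(source: np.ndarray):
    p, k = source.shape
    K = _kernel_matrix(source)
    P = np.column_stack([np.ones(p), source])
    L = np.zeros((p + k + 1, p + k + 1))
    L[:p, :p] = K
    L[:p, p:] = P
    L[p:, :p] = P.T
    return L, K, P


@dataclass
class TpsModel:
    """A fitted thin-plate spline mapping source landmarks onto targets."""

    source: np.ndarray
    target: np.ndarray
    affine: np.ndarray       # (k+1, k): row 0 translation, rows 1.. linear part
    weights: np.ndarray      # (p, k) nonaffine kernel weights

    @property
    def k(self) -> int:
        return self.source.shape[1]

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return warp_points(self, pts)


def fit_tps(source, target) -> TpsModel:
    """Fit the TPS interpolant carrying ``source`` landmarks onto ``target``.

    Exact at the landmarks; smooth (minimum bending energy) elsewhere.
    Duplicate source landmarks make the system singular and raise an error.
    """
    S = _coords(source)
    T = _coords(target)
    if S.shape != T.shape:
        raise LandmarkError("source and target must be congruent")
    p, k = S.shape
    d = np.linalg.norm(S[:, None] - S[None, :], axis=-1)
    if np.any(d[~np.eye(p, dtype=bool)] == 0):
        raise LandmarkError("duplicate source landmarks: TPS system singular")
    L, _, _ = _bordered_system(S)
    rhs = np.zeros((p + k + 1, k))
    rhs[:p] = T
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as e:
        raise LandmarkError(f"singular TPS system: {e}") from e
    return TpsModel(source=S, target=T, affine=sol[p:], weights=sol[:p])


def warp_points(model: TpsModel, pts: np.ndarray) -> np.ndarray:
    """Map arbitrary points through a fitted TPS model."""
    pts = np.atleast_2d(np.asarray(pts, float))
    d = np.linalg.norm(pts[:, None, :] - model.source[None, :, :], axis=-1)
    U = tps_kernel(d, model.k)
    return model.affine[0] + pts @ model.affine[1:] + U @ model.weights


@dataclass
class BendingEnergyModel:
    """Bending-energy matrix of a reference shape and its partial-warp basis.

    ``be_matrix`` is p x p symmetric PSD with a (k+1)-dimensional null space
    spanned by the constant vector and the reference coordinate columns
    (affine displacements cost nothing). ``eigenvalues`` are the p-(k+1)
    positive eigenvalues in ascending order; ``partial_warps`` the matching
    orthonormal eigenvectors (columns).
    """

    reference: np.ndarray
    be_matrix: np.ndarray
    eigenvalues: np.ndarray
    partial_warps: np.ndarray

    @property
    def p(self) -> int:
        return self.reference.shape[0]

    @property
    def k(self) -> int:
        return self.reference.shape[1]

    @property
    def n_warps(self) -> int:
        return self.eigenvalues.size


def bending_energy_matrix(reference) -> BendingEnergyModel:
    """Bending-energy matrix and partial warps of a reference configuration.

    The matrix is the upper-left p x p block of the inverse bordered kernel
    system; it is symmetrized and eigenvalues in [-1e-10, 0) are clipped to
    zero. Exactly k+1 zero eigenvalues are expected; more negative values
    indicate a numerically unusable (near-degenerate) reference.
    """
    R = _coords(reference)
    p, k = R.shape
    L, _, _ = _bordered_system(R)
    cond = np.linalg.cond(L)
    if not np.isfinite(cond) or cond > 1e14:
        raise LandmarkError(f"near-singular TPS kernel system (condition number {cond:.3g})")
    Linv = np.linalg.inv(L)
    B = Linv[:p, :p]
    B = 0.5 * (B + B.T)
    evals, evecs = np.linalg.eigh(B)
    scale = max(evals.max(), 1e-300)
    if evals.min() < -1e-10 * max(1.0, scale):
        raise LandmarkError(f"bending-energy matrix has negative eigenvalue {evals.min():.3g}")
    evals = np.clip(evals, 0.0, None)
    # k+1 smallest are the affine null space
    nz = slice(k + 1, None)
    return BendingEnergyModel(
        reference=R, be_matrix=B, eigenvalues=evals[nz], partial_warps=evecs[:, nz]
    )


def deformation_bending_energy(model: BendingEnergyModel, target) -> float:
    """Bending energy of the deformation from the reference to ``target``.

    Quadratic form of the displacement in the bending-energy matrix, summed
    over coordinate axes. Zero iff the deformation is affine.
    """
    T = _coords(target)
    if T.shape != model.reference.shape:
        raise LandmarkError("target incongruent with bending-energy reference")
    D = T - model.reference
    return float(np.einsum("ja,jl,la->", D, model.be_matrix, D))


def partial_warp_scores(model: BendingEnergyModel, sup) -> np.ndarray:
    """Partial-warp scores of a superimposed sample.

    Projects each specimen's residual from the reference onto each partial
    warp, per coordinate axis. Returns (n, n_warps * k), ordered warp-major
    (warp 1 x, warp 1 y, ..., warp 2 x, ...), warps by ascending bending
    energy (largest scale first).
    """
    aligned = sup.aligned if isinstance(sup, Superimposition) else np.asarray(sup, float)
    if aligned.shape[1:] != model.reference.shape:
        raise LandmarkError("sample landmarks incongruent with bending-energy reference")
    resid = aligned - model.reference  # (n, p, k)
    scores = np.einsum("npk,pw->nwk", resid, model.partial_warps)
    return scores.reshape(aligned.shape[0], -1)


def reconstruct_from_partial_warps(model: BendingEnergyModel, scores: np.ndarray) -> np.ndarray:
    """Inverse of :func:`partial_warp_scores`: (n, p, k) nonaffine displacement fields."""
    n = scores.shape[0]
    S = scores.reshape(n, model.n_warps, model.k)
    return np.einsum("nwk,pw->npk", S, model.partial_warps)


def uniform_basis(model: BendingEnergyModel, mode: str = "shape") -> np.ndarray:
    """Orthonormal basis (rows, in flattened p*k space) of the uniform
    (affine) shape subspace within tangent space at the reference.

    Constructed as the span of linear displacement fields of the centered
    reference, with translations, the scaling direction and rotation
    generators projected out: dimension 2 in 2D shape space, 5 in 3D.
    """
    R = model.reference - model.reference.mean(axis=0)
    p, k = R.shape
    fields = []
    for a in range(k):       # displaced axis
        for b in range(k):   # source coordinate
            F = np.zeros((p, k))
            F[:, a] = R[:, b]
            fields.append(F.ravel())
    A = np.asarray(fields).T  # (pk, k*k)
    nuis = tangent_basis_nuisance(R, mode=mode)  # rotations (+ scaling in shape mode)
    A = A - nuis.T @ (nuis @ A)
    Q, s, _ = np.linalg.svd(A, full_matrices=False)
    keep = s > 1e-10 * s[0]
    return Q[:, keep].T


def nonaffine_basis(model: BendingEnergyModel) -> np.ndarray:
    """Orthonormal basis (rows, flattened p*k space) of the nonaffine subspace."""
    p, k = model.reference.shape
    vecs = []
    for w in range(model.n_warps):
        for a in range(k):
            F = np.zeros((p, k))
            F[:, a] = model.partial_warps[:, w]
            vecs.append(F.ravel())
    return np.asarray(vecs)


def uniform_component(model: BendingEnergyModel, sup) -> np.ndarray:
    """Uniform (affine) component scores of a superimposed sample.

    Residuals from the reference are projected onto the uniform basis of
    :func:`uniform_basis`; the result is orthogonal to every partial-warp
    direction. Returns (n, u) with u = 2 (2D) or 5 (3D).
    """
    aligned = sup.aligned if isinstance(sup, Superimposition) else np.asarray(sup, float)
    mode = sup.mode if isinstance(sup, Superimposition) else "shape"
    resid = (aligned - model.reference).reshape(aligned.shape[0], -1)
    U = uniform_basis(model, mode=mode)
    return resid @ U.T


def deformation_grid(model: TpsModel, resolution: int = 20, margin: float = 0.05,
                     plane: tuple = (0, 1), plane_value: float = None):
    """Regular grid over the source bounding box, warped through the model.

    Returns a list of (m, k) polylines (the warped grid lines), ready for
    plotting. For 3D models the grid lies in the axis-aligned ``plane``
    through ``plane_value`` (default: the source mean on the remaining axis).
    """
    if resolution < 2:
        raise ValueError("grid resolution must be at least 2")
    S = model.source
    k = model.k
    a, b = plane
    lo, hi = S.min(axis=0), S.max(axis=0)
    pad = margin * (hi - lo)
    lo, hi = lo - pad, hi + pad
    u = np.linspace(lo[a], hi[a], resolution)
    v = np.linspace(lo[b], hi[b], resolution)
    dense = 5 * resolution  # points per line, so curvature is visible
    ud = np.linspace(lo[a], hi[a], dense)
    vd = np.linspace(lo[b], hi[b], dense)

    def embed(xa, xb):
        pts = np.zeros((len(xa), k))
        pts[:, a] = xa
        pts[:, b] = xb
        if k == 3:
            c = 3 - a - b
            pts[:, c] = S[:, c].mean() if plane_value is None else plane_value
        return pts

    lines = []
    for x in u:
        lines.append(warp_points(model, embed(np.full(dense, x), vd)))
    for y in v:
        lines.append(warp_points(model, embed(ud, np.full(dense, y))))
    return lines
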