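"""Sliding semilandmarks on curves and surfaces.

Semilandmarks carry anatomical information only orthogonal to the curve or
surface they lie on; their position *along* the structure is arbitrary and
is estimated by sliding along local tangents so as to minimize either the
thin-plate-spline bending energy or the Procrustes distance between each
configuration and the sample mean shape. The Procrustes-distance (``d2``)
criterion is a simple orthogonal projection and converges monotonically;
the bending criterion penalizes no affine variation and therefore need not
converge — this is expected behavior and is reported, not hidden.

Sliding displacements are computed in the Procrustes-aligned frame and
mapped back into each specimen's native frame, so fixed (anatomical)
landmarks are never touched and reprojection can use the specimen's own
curve polylines or surface mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .superimpose import centroid_size, gpa, optimal_rotation
from .thinplate import BendingEnergyModel, bending_energy_matrix, deformation_bending_energy
from .types import LandmarkError, LandmarkSample


@dataclass
class SemilandmarkScheme:
    """Which landmarks are fixed, on curves, or on surfaces.

    ``curves`` is a list of ordered index chains; each chain is a polyline
    of semilandmarks, optionally anchored at fixed endpoints (endpoint
    indices listed in ``fixed`` do not slide but still define tangents).
    ``surface_points`` slide within their local tangent plane, which needs a
    normal from a mesh or a supplied normal provider.
    """

    fixed: tuple = ()
    curves: tuple = ()
    surface_points: tuple = ()

    def __post_init__(self):
        self.fixed = tuple(int(i) for i in self.fixed)
        self.curves = tuple(tuple(int(i) for i in c) for c in self.curves)
        self.surface_points = tuple(int(i) for i in self.surface_points)
        for c in self.curves:
            if len(c) < 2:
                raise LandmarkError("each curve chain needs at least 2 points")
        sliding = self.curve_sliders() + list(self.surface_points)
        groups = [set(self.fixed), set(i for c in self.curves for i in c) - set(self.fixed),
                  set(self.surface_points)]
        for a in range(3):
            for b in range(a + 1, 3):
                overlap = groups[a] & groups[b]
                if overlap:
                    raise LandmarkError(f"indices {sorted(overlap)} appear in multiple roles")

    def curve_sliders(self) -> list:
        """Curve indices that actually slide (not anchored fixed points)."""
        fixed = set(self.fixed)
        return [i for c in self.curves for i in c if i not in fixed]

    def sliders(self) -> list:
        return self.curve_sliders() + list(self.surface_points)


def estimate_curve_tangents(config, scheme: SemilandmarkScheme) -> dict:
    """Unit tangent per curve semilandmark.

    Interior chain points use the normalized central difference of their
    chain neighbors; chain endpoints use the one-sided difference.
    Returns {landmark index: (k,) unit vector}.
    """
    coords = config.coords if hasattr(config, "coords") else np.asarray(config, float)
    fixed = set(scheme.fixed)
    tangents = {}
    for chain in scheme.curves:
        pts = coords[list(chain)]
        for j, idx in enumerate(chain):
            if idx in fixed:   # anchored points never slide; no tangent needed
                continue
            lo = max(j - 1, 0)
            hi = min(j + 1, len(chain) - 1)
            d = pts[hi] - pts[lo]
            norm = np.linalg.norm(d)
            if norm == 0:
                raise LandmarkError(
                    f"coincident chain neighbors around landmark {idx} "
                    f"(chain positions {lo}..{hi})"
                )
            tangents[idx] = d / norm
    return tangents


def _tangent_pair(normal: np.ndarray):
    n = normal / np.linalg.norm(normal)
    e = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, e)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


def estimate_surface_tangent_planes(config, scheme: SemilandmarkScheme,
                                    mesh=None, normals=None) -> dict:
    """Two orthonormal tangent vectors per surface semilandmark.

    Normals come from a supplied (len(surface_points), 3) array or from the
    nearest face of a triangulated mesh. Returns {index: (t1, t2)} with
    t1, t2 orthonormal and orthogonal to the normal.
    """
    coords = config.coords if hasattr(config, "coords") else np.asarray(config, float)
    idx = list(scheme.surface_points)
    if not idx:
        return {}
    if normals is None:
        if mesh is None:
            raise LandmarkError("surface semilandmarks need a mesh or explicit normals")
        _, _, normals = closest_point_on_mesh(coords[idx], mesh, return_normals=True)
    normals = np.asarray(normals, float)
    return {i: _tangent_pair(normals[j]) for j, i in enumerate(idx)}


def _direction_matrix(scheme, tangents_c: dict, tangents_s: dict, p: int, k: int):
    """Columns = flattened unit displacement fields, one per sliding dof."""
    cols = []
    owners = []
    for i in scheme.curve_sliders():
        F = np.zeros((p, k))
        F[i] = tangents_c[i]
        cols.append(F.ravel())
        owners.append(i)
    for i in scheme.surface_points:
        for t in tangents_s[i]:
            F = np.zeros((p, k))
            F[i] = t
            cols.append(F.ravel())
            owners.append(i)
    if not cols:
        return np.zeros((p * k, 0)), owners
    return np.asarray(cols).T, owners


def slide_step(config, consensus, scheme: SemilandmarkScheme, criterion: str = "bending",
               be_model: BendingEnergyModel = None, mesh=None, normals=None):
    """One sliding step of a single configuration toward the consensus.

    Solves the generalized least-squares problem for the tangent
    displacement amplitudes: the ``bending`` criterion minimizes the TPS
    quadratic form of (slid config - consensus) in the consensus
    bending-energy matrix, applied identically to every coordinate axis;
    the ``d2`` criterion reduces to the independent orthogonal projection
    of each semilandmark's residual onto its tangent line or plane.

    Returns (slid coordinates (p, k), amplitudes (dofs,)).
    """
    coords = config.coords if hasattr(config, "coords") else np.asarray(config, float)
    target = consensus.coords if hasattr(consensus, "coords") else np.asarray(consensus, float)
    p, k = coords.shape
    tc = estimate_curve_tangents(coords, scheme)
    ts = estimate_surface_tangent_planes(coords, scheme, mesh=mesh, normals=normals)
    M, _ = _direction_matrix(scheme, tc, ts, p, k)
    if M.shape[1] == 0:
        return coords.copy(), np.zeros(0)
    r = (coords - target).ravel()
    if criterion == "d2":
        t = -(M.T @ r)
    elif criterion == "bending":
        if be_model is None:
            be_model = bending_energy_matrix(target)
        Q = np.kron(be_model.be_matrix, np.eye(k))
        A = M.T @ Q @ M
        b = -(M.T @ (Q @ r))
        try:
            t = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn("singular sliding normal equations; using ridge fallback",
                          RuntimeWarning)
            t = np.linalg.solve(A + 1e-8 * np.eye(A.shape[0]), b)
    else:
        raise ValueError("criterion must be 'bending' or 'd2'")
    slid = coords + (M @ t).reshape(p, k)
    return slid, t


@dataclass
class SlidingResult:
    """Outcome of iterative sliding: the slid sample and its objective trace."""

    sample: LandmarkSample
    iterations: int
    objective: np.ndarray  # per-iteration criterion value (incl. initial)
    converged: bool
    criterion: str


def _sample_objective(aligned, consensus, criterion, be_model):
    if criterion == "d2":
        return float(((aligned - consensus) ** 2).sum())
    return float(sum(deformation_bending_energy(be_model, a) for a in aligned))


def slide(sample: LandmarkSample, scheme: SemilandmarkScheme, criterion: str = "bending",
          step_fraction: float = None, max_iter: int = 10, update_mean: bool = True,
          curve_geometry=None, mesh=None, normals=None, symmetrize_mean=None,
          amplitude_tol: float = 1e-6) -> SlidingResult:
    """Iteratively slide semilandmarks across a whole sample.

    Each iteration: GPA -> (optionally symmetrize the consensus) ->
    recompute tangents from current positions -> slide each specimen by
    ``step_fraction`` of the computed tangent displacement -> reproject to
    the specimen's curve polylines / surface mesh when geometry is given.
    Stops at ``max_iter`` or when the mean sliding amplitude drops below
    ``amplitude_tol`` times the consensus centroid size.

    ``curve_geometry``: list over curve chains of (m, k) polylines, either
    one list shared by all specimens or one list per specimen.
    ``symmetrize_mean``: optional callable mapping the consensus (p, k) to a
    symmetrized consensus (see the symmetry module).
    ``update_mean=False`` freezes the consensus of the first iteration,
    which can stabilize the bending criterion.
    """
    if step_fraction is None:
        step_fraction = 0.5 if len(scheme.surface_points) else 1.0
    current = sample
    objective = []
    frozen_consensus = None
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        sup = gpa(current, mode="shape")
        consensus = sup.mean_shape
        if frozen_consensus is not None:
            consensus = frozen_consensus
        elif symmetrize_mean is not None:
            consensus = symmetrize_mean(consensus)
        if not update_mean and frozen_consensus is None:
            frozen_consensus = consensus
        be_model = bending_energy_matrix(consensus) if criterion == "bending" else None
        objective.append(_sample_objective(sup.aligned, consensus, criterion, be_model))

        new_coords = current.as_array().copy()
        amplitudes = []
        for i in range(sample.n):
            slid_aligned, t = slide_step(
                sup.aligned[i], consensus, scheme, criterion=criterion,
                be_model=be_model, mesh=_per_case(mesh, i), normals=_per_case(normals, i),
            )
            amplitudes.append(np.abs(t).sum() if t.size else 0.0)
            delta_aligned = (slid_aligned - sup.aligned[i]) * step_fraction
            # map the displacement back into the specimen's native frame
            orig = current.as_array()[i]
            cen = orig.mean(axis=0)
            s = centroid_size(orig)
            R = optimal_rotation((orig - cen) / s, sup.aligned[i])
            delta_orig = (delta_aligned @ R.T) * s
            new_coords[i] = orig + delta_orig
            new_coords[i] = _reproject(new_coords[i], scheme, curve_geometry, mesh, i)
        current = current.with_coords(new_coords)
        if amplitudes and np.mean(amplitudes) * step_fraction < amplitude_tol:
            converged = True
            break
        if not amplitudes:
            converged = True
            break
    # final objective after the last slide
    sup = gpa(current, mode="shape")
    consensus = frozen_consensus if frozen_consensus is not None else sup.mean_shape
    be_model = bending_energy_matrix(consensus) if criterion == "bending" else None
    objective.append(_sample_objective(sup.aligned, consensus, criterion, be_model))
    return SlidingResult(sample=current, iterations=it,
                         objective=np.asarray(objective), converged=converged,
                         criterion=criterion)


def _per_case(obj, i):
    # a plain list means one entry per specimen; anything else is shared
    if isinstance(obj, list):
        return obj[i]
    return obj


def _reproject(coords, scheme, curve_geometry, mesh, case_index):
    out = coords.copy()
    if curve_geometry is not None:
        geom = curve_geometry
        if isinstance(geom, list) and geom and isinstance(geom[0], list):
            geom = geom[case_index]
        fixed = set(scheme.fixed)
        for chain, polyline in zip(scheme.curves, geom):
            idx = [i for i in chain if i not in fixed]
            if idx:
                out[idx] = project_to_curve(out[idx], polyline)
    mesh = _per_case(mesh, case_index)
    if mesh is not None and scheme.surface_points:
        idx = list(scheme.surface_points)
        out[idx], _ = closest_point_on_mesh(out[idx], mesh)
    return out


def project_to_curve(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Nearest point on a polyline for each query point (brute force over segments)."""
    P = np.atleast_2d(np.asarray(points, float))
    C = np.asarray(polyline, float)
    if C.ndim != 2 or len(C) < 2:
        raise LandmarkError("curve geometry must be a polyline with >= 2 points")
    A, B = C[:-1], C[1:]
    AB = B - A                                        # (s, k)
    denom = (AB ** 2).sum(axis=1)
    denom[denom == 0] = 1.0
    t = ((P[:, None, :] - A[None]) * AB[None]).sum(-1) / denom   # (m, s)
    t = np.clip(t, 0.0, 1.0)
    proj = A[None] + t[..., None] * AB[None]          # (m, s, k)
    d2 = ((proj - P[:, None, :]) ** 2).sum(-1)
    best = d2.argmin(axis=1)
    return proj[np.arange(len(P)), best]


def closest_point_on_mesh(points: np.ndarray, mesh, return_normals: bool = False):
    """Nearest point on a triangulated mesh (brute force over triangles).

    ``mesh`` is anything with ``vertices`` and ``faces`` (e.g. a trimesh
    Trimesh). Returns (projected points, distances[, face normals]).
    """
    P = np.atleast_2d(np.asarray(points, float))
    V = np.asarray(mesh.vertices, float)
    F = np.asarray(mesh.faces, int)
    if len(F) == 0:
        raise LandmarkError("empty mesh")
    tri = V[F]  # (f, 3, 3)
    proj = _closest_on_triangles(P, tri)              # (m, f, 3)
    d2 = ((proj - P[:, None, :]) ** 2).sum(-1)
    best = d2.argmin(axis=1)
    out = proj[np.arange(len(P)), best]
    dist = np.sqrt(d2[np.arange(len(P)), best])
    if return_normals:
        normals = _interpolated_normals(out, best, V, F, mesh)
        return out, dist, normals
    return out, dist


def _interpolated_normals(points, face_idx, V, F, mesh):
    """Smooth normals at surface points: barycentric interpolation of vertex
    normals when the mesh provides them, facet normals otherwise."""
    tri = V[F[face_idx]]                 # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    face_n = np.cross(b - a, c - a)
    face_n /= np.linalg.norm(face_n, axis=1, keepdims=True)
    vn = getattr(mesh, "vertex_normals", None)
    if vn is None or len(vn) != len(V):
        return face_n
    # barycentric coordinates of each point in its triangle
    v0, v1, v2 = b - a, c - a, points - a
    d00 = (v0 * v0).sum(1)
    d01 = (v0 * v1).sum(1)
    d11 = (v1 * v1).sum(1)
    d20 = (v2 * v0).sum(1)
    d21 = (v2 * v1).sum(1)
    den = d00 * d11 - d01 * d01
    den = np.where(den == 0, 1.0, den)
    w1 = (d11 * d20 - d01 * d21) / den
    w2 = (d00 * d21 - d01 * d20) / den
    w0 = 1.0 - w1 - w2
    W = np.clip(np.column_stack([w0, w1, w2]), 0.0, 1.0)
    n = np.einsum("mj,mjk->mk", W, np.asarray(vn)[F[face_idx]])
    bad = np.linalg.norm(n, axis=1) < 1e-12
    n[bad] = face_n[bad]
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _closest_on_triangles(P: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each query point.

    Standard region-based point-triangle projection (Ericson), vectorized
    over the (points x triangles) grid.
    """
    a, b, c = tri[:, 0][None], tri[:, 1][None], tri[:, 2][None]  # (1, f, 3)
    p = P[:, None, :]                                            # (m, 1, 3)
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    inside = a + v[..., None] * ab + w[..., None] * ac

    out = inside.copy()
    # vertex regions
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
    m_ab = (~m_a) & (~m_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    m_ac = (~m_a) & (~m_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    m_bc = (~m_b) & (~m_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(m_bc[..., None], b + t_bc[..., None] * (c - b), out)
    out = np.where(m_ac[..., None], a + t_ac[..., None] * ac, out)
    out = np.where(m_ab[..., None], a + t_ab[..., None] * ab, out)
    out = np.where(m_c[..., None], np.broadcast_to(c, out.shape), out)
    out = np.where(m_b[..., None], np.broadcast_to(b, out.shape), out)
    out = np.where(m_a[..., None], np.broadcast_to(a, out.shape), out)
    return out
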