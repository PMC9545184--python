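"""Synthetic landmark data generators.

Every demonstration in this package runs on simulated samples whose
structure mirrors the study designs the methods were built for:

- the Mardia-Dryden distribution — iid isotropic Gaussian noise on every
  landmark coordinate, the field's "pure noise" null model, under which
  centroid size is uncorrelated with shape and the partial-warp variance
  spectrum is flat;
- the self-similar shape distribution — independent partial-warp scores
  with variance proportional to 1/lambda^s (s = 1 in 2D, 2 in 3D), giving
  equal non-affine shape variance at every spatial scale and landmark
  covariances that decay with distance;
- a two-group "face study" design: two sexes of 100, a smooth sex
  mean-difference, lognormal centroid size with allometry, a continuous
  covariate effect (BMI-like), emulating a 200-individual landmark study;
- bilateral samples with directional asymmetry, fluctuating asymmetry and
  replicate measurement error for the symmetry machinery;
- the four-landmark square demo in which isotropic noise alone produces
  inter-landmark-distance correlations of about 0.35 and shape-coordinate
  correlations up to about +/-0.5.

Auto-generated effect vectors are smooth, large-scale patterns (random
weights on the lowest-bending-energy partial warps) so simulated
"biological" effects look like real regression findings rather than white
noise. All samplers are exactly reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .superimpose import centroid_size, gpa, tangent_coordinates
from .symmetry import SymmetryMap, relabel_reflect, symmetrize_consensus
from .thinplate import BendingEnergyModel, bending_energy_matrix, reconstruct_from_partial_warps
from .types import LandmarkError, LandmarkSample, make_sample


@dataclass
class GridTemplate:
    """Regular lattice template: rows x cols (x layers) unit-spaced vertices
    centered at the origin."""

    coords: np.ndarray
    rows: int
    cols: int
    layers: int = 1

    @property
    def p(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def grid_template(rows: int, cols: int, layers: int = None) -> GridTemplate:
    """Vertices of a regular 2D or 3D grid, unit spacing, centered at the origin."""
    if rows < 2 or cols < 2:
        raise LandmarkError("grid needs at least 2 rows and 2 columns")
    ax_r = np.arange(rows) - (rows - 1) / 2.0
    ax_c = np.arange(cols) - (cols - 1) / 2.0
    if layers is None:
        rr, cc = np.meshgrid(ax_r, ax_c, indexing="ij")
        coords = np.column_stack([rr.ravel(), cc.ravel()])
        return GridTemplate(coords=coords, rows=rows, cols=cols)
    ax_l = np.arange(layers) - (layers - 1) / 2.0
    rr, cc, ll = np.meshgrid(ax_r, ax_c, ax_l, indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel(), ll.ravel()])
    return GridTemplate(coords=coords, rows=rows, cols=cols, layers=layers)


def _template_coords(template) -> np.ndarray:
    if isinstance(template, GridTemplate):
        return template.coords
    if hasattr(template, "coords"):
        return np.asarray(template.coords, float)
    return np.asarray(template, float)


def sample_mardia_dryden(template, n: int, sigma: float, seed: int) -> LandmarkSample:
    """Template plus iid Gaussian noise (SD ``sigma``) on every coordinate."""
    rng = np.random.default_rng(seed)
    T = _template_coords(template)
    coords = T[None] + rng.normal(0.0, sigma, size=(n, *T.shape))
    return make_sample(coords)


def sample_self_similar(template, n: int, sigma: float, seed: int,
                        exponent: float = None,
                        be_model: BendingEnergyModel = None) -> LandmarkSample:
    """Self-similar shape distribution around a template.

    Independent partial-warp scores with SD proportional to lambda^(-s/2)
    (s = 1 in 2D, 2 in 3D), normalized so the largest-scale warp has score
    SD ``sigma``; no affine variation. With ``exponent=0`` the construction
    collapses to equal variance on every warp, i.e. isotropic non-affine
    noise, which cross-checks against the Mardia-Dryden sampler.
    """
    rng = np.random.default_rng(seed)
    T = _template_coords(template)
    k = T.shape[1]
    if be_model is None:
        be_model = bending_energy_matrix(T)
    s_exp = (1.0 if k == 2 else 2.0) if exponent is None else float(exponent)
    lam = be_model.eigenvalues
    sd = sigma * (lam / lam[0]) ** (-s_exp / 2.0)
    scores = rng.normal(size=(n, be_model.n_warps, k)) * sd[None, :, None]
    disp = reconstruct_from_partial_warps(be_model, scores.reshape(n, -1))
    return make_sample(T[None] + disp)


def four_landmark_demo(n: int = 5000, sigma: float = 0.05, seed: int = 0,
                       template: np.ndarray = None) -> dict:
    """Four 2D landmarks varying isotropically around a square.

    The geometry of form and shape alone — not any biological process —
    makes the six inter-landmark distances and the eight Procrustes shape
    coordinates correlated: distances sharing a landmark correlate at about
    0.35 and shape coordinates up to about +/-0.5, while the underlying
    coordinate noise is fully uncorrelated.

    Returns a dict with the sample, the (n, 6) distance matrix, distance
    and shape-coordinate correlation matrices, the maxima of interest, and
    the numerical ranks of the shape and Boas coordinate covariances
    (4 and 5: the degrees of freedom of shape and form).
    """
    if template is None:
        template = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    sample = sample_mardia_dryden(template, n=n, sigma=sigma, seed=seed)
    arr = sample.as_array()
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    dists = np.stack([
        np.linalg.norm(arr[:, i] - arr[:, j], axis=1) for i, j in pairs
    ], axis=1)
    dist_corr = np.corrcoef(dists, rowvar=False)
    sharing = np.array([
        [len({*pairs[a]} & {*pairs[b]}) > 0 and a != b for b in range(6)]
        for a in range(6)
    ])
    max_dist_corr = float(dist_corr[sharing].max())

    sup_shape = gpa(sample, mode="shape")
    shape_coords = sup_shape.flat()
    shape_corr = np.corrcoef(shape_coords, rowvar=False)
    off = ~np.eye(8, dtype=bool)
    max_shape_corr = float(np.abs(shape_corr[off]).max())

    _, shape_rank = tangent_coordinates(sup_shape)
    sup_boas = gpa(sample, mode="boas")
    _, boas_rank = tangent_coordinates(sup_boas)

    return {
        "sample": sample,
        "distances": dists,
        "distance_pairs": pairs,
        "distance_correlations": dist_corr,
        "shape_correlations": shape_corr,
        "max_distance_correlation": max_dist_corr,
        "max_shape_coordinate_correlation": max_shape_corr,
        "shape_rank": shape_rank,
        "boas_rank": boas_rank,
    }


def smooth_effect_vector(template, seed: int, n_warps: int = 3,
                         scale: float = 1.0) -> np.ndarray:
    """A smooth (large-scale) shape pattern: random weights on the lowest
    bending-energy partial warps, unit norm times ``scale``. Shape (p, k)."""
    rng = np.random.default_rng(seed)
    T = _template_coords(template)
    bem = bending_energy_matrix(T)
    k = T.shape[1]
    m = min(n_warps, bem.n_warps)
    scores = np.zeros((1, bem.n_warps, k))
    scores[0, :m, :] = rng.normal(size=(m, k))
    v = reconstruct_from_partial_warps(bem, scores.reshape(1, -1))[0]
    return scale * v / np.linalg.norm(v)


@dataclass
class GroupStudySpec:
    """Parameters of the two-group face-study design.

    Defaults mirror a 200-individual, two-sex landmark study on a modest
    5x5 grid: a smooth sex mean-difference, lognormal centroid size with a
    sex size offset and a smooth allometric shape effect of log size, a
    BMI-like Gaussian covariate with its own smooth effect, and isotropic
    measurement/individual noise on top.
    """

    template: object = None
    n_per_group: int = 100
    sigma: float = 0.01            # isotropic residual SD (template units)
    sex_effect_size: float = 0.08  # norm of the sex mean-difference (template units)
    size_log_mean: tuple = (0.0, 0.05)   # per-sex mean of log centroid-size factor
    size_log_sd: float = 0.10
    allometry_size: float = 0.30   # shape change (template units) per unit log size
    covariate_effect_size: float = 0.01   # shape change per covariate unit
    covariate_mean: tuple = (22.0, 24.0)  # per-sex covariate (BMI-like) mean
    covariate_sd: float = 3.0

    def resolved_template(self) -> np.ndarray:
        t = grid_template(5, 5) if self.template is None else self.template
        return _template_coords(t)


def sample_group_study(spec: GroupStudySpec = None, seed: int = 0):
    """Two-sex sample with sex, allometry and covariate effects.

    Per case: shape = template + sex mean-difference + allometric vector x
    (log size deviation) + covariate vector x (covariate - grand mean) +
    isotropic noise, then scaled by the case's centroid-size factor.
    Returns (LandmarkSample with covariates attached, effects dict with the
    true generating vectors for recovery checks).
    """
    spec = spec or GroupStudySpec()
    rng = np.random.default_rng(seed)
    T = spec.resolved_template()
    seeds = rng.integers(0, 2 ** 31 - 1, size=3)
    sex_vec = smooth_effect_vector(T, int(seeds[0]), scale=spec.sex_effect_size)
    allo_vec = smooth_effect_vector(T, int(seeds[1]), scale=spec.allometry_size)
    cov_vec = smooth_effect_vector(T, int(seeds[2]), scale=spec.covariate_effect_size)

    rows = []
    coords = []
    grand_cov_mean = float(np.mean(spec.covariate_mean))
    for g, sex in enumerate(("F", "M")):
        for i in range(spec.n_per_group):
            logsize = rng.normal(spec.size_log_mean[g], spec.size_log_sd)
            covariate = rng.normal(spec.covariate_mean[g], spec.covariate_sd)
            shape = (
                T
                + (g - 0.5) * sex_vec
                + logsize * allo_vec
                + (covariate - grand_cov_mean) * cov_vec
                + rng.normal(0.0, spec.sigma, size=T.shape)
            )
            coords.append(shape * np.exp(logsize))
            rows.append({"id": f"{sex}{i + 1}", "sex": sex,
                         "log_size_factor": logsize, "covariate": covariate})
    coords = np.stack(coords)
    table = pd.DataFrame(rows)
    sample = make_sample(coords, ids=table["id"].tolist(), covariates=table)
    effects = {"sex": sex_vec, "allometry": allo_vec, "covariate": cov_vec}
    return sample, effects


def mirrored_grid_map(rows: int, cols: int) -> SymmetryMap:
    """Symmetry map of a rows x cols grid mirrored across its middle column.

    Requires odd ``cols`` (the middle column is the midline). Pairs mirror
    columns; axis 1 (the column axis of :func:`grid_template`) is the
    reflection axis.
    """
    if cols % 2 == 0:
        raise LandmarkError("mirrored grid needs an odd number of columns")
    index = np.arange(rows * cols).reshape(rows, cols)
    mid = cols // 2
    pairs = []
    midline = list(index[:, mid])
    for c in range(mid):
        for r in range(rows):
            pairs.append((int(index[r, c]), int(index[r, cols - 1 - c])))
    return SymmetryMap(pairs=tuple(pairs), midline=tuple(int(i) for i in midline), axis=1)


@dataclass
class BilateralSpec:
    """Parameters for bilateral (object symmetry) samples."""

    template: object = None
    n: int = 100
    symmetric_sd: float = 0.02     # individual symmetric variation
    directional_size: float = 0.04 # norm of the DA vector
    fluctuating_sd: float = 0.015  # FA SD per asymmetric dimension
    error_sd: float = 0.0          # per-replicate measurement noise
    replicates: int = 1


def _nuisance_basis(T: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows, flattened) of the similarity nuisance space
    at the template: translations, rotation generators, scaling."""
    from .superimpose import _rotation_generators

    p, k = T.shape
    Tc = T - T.mean(axis=0)
    vecs = []
    for a in range(k):
        F = np.zeros((p, k))
        F[:, a] = 1.0
        vecs.append(F.ravel())
    for J in _rotation_generators(k):
        vecs.append((Tc @ J.T).ravel())
    vecs.append(Tc.ravel())
    Q, _ = np.linalg.qr(np.asarray(vecs).T)
    return Q.T


def _asymmetric_subspace(T: np.ndarray, smap: SymmetryMap) -> np.ndarray:
    """Orthonormal basis (rows, flattened) of purely asymmetric *shape*
    displacement fields at a symmetric template: fields with
    v_reflected = -v, orthogonal to translations/rotations/scaling (which
    GPA would absorb anyway)."""
    p, k = T.shape
    dim = p * k
    # the relabel-reflection acts linearly on flattened displacement fields
    perm = smap.permutation(p)
    def reflect_field(v):
        F = v.reshape(p, k)[perm].copy()
        F[:, smap.axis] = -F[:, smap.axis]
        return F.ravel()
    R = np.stack([reflect_field(e) for e in np.eye(dim)]).T
    evals, evecs = np.linalg.eigh(0.5 * (R + R.T))
    A = evecs[:, evals < 0].T  # eigenvalue -1 block: anti-symmetric fields
    N = _nuisance_basis(T)
    A = A - (A @ N.T) @ N
    Q, s, _ = np.linalg.svd(A.T, full_matrices=False)
    return Q[:, s > 1e-8].T


def sample_bilateral_asymmetry(spec: BilateralSpec, smap: SymmetryMap, seed: int = 0):
    """Bilateral sample: symmetric individual variation + directional
    asymmetry + individual fluctuating asymmetry + replicate error.

    The template is symmetrized under ``smap`` if it is not already
    symmetric. FA and DA live in the asymmetric subspace (fields that flip
    sign under relabel-reflection); symmetric individual variation in its
    orthogonal complement. Returns (sample, truth dict); with
    ``spec.replicates > 1`` the sample carries one configuration per
    replicate, ids repeated, and a ``replicate`` covariate column.
    """
    rng = np.random.default_rng(seed)
    T = _template_coords(spec.template if spec.template is not None else grid_template(5, 5))
    T = symmetrize_consensus(T, smap)
    p, k = T.shape
    A = _asymmetric_subspace(T, smap)            # (m, pk)
    S = _symmetric_complement(A, T)

    da_raw = rng.normal(size=A.shape[0]) @ A
    da = spec.directional_size * da_raw / np.linalg.norm(da_raw)

    coords, rows = [], []
    for i in range(spec.n):
        sym_dev = (rng.normal(0.0, spec.symmetric_sd, size=S.shape[0]) @ S)
        fa = (rng.normal(0.0, spec.fluctuating_sd, size=A.shape[0]) @ A)
        base = T.ravel() + sym_dev + 0.5 * (da + fa)
        for rep in range(spec.replicates):
            err = rng.normal(0.0, spec.error_sd, size=p * k) if spec.error_sd > 0 else 0.0
            coords.append((base + err).reshape(p, k))
            rows.append({"id": f"ind{i + 1}", "replicate": rep + 1})
    table = pd.DataFrame(rows)
    configs = make_sample(np.stack(coords), ids=table["id"].tolist(), covariates=table)
    return configs, {"directional": da, "template": T}


def _symmetric_complement(A: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the symmetric shape subspace: the complement of
    the asymmetric subspace and the similarity nuisance space."""
    dim = T.size
    N = _nuisance_basis(T)
    proj = np.eye(dim) - A.T @ A - N.T @ N
    Q, s, _ = np.linalg.svd(proj)
    return Q[:, s > 0.5].T
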