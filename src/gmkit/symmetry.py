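"""Object-symmetry analysis: symmetric/asymmetric decomposition, directional
and fluctuating asymmetry, Procrustes ANOVA, uncentered asymmetry PCA.

For a bilaterally symmetric structure, each configuration is contrasted
with its *relabeled reflection*: mirror the coordinates and swap paired
(left/right) landmark labels. The average of a shape and its relabeled
reflection is perfectly symmetric; their difference vector is the object's
asymmetry, whose length (a Procrustes distance) is the total magnitude of
shape asymmetry. The sample mean of the asymmetry vectors is directional
asymmetry (DA); individual deviations from it are fluctuating asymmetry
(FA). Symmetric and asymmetric variation occupy orthogonal subspaces of
tangent space, so sums of squares decompose additively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .superimpose import Superimposition, gpa, optimal_rotation, procrustes_distance
from .types import LandmarkError, LandmarkSample, make_sample


@dataclass(frozen=True)
class SymmetryMap:
    """Pairing of bilateral landmarks.

    ``pairs``: (left, right) index tuples; ``midline``: indices mapping to
    themselves; together they must cover every landmark exactly once.
    ``axis``: the coordinate axis negated by the reflection (default 0);
    the decomposition is invariant to this choice after Procrustes
    alignment.
    """

    pairs: tuple
    midline: tuple = ()
    axis: int = 0

    def __post_init__(self):
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        midline = tuple(int(i) for i in self.midline)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "midline", midline)
        used = [i for ab in pairs for i in ab] + list(midline)
        if len(used) != len(set(used)):
            raise LandmarkError("symmetry map indices overlap")
        for a, b in pairs:
            if a == b:
                raise LandmarkError(f"pair ({a},{b}) is not a pair")

    def covers(self, p: int) -> bool:
        used = {i for ab in self.pairs for i in ab} | set(self.midline)
        return used == set(range(p))

    def permutation(self, p: int) -> np.ndarray:
        if not self.covers(p):
            raise LandmarkError("symmetry map does not cover all landmarks exactly once")
        perm = np.arange(p)
        for a, b in self.pairs:
            perm[a], perm[b] = b, a
        return perm


def relabel_reflect(config, smap: SymmetryMap) -> np.ndarray:
    """Relabeled reflection: negate the reflection axis, swap paired labels.

    An involution: applying it twice returns the input.
    """
    coords = config.coords if hasattr(config, "coords") else np.asarray(config, float)
    p = coords.shape[0]
    perm = smap.permutation(p)
    out = coords[perm].copy()
    out[:, smap.axis] = -out[:, smap.axis]
    return out


def symmetrize_consensus(consensus: np.ndarray, smap: SymmetryMap) -> np.ndarray:
    """Perfectly symmetric version of one configuration: average it with its
    Procrustes-aligned relabeled reflection."""
    c = consensus - consensus.mean(axis=0)
    refl = relabel_reflect(c, smap)
    refl = refl - refl.mean(axis=0)
    R = optimal_rotation(refl, c)
    return 0.5 * (c + refl @ R)


def symmetry_gpa(sample: LandmarkSample, smap: SymmetryMap) -> Superimposition:
    """Joint GPA of the n originals and their n relabeled reflections.

    The returned superimposition holds 2n aligned configurations (originals
    first, reflections second, same order); its consensus is perfectly
    symmetric by construction.
    """
    arr = sample.as_array()
    refl = np.stack([relabel_reflect(a, smap) for a in arr])
    both = make_sample(
        np.concatenate([arr, refl]),
        ids=[f"{i}" for i in sample.ids] + [f"{i}__reflected" for i in sample.ids],
    )
    sup = gpa(both, mode="shape")
    # enforce exact symmetry of the consensus (it is symmetric up to
    # convergence error by construction)
    sup.mean_shape = symmetrize_consensus(sup.mean_shape, smap)
    sup.mean_shape /= np.sqrt((sup.mean_shape ** 2).sum())
    return sup


@dataclass
class AsymmetryDecomposition:
    """Per-specimen symmetric components and asymmetry vectors.

    ``symmetric``: (n, p, k) symmetric component of each case (average of
    its aligned original and aligned reflection); ``asymmetry``: (n, p*k)
    full difference vectors (original - reflection), so each case is
    reconstructed as symmetric + asymmetry/2; ``directional``: (p*k,) mean
    asymmetry; ``fluctuating``: (n, p*k) deviations from it (rows sum to
    zero). ``anova``: sums of squares and proportions.
    """

    symmetric: np.ndarray
    asymmetry: np.ndarray
    directional: np.ndarray
    fluctuating: np.ndarray
    anova: pd.DataFrame
    consensus: np.ndarray
    ids: list


def decompose_asymmetry(sample: LandmarkSample, smap: SymmetryMap) -> AsymmetryDecomposition:
    """Symmetric / directional / fluctuating decomposition of a sample.

    Sums of squares use the halving convention SS_asym = sum |a_i|^2 / 2
    (a case sits at symmetric + a/2 and its reflection at symmetric - a/2),
    so SS_symmetric + SS_DA + SS_FA equals the total SS of the joint 2n
    superimposition up to the 2x counting of each specimen. Proportions are
    reported both of the grand total and of the asymmetric part alone.
    """
    n = sample.n
    sup = symmetry_gpa(sample, smap)
    orig = sup.aligned[:n]
    refl = sup.aligned[n:]
    sym = 0.5 * (orig + refl)
    asym = (orig - refl).reshape(n, -1)
    directional = asym.mean(axis=0)
    fluctuating = asym - directional
    mu = sup.mean_shape
    ss_sym = float(((sym - mu) ** 2).sum())
    ss_da = 0.5 * n * float(directional @ directional)
    ss_fa = 0.5 * float((fluctuating ** 2).sum())
    total = ss_sym + ss_da + ss_fa
    asym_total = ss_da + ss_fa
    table = pd.DataFrame(
        {
            "SS": [ss_sym, ss_da, ss_fa, total],
            "prop_total": [x / total if total > 0 else np.nan
                           for x in (ss_sym, ss_da, ss_fa, total)],
            "prop_asymmetric": [np.nan,
                                ss_da / asym_total if asym_total > 0 else np.nan,
                                ss_fa / asym_total if asym_total > 0 else np.nan,
                                np.nan],
        },
        index=["symmetric", "directional_asymmetry", "fluctuating_asymmetry", "total"],
    )
    return AsymmetryDecomposition(
        symmetric=sym, asymmetry=asym, directional=directional,
        fluctuating=fluctuating, anova=table, consensus=mu, ids=list(sample.ids),
    )


def asymmetry_magnitudes(decomp: AsymmetryDecomposition) -> np.ndarray:
    """Per-case total magnitude of shape asymmetry: |asymmetry vector|,
    the Procrustes distance between a case and its relabeled reflection."""
    return np.linalg.norm(decomp.asymmetry, axis=1)


def procrustes_anova_symmetry(sample: LandmarkSample, smap: SymmetryMap,
                              replicates=None) -> pd.DataFrame:
    """Procrustes ANOVA for object symmetry.

    Without replicates, delegates to :func:`decompose_asymmetry`. With a
    replicate label per configuration (balanced design required), the
    within-individual replicate variation is separated as measurement
    error: individual symmetric SS and FA SS are computed from individual
    means over replicates, and the residual replicate scatter (symmetric
    and asymmetric alike) is the error SS. SS are additive to the total.
    """
    if replicates is None:
        return decompose_asymmetry(sample, smap).anova
    replicates = np.asarray(replicates)
    ids = np.asarray(sample.ids)
    indiv = pd.unique(ids)
    counts = pd.Series(ids).value_counts()
    if counts.nunique() != 1 or counts.iloc[0] < 2:
        raise LandmarkError("balanced replicate design required (>= 2 replicates each)")
    r = int(counts.iloc[0])
    n_ind = len(indiv)
    sup = symmetry_gpa(sample, smap)
    n = sample.n
    orig = sup.aligned[:n].reshape(n, -1)
    refl = sup.aligned[n:].reshape(n, -1)
    sym = 0.5 * (orig + refl)
    asym = orig - refl
    mu = sup.mean_shape.ravel()

    idx = {u: np.where(ids == u)[0] for u in indiv}
    sym_ind = np.stack([sym[idx[u]].mean(axis=0) for u in indiv])
    asym_ind = np.stack([asym[idx[u]].mean(axis=0) for u in indiv])
    directional = asym_ind.mean(axis=0)

    ss_ind = r * float(((sym_ind - mu) ** 2).sum())
    ss_da = 0.5 * r * n_ind * float(directional @ directional)
    ss_fa = 0.5 * r * float(((asym_ind - directional) ** 2).sum())
    pos = _expand(idx, indiv, n)
    ss_err = float(((sym - sym_ind[pos]) ** 2).sum()) \
        + 0.5 * float(((asym - asym_ind[pos]) ** 2).sum())
    total = ss_ind + ss_da + ss_fa + ss_err
    rows = {
        "individuals": ss_ind,
        "directional_asymmetry": ss_da,
        "fluctuating_asymmetry": ss_fa,
        "measurement_error": ss_err,
        "total": total,
    }
    return pd.DataFrame(
        {"SS": list(rows.values()),
         "prop_total": [v / total if total > 0 else np.nan for v in rows.values()]},
        index=list(rows),
    )


def _expand(idx, indiv, n):
    """Map each of the n rows to its individual's position in `indiv`."""
    pos = np.empty(n, dtype=int)
    for j, u in enumerate(indiv):
        pos[idx[u]] = j
    return pos


def uncentered_asymmetry_pca(decomp: AsymmetryDecomposition):
    """PCA of the asymmetry vectors *without centering*.

    Components maximize average squared deviation from zero (perfect
    symmetry) rather than from the sample mean: a singular value
    decomposition of the uncentered asymmetry matrix. Scores are read as
    vectors from the origin; squared singular values sum to the total
    squared asymmetry norm.

    Returns (components (q, m) columns, singular values, scores (n, m)).
    """
    A = decomp.asymmetry
    if not np.any(A):
        raise LandmarkError("all-zero asymmetry matrix")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    m = int(np.sum(s > 1e-12 * s[0]))
    comps = Vt[:m].T
    # deterministic sign: largest-magnitude loading positive
    for j in range(m):
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
    scores = A @ comps
    return comps, s[:m], scores


def symmetrize_sample(sample: LandmarkSample, smap: SymmetryMap) -> LandmarkSample:
    """Replace each configuration by its symmetric component, removing all
    asymmetric variation. Output variance never exceeds input variance."""
    decomp = decompose_asymmetry(sample, smap)
    return make_sample(decomp.symmetric, ids=sample.ids,
                       landmark_names=sample.landmark_names,
                       covariates=sample.covariates)
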