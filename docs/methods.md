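# Methods

This note records the models, conventions and numerical choices behind
`gmkit`, and what the simulation-based tests do and do not establish.

## Superimposition

GPA uses partial Procrustes superimposition: every configuration is
centered and scaled to unit centroid size exactly, then rotated (proper
rotations only, det +1; reflections are never introduced silently) to the
running consensus. The summed squared deviation from the consensus is
non-increasing across iterations; iteration stops when its change falls
below 1e-10 (max 100 iterations), followed by a short polish loop that
re-rotates until the consensus is stationary to ~1e-13. The polish matters:
the exact rank statements below require rotations optimal with respect to
the *final* consensus to near machine precision. The final orientation is
fixed by rotating the consensus (and with it the whole sample) to
configuration 1, so outputs are reproducible; superimpositions of
nuisance-transformed inputs agree up to that one global rotation.

Boas (form) coordinates are computed as shape coordinates re-multiplied by
centroid size, which is algebraically the same as skipping the scaling
step and keeps the two coordinate systems exactly consistent.

Tangent coordinates are mean-centered aligned coordinates orthogonally
projected onto the tangent plane at the consensus: the components along
the rotation generators `J μ` and (in shape mode) the consensus direction
`μ` itself are removed. Rotation components are already exactly zero at an
OPA optimum (`r·Jμ = r·Jr = 0`); the scale component is a second-order
sphere-curvature term that the projection removes, and with it the
numerical rank of the tangent data becomes exactly `pk − 4` (2D shape),
`pk − 7` (3D shape), or one more in Boas mode, at the fixed relative
singular-value threshold of 1e-8. No stereographic rescaling is applied;
for the small-variance data in scope all downstream methods are linear.

## Thin-plate splines and partial warps

Kernels are `U(r) = r² ln r` in 2D and `U(r) = −r` in 3D; the 3D sign is
chosen so the bending form is positive semidefinite. Any consistent
positive rescaling of the kernel rescales all eigenvalues equally and
cancels in every ratio, regression or relative eigenanalysis in the
package. The bending-energy matrix is the upper-left block of the inverse
bordered system, symmetrized; eigenvalues in [−1e-10, 0) are clipped to
zero and exactly `k + 1` zero eigenvalues (the affine null space) are
expected — more indicates a degenerate reference, reported with the
condition number. Partial warps are the eigenvectors with positive
eigenvalue, ascending, so warp 1 is the largest-scale pattern.

The uniform (affine) component is constructed as the span of linear
displacement fields of the centered reference with translations, the
scaling direction and rotation generators projected out — dimension 2 in
2D, 5 in 3D. This orthogonal-projection construction spans the same
subspace as the classical two-vector parameterization. Together with the
partial warps it reconstructs tangent-projected residuals exactly.

## Sliding semilandmarks

Tangent directions are recomputed each iteration from the current (slid)
positions: central differences along curve chains, one-sided at chain
ends; anchored fixed endpoints need no tangent and never move. Surface
points get a tangent pair orthogonal to a mesh normal; normals are
interpolated from vertex normals barycentrically at the foot point, which
is markedly more accurate than facet normals on coarse meshes.

One sliding step solves the generalized least squares for all tangent
amplitudes jointly: minimize `(r + M t)ᵀ Q (r + M t)` with `Q = B ⊗ I`
(bending criterion, `B` from the consensus, identical on every coordinate
axis) or `Q = I` (Procrustes-distance criterion, which decouples into
independent orthogonal projections). Singular normal equations fall back
to a 1e-8 ridge with a warning. Displacements are computed in the aligned
frame and mapped back through each specimen's similarity transform, so
fixed landmarks stay bit-identical and reprojection uses the specimen's
native curve polylines or mesh. Default step fraction is 1.0 for curves
and 0.5 for surfaces, max 10 iterations, amplitude tolerance 1e-6 of the
consensus centroid size.

The d2 criterion is monotone and terminates; its zero-variance optimum is
a *continuum* (any spacing shared by all specimens), so limit positions
are path-dependent even though the objective value is not — the damping
test checks the objective, not coordinates. The bending criterion puts no
penalty on affine variation and can increase shape variance or fail to
converge; both behaviors are reported in the result object rather than
suppressed.

## Symmetry

The relabeled reflection negates one coordinate axis (configurable;
decompositions are axis-invariant after alignment) and swaps paired
landmark labels. The joint GPA of the n originals and n reflections yields
a perfectly symmetric consensus; each case decomposes into symmetric
component `(o + r)/2` and asymmetry vector `o − r`, so a case is
`symmetric + asymmetry/2`. Sums of squares follow the halving convention
`SS_asym = Σ|a|²/2`, making SS exactly additive; proportions are reported
both of the grand total and of the asymmetric part alone, since published
percentages use either denominator. With balanced replicates, individual
means separate measurement error; note the asymmetry vector *doubles* the
error's asymmetric component (variance `4σ²_err` per asymmetric
dimension), which the recovery tests account for. Asymmetry PCA is the
SVD of the *uncentered* asymmetry matrix: deviations from perfect symmetry
(the origin), not from the mean asymmetry, are what the components
maximize.

Symmetric and asymmetric displacement fields occupy exactly orthogonal
subspaces; empirical cross-covariance between the two score sets vanishes
only in the small-asymmetry limit (residual coupling is second-order
Procrustes curvature) and at finite n carries ordinary `1/√n` sampling
covariance — the tests distinguish these three statements.

## Ordination and covariance comparison

Covariances use `n − 1` denominators; the group-mean covariance of bgPCA
uses `g − 1` with unweighted means by default (each group counts equally),
a weighted option for unbalanced designs. Cross-validated bgPCA recomputes
the group-mean basis without the focal case. CVA whitens the pooled
within-group covariance on the chosen PC basis so canonical scores have
unit within-group variance, and back-transforms axes to coordinate space
for visualization. QDA classification recomputes the PCA inside every
leave-one-out fold — scores from a PCA of all cases would leak the
left-out case into the basis — with equal priors and ties resolved to the
lower group index. Axis signs follow one convention everywhere: the
largest-magnitude loading is positive.

Relative eigenanalysis is the generalized symmetric eigenproblem; the
denominator matrix must be nonsingular on the analysis basis, and the
error message says to reduce dimensions rather than silently
regularizing. A programmatic PC-count default (smallest m with ≥90%
cumulative variance) exists but logs a prominent warning: automatic
dimension choices hide exactly the artifacts this module demonstrates.

## Association

Shape regression is per-coordinate OLS reported jointly. Multivariate R²
is the explained fraction of total shape variance (equivalently the
variance-weighted mean of per-coordinate R²); the regression-score R² is
the squared correlation of the predictor with the data projected on the
normalized coefficient vector. The two react to added PCs in opposite
directions, which `pc_sensitivity_curve` traces.

PLS, RRR and CCA are SVDs of `S_xy`, `S_xx^(−1/2) S_xy`, and
`S_xx^(−1/2) S_xy S_yy^(−1/2)` respectively, on PC-reduced bases where
inversion demands it (PC reduction, not ridge, so loadings stay
inspectable). The RRR statistic is the slope of the y-latent per standard
deviation of the x-latent — the normalization under which "maximal slope"
is well defined and under which RRR beats every other direction; an
unstandardized slope can be made arbitrarily large by shrinking the
x-weights. Blocks are column-centered; the y block is never standardized
by default (shape coordinates share units). Latent signs make each
x-latent covary positively with the first x variable.

## Spatial scale

The variance spectrum sums each warp's score variance over coordinate
axes and regresses log variance on log(1/λ) by unweighted OLS, averaging
repeated eigenvalues first (a tied λ is one spatial scale). The
self-similar reference exponent is fixed at 1 (2D) and 2 (3D) — the
slopes that define the self-similar distribution — but is exposed as a
parameter. Affine variation is excluded throughout (bending energy is
undefined for it). Relative intrinsic warps contrast the observed warp
covariance with the diagonal self-similar reference `1/λ^s`, normalized
to unit geometric mean so only the spectrum's *shape* matters.

Two caveats the tests encode: on a symmetric grid template the
bending-energy eigenvalues come in degenerate pairs, so a consensus warp
basis may permute or rotate within a tied pair relative to the template's
(comparisons are therefore made between subspaces); and landmark
covariance under self-similarity decays with distance only through
mid-range separations — at the largest distances the biggest warp makes
opposite corners co-move again, so the rank correlation with distance is
negative but modest.

## Simulation models and their limits

`sample_mardia_dryden` adds iid Gaussian noise (SD σ) to every coordinate
of a template: the null model in which centroid size is uncorrelated with
shape and the warp spectrum is flat. `sample_self_similar` draws
independent warp scores with SD ∝ λ^(−s/2), largest-scale warp SD = σ,
zero affine variation; with s forced to 0 it collapses to a flat spectrum,
cross-checking the two generators. The four-landmark demo uses a unit
square, for which the shared-distance correlation has the analytic
small-noise limit cos45°/2 ≈ 0.354; at the demonstration noise level
(σ = 0.05 of the side) the finite-noise value is ≈ 0.37.

The two-group study generator mirrors a 200-individual, two-sex design on
a 5×5 grid (the grid stands in for a dense facial landmark set at desk
scale): smooth sex, allometric and covariate effect vectors (random
weights on the three largest-scale warps, so effects look like biological
gradients rather than white noise), lognormal size with a sex offset, a
BMI-like covariate differing in mean between sexes, and isotropic residual
noise. Default effect sizes (σ = 0.01 template units, sex effect 0.08,
allometry 0.3 per log-size unit with size SD 0.10, covariate effect 0.01
per unit with SD 3) were set by a power calculation so that coefficient
vectors are estimable at n = 200 with cosine ≈ 0.98 to the truth —
comfortably above the 0.95 the recovery tests require — while keeping all
three effects mutually confounded through the sex differences, which is
what makes the multiple-regression recovery non-trivial. The bilateral
generator draws directional and fluctuating asymmetry inside the purely
asymmetric shape subspace (reflection-antisymmetric fields orthogonal to
translations, rotations and scaling) and symmetric variation in its
complement, so generated effects are identifiable after GPA.

What passing these tests shows: the estimators recover the generating
structures at realistic effect-to-noise ratios, and the artifacts the
package warns about appear exactly where theory says. What they do not
show: performance under landmark digitization biases, missing landmarks,
curved-space effects at large shape variance, or correlated (non-isotropic,
non-self-similar) noise — real data have all of these.

## Problem sizes

Test-suite simulations use n between 40 and 5000 on templates of 4–27
landmarks, chosen so every statistic's Monte-Carlo error is well inside
its asserted tolerance; the reference script's sizes (n = 5000 for the
four-landmark statistic, n = 1000 for the slopes, 20 × n = 100 for the
classification rate) match the demonstrations they reproduce.
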