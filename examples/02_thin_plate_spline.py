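"""Thin-plate splines: warps, bending energy, partial warps.

Fits the TPS from a square to a kite, evaluates bending energy (zero for
affine differences, quadratic in extrapolation), and shows the
spatial-scale ordering of the partial-warp eigenvalues of a 5x5 grid.
"""

import numpy as np

from gmkit import bending_energy_matrix, deformation_bending_energy, fit_tps, warp_points
from gmkit.simulate import grid_template

square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
kite = np.array([[0.0, -0.2], [1.0, 0.0], [1.0, 1.0], [0.0, 1.2]])

model = fit_tps(square, kite)
print("landmarks map exactly:",
      np.abs(warp_points(model, square) - kite).max() < 1e-9)
print(f"midpoint (0.5, 0.5) warps to {np.round(warp_points(model, [[0.5, 0.5]])[0], 4)}")

grid = grid_template(5, 5)
bem = bending_energy_matrix(grid.coords)
print(f"\npartial warps of the 5x5 grid: {bem.n_warps} "
      f"(p - k - 1 = {grid.p - 3} per axis)")
print(f"eigenvalue range {bem.eigenvalues[0]:.4f} (largest scale) .. "
      f"{bem.eigenvalues[-1]:.4f} (most local)")
# localized deformations cost more bending energy than large-scale ones

shear = grid.coords @ np.array([[1.0, 0.3], [0.0, 1.0]]).T
print(f"bending energy of a pure shear: "
      f"{deformation_bending_energy(bem, shear):.2e} (affine -> zero)")

bump = grid.coords.copy()
bump[12] += [0.0, 0.3]  # displace the central landmark
be1 = deformation_bending_energy(bem, bump)
bump2 = grid.coords + 2 * (bump - grid.coords)
print(f"central bump: bending energy {be1:.4f}; doubled displacement: "
      f"{deformation_bending_energy(bem, bump2):.4f} (= 4x, a quadratic form)")
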