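"""Align two simulated tissue sections related by a known deformation.

A 5,000-cell tissue is deformed by a known affine (rotation 15°, scale
1.05, translation (300, −200) μm) plus a smooth bump field (max ~150 μm).
The solver first recovers the affine, then switches on the velocity-field
(diffeomorphic) refinement; because the generator carries exact per-cell
correspondences, recovery error is measured directly.
"""

import numpy as np

from stwarp.raster import normalize_image, rasterize
from stwarp.solver import SolverConfig, run_lddmm
from stwarp.synthetic import DeformationSpec, SyntheticSpec, deform, generate_tissue

points, _ = generate_tissue(SyntheticSpec(seed=1))
truth = DeformationSpec(
    rotation_deg=15.0, scale=1.05, translation=(300.0, -200.0),
    bump_centers=[[2000.0, 2500.0], [5500.0, 4000.0], [3500.0, 6500.0]],
    bump_amplitudes=[[120.0, -90.0], [-100.0, 110.0], [80.0, 120.0]],
    bump_scale=1000.0,
)
moved, _ = deform(points, truth)

dx = 100.0
source = normalize_image(rasterize(points, dx=dx, blur_std=1.5))
target = normalize_image(rasterize(moved, dx=dx, blur_std=1.5))

cfg = SolverConfig(
    dx=dx, niter=1500, diffeo_start=500, sigma_M=0.15, sigma_B=0.3,
    sigma_A=0.4, contrast_degree=1, ep_L=1e-10, ep_T=1e-3, ep_V=1.0,
)
result = run_lddmm(source, target, cfg)

aligned = result.transform_points(points)
err = np.linalg.norm(aligned.coords - moved.coords, axis=1)
hist = result.loss_history
print(f"objective: {hist[0, 3]:.3g} (epoch 0) -> {hist[-1, 3]:.3g} (final)")
print(f"recovered linear part:\n{np.round(result.A.linear, 4)}")
print(f"true linear part:\n{np.round(truth.affine_matrix(2)[:2, :2], 4)}")
print(f"mean correspondence error: {err.mean():.1f} um "
      f"(median {np.median(err):.1f} um) at dx={dx:.0f} um")
# Errors well below one raster pixel mean the solved map reproduces the
# generating deformation at sub-pixel accuracy.
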