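"""Robust matching when the target section is missing a hemisphere.

The matching term weights every target pixel by the posterior probability
that it is explained by the transformed source (vs background/artifact,
a three-component Gaussian mixture on the target intensities). Source
cells mapping into missing tissue land on background-dominated pixels and
are flagged non-matching at the 0.85 posterior threshold.
"""

import numpy as np

from stwarp.raster import normalize_image, rasterize
from stwarp.solver import SolverConfig, matching_mask, run_lddmm
from stwarp.synthetic import SyntheticSpec, cut_section, generate_tissue

points, _ = generate_tissue(SyntheticSpec(seed=3))
median_x = float(np.median(points.coords[:, 1]))
kept, removed = cut_section(points, normal=[0.0, 1.0], offset=median_x)

dx = 100.0
source = normalize_image(rasterize(points, dx=dx, blur_std=1.5))
target = normalize_image(rasterize(kept, dx=dx, blur_std=1.5))

cfg = SolverConfig(
    dx=dx, niter=300, diffeo_start=10**9, sigma_M=0.15, sigma_B=0.05,
    sigma_A=0.3, muB="black", contrast_degree=1,
    ep_L=1e-11, ep_T=1e-4, A0=np.eye(3),
)
result = run_lddmm(source, target, cfg)

mask, flags = matching_mask(result, points)  # threshold 0.85
print(f"target kept {kept.n}/{points.n} cells (cut at x={median_x:.0f} um)")
print(f"matched pixels: {mask.mean():.1%} of the target grid")
print(f"cells in the removed hemisphere flagged non-matching: "
      f"{np.mean(~flags[removed]):.1%}")
print(f"cells in shared tissue flagged matching: "
      f"{np.mean(flags[~removed]):.1%}")
# Both fractions well above 90% show the mixture correctly separates
# missing tissue from shared tissue without distorting the map.
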