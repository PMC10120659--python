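# Methods

## Problem and model

`stwarp` aligns spatial transcriptomics (ST) sections — delivered as
tables of cell centroids in physical μm, optionally with per-cell gene
counts — to other sections, to histology images, or to a 3D annotated
reference volume. Direct point-cloud matching is quadratic in the number
of cells, so each cloud is first converted into an image: the cells are
treated as a sum of point masses (a space measure), binned at resolution
`dx` and convolved with an isotropic Gaussian of standard deviation
`blur_std·dx`. The result is a density (integral = number of cells, up to
kernel truncation at the padded boundary), carried with explicit physical
pixel-center coordinates so grids of different extent and resolution
compose safely.

The alignment map is the composition

    x ↦ A · φ₁(x)

of a diffeomorphism φ₁ — the time-1 flow of a time-varying velocity
field v_t, t ∈ [0, 1], sampled at `nt` time steps — with an affine
transform A in homogeneous coordinates (diffeomorphism first, affine
second). Flowing along a smooth velocity field guarantees a smooth,
invertible map with positive Jacobian determinant: tissue may bend and
stretch but never tear or fold, and cell neighbor relations are
preserved. Points are pushed through the forward flow; images are
resampled through the backward flow (integration of −v with the time
samples reversed). The two are discretizations of exact inverses, so a
sampled map is never inverted numerically.

The solved objective is E = R(v) + M + P with

* **Regularization** R(v) = (1/2σ_R²)·(1/nt)·Σ_t Σ_x ‖(L v_t)(x)‖² dx^d,
  where L = (1 − a²Δ)^p is a Sobolev operator applied spectrally through
  the discrete Laplacian symbol ℓ̂(ξ) = Σᵢ (2/dxᵢ²)(1 − cos 2π ξᵢ dxᵢ).
  `a` (μm) sets the smoothness scale of admissible deformations; `p` the
  operator order.
* **Matching** M = (1/2σ_M²)·Σ_x W_match(x)·‖f_θ(Î(x)) − J(x)‖² dx^d,
  where Î is the transformed source sampled on the target grid, f_θ a
  per-target-channel polynomial contrast transform in the scalar source
  intensity (reconciling density images with e.g. H&E intensities), and
  W_match the posterior probability that target pixel x is explained by
  the transformed source. W comes from a three-component Gaussian
  mixture on the target intensities — means {f_θ(Î(x)), μ_B, μ_A}, stds
  {σ_M, σ_B, σ_A} for the matching, background and artifact components —
  updated by one EM sweep per epoch. Modelling the mixture on the target
  only means the *more complete* section should be the source.
* **Landmarks** P = (1/2σ_P²)·Σᵢ ‖A·φ₁(sᵢ) − tᵢ‖² for optional paired
  points, which also initialize A by least squares.

Every σ enters uniformly as a standard deviation: 1/(2σ²) in its
quadratic term and as the Gaussian std of its mixture component. (The
published parameter table labels σ_A/σ_B "variances" and σ_M a "weight";
treating all of them as standard deviations is the single consistent
reading and is what the formulas above implement.)

## Optimization

Steepest descent with three step sizes: `epL` for the linear part of A,
`epT` for the translation, `epV` for v (from epoch `diffeo_start` on —
setting it > 0 yields coarse-to-fine, affine-first optimization). The
mixture weights and contrast coefficients are refit once per epoch and
held fixed within each gradient step (EM-in-the-loop), which keeps the
descent stable.

Gradients are computed as the **exact discrete adjoint** of the forward
computation — reverse-mode differentiation written by hand through the
affine solve, the semi-Lagrangian Euler integration and the multilinear
interpolation (the three primitives in `_interp.py` form exact
adjoint/VJP pairs; `tests/test_solver.py` checks the assembled gradient
against central finite differences). This matches what autodiff would
produce for the identical discretization without requiring a tensor
framework. The raw derivative with respect to v is a covector; it is
converted to a descent direction by multiplying its spectrum with
K̂ = L̂⁻² (the natural gradient under the Sobolev metric), so updates to v
are automatically smooth and the flow remains diffeomorphic at practical
step sizes.

For 3D→2D alignment (section to atlas volume) the target section is
embedded at z = 0 of target space; each target pixel (0, y, x) is pulled
through A⁻¹ (4×4) and the backward 3D flow and the source volume is
sampled there. The slice depth is absorbed into A's z-translation, so
the initial `T0` should carry an approximate z-offset; everything else
is the identical loop with d = 3. Annotation lift-over maps each cell
(y, x) → (0, y, x) → source volume coordinates and reads the
nearest-voxel label (0 outside the volume).

## Parameters

| name | meaning | default |
|---|---|---|
| dx | raster resolution (μm) | 30 |
| blur_std | raster kernel std (pixels) | 1 |
| sigmaM / sigmaB / sigmaA | matching / background / artifact std | 1.0 / 2 / 5 |
| sigmaR | regularization weight | 5e5 |
| sigmaP | landmark weight | 2e1 |
| a, p | Sobolev scale (μm), order | 500, 2 |
| niter, diffeo_start, nt | epochs, v-start epoch, time steps | 5000, 0, 3 |
| epL, epT, epV | step sizes (linear, translation, velocity) | 2e-8, 2e-1, 2e3 |
| muB, muA | background/artifact means; "black"=0, "white"=1 (fixed), numeric (fixed), or None (EM-estimated) | None |
| contrast_degree | polynomial degree of f_θ | 3 |

Defaults mirror the published tool. The step-size defaults assume
unnormalized intensities with σ_M = 1; on percentile-normalized [0, 1]
rasters with σ_M ≈ 0.15 the gradients are several orders of magnitude
larger and the steps must be reduced accordingly (the reference tool's
own per-dataset configurations do exactly this). The examples and tests
use epL ≈ 1e-10, epT ≈ 1e-3, epV ≈ 1 in that regime. `blur_std = 1`
pixel is this package's choice; the kernel bandwidth relative to dx is a
free parameter of the method.

When μ_B/μ_A are not user-fixed they are initialized to the per-channel
minimum/maximum of the target and re-estimated by the M-step each epoch;
priors start uniform (1/3 each) and become the mean posteriors.

## Synthetic stated world

The generator (`stwarp.synthetic`) emulates a single-cell-resolution ST
section: 5,000 cells in an 8×8 mm domain clustered into 8 Gaussian blobs
(σ = 600 μm), 29 cell types (one dominant type per blob, fraction 0.6),
10 genes with per-type mean counts under multiplicative lognormal noise
(σ_log = 0.3). Deformations are an affine followed by a Gaussian-bump
displacement field; the construction enforces the analytic bound
Σⱼ ‖aⱼ‖ e^(−1/2)/sⱼ < 1, which guarantees the generating map is itself
diffeomorphic, and carries exact per-cell correspondences so recovery
error is measured directly. The 3D world is a smooth blob intensity
volume (24×40×36 voxels at 50 μm) with region labels assigned by nearest
blob above an intensity threshold.

What a green test does establish: sub-pixel recovery of known affine and
smooth deformations from density images; correct separation of missing
vs shared tissue by the mixture posteriors; exact agreement of every
statistic with brute-force implementations. What it does not: alignment
quality on real tissue (no segmentation errors, no platform-specific
detection noise, no genuinely non-corresponding anatomy, only 10 broadly
expressed genes), and nothing about landmark placement variability.

## Numerical choices

* Interpolation is multilinear everywhere with nearest-edge extension;
  clamped coordinates have zero derivative, which keeps gradients
  bounded when mass leaves the grid.
* The velocity grid is the source grid padded by 2 pixels, so v is
  defined wherever source mass exists; its cell volume and `nt` enter
  the energy exactly as written above.
* Backward/forward Euler flows are O(1/nt)-consistent inverses; with
  nt = 3 and the regularized fields the solver produces, round-trip
  error stays below one velocity-grid pixel (asserted in the tests).
* Mixture underflow (all three components at ~0 density) yields a
  uniform posterior at that pixel; log-densities are max-shifted before
  exponentiation.
* A rank-deficient contrast design (constant warped source) falls back
  to the weighted mean (degree 0) with a warning.
* A constant image channel normalizes to zeros with a warning.
* Fixed-step descent is not strictly monotone; the contract asserted in
  tests is final ≤ epoch-0 and ≥90% non-increasing epochs.
* The solver is deterministic (pure numpy); seeds only enter synthetic
  data generation and the random-region statistic.

## Design choices on open points

* Operator L = (1 − a²Δ)^p: the canonical LDDMM choice consistent with
  a "smoothness scale" and a "power of Laplacian" parameter.
* Contrast f_θ: per-target-channel polynomial in the scalar source
  intensity (the solver requires a single-channel source; density
  rasters are). Degree 3 by default, degree 1 recommended for noisy or
  partial data.
* Pseudospot aggregation assigns a cell to the *nearest* qualifying spot
  when spot circles overlap (real capture arrays are non-overlapping).
* Region expansion by k-NN is read as the union of the members' k
  nearest neighbors over all cells — consistent with "≈100 μm" of
  boundary growth at single-cell densities — rather than adding exactly
  k cells.
* Shannon entropy uses the natural log (the elementwise-entropy
  convention of `scipy.special.entr`), so a one-hot composition has
  H = 0 and uniform-over-K has H = ln K.
* GMM means update every epoch (no schedule); the published epoch
  counts/σ overrides per dataset are treated as example configurations.

## Limitations

* Fixed-step steepest descent can sit in local minima for large
  misorientations; landmarks (3+ pairs) initialize A by least squares
  and add a pull term, which is the intended remedy.
* The mixture handles missing tissue in the *target* only; choose the
  more complete section as the source.
* Isotropic kernels bias accuracy toward structures at the chosen
  raster scale; thin (< dx) structures are not reliably alignable.
* No multi-resolution pyramid, no stochastic optimizers, no GPU path.
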