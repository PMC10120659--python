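"""Energy terms of the alignment objective.

The objective is E = R(v) + M(f_θ(φ·I_S), I_T) + P(A, φ; landmarks):

* R — Sobolev regularization of the velocity field under the operator
  L = (1 − a²Δ)^p, applied spectrally on the velocity grid;
* M — Gaussian-mixture-weighted sum of squares between the contrast-
  transformed, transformed source and the target. A three-component
  mixture (matching / background / artifact) on the *target* intensities
  downweights pixels the source cannot explain (missing tissue, tears);
* P — quadratic penalty pulling mapped source landmarks onto their
  target partners.

Raw derivatives of E w.r.t. v are covectors; `smooth_gradient` converts
them to gradient vectors under the Sobolev metric (multiplication of the
spectrum by K = (L†L)⁻¹), the "natural gradient" used for descent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import AffineTransform, LandmarkSet, VelocityField, flow_points

__all__ = [
    "MixtureWeights",
    "ContrastModel",
    "EnergyWeights",
    "operator_symbol",
    "regularization_energy",
    "smooth_gradient",
    "fit_contrast",
    "em_update_weights",
    "matching_energy",
    "landmark_energy",
]

@dataclass
class MixtureWeights:
    """Per-target-pixel posteriors over {matching, background, artifact}.

    posteriors has shape (3, *target grid) and sums to 1 pixelwise;
    mu_B / mu_A are per-channel means of the background and artifact
    Gaussians; priors is a 3-simplex of component weights.
    """

    posteriors: np.ndarray
    mu_B: np.ndarray
    mu_A: np.ndarray
    priors: np.ndarray = field(default_factory=lambda: np.full(3, 1.0 / 3.0))

    def __post_init__(self):
        self.posteriors = np.asarray(self.posteriors, float)
        self.mu_B = np.atleast_1d(np.asarray(self.mu_B, float))
        self.mu_A = np.atleast_1d(np.asarray(self.mu_A, float))
        self.priors = np.asarray(self.priors, float)
        if self.posteriors.shape[0] != 3:
            raise ValueError("posteriors must have 3 components")
        s = self.posteriors.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("posteriors must sum to 1 pixelwise")
        if (self.posteriors < -1e-12).any() or (self.posteriors > 1 + 1e-12).any():
            raise ValueError("posteriors must lie in [0, 1]")

    @property
    def matching(self) -> np.ndarray:
        return self.posteriors[0]

    @classmethod
    def uniform(cls, grid_shape, n_channels: int = 1) -> "MixtureWeights":
        post = np.full((3,) + tuple(grid_shape), 1.0 / 3.0)
        return cls(post, np.zeros(n_channels), np.ones(n_channels))


@dataclass
class ContrastModel:
    """Per-target-channel polynomial in the (scalar) source intensity.

    theta has shape (c_target, degree + 1), constant term first:
    f_θ(s)_c = Σ_j theta[c, j] s^j.
    """

    theta: np.ndarray
    degree: int

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, float))
        if not np.isfinite(self.theta).all():
            raise ValueError("contrast coefficients must be finite")
        if self.theta.shape[1] != self.degree + 1:
            raise ValueError("theta must have degree + 1 columns per channel")

    def __call__(self, s: np.ndarray) -> np.ndarray:
        """Evaluate; returns shape (c_target, *s.shape)."""
        s = np.asarray(s, float)
        powers = np.stack([s**j for j in range(self.degree + 1)])
        return np.tensordot(self.theta, powers, axes=(1, 0))

    def derivative(self, s: np.ndarray) -> np.ndarray:
        """df_θ/ds, shape (c_target, *s.shape)."""
        s = np.asarray(s, float)
        if self.degree == 0:
            return np.zeros((self.theta.shape[0],) + s.shape)
        powers = np.stack(
            [j * s ** (j - 1) for j in range(1, self.degree + 1)]
        )
        return np.tensordot(self.theta[:, 1:], powers, axes=(1, 0))


@dataclass
class EnergyWeights:
    """The σ parameters weighting the objective terms.

    Each σ enters as 1/(2σ²) in its quadratic term and as the standard
    deviation of the corresponding mixture component (σM, σB, σA).
    """

    sigma_M: float = 1.0
    sigma_R: float = 5.0e5
    sigma_P: float = 2.0e1
    sigma_A: float = 5.0
    sigma_B: float = 2.0

    def __post_init__(self):
        for name in ("sigma_M", "sigma_R", "sigma_P", "sigma_A", "sigma_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def operator_symbol(axis_coords: Sequence[np.ndarray], a: float, p: float) -> np.ndarray:
    """Spectral multiplier of the Sobolev operator L = (1 − a²Δ)^p.

    Uses the discrete Laplacian symbol ℓ̂(ξ) = Σᵢ (2/dxᵢ²)(1 − cos(2π ξᵢ dxᵢ))
    on the uniform grid, so L̂(0) = 1 and L̂ grows with frequency. Returned
    with the full-FFT frequency layout of the grid.
    """
    if a <= 0 or p < 1:
        raise ValueError("need a > 0 and p >= 1")
    lap = 0.0
    shape = tuple(len(ax) for ax in axis_coords)
    for k, ax in enumerate(axis_coords):
        dx = float(ax[1] - ax[0]) if len(ax) > 1 else 1.0
        xi = np.fft.fftfreq(len(ax), d=dx)
        term = (2.0 / dx**2) * (1.0 - np.cos(2.0 * np.pi * xi * dx))
        bshape = [1] * len(shape)
        bshape[k] = len(ax)
        lap = lap + term.reshape(bshape)
    return (1.0 + a**2 * lap) ** p


def _apply_symbol(field_vals: np.ndarray, symbol: np.ndarray) -> np.ndarray:
    """Filter each leading component of a (…, *grid) field by a spectral symbol."""
    axes = tuple(range(field_vals.ndim - symbol.ndim, field_vals.ndim))
    spec = np.fft.fftn(field_vals, axes=axes)
    return np.real(np.fft.ifftn(spec * symbol, axes=axes))


def regularization_energy(v: VelocityField, sigma_R: float) -> float:
    """R(v) = (1/(2σR²)) · (1/nt) Σ_t Σ_x ‖(L v_t)(x)‖² dx^d.

    A positive-definite quadratic form in v: zero iff v ≡ 0, and scaling
    v by c scales R by c².
    """
    symbol = operator_symbol(v.axis_coords, v.a, v.p)
    Lv = _apply_symbol(v.samples, symbol)
    cell = float(np.prod(v.dx))
    return float(np.sum(Lv**2) * cell / (2.0 * sigma_R**2 * v.nt))


def regularization_gradient(v: VelocityField, sigma_R: float) -> np.ndarray:
    """Raw derivative of R w.r.t. the velocity samples: (dx^d/(σR² nt)) L†L v."""
    symbol = operator_symbol(v.axis_coords, v.a, v.p)
    cell = float(np.prod(v.dx))
    return _apply_symbol(v.samples, symbol**2) * (cell / (sigma_R**2 * v.nt))


def smooth_gradient(raw_grad: np.ndarray, axis_coords, a: float, p: float) -> np.ndarray:
    """Convert a raw derivative (covector) into a Sobolev gradient vector.

    Multiplies the spectrum by K̂ = L̂⁻², the inverse of the squared
    operator symbol; constant fields pass through unchanged (L̂(0) = 1)
    while high-frequency content is strongly suppressed.
    """
    symbol = operator_symbol(axis_coords, a, p)
    return _apply_symbol(np.asarray(raw_grad, float), symbol**-2.0)


def fit_contrast(
    transformed_source: np.ndarray,
    target: np.ndarray,
    weights: Optional[np.ndarray] = None,
    degree: int = 3,
) -> ContrastModel:
    """Weighted polynomial least squares mapping source intensity to target.

    Per target channel c solves θ_c = argmin Σ_x w(x)·(poly_θ(s(x)) − t_c(x))².
    ``transformed_source`` is the scalar warped source intensity (any grid
    shape); ``target`` is (c, *grid). A rank-deficient design (e.g. constant
    source) falls back to degree 0 — the weighted mean — with a warning.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    s = np.asarray(transformed_source, float).ravel()
    t = np.asarray(target, float).reshape(np.asarray(target).shape[0], -1)
    if s.size != t.shape[1]:
        raise ValueError("source and target must share a grid")
    w = np.ones_like(s) if weights is None else np.asarray(weights, float).ravel()
    sw = np.sqrt(np.clip(w, 0.0, None))

    deg = degree
    design = np.stack([s**j for j in range(deg + 1)], axis=1)
    X = design * sw[:, None]
    Y = t.T * sw[:, None]
    if deg >= 1 and np.linalg.matrix_rank(X) < deg + 1:
        warnings.warn("rank-deficient contrast design; falling back to degree 0")
        wsum = w.sum()
        mean = (t * w).sum(axis=1) / wsum if wsum > 0 else t.mean(axis=1)
        theta = np.zeros((t.shape[0], degree + 1))
        theta[:, 0] = mean
        return ContrastModel(theta, degree)
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    return ContrastModel(coef.T, deg)


def em_update_weights(
    pred: np.ndarray,
    target: np.ndarray,
    ew: EnergyWeights,
    mu_B: Optional[np.ndarray] = None,
    mu_A: Optional[np.ndarray] = None,
    priors: Optional[np.ndarray] = None,
    fix_mu_B: bool = False,
    fix_mu_A: bool = False,
) -> MixtureWeights:
    """One EM sweep of the three-component Gaussian mixture on the target.

    E-step: Bayes posteriors per target pixel across isotropic Gaussians
    with per-pixel means {pred(x), μB, μA} and stds {σM, σB, σA} (product
    over channels for multi-channel targets). M-step: priors become the
    mean posteriors; μB and μA move to the posterior-weighted target means
    unless fixed by the user. If every component underflows at a pixel the
    posterior there is uniform.

    pred and target both have shape (c, *grid); returns the updated weights.
    """
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValueError("pred and target must share shape (c, *grid)")
    c = pred.shape[0]
    grid_shape = pred.shape[1:]
    npix = int(np.prod(grid_shape))
    P = pred.reshape(c, npix)
    T = target.reshape(c, npix)
    mu_B = np.zeros(c) if mu_B is None else np.broadcast_to(
        np.atleast_1d(np.asarray(mu_B, float)), (c,)
    ).copy()
    mu_A = np.ones(c) if mu_A is None else np.broadcast_to(
        np.atleast_1d(np.asarray(mu_A, float)), (c,)
    ).copy()
    priors = np.full(3, 1.0 / 3.0) if priors is None else np.asarray(priors, float)

    means = [P, mu_B[:, None], mu_A[:, None]]
    sigmas = [ew.sigma_M, ew.sigma_B, ew.sigma_A]
    loglik = np.empty((3, npix))
    for k in range(3):
        sq = ((T - means[k]) ** 2).sum(axis=0)
        loglik[k] = (
            -0.5 * sq / sigmas[k] ** 2
            - c * np.log(sigmas[k])
            + np.log(max(priors[k], 1e-300))
        )
    m = loglik.max(axis=0)
    dens = np.exp(loglik - m)
    tot = dens.sum(axis=0)
    # all-underflow guard: exp(0) = 1 at the max, so tot >= 1 unless nan
    bad = ~np.isfinite(tot) | (tot <= 0)
    post = np.where(bad, 1.0 / 3.0, dens / np.where(bad, 1.0, tot))

    new_priors = post.mean(axis=1)
    new_mu_B, new_mu_A = mu_B, mu_A
    if not fix_mu_B and post[1].sum() > 0:
        new_mu_B = (T * post[1]).sum(axis=1) / post[1].sum()
    if not fix_mu_A and post[2].sum() > 0:
        new_mu_A = (T * post[2]).sum(axis=1) / post[2].sum()
    return MixtureWeights(
        post.reshape((3,) + grid_shape), new_mu_B, new_mu_A, new_priors
    )


def matching_energy(
    pred: np.ndarray,
    target: np.ndarray,
    W_match: np.ndarray,
    sigma_M: float,
    cell_volume: float = 1.0,
) -> float:
    """M = (1/(2σM²)) Σ_x W_match(x)·‖pred(x) − target(x)‖² dx^d."""
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    sq = ((pred - target) ** 2).sum(axis=0)
    return float(np.sum(np.asarray(W_match) * sq) * cell_volume / (2.0 * sigma_M**2))


def landmark_energy(
    A: AffineTransform,
    v: Optional[VelocityField],
    lm: LandmarkSet,
    sigma_P: float,
) -> float:
    """P = (1/(2σP²)) Σᵢ ‖A·φ₁(sᵢ) − tᵢ‖² for the current map."""
    src = lm.source_pts
    if v is not None:
        src = flow_points(v, src, direction="forward")
    mapped = A.apply(src)
    return float(np.sum((mapped - lm.target_pts) ** 2) / (2.0 * sigma_P**2))
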