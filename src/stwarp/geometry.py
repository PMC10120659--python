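"""Affine maps, velocity-field flows, and their application to points and images.

The alignment map is the composition x ↦ A·φ₁(x) of a diffeomorphism φ₁ —
obtained by integrating a time-varying velocity field v_t from t = 0 to 1 —
with an affine transform A in homogeneous coordinates. Points are pushed
through the forward flow; images are resampled through the backward flow
(integration of −v in reversed time), so an inverse of a sampled map is
never computed numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from ._interp import interp
from .raster import PointSet, RasterImage

__all__ = [
    "AffineTransform",
    "VelocityField",
    "DiffeoMap",
    "LandmarkSet",
    "fit_affine_landmarks",
    "integrate_velocity",
    "flow_points",
    "apply_map_to_points",
    "resample_image",
    "jacobian_determinant",
]


@dataclass
class AffineTransform:
    """Affine map in homogeneous coordinates; matrix is (d+1)×(d+1)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] not in (3, 4):
            raise ValueError("matrix must be 3x3 (2D) or 4x4 (3D)")
        if not np.allclose(m[-1], np.eye(m.shape[0])[-1]):
            raise ValueError("last row of an affine matrix must be [0...0, 1]")
        if abs(np.linalg.det(self.linear)) < 1e-300:
            raise ValueError("linear part is singular")

    @classmethod
    def identity(cls, d: int) -> "AffineTransform":
        return cls(np.eye(d + 1))

    @classmethod
    def from_linear_translation(cls, L, T) -> "AffineTransform":
        L = np.asarray(L, float)
        T = np.asarray(T, float)
        d = L.shape[0]
        m = np.eye(d + 1)
        m[:d, :d] = L
        m[:d, d] = T
        return cls(m)

    @property
    def d(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:-1, :-1]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:-1, -1]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to (n, d) coordinates."""
        coords = np.asarray(coords, float)
        return coords @ self.linear.T + self.translation


@dataclass
class VelocityField:
    """Time-sampled smooth vector field generating a diffeomorphism.

    samples has shape (nt, d, *grid) in μm per unit flow time, on the grid
    given by axis_coords. a (μm) and p parameterize the Sobolev metric
    (1 − a²Δ)^p under which the field is regularized.
    """

    samples: np.ndarray
    axis_coords: Sequence[np.ndarray]
    a: float = 500.0
    p: float = 2.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.axis_coords = [np.asarray(ax, float) for ax in self.axis_coords]
        d = len(self.axis_coords)
        if self.samples.ndim != d + 2 or self.samples.shape[1] != d:
            raise ValueError("samples must have shape (nt, d, *grid)")
        if self.samples.shape[0] < 1:
            raise ValueError("need nt >= 1")
        if self.a <= 0 or self.p < 1:
            raise ValueError("need a > 0 and p >= 1")
        if not np.isfinite(self.samples).all():
            raise ValueError("velocity samples must be finite")

    @property
    def nt(self) -> int:
        return self.samples.shape[0]

    @property
    def d(self) -> int:
        return self.samples.shape[1]

    @property
    def grid_shape(self):
        return self.samples.shape[2:]

    @property
    def dx(self) -> np.ndarray:
        return np.array(
            [a[1] - a[0] if len(a) > 1 else 1.0 for a in self.axis_coords]
        )

    @classmethod
    def zeros(cls, axis_coords, nt: int = 3, a: float = 500.0, p: float = 2.0):
        grid = tuple(len(ax) for ax in axis_coords)
        d = len(axis_coords)
        return cls(np.zeros((nt, d) + grid), axis_coords, a=a, p=p)


@dataclass
class DiffeoMap:
    """A flow map sampled on a grid: positions (d, *grid) in μm."""

    positions: np.ndarray
    axis_coords: Sequence[np.ndarray]
    direction: str = "forward"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.axis_coords = [np.asarray(a, float) for a in self.axis_coords]
        if self.positions.shape[0] != len(self.axis_coords):
            raise ValueError("positions must be (d, *grid)")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")

    @property
    def d(self) -> int:
        return self.positions.shape[0]

    def displacement(self) -> np.ndarray:
        grid = np.stack(np.meshgrid(*self.axis_coords, indexing="ij"))
        return self.positions - grid

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        """Evaluate the map at (n, d) physical coordinates.

        The displacement field is interpolated (nearest-edge extension
        outside the grid) and added to the query positions.
        """
        pts = np.asarray(coords, float).T
        disp = interp(self.axis_coords, self.displacement(), pts)
        return (pts + disp).T


@dataclass
class LandmarkSet:
    """Paired source/target landmark coordinates (m, d), matched by row."""

    source_pts: np.ndarray
    target_pts: np.ndarray

    def __post_init__(self):
        self.source_pts = np.atleast_2d(np.asarray(self.source_pts, float))
        self.target_pts = np.atleast_2d(np.asarray(self.target_pts, float))
        if self.source_pts.shape != self.target_pts.shape:
            raise ValueError("source and target landmarks must pair up")
        if self.source_pts.shape[0] < 1:
            raise ValueError("need at least one landmark pair")
        if not (np.isfinite(self.source_pts).all() and np.isfinite(self.target_pts).all()):
            raise ValueError("landmarks must be finite")

    @property
    def m(self) -> int:
        return self.source_pts.shape[0]

    @property
    def d(self) -> int:
        return self.source_pts.shape[1]


def fit_affine_landmarks(lm: LandmarkSet) -> Tuple[AffineTransform, float]:
    """Least-squares affine from paired landmarks.

    Minimizes Σᵢ ‖A·sᵢ − tᵢ‖² over affine A; returns (A, residual) where
    residual is the summed squared error of the fit. Requires at least
    d + 1 non-degenerate (non-collinear / non-coplanar) source points.
    """
    d = lm.d
    if lm.m < d + 1:
        raise ValueError(f"need at least {d + 1} landmark pairs in {d}D")
    design = np.hstack([lm.source_pts, np.ones((lm.m, 1))])
    if np.linalg.matrix_rank(design) < d + 1:
        raise ValueError(
            "degenerate landmark configuration (collinear/coplanar); "
            "add more spread-out landmarks"
        )
    coef, _, _, _ = np.linalg.lstsq(design, lm.target_pts, rcond=None)
    m = np.eye(d + 1)
    m[:d, :d] = coef[:d].T
    m[:d, d] = coef[d]
    A = AffineTransform(m)
    residual = float(np.sum((A.apply(lm.source_pts) - lm.target_pts) ** 2))
    return A, residual


def flow_points(
    v: VelocityField, coords: np.ndarray, direction: str = "forward"
) -> np.ndarray:
    """Integrate points along the velocity field with nt Euler steps.

    forward: dx/dt = v_t(x), t = 0 → 1. backward: integrates −v with the
    time samples in reversed order, approximating the inverse flow.
    """
    pts = np.asarray(coords, float).T.copy()  # (d, n)
    dt = 1.0 / v.nt
    steps = range(v.nt) if direction == "forward" else range(v.nt - 1, -1, -1)
    sign = 1.0 if direction == "forward" else -1.0
    for t in steps:
        vel = interp(v.axis_coords, v.samples[t], pts)
        pts = pts + sign * dt * vel
    return pts.T


def integrate_velocity(
    v: VelocityField, direction: str = "forward", axis_coords=None
) -> DiffeoMap:
    """Integrate the velocity field into a flow map sampled on a grid.

    The map is evaluated at the pixel centers of ``axis_coords`` (default:
    the velocity field's own grid). A zero field yields the identity map
    exactly; a constant field a pure translation.
    """
    if axis_coords is None:
        axis_coords = v.axis_coords
    grid = np.stack(np.meshgrid(*axis_coords, indexing="ij"))
    flat = grid.reshape(v.d, -1).T
    mapped = flow_points(v, flat, direction=direction)
    return DiffeoMap(mapped.T.reshape(grid.shape), axis_coords, direction=direction)


def apply_map_to_points(
    A: Optional[AffineTransform],
    phi: Optional[DiffeoMap],
    pts: PointSet,
    return_flags: bool = False,
):
    """Apply the composed map x ↦ A·φ(x) to a point set.

    The diffeomorphism acts first, the affine second (homogeneous matrix
    multiplication), matching how the alignment map is composed. Features
    and labels are carried through unchanged. Points outside φ's grid use
    nearest-edge displacement extension; with ``return_flags=True`` a
    boolean in-grid flag per point is also returned.
    """
    coords = pts.coords
    d = coords.shape[1]
    if phi is not None:
        if phi.d != d:
            raise ValueError("map dimension does not match points")
        coords = phi(coords)
        lo = np.array([ax[0] for ax in phi.axis_coords])
        hi = np.array([ax[-1] for ax in phi.axis_coords])
        inside = np.all((pts.coords >= lo) & (pts.coords <= hi), axis=1)
    else:
        inside = np.ones(pts.n, dtype=bool)
    if A is not None:
        if A.d != d:
            raise ValueError("affine dimension does not match points")
        coords = A.apply(coords)
    out = pts.with_coords(coords)
    if return_flags:
        return out, inside
    return out


def resample_image(
    source: RasterImage,
    A: Optional[AffineTransform],
    phi_back: Optional[DiffeoMap],
    target_axis_coords,
    fill: Optional[float] = None,
) -> RasterImage:
    """Pull the source image onto a target grid through the group action.

    For each target pixel x the value is the source interpolated at
    φ_back(A⁻¹x) — the standard action of the map A∘φ on images. Pixels
    that land outside the source support take ``fill`` (default: the
    per-channel mean of the source's border pixels, a background estimate).
    """
    target_axis_coords = [np.asarray(a, float) for a in target_axis_coords]
    grid = np.stack(np.meshgrid(*target_axis_coords, indexing="ij"))
    d = grid.shape[0]
    pts = grid.reshape(d, -1).T
    if A is not None:
        pts = A.inverse().apply(pts)
    if phi_back is not None:
        pts = phi_back(pts)
    vals = interp(source.axis_coords, source.values, pts.T)
    lo = np.array([ax[0] for ax in source.axis_coords])
    hi = np.array([ax[-1] for ax in source.axis_coords])
    outside = np.any((pts < lo) | (pts > hi), axis=1)
    if outside.any():
        for c in range(vals.shape[0]):
            fv = fill
            if fv is None:
                edge = _edge_values(source.values[c])
                fv = float(edge.mean())
            vals[c, outside] = fv
    shape = (source.values.shape[0],) + tuple(len(a) for a in target_axis_coords)
    return RasterImage(vals.reshape(shape), target_axis_coords, source.channel_names)


def _edge_values(arr: np.ndarray) -> np.ndarray:
    vals = []
    for k in range(arr.ndim):
        vals.append(np.take(arr, 0, axis=k).ravel())
        vals.append(np.take(arr, -1, axis=k).ravel())
    return np.concatenate(vals)


def jacobian_determinant(phi: DiffeoMap) -> np.ndarray:
    """Central-difference Jacobian determinant of a sampled map, per node.

    A value of 1 everywhere for the identity, s^d for a uniform scale s;
    strictly positive everywhere for a true diffeomorphism.
    """
    d = phi.d
    if any(s < 3 for s in phi.positions.shape[1:]):
        raise ValueError("need at least 3 nodes per axis")
    spacing = [float(a[1] - a[0]) for a in phi.axis_coords]
    J = np.empty(phi.positions.shape[1:] + (d, d))
    for i in range(d):
        grads = np.gradient(phi.positions[i], *spacing)
        if d == 1:
            grads = [grads]
        for j in range(d):
            J[..., i, j] = grads[j]
    return np.linalg.det(J)
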