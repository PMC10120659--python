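"""Multilinear grid interpolation with reverse-mode adjoints.

All registration machinery reduces to three primitives on a uniform grid:

* ``interp`` — sample a (c, *grid) field at scattered physical points
  (bi/trilinear, nearest-edge extension outside the grid);
* ``interp_vjp_values`` — adjoint with respect to the field values
  (scatter/"splat" of a cotangent back onto the grid nodes);
* ``interp_point_jacobian`` — derivative of the sampled values with
  respect to the point coordinates.

Keeping these exact adjoint pairs in one place lets the solver assemble
the gradient of the full objective by hand, matching what reverse-mode
autodiff would produce for the identical discretization.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["interp", "interp_vjp_values", "interp_point_jacobian"]


def _fractional_index(axis_coords, points):
    """Convert physical coordinates to clamped fractional grid indices.

    Returns (i0, frac, unclamped_mask) where i0 is the lower corner index
    (clamped to [0, n-2]), frac in [0, 1] the offset within the cell, and
    unclamped_mask marks coordinates strictly inside the grid (where the
    derivative w.r.t. the point coordinate is nonzero).
    """
    d = len(axis_coords)
    i0 = np.empty((d, points.shape[1]), dtype=np.intp)
    frac = np.empty((d, points.shape[1]))
    inside = np.empty((d, points.shape[1]), dtype=bool)
    for k, ax in enumerate(axis_coords):
        n = len(ax)
        dx = ax[1] - ax[0] if n > 1 else 1.0
        f = (points[k] - ax[0]) / dx
        inside[k] = (f > 0.0) & (f < n - 1)
        f = np.clip(f, 0.0, n - 1)
        lo = np.clip(np.floor(f).astype(np.intp), 0, max(n - 2, 0))
        i0[k] = lo
        frac[k] = f - lo
    return i0, frac, inside


def interp(axis_coords, values, points):
    """Multilinear interpolation of ``values`` (c, *grid) at ``points`` (d, n).

    Coordinates are physical; ``axis_coords`` are the uniformly spaced
    pixel-center positions per axis. Points outside the grid are clamped
    to the edge (nearest-edge extension).
    """
    values = np.asarray(values)
    d = len(axis_coords)
    i0, frac, _ = _fractional_index(axis_coords, points)
    out = np.zeros((values.shape[0], points.shape[1]))
    for corner in itertools.product((0, 1), repeat=d):
        w = np.ones(points.shape[1])
        idx = []
        for k, c in enumerate(corner):
            w = w * (frac[k] if c else 1.0 - frac[k])
            idx.append(np.minimum(i0[k] + c, len(axis_coords[k]) - 1))
        out += values[(slice(None), *idx)] * w
    return out


def interp_vjp_values(axis_coords, points, cotangent, grid_shape):
    """Adjoint of ``interp`` w.r.t. the field values: splat ``cotangent``.

    cotangent has shape (c, n); returns an array of shape (c, *grid_shape).
    """
    cotangent = np.asarray(cotangent)
    d = len(axis_coords)
    i0, frac, _ = _fractional_index(axis_coords, points)
    out = np.zeros((cotangent.shape[0],) + tuple(grid_shape))
    flat = out.reshape(cotangent.shape[0], -1)
    strides = np.array([int(np.prod(grid_shape[k + 1:])) for k in range(d)], dtype=np.intp)
    for corner in itertools.product((0, 1), repeat=d):
        w = np.ones(points.shape[1])
        lin = np.zeros(points.shape[1], dtype=np.intp)
        for k, c in enumerate(corner):
            w = w * (frac[k] if c else 1.0 - frac[k])
            lin += np.minimum(i0[k] + c, len(axis_coords[k]) - 1) * strides[k]
        for ch in range(cotangent.shape[0]):
            np.add.at(flat[ch], lin, cotangent[ch] * w)
    return out


def interp_point_jacobian(axis_coords, values, points):
    """Derivative of interpolated values w.r.t. the point coordinates.

    Returns an array of shape (c, d, n): d(interp)_c / d(points)_k.
    Zero where a coordinate is clamped at the grid edge.
    """
    values = np.asarray(values)
    d = len(axis_coords)
    i0, frac, inside = _fractional_index(axis_coords, points)
    dxs = [ax[1] - ax[0] if len(ax) > 1 else 1.0 for ax in axis_coords]
    out = np.zeros((values.shape[0], d, points.shape[1]))
    for corner in itertools.product((0, 1), repeat=d):
        idx = [np.minimum(i0[k] + c, len(axis_coords[k]) - 1)
               for k, c in enumerate(corner)]
        vals = values[(slice(None), *idx)]  # (c, n)
        for kd in range(d):
            w = np.ones(points.shape[1])
            for k, c in enumerate(corner):
                if k == kd:
                    w = w * ((1.0 if c else -1.0) / dxs[k])
                else:
                    w = w * (frac[k] if c else 1.0 - frac[k])
            out[:, kd, :] += vals * w * inside[kd]
    return out
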