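"""Point clouds and their rasterization into smooth density images.

Single-cell spatial transcriptomics datasets are delivered as tables of
cell centroids in physical micrometers. Solving an alignment directly on
the cells is quadratic in their number, so the cloud is first modelled as
a sum of point masses (a space measure) and convolved with an isotropic
Gaussian kernel to obtain a smooth intensity function, which is then
sampled on a uniform pixel grid. All downstream registration operates on
these raster images; the solved map is applied back to the original
coordinates afterwards.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

#: Default raster resolution in micrometers.
DEFAULT_DX = 30.0


@dataclass
class PointSet:
    """Cell centroids in physical μm with optional per-cell features.

    Parameters
    ----------
    coords
        (n, d) array of positions in μm, d in {2, 3}. Axis order is
        (y, x) in 2D and (z, y, x) in 3D, matching image axis order.
    features
        Optional (n, g) non-negative matrix, e.g. gene counts.
    labels
        Optional length-n categorical labels (cell types, regions).
    feature_names
        Optional names for the g feature columns.
    """

    coords: np.ndarray
    features: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    feature_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be (n, d) with d in {2, 3}")
        bad = ~np.isfinite(self.coords).all(axis=1)
        if bad.any():
            raise ValueError(
                f"non-finite coordinate at row {int(np.flatnonzero(bad)[0])}"
            )
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape[0] != self.n:
                raise ValueError("features row count must match coords")
            if (self.features < 0).any():
                raise ValueError("features must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n:
                raise ValueError("labels length must match coords")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray) -> "PointSet":
        """Copy of this set with new coordinates; features/labels carried."""
        return PointSet(coords, self.features, self.labels, self.feature_names)


@dataclass
class RasterImage:
    """Channels-first image with explicit physical pixel-center coordinates.

    values has shape (c, *grid); axis_coords holds one strictly increasing,
    uniformly spaced array of pixel-center positions (μm) per grid axis.
    """

    values: np.ndarray
    axis_coords: Sequence[np.ndarray]
    channel_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.axis_coords = [np.asarray(a, dtype=float) for a in self.axis_coords]
        if self.values.ndim != len(self.axis_coords) + 1:
            raise ValueError("values must be (c, *grid) matching axis_coords")
        for k, ax in enumerate(self.axis_coords):
            if len(ax) != self.values.shape[k + 1]:
                raise ValueError(f"axis_coords[{k}] length mismatch with grid")
            if len(ax) > 1:
                steps = np.diff(ax)
                if not np.all(steps > 0) or not np.allclose(steps, steps[0]):
                    raise ValueError("axis_coords must be uniform and increasing")
        if not np.isfinite(self.values).all():
            raise ValueError("image values must be finite")

    @property
    def d(self) -> int:
        return len(self.axis_coords)

    @property
    def dx(self) -> np.ndarray:
        """Pixel width per axis (μm)."""
        return np.array(
            [a[1] - a[0] if len(a) > 1 else 1.0 for a in self.axis_coords]
        )

    @property
    def grid_shape(self):
        return self.values.shape[1:]

    def meshgrid(self) -> np.ndarray:
        """(d, *grid) array of pixel-center positions."""
        return np.stack(np.meshgrid(*self.axis_coords, indexing="ij"))


def rasterize(
    points: PointSet,
    dx: float = DEFAULT_DX,
    blur_std: float = 1.0,
    channel: str = "density",
) -> RasterImage:
    """Bin points into pixels and blur with an isotropic Gaussian.

    The cloud is treated as a sum of unit point masses (``channel="density"``)
    or of the per-cell feature vectors (``channel="features"``). The grid
    spans the point bounding box padded by ceil(4·blur_std) pixels, and the
    result is normalized as a density: sum(values)·dx^d equals the total
    mass up to boundary truncation of the kernel.

    Parameters
    ----------
    points : PointSet
    dx : float
        Pixel resolution in μm (default 30).
    blur_std : float
        Gaussian kernel standard deviation in *pixels* (physical bandwidth
        blur_std·dx).
    channel : {"density", "features"}
    """
    if points.n == 0:
        raise ValueError("cannot rasterize an empty point set")
    if dx <= 0:
        raise ValueError("dx must be positive")
    if blur_std < 0:
        raise ValueError("blur_std must be non-negative")
    d = points.d
    pad = int(np.ceil(4 * blur_std))
    lo = points.coords.min(axis=0) - pad * dx
    hi = points.coords.max(axis=0)
    nbins = np.ceil((hi - lo) / dx).astype(int) + pad + 1
    axis_coords = [lo[k] + dx * (np.arange(nbins[k]) + 0.5) for k in range(d)]

    idx = np.floor((points.coords - lo) / dx).astype(np.intp)
    for k in range(d):
        idx[:, k] = np.clip(idx[:, k], 0, nbins[k] - 1)
    lin = np.ravel_multi_index(tuple(idx.T), tuple(nbins))

    if channel == "density":
        weights = np.ones((points.n, 1))
        names = ["density"]
    elif channel == "features":
        if points.features is None:
            raise ValueError("point set has no features to rasterize")
        weights = points.features
        names = list(points.feature_names) if points.feature_names else None
    else:
        raise ValueError("channel must be 'density' or 'features'")

    nchan = weights.shape[1]
    vals = np.zeros((nchan, int(np.prod(nbins))))
    for c in range(nchan):
        vals[c] = np.bincount(lin, weights=weights[:, c], minlength=vals.shape[1])
    vals = vals.reshape((nchan,) + tuple(nbins)) / dx**d
    if blur_std > 0:
        for c in range(nchan):
            vals[c] = gaussian_filter(vals[c], sigma=blur_std, mode="constant")
    return RasterImage(vals, axis_coords, channel_names=names)


def normalize_image(
    img: RasterImage, lo_pct: float = 0.0, hi_pct: float = 100.0
) -> RasterImage:
    """Affinely rescale each channel so [lo_pct, hi_pct] percentiles → [0, 1].

    Values are clipped to [0, 1]; a constant channel becomes zeros (with a
    warning). Scale-invariant: c·image normalizes identically to image.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    out = np.empty_like(img.values)
    for c in range(img.values.shape[0]):
        lo, hi = np.percentile(img.values[c], [lo_pct, hi_pct])
        if hi <= lo:
            warnings.warn(f"channel {c} is constant; normalized to zeros")
            out[c] = 0.0
        else:
            out[c] = np.clip((img.values[c] - lo) / (hi - lo), 0.0, 1.0)
    return RasterImage(out, [a.copy() for a in img.axis_coords], img.channel_names)
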