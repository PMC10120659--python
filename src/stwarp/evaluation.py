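"""Alignment-quality statistics.

After aligning, correspondence is quantified on aggregated expression:
cells are pooled into 200 μm grid pixels (or into pseudospots matching a
capture array's spot centers and radius), counts are CPM-normalized and
log10(x+1)-transformed, and per-gene cosine similarity is computed across
matched units. Region-level agreement uses cell-type composition vectors
(Euclidean distance), size-matched random regions, k-NN region expansion
and Shannon entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import entr
from sklearn.neighbors import NearestNeighbors

from .raster import PointSet

__all__ = [
    "AggregatedMatrix",
    "CompositionVector",
    "grid_aggregate",
    "pseudospot_aggregate",
    "cpm_log_normalize",
    "cosine_similarity_per_feature",
    "landmark_rmse",
    "composition",
    "composition_distance",
    "random_region",
    "expand_region_knn",
    "shannon_entropy",
]

#: Default aggregation grid size in μm.
DEFAULT_GRID_SIZE = 200.0


@dataclass
class AggregatedMatrix:
    """Per-unit (grid pixel or spot) feature sums.

    unit_ids identify the units; unit_positions are their centers (μm);
    features is the units×g non-negative sum matrix. cell_unit maps each
    input cell to its unit index (−1 for unassigned cells).
    """

    unit_ids: np.ndarray
    unit_positions: np.ndarray
    features: np.ndarray
    cell_unit: np.ndarray

    def __post_init__(self):
        if (np.asarray(self.features) < 0).any():
            raise ValueError("aggregated features must be non-negative")


class CompositionVector(np.ndarray):
    """Proportions over K cell types: non-negative, sums to 1 (or all-zero)."""

    def __new__(cls, data):
        arr = np.asarray(data, float).view(cls)
        if (arr < -1e-12).any():
            raise ValueError("composition entries must be non-negative")
        s = float(arr.sum())
        if s > 0 and not np.isclose(s, 1.0):
            raise ValueError("composition must sum to 1 (or be all zero)")
        return arr


def grid_aggregate(points: PointSet, grid_size: float = DEFAULT_GRID_SIZE) -> AggregatedMatrix:
    """Sum per-cell features within square (or cubic) grid pixels.

    Pixel index per axis is floor((coord − min)/grid_size); only occupied
    pixels are returned. Total assigned counts are conserved exactly.
    """
    if points.features is None:
        raise ValueError("point set has no features to aggregate")
    lo = points.coords.min(axis=0)
    idx = np.floor((points.coords - lo) / grid_size).astype(np.intp)
    ids, inverse = np.unique(idx, axis=0, return_inverse=True)
    feats = np.zeros((ids.shape[0], points.features.shape[1]))
    np.add.at(feats, inverse, points.features)
    centers = lo + (ids + 0.5) * grid_size
    return AggregatedMatrix(ids, centers, feats, inverse)


def pseudospot_aggregate(
    points: PointSet, centers: np.ndarray, radius: float
) -> AggregatedMatrix:
    """Sum features of the cells within ``radius`` of each spot center.

    Mirrors aggregation of single cells into capture-array pseudospots: a
    cell belongs to a spot when its distance to the spot centroid is less
    than the spot radius. Should spots overlap, the cell is assigned only
    to the nearest qualifying center; cells within no spot are dropped.
    """
    if points.features is None:
        raise ValueError("point set has no features to aggregate")
    if radius <= 0:
        raise ValueError("radius must be positive")
    centers = np.atleast_2d(np.asarray(centers, float))
    tree = cKDTree(centers)
    dist, nearest = tree.query(points.coords)
    assigned = np.where(dist < radius, nearest, -1)
    feats = np.zeros((centers.shape[0], points.features.shape[1]))
    ok = assigned >= 0
    np.add.at(feats, assigned[ok], points.features[ok])
    return AggregatedMatrix(
        np.arange(centers.shape[0]), centers, feats, assigned
    )


def cpm_log_normalize(mat: np.ndarray) -> np.ndarray:
    """Counts-per-million then log10 with a pseudocount of 1, per unit row.

    Rows with zero total stay zero (with a warning).
    """
    mat = np.asarray(mat, float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    totals = mat.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} unit(s) with zero total counts")
    cpm = np.divide(mat * 1e6, totals, out=np.zeros_like(mat), where=totals > 0)
    return np.log10(cpm + 1.0)


def cosine_similarity_per_feature(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cosine similarity per feature column across matched units.

    A and B are units×g with identical unit indexing. Columns that are
    zero in both matrices are undefined and reported as NaN.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("matrices must share shape (units x features)")
    num = (A * B).sum(axis=0)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    denom = na * nb
    out = np.full(A.shape[1], np.nan)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def landmark_rmse(source_pts: np.ndarray, target_pts: np.ndarray) -> float:
    """Root-mean-square distance (μm) between paired landmark positions."""
    source_pts = np.atleast_2d(np.asarray(source_pts, float))
    target_pts = np.atleast_2d(np.asarray(target_pts, float))
    if source_pts.shape != target_pts.shape:
        raise ValueError("landmark sets must pair up")
    d2 = ((source_pts - target_pts) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def composition(labels: np.ndarray, categories: Optional[Sequence] = None) -> CompositionVector:
    """Cell-type composition vector of a region's labels over K categories."""
    labels = np.asarray(labels)
    if categories is None:
        categories = np.unique(labels)
    counts = np.array([(labels == c).sum() for c in categories], float)
    total = counts.sum()
    return CompositionVector(counts / total if total > 0 else counts)


def composition_distance(r1, r2) -> float:
    """Euclidean distance between two cell-type composition vectors."""
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    if r1.shape != r2.shape:
        raise ValueError("composition vectors must have the same length")
    return float(np.linalg.norm(r1 - r2))


def random_region(points: PointSet, n_cells: int, seed: int) -> np.ndarray:
    """Indices of a size-matched random region: the n_cells nearest cells
    to a uniformly drawn integer (μm) center within the bounding box."""
    if n_cells > points.n:
        raise ValueError("n_cells exceeds the number of cells")
    rng = np.random.default_rng(seed)
    lo = np.floor(points.coords.min(axis=0)).astype(int)
    hi = np.floor(points.coords.max(axis=0)).astype(int)
    center = np.array([rng.integers(lo[k], hi[k] + 1) for k in range(points.d)])
    dist = np.linalg.norm(points.coords - center, axis=1)
    return np.argsort(dist, kind="stable")[:n_cells]


def expand_region_knn(points: PointSet, region: np.ndarray, k: int = 100) -> np.ndarray:
    """Expand a region by the union of its members' k nearest neighbors.

    Neighbors are found among all cells; the result always contains the
    input region. k = 0 returns the region unchanged; k ≥ n returns all
    cells.
    """
    region = np.asarray(region, dtype=np.intp)
    if k <= 0:
        return np.unique(region)
    if k >= points.n:
        return np.arange(points.n)
    # k+1 neighbors per member: the member itself (distance 0) plus k others
    nn = NearestNeighbors(n_neighbors=min(k + 1, points.n), algorithm="ball_tree")
    nn.fit(points.coords)
    _, neigh = nn.kneighbors(points.coords[region])
    return np.union1d(region, neigh.ravel())


def shannon_entropy(comp) -> float:
    """Shannon entropy H = −Σ p ln p (nats) of a composition vector.

    Zero for a one-hot composition; ln K for uniform over K types.
    """
    p = np.asarray(comp, float)
    return float(entr(p).sum())
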