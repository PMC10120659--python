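"""End-to-end workflows tying the modules into runnable pipelines.

Each function is a thin, file-to-file wrapper over the library: read the
inputs, run one capability, write the outputs. They are the scripting
surface of the package (see examples/ for narrative usage); all
randomness is seeded through the config or an explicit seed argument.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as stio
from .evaluation import (
    cosine_similarity_per_feature,
    cpm_log_normalize,
    grid_aggregate,
)
from .raster import PointSet, normalize_image, rasterize
from .solver import (
    AlignmentResult,
    SolverConfig,
    lift_over_labels,
    matching_mask,
    run_lddmm,
    run_lddmm_3d_to_2d,
)
from .synthetic import DeformationSpec, SyntheticSpec, deform, generate_tissue

__all__ = [
    "rasterize_csv",
    "align",
    "align3d",
    "transform_points",
    "liftover",
    "evaluate",
    "simulate",
]


def rasterize_csv(cells_csv, out_tiff, dx: float = 30.0, blur_std: float = 1.0,
                  schema=None, normalize: bool = True):
    """CSV of cell positions → density raster TIFF (+ grid side-car)."""
    pts = stio.read_points_csv(cells_csv, schema)
    img = rasterize(pts, dx=dx, blur_std=blur_std)
    if normalize:
        img = normalize_image(img)
    stio.write_image(img, out_tiff)
    return img


def align(source_csv, target_csv, out_npz, config: Optional[dict] = None,
          schema=None, landmarks=None) -> AlignmentResult:
    """Align two cell tables (2D↔2D) and save the solved transform."""
    cfg = SolverConfig.from_dict(config or {})
    src = normalize_image(rasterize(stio.read_points_csv(source_csv, schema), dx=cfg.dx))
    tgt = normalize_image(rasterize(stio.read_points_csv(target_csv, schema), dx=cfg.dx))
    result = run_lddmm(src, tgt, cfg, landmarks)
    stio.save_alignment(result, out_npz)
    return result


def align3d(volume_nrrd_or_image, target_csv, out_npz,
            config: Optional[dict] = None, schema=None) -> AlignmentResult:
    """Align a 3D intensity volume to a 2D section and save the transform."""
    cfg = SolverConfig.from_dict(config or {})
    vol = volume_nrrd_or_image  # a RasterImage; callers load NRRD via stwarp.io
    tgt = normalize_image(rasterize(stio.read_points_csv(target_csv, schema), dx=cfg.dx))
    result = run_lddmm_3d_to_2d(vol, tgt, cfg)
    stio.save_alignment(result, out_npz)
    return result


def transform_points(alignment_npz, cells_csv, out_csv, schema=None) -> PointSet:
    """Apply a saved alignment to a cell table; writes original + aligned."""
    result = stio.load_alignment(alignment_npz)
    pts = stio.read_points_csv(cells_csv, schema)
    moved = result.transform_points(pts)
    _, flags = matching_mask(result, pts)
    stio.write_aligned_points(pts, moved, out_csv, flags=flags)
    return moved


def liftover(alignment_npz, labels_nrrd, cells_csv, out_csv, schema=None):
    """Lift atlas annotations over a saved 3D→2D alignment onto cells."""
    result = stio.load_alignment(alignment_npz)
    labels = stio.read_nrrd_labels(labels_nrrd)
    pts = stio.read_points_csv(cells_csv, schema)
    ids = lift_over_labels(result, labels, pts)
    stio.write_aligned_points(pts, pts, out_csv, labels=ids)
    return ids


def evaluate(aligned_csv, target_csv, out_csv, schema=None,
             grid_size: float = 200.0) -> pd.DataFrame:
    """Per-gene cosine similarity report on grid-aggregated expression.

    Cells from both tables are pooled into a shared grid of
    ``grid_size``-μm pixels; counts are summed per pixel, CPM + log10(+1)
    normalized, and compared per gene across pixels occupied in both.
    """
    a = stio.read_points_csv(aligned_csv, schema)
    b = stio.read_points_csv(target_csv, schema)
    lo = np.minimum(a.coords.min(axis=0), b.coords.min(axis=0))
    shift_a = a.with_coords(a.coords - lo)
    shift_b = b.with_coords(b.coords - lo)
    agg_a = grid_aggregate(shift_a, grid_size)
    agg_b = grid_aggregate(shift_b, grid_size)
    ids_a = {tuple(i): k for k, i in enumerate(agg_a.unit_ids)}
    ids_b = {tuple(i): k for k, i in enumerate(agg_b.unit_ids)}
    shared = sorted(set(ids_a) & set(ids_b))
    A = cpm_log_normalize(agg_a.features[[ids_a[s] for s in shared]])
    B = cpm_log_normalize(agg_b.features[[ids_b[s] for s in shared]])
    cos = cosine_similarity_per_feature(A, B)
    names = a.feature_names or [f"gene{i}" for i in range(len(cos))]
    df = pd.DataFrame({"gene": names, "cosine_similarity": cos})
    df.to_csv(out_csv, index=False)
    return df


def simulate(out_dir, seed: int = 0, spec: Optional[SyntheticSpec] = None,
             deformation: Optional[DeformationSpec] = None):
    """Generate a source/target synthetic tissue pair as CSV fixtures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or SyntheticSpec(seed=seed)
    deformation = deformation or DeformationSpec(
        rotation_deg=10.0, scale=1.02, translation=(200.0, -150.0)
    )
    pts, truth = generate_tissue(spec)
    moved, _ = deform(pts, deformation)
    stio.write_points_csv(pts, out / "source_cells.csv")
    stio.write_points_csv(moved, out / "target_cells.csv")
    np.savetxt(out / "region_labels.csv", truth["region"], fmt="%d")
    return pts, moved, truth
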