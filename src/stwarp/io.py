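"""Readers and writers for the formats the aligner touches.

Cells and landmarks travel as plain CSV, images as PNG/TIFF with a JSON
side-car carrying the physical grid, atlas annotation volumes as NRRD,
and solved alignments as a single ``.npz`` container. Coordinates are
physical μm end-to-end; an image's pixel size must be declared (argument
or side-car), never guessed from the file alone.

NRRD reading/writing is a deliberately small implementation covering the
detached-header-free, raw/gzip-encoded files the atlas distributions use
(no pynrrd in the target environment).
"""

from __future__ import annotations

import gzip
import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .geometry import AffineTransform, LandmarkSet, VelocityField
from .raster import PointSet, RasterImage
from .solver import AlignmentResult, LabelVolume, SolverConfig

__all__ = [
    "CellTableSchema",
    "read_points_csv",
    "write_points_csv",
    "read_landmarks_csv",
    "read_image",
    "write_image",
    "read_nrrd_labels",
    "write_nrrd_labels",
    "write_aligned_points",
    "save_alignment",
    "load_alignment",
]


@dataclass
class CellTableSchema:
    """Column mapping for a per-cell table; coordinates are in μm.

    Note the PointSet axis order is (y, x) / (z, y, x), while tables
    conventionally store x and y columns; the reader reorders.
    """

    x_col: str = "x"
    y_col: str = "y"
    z_col: Optional[str] = None
    count_cols: Optional[Sequence[str]] = None
    label_col: Optional[str] = None
    delimiter: str = ","


def read_points_csv(path, schema: Optional[CellTableSchema] = None) -> PointSet:
    """Read a cell-position table into a PointSet.

    Count columns become the feature matrix; a label column becomes the
    categorical labels. Missing columns and unparseable coordinate rows
    raise with the offending name or line.
    """
    schema = schema or CellTableSchema()
    df = pd.read_csv(path, delimiter=schema.delimiter)
    cols = [schema.y_col, schema.x_col]
    if schema.z_col is not None:
        cols = [schema.z_col] + cols
    needed = list(cols) + list(schema.count_cols or [])
    if schema.label_col:
        needed.append(schema.label_col)
    for c in needed:
        if c not in df.columns:
            raise ValueError(f"missing column {c!r} in {path}")
    coords = df[cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(coords).all(axis=1))
    if bad.size:
        raise ValueError(
            f"unparseable coordinate at line {int(bad[0]) + 2} of {path}"
        )
    features = None
    names = None
    if schema.count_cols:
        names = list(schema.count_cols)
        features = df[names].to_numpy(float)
    labels = df[schema.label_col].to_numpy() if schema.label_col else None
    return PointSet(coords, features, labels, names)


def write_points_csv(points: PointSet, path, schema: Optional[CellTableSchema] = None):
    """Inverse of :func:`read_points_csv` at full float precision."""
    schema = schema or CellTableSchema(
        z_col="z" if points.d == 3 else None,
        count_cols=points.feature_names,
        label_col="label" if points.labels is not None else None,
    )
    cols = {}
    axes = ([schema.z_col] if points.d == 3 else []) + [schema.y_col, schema.x_col]
    for k, name in enumerate(axes):
        cols[name] = points.coords[:, k]
    if points.features is not None:
        names = points.feature_names or [
            f"count{i}" for i in range(points.features.shape[1])
        ]
        for i, name in enumerate(names):
            cols[name] = points.features[:, i]
    if points.labels is not None:
        cols[schema.label_col or "label"] = points.labels
    pd.DataFrame(cols).to_csv(path, index=False, sep=schema.delimiter)


def read_landmarks_csv(source_path, target_path) -> LandmarkSet:
    """Read paired landmark CSVs (columns x, y[, z]), matched by row order."""
    def one(path):
        df = pd.read_csv(path)
        if "z" in df.columns:
            return df[["z", "y", "x"]].to_numpy(float)
        return df[["y", "x"]].to_numpy(float)

    return LandmarkSet(one(source_path), one(target_path))


def read_image(path, pixel_size: Optional[float] = None, origin=None) -> RasterImage:
    """Read a PNG/TIFF into a channels-first float image scaled to [0, 1].

    The physical pixel size (μm) comes from a ``<path>.json`` side-car
    (keys ``pixel_size``, optional ``origin``) or the ``pixel_size``
    argument; one of the two is required.
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    else:
        raise ValueError(f"unsupported image shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.bits > 16:
            raise ValueError(f"unsupported bit depth: {arr.dtype}")
        arr = arr.astype(float) / info.max
    else:
        arr = arr.astype(float)
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = meta.get("pixel_size", pixel_size)
        origin = meta.get("origin", origin)
    if pixel_size is None:
        raise ValueError(
            "pixel size unknown: pass pixel_size= or provide a .json side-car"
        )
    origin = np.zeros(arr.ndim - 1) if origin is None else np.asarray(origin, float)
    axes = [
        origin[k] + pixel_size * (np.arange(n) + 0.5)
        for k, n in enumerate(arr.shape[1:])
    ]
    return RasterImage(arr, axes)


def write_image(img: RasterImage, path):
    """Write a TIFF plus a JSON side-car with the grid origin and spacing."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(img.values, 0, -1).astype(np.float32))
    meta = {
        "pixel_size": float(img.dx[0]),
        "origin": [float(a[0] - (a[1] - a[0]) / 2) if len(a) > 1 else float(a[0])
                   for a in img.axis_coords],
        "axis_start": [float(a[0]) for a in img.axis_coords],
        "spacing": [float(s) for s in img.dx],
        "shape": list(img.grid_shape),
    }
    path.with_name(path.name + ".json").write_text(json.dumps(meta))


# --------------------------------------------------------------------------
# minimal NRRD support (raw / gzip encodings, attached header)

def _parse_nrrd_header(fh):
    magic = fh.readline().decode("ascii", "replace")
    if not magic.startswith("NRRD"):
        raise ValueError("not an NRRD file")
    fields = {}
    while True:
        line = fh.readline()
        if line in (b"\n", b"\r\n", b""):
            break
        text = line.decode("ascii", "replace").strip()
        if text.startswith("#") or ":" not in text:
            continue
        key, val = text.split(":", 1)
        fields[key.strip().lower()] = val.lstrip("=").strip()
    return fields


_NRRD_TYPES = {
    "signed char": np.int8, "int8": np.int8, "uint8": np.uint8,
    "unsigned char": np.uint8, "short": np.int16, "int16": np.int16,
    "unsigned short": np.uint16, "uint16": np.uint16, "int": np.int32,
    "int32": np.int32, "unsigned int": np.uint32, "uint32": np.uint32,
    "long long": np.int64, "int64": np.int64, "uint64": np.uint64,
    "unsigned long long": np.uint64, "float": np.float32, "double": np.float64,
}


def read_nrrd_labels(path, spacing: Optional[Sequence[float]] = None) -> LabelVolume:
    """Read an integer NRRD annotation volume into a LabelVolume.

    Axis coordinates (μm) come from the ``space directions`` / ``spacings``
    header (plus ``space origin`` if present); when the header has neither,
    an explicit ``spacing`` argument is required. NRRD stores sizes fastest
    axis first; the returned array is indexed slowest-first, matching the
    package's (z, y, x)-style axis order.
    """
    with open(path, "rb") as fh:
        fields = _parse_nrrd_header(fh)
        payload = fh.read()
    sizes = [int(s) for s in fields["sizes"].split()]
    dtype = _NRRD_TYPES[fields["type"].strip()]
    if not np.issubdtype(dtype, np.integer):
        raise ValueError("label volume must have an integer payload")
    enc = fields.get("encoding", "raw").lower()
    if enc in ("gzip", "gz"):
        payload = zlib.decompress(payload, zlib.MAX_WBITS | 32)
    elif enc != "raw":
        raise ValueError(f"unsupported NRRD encoding: {enc}")
    endian = fields.get("endian", "little")
    dt = np.dtype(dtype).newbyteorder("<" if endian == "little" else ">")
    data = np.frombuffer(payload, dtype=dt, count=int(np.prod(sizes)))
    arr = data.reshape(sizes[::-1])  # slowest axis first

    steps = None
    if "space directions" in fields:
        vecs = [
            v for v in fields["space directions"].split(")")
            if "(" in v
        ]
        mats = [np.array([float(x) for x in v.split("(")[1].split(",")]) for v in vecs]
        steps = [float(np.linalg.norm(m)) for m in mats]
    elif "spacings" in fields:
        steps = [float(s) for s in fields["spacings"].split()]
    if steps is None:
        if spacing is None:
            raise ValueError(
                "NRRD header has no spacing; pass spacing=(dz, dy, dx)"
            )
        steps = list(spacing)
    steps = steps[::-1]  # match slowest-first axis order
    origin = np.zeros(arr.ndim)
    if "space origin" in fields:
        origin = np.array([
            float(x) for x in fields["space origin"].strip("() ").split(",")
        ])[::-1]
    axes = [origin[k] + steps[k] * np.arange(n) for k, n in enumerate(arr.shape)]
    return LabelVolume(np.ascontiguousarray(arr.astype(np.int64)), axes)


def write_nrrd_labels(vol: LabelVolume, path, encoding: str = "gzip"):
    """Write a LabelVolume as NRRD (int32 payload, gzip or raw encoding)."""
    arr = np.ascontiguousarray(vol.labels.astype("<i4"))
    sizes = list(arr.shape[::-1])
    steps = [float(a[1] - a[0]) if len(a) > 1 else 1.0 for a in vol.axis_coords]
    dirs = []
    for k in range(3):
        vec = [0.0, 0.0, 0.0]
        vec[k] = steps[::-1][k]
        dirs.append("(" + ",".join(str(x) for x in vec) + ")")
    origin = [float(a[0]) for a in vol.axis_coords][::-1]
    header = [
        "NRRD0004",
        "type: int32",
        "dimension: 3",
        "space dimension: 3",
        f"sizes: {' '.join(str(s) for s in sizes)}",
        f"space directions: {' '.join(dirs)}",
        f"space origin: ({','.join(str(x) for x in origin)})",
        "endian: little",
        f"encoding: {encoding}",
        "",
        "",
    ]
    payload = arr.tobytes()
    if encoding == "gzip":
        payload = gzip.compress(payload)
    elif encoding != "raw":
        raise ValueError("encoding must be 'raw' or 'gzip'")
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(payload)


def write_aligned_points(
    points: PointSet,
    aligned: PointSet,
    path,
    flags: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
):
    """Write original + aligned coordinates with optional flag/label columns.

    Columns: the original coordinates (x, y[, z]), the aligned coordinates
    (aligned_x, ...), ``matched`` (empty when no mask was computed) and
    ``region_label`` (when atlas labels were lifted over).
    """
    if aligned.n != points.n:
        raise ValueError("aligned point count must match the original")
    names = ["z", "y", "x"][-points.d:]
    cols = {}
    for k, name in enumerate(names):
        cols[name] = points.coords[:, k]
    for k, name in enumerate(["z", "y", "x"][-aligned.d:]):
        cols[f"aligned_{name}"] = aligned.coords[:, k]
    cols["matched"] = (
        np.asarray(flags, dtype=bool) if flags is not None
        else np.full(points.n, "", dtype=object)
    )
    if labels is not None:
        cols["region_label"] = np.asarray(labels)
    pd.DataFrame(cols).to_csv(path, index=False)


def save_alignment(result: AlignmentResult, path):
    """Serialize a solved alignment so it can be re-applied without re-solving."""
    cfg = result.config
    cfg_meta = {
        k: v for k, v in cfg.__dict__.items()
        if isinstance(v, (int, float, str, type(None)))
    }
    np.savez_compressed(
        path,
        affine=result.A.matrix,
        velocity=result.v.samples,
        a=result.v.a,
        p=result.v.p,
        posteriors=result.W.posteriors,
        mu_B=result.W.mu_B,
        mu_A=result.W.mu_A,
        priors=result.W.priors,
        contrast_theta=result.contrast.theta,
        contrast_degree=result.contrast.degree,
        loss_history=result.loss_history,
        config_json=json.dumps(cfg_meta),
        n_source_axes=len(result.source_axis_coords),
        **{f"vax{k}": a for k, a in enumerate(result.v.axis_coords)},
        **{f"sax{k}": a for k, a in enumerate(result.source_axis_coords)},
        **{f"tax{k}": a for k, a in enumerate(result.target_axis_coords)},
    )


def load_alignment(path) -> AlignmentResult:
    from .objective import ContrastModel, MixtureWeights

    with np.load(path, allow_pickle=False) as z:
        d = int(z["n_source_axes"])
        vax = [z[f"vax{k}"] for k in range(d)]
        sax = [z[f"sax{k}"] for k in range(d)]
        tax = [z[f"tax{k}"] for k in range(len(z["posteriors"].shape) - 1)]
        cfg = SolverConfig(**json.loads(str(z["config_json"])))
        return AlignmentResult(
            A=AffineTransform(z["affine"]),
            v=VelocityField(z["velocity"], vax, a=float(z["a"]), p=float(z["p"])),
            loss_history=z["loss_history"],
            W=MixtureWeights(z["posteriors"], z["mu_B"], z["mu_A"], z["priors"]),
            contrast=ContrastModel(z["contrast_theta"], int(z["contrast_degree"])),
            source_axis_coords=sax,
            target_axis_coords=tax,
            config=cfg,
        )
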