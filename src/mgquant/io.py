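"""Format readers and writers: TIFF stacks with JSON sidecars, label
images, ROI files (label TIFF or polygon JSON), and CSV tables.

Round trips are lossless for integer label images and tables; malformed
files raise errors that name the offending file and field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ihc import RoiRegion
from .stacks import ImageStack3D

__all__ = [
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "read_roi",
    "write_roi_polygons",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """A file could not be parsed; the message names file and field."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack3D, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON voxel-size sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(stack.voxels, dtype=np.float32), photometric="minisblack"
    )
    _sidecar(path).write_text(
        json.dumps({"voxel_xy_um": stack.voxel_xy, "voxel_z_um": stack.voxel_z})
    )
    return path


def read_stack(path: str | Path) -> ImageStack3D:
    """Read a multi-page TIFF stack; voxel sizes come from the sidecar."""
    path = Path(path)
    try:
        voxels = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types
        raise FormatError(f"{path}: cannot read TIFF stack ({exc})") from exc
    sc = _sidecar(path)
    if not sc.exists():
        raise FormatError(f"{path}: missing voxel-size sidecar {sc.name}")
    meta = json.loads(sc.read_text())
    for key in ("voxel_xy_um", "voxel_z_um"):
        if key not in meta:
            raise FormatError(f"{sc}: missing field {key!r}")
    return ImageStack3D(voxels, meta["voxel_xy_um"], meta["voxel_z_um"])


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(labels, dtype=np.int32), photometric="minisblack"
    )
    return path


def read_labels(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read label TIFF ({exc})") from exc
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: label image must be integer, got {arr.dtype}")
    return arr


def write_roi_polygons(polygons: dict[str, list[list[float]]], path: str | Path) -> Path:
    """Write named polygons as JSON: {name: [[row, col], ...], ...}."""
    path = Path(path)
    path.write_text(json.dumps({k: list(map(list, v)) for k, v in polygons.items()}))
    return path


def read_roi(
    path: str | Path, shape_hw: tuple[int, int], mpp: float
) -> dict[str, RoiRegion]:
    """Read ROIs from a label-image TIFF or a polygon JSON file.

    Polygon files map region names to [row, col] vertex lists; they are
    rasterized with pixel-centre inclusion.  Label TIFFs yield one region
    per non-zero label, named ``roi_<label>``.
    """
    from skimage.measure import grid_points_in_poly

    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
        out = {}
        for name, verts in data.items():
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
                raise FormatError(
                    f"{path}: polygon {name!r} must be an (n>=3, 2) vertex list"
                )
            # grid_points_in_poly tests integer lattice points; shift by
            # half a pixel to get pixel-centre inclusion
            mask = grid_points_in_poly(shape_hw, verts - 0.5)
            out[name] = RoiRegion(name=name, mask=mask, mpp=mpp)
        return out
    labels = read_labels(path)
    if labels.shape != tuple(shape_hw):
        raise FormatError(
            f"{path}: label image shape {labels.shape} != slide shape {shape_hw}"
        )
    return {
        f"roi_{v}": RoiRegion(name=f"roi_{v}", mask=labels == v, mpp=mpp)
        for v in np.unique(labels)
        if v != 0
    }


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read CSV ({exc})") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
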