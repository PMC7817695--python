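"""Reading and writing the pipeline's file formats.

Images are 8/16-bit TIFF or PNG; binary masks 8-bit PNG (0/255); density
volumes multi-page TIFF stacks with a JSON sidecar carrying the voxel size
and units; cohorts tidy CSV; specs, landmarks, polygons and results JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .ct import DensityVolume, TibiaLandmarks

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_volume",
    "write_volume",
    "read_cohort",
    "write_cohort",
    "read_json",
    "write_json",
    "read_landmarks",
]


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def write_image(path, pixels: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def read_mask(path) -> np.ndarray:
    return read_image(path) > 0


def write_mask(path, mask: np.ndarray) -> None:
    write_image(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_volume(path, volume: DensityVolume) -> None:
    """Multi-page 32-bit TIFF stack plus a JSON sidecar with the voxel size."""
    path = Path(path)
    tifffile.imwrite(path, volume.voxels.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"voxel_size_um": volume.voxel_size, "units": "mg HA/cm^3"})
    )


def read_volume(path) -> DensityVolume:
    path = Path(path)
    voxels = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    return DensityVolume(voxels=voxels, voxel_size=float(meta["voxel_size_um"]))


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "line" not in table.columns:
        raise ValueError("cohort CSV must contain a 'line' column")
    return table


def write_cohort(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_Encoder))


def read_json(path):
    return json.loads(Path(path).read_text())


def read_landmarks(path) -> TibiaLandmarks:
    d = read_json(path)
    return TibiaLandmarks(
        ml_extent=tuple(d["ml_extent"]),
        ap_extent=tuple(d["ap_extent"]),
        plateau_edges={k: tuple(v) for k, v in d["plateau_edges"].items()},
        growth_plate_z=int(d["growth_plate_z"]),
    )
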