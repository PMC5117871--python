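"""Reading and writing of images and profile tables.

Images travel as TIFF with pixel-size metadata (tifffile); profiles and
fields as plain CSV (pandas) with the column conventions used across the
package: positions in um, velocities in um/min, rates in 1/min.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flow import VelocityMap
from .nematic import NematicProfile, OrientationField

__all__ = [
    "write_tiff",
    "read_tiff",
    "orientation_field_frame",
    "velocity_map_frame",
    "write_profile_csv",
    "read_profile_csv",
]


def write_tiff(path: str | Path, image: np.ndarray, pixel_size: float) -> None:
    """Write a single- or multi-page TIFF with pixel size recorded (um/px)."""
    tifffile.imwrite(
        str(path),
        np.asarray(image, np.float32),
        resolution=(1.0 / pixel_size, 1.0 / pixel_size),
        metadata={"unit": "um", "pixel_size_um": pixel_size},
    )


def read_tiff(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a TIFF; returns (array, pixel_size_um or None when absent)."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        pixel_size = None
        meta = tif.shaped_metadata or tif.imagej_metadata
        if meta:
            record = meta[0] if isinstance(meta, (list, tuple)) else meta
            if isinstance(record, dict) and "pixel_size_um" in record:
                pixel_size = float(record["pixel_size_um"])
    return data, pixel_size


def orientation_field_frame(field: OrientationField) -> pd.DataFrame:
    """Flatten an orientation field to rows (x_um, y_um, Qxx, Qxy, theta_rad, A)."""
    xx, yy = np.meshgrid(field.x_um, field.y_um)
    return pd.DataFrame(
        {
            "x_um": xx.ravel(),
            "y_um": yy.ravel(),
            "Qxx": field.Qxx.ravel(),
            "Qxy": field.Qxy.ravel(),
            "theta_rad": field.theta.ravel(),
            "A": field.A.ravel(),
        }
    )


def velocity_map_frame(vmap: VelocityMap) -> pd.DataFrame:
    """Flatten a PIV map to rows (x_um, y_um, vx, vy, quality, valid)."""
    xx, yy = np.meshgrid(vmap.x_um, vmap.y_um)
    return pd.DataFrame(
        {
            "x_um": xx.ravel(),
            "y_um": yy.ravel(),
            "vx_um_per_min": vmap.vx.ravel(),
            "vy_um_per_min": vmap.vy.ravel(),
            "quality": vmap.quality.ravel(),
            "valid": vmap.valid.ravel(),
        }
    )


def write_profile_csv(path: str | Path, x_um: np.ndarray, **columns) -> None:
    """Write 1-D profiles sharing the grid x_um as a CSV table."""
    frame = pd.DataFrame({"x_um": np.asarray(x_um, float)})
    for name, values in columns.items():
        frame[name] = np.asarray(values, float)
    frame.to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def nematic_profile_frame(profile: NematicProfile) -> pd.DataFrame:
    data = {"x_um": profile.x, "Q": profile.Q}
    if profile.Qxy is not None:
        data["Qxy"] = profile.Qxy
    return pd.DataFrame(data)
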