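"""Volume I/O: multi-page TIFF with voxel-pitch metadata.

Volumes are stored as multi-page TIFFs (page = z plane) with the grid pitch,
origin and coordinate frame recorded in the JSON image description that
tifffile writes for shaped arrays; x/y pitch is additionally mirrored into
the TIFF resolution tags. float32 data round-trips bit-exactly; unsigned
integer input is promoted losslessly to float32 on load.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile

from .volume import Volume

__all__ = ["load_volume", "save_volume"]

DEFAULT_PITCH = (1.0, 1.0, 1.0)


def save_volume(vol: Volume, path) -> None:
    path = Path(path)
    data = vol.data
    if data.dtype not in (np.float32, np.uint8, np.uint16):
        data = data.astype(np.float32)
    pz, py, px = vol.pitch
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",  # never guess RGB for small lateral sizes
        metadata={
            "pitch_um": list(vol.pitch),
            "origin_vox": list(vol.origin),
            "frame": vol.frame,
        },
        resolution=(1.0 / px, 1.0 / py),
    )


def load_volume(path) -> Volume:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise IOError(f"cannot read TIFF volume {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise IOError(f"{path} does not hold a 3D volume (shape {data.shape})")
    if data.dtype != np.float32:
        if not (np.issubdtype(data.dtype, np.unsignedinteger) and data.dtype.itemsize <= 2):
            data = data.astype(np.float32)
        else:
            data = data.astype(np.float32)  # lossless for 8/16-bit unsigned
    pitch = meta.get("pitch_um")
    if pitch is None:
        warnings.warn(
            f"{path} has no pitch metadata; defaulting to {DEFAULT_PITCH} um",
            stacklevel=2,
        )
        pitch = DEFAULT_PITCH
    origin = meta.get("origin_vox")
    frame = meta.get("frame", "fixed")
    return Volume(data, tuple(pitch), tuple(origin) if origin else None, frame)
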