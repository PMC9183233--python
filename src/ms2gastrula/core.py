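"""Core containers and file IO.

A :class:`VoxelGrid` is the in-memory form of a two-channel time-lapse
volumetric movie with its physical calibration and nc14 time origin.  Stacks
are written as multi-page TIFF with dimension order (C, T, Z, Y, X) recorded
in the metadata; tables go to CSV and event records to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile


@dataclass
class VoxelGrid:
    """Multi-channel 4D movie: data has shape (C, T, Z, Y, X)."""

    data: np.ndarray
    voxel_xy: float
    voxel_z: float
    frame_interval: float          # seconds / frame
    t0_nc14: int = 0               # frame index of nc14 start
    channels: dict = field(default_factory=lambda: {"nuclear": 0, "spot": 1})

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError("VoxelGrid data must be 5D (C, T, Z, Y, X)")
        if min(self.voxel_xy, self.voxel_z, self.frame_interval) <= 0:
            raise ValueError("calibration values must be positive")
        if not 0 <= self.t0_nc14 < self.n_frames:
            raise ValueError("t0_nc14 must be a valid frame index")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def channel(self, role: str) -> np.ndarray:
        """(T, Z, Y, X) array for a channel role ('nuclear' or 'spot')."""
        return self.data[self.channels[role]]

    def time_minutes(self, frame) -> np.ndarray:
        """Minutes into nc14 of the given frame index/indices."""
        return (np.asarray(frame) - self.t0_nc14) * self.frame_interval / 60.0

    @property
    def times(self) -> np.ndarray:
        return self.time_minutes(np.arange(self.n_frames))


def write_stack(path, grid: VoxelGrid) -> None:
    meta = {
        "axes_order": "CTZYX",
        "shape": list(grid.data.shape),
        "voxel_xy": grid.voxel_xy,
        "voxel_z": grid.voxel_z,
        "frame_interval": grid.frame_interval,
        "t0_nc14": grid.t0_nc14,
        "channels": grid.channels,
    }
    pages = grid.data.reshape(-1, *grid.data.shape[-2:])
    tifffile.imwrite(path, pages, metadata=None,
                     description=json.dumps(meta))


def read_stack(path) -> VoxelGrid:
    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description
        try:
            meta = json.loads(desc)
            data = tf.asarray().reshape(meta["shape"])
            return VoxelGrid(
                data=data, voxel_xy=meta["voxel_xy"],
                voxel_z=meta["voxel_z"],
                frame_interval=meta["frame_interval"],
                t0_nc14=meta["t0_nc14"],
                channels={k: int(v) for k, v in meta["channels"].items()})
        except (TypeError, KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: missing or malformed stack metadata") from exc


def write_labels(path, labels: np.ndarray) -> None:
    """Per-frame label volumes (T, Z, Y, X) as 16-bit TIFF."""
    arr = np.asarray(labels)
    if arr.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(path, arr.reshape(-1, *arr.shape[-2:]).astype(np.uint16),
                     description=json.dumps({"shape": list(arr.shape)}))


def read_labels(path) -> np.ndarray:
    with tifffile.TiffFile(path) as tf:
        meta = json.loads(tf.pages[0].description)
        return tf.asarray().reshape(meta["shape"])


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(path, events: dict) -> None:
    with open(path, "w") as fh:
        json.dump(events, fh, indent=1, default=float)


def read_events(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
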