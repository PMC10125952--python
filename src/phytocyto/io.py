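"""Micrograph container and TIFF/CSV input-output.

Images are single-plane grayscale TIFFs, one file per channel, named
``<field>_<channel>.tif``.  Intensity channels are stored as float32 in
arbitrary fluorescence units (a.u.); label masks are uint16 rasters with
0 = background and k > 0 = object k.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "Micrograph",
    "read_micrograph",
    "write_micrograph",
    "read_mask",
    "write_mask",
]


@dataclass
class Micrograph:
    """Multi-channel 2D intensity raster with named channels.

    Parameters
    ----------
    data : ndarray, shape (h, w, c)
        Non-negative intensities, one plane per channel.
    channels : sequence of str
        Unique channel labels, one per plane.
    bit_depth : int
        Nominal acquisition bit depth (informational).
    pixel_size_um : float, optional
        Physical pixel size in micrometres.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    bit_depth: int = 32
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError(f"expected (h, w, c) array, got shape {arr.shape}")
        self.data = arr
        self.channels = tuple(self.channels)
        if len(self.channels) != arr.shape[2]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {arr.shape[2]} planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"channel labels not unique: {self.channels}")
        if np.any(arr < 0):
            raise ValueError("negative intensities not allowed")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def channel(self, label: str) -> np.ndarray:
        """Return the single-channel raster for *label* (a view)."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channels}"
            ) from None
        return self.data[:, :, idx]


def write_micrograph(img: Micrograph, directory: str | Path, field_name: str) -> list[Path]:
    """Write one float32 TIFF per channel, named ``<field>_<channel>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for label in img.channels:
        path = directory / f"{field_name}_{label}.tif"
        tifffile.imwrite(path, img.channel(label).astype(np.float32))
        paths.append(path)
    return paths


def read_micrograph(
    directory: str | Path,
    field_name: str,
    channels: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
) -> Micrograph:
    """Assemble a :class:`Micrograph` from ``<field>_<channel>.tif`` files.

    When *channels* is None, all files matching the field prefix are read
    and channel labels inferred from filenames (sorted lexicographically).
    """
    directory = Path(directory)
    if channels is None:
        pattern = re.compile(re.escape(field_name) + r"_(.+)\.tif{1,2}$")
        channels = sorted(
            m.group(1)
            for p in directory.iterdir()
            if (m := pattern.match(p.name)) is not None
        )
        if not channels:
            raise FileNotFoundError(
                f"no files matching {field_name}_*.tif under {directory}"
            )
    planes = []
    for label in channels:
        path = directory / f"{field_name}_{label}.tif"
        planes.append(np.asarray(tifffile.imread(path), dtype=np.float64))
    data = np.stack(planes, axis=-1)
    return Micrograph(data, tuple(channels), pixel_size_um=pixel_size_um)


def write_mask(labels: np.ndarray, path: str | Path) -> Path:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values out of uint16 range")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(np.int32)
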