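"""In-memory containers for multi-channel micrographs and confocal stacks.

Two containers cover everything downstream modules consume:

``MultiChannelImage``
    A single 2D field of view with named channels sharing one pixel grid and
    an isotropic pixel size in micrometres.  TIRF micrographs of synapses are
    represented this way.

``VolumeStack``
    A 3D multi-channel z-stack with anisotropic voxel size: the xy pixel size
    and the z step are independent (confocal stacks are typically acquired
    with a coarser z step, e.g. 0.25 um, than the xy sampling).

Both round-trip through OME-TIFF via :mod:`tifffile`, carrying the physical
pixel sizes in the OME metadata so a re-loaded image quantifies identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import tifffile


def _validate_channels(channels: Mapping[str, np.ndarray], ndim: int) -> dict[str, np.ndarray]:
    if not channels:
        raise ValueError("at least one channel is required")
    out: dict[str, np.ndarray] = {}
    shape = None
    for name, arr in channels.items():
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != ndim:
            raise ValueError(f"channel {name!r} has ndim {arr.ndim}, expected {ndim}")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"channel {name!r} shape {arr.shape} != {shape}")
        out[str(name)] = arr
    return out


@dataclass
class MultiChannelImage:
    """A 2D micrograph with named channels on a common pixel grid.

    Parameters
    ----------
    channels
        Mapping channel name -> 2D float array (row = y, column = x).
    pixel_size_um
        Isotropic pixel size in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.channels = _validate_channels(self.channels, ndim=2)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    def to_tiff(self, path: str | Path) -> None:
        """Write all channels as one multi-channel OME-TIFF with pixel size."""
        data = np.stack([self.channels[c] for c in self.channels]).astype(np.float32)
        tifffile.imwrite(
            str(path),
            data,
            ome=True,
            metadata={
                "axes": "CYX",
                "Channel": {"Name": self.channel_names},
                "PhysicalSizeX": self.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
            },
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "MultiChannelImage":
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            names, px = _ome_channel_metadata(tif)
        if data.ndim == 2:
            data = data[None]
        if names is None or len(names) != data.shape[0]:
            names = [f"ch{i}" for i in range(data.shape[0])]
        return cls({n: data[i] for i, n in enumerate(names)}, pixel_size_um=px or 1.0)


@dataclass
class VolumeStack:
    """A 3D multi-channel confocal stack with anisotropic voxel size.

    Channel arrays are indexed ``(z, y, x)``; ``pixel_size_um`` applies to x
    and y, ``z_step_um`` to z.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("voxel sizes must be positive")
        self.channels = _validate_channels(self.channels, ndim=3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        """Voxel edge lengths as (x, y, z) in micrometres."""
        return (self.pixel_size_um, self.pixel_size_um, self.z_step_um)

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.z_step_um

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def to_tiff(self, path: str | Path) -> None:
        data = np.stack([self.channels[c] for c in self.channels], axis=1).astype(np.float32)
        tifffile.imwrite(
            str(path),
            data,
            ome=True,
            metadata={
                "axes": "ZCYX",
                "Channel": {"Name": self.channel_names},
                "PhysicalSizeX": self.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": self.z_step_um,
                "PhysicalSizeZUnit": "µm",
            },
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "VolumeStack":
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()  # ZCYX per our writer
            names, px = _ome_channel_metadata(tif)
            pz = _ome_z_step(tif)
        if data.ndim == 3:
            data = data[:, None]
        nchan = data.shape[1]
        if names is None or len(names) != nchan:
            names = [f"ch{i}" for i in range(nchan)]
        return cls(
            {n: data[:, i] for i, n in enumerate(names)},
            pixel_size_um=px or 1.0,
            z_step_um=pz or 1.0,
        )


def _ome_channel_metadata(tif: tifffile.TiffFile) -> tuple[list[str] | None, float | None]:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        px = float(pixels.get("PhysicalSizeX")) if pixels.get("PhysicalSizeX") else None
        names = [c.get("Name") or f"ch{i}" for i, c in enumerate(pixels.findall("ome:Channel", ns))]
        return (names or None), px
    except Exception:
        return None, None


def _ome_z_step(tif: tifffile.TiffFile) -> float | None:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        v = pixels.get("PhysicalSizeZ")
        return float(v) if v else None
    except Exception:
        return None


def write_movie_tiff(path: str | Path, frames: list[MultiChannelImage]) -> None:
    """Write a time series of multi-channel images as one TCYX OME-TIFF."""
    if not frames:
        raise ValueError("empty movie")
    names = frames[0].channel_names
    data = np.stack(
        [np.stack([f.channels[c] for c in names]) for f in frames]
    ).astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "TCYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": frames[0].pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": frames[0].pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_movie_tiff(path: str | Path) -> list[MultiChannelImage]:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        names, px = _ome_channel_metadata(tif)
    if data.ndim == 3:  # TYX single channel
        data = data[:, None]
    nchan = data.shape[1]
    if names is None or len(names) != nchan:
        names = [f"ch{i}" for i in range(nchan)]
    return [
        MultiChannelImage({n: data[t, i] for i, n in enumerate(names)}, pixel_size_um=px or 1.0)
        for t in range(data.shape[0])
    ]


def write_json(path: str | Path, payload: dict) -> None:
    """Write a JSON sidecar with numpy types coerced to plain Python."""

    def default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
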