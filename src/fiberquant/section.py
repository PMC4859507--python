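"""Containers and disk formats for multi-channel muscle sections.

A section is a set of co-registered single-plane fluorescence rasters
(laminin, the four MyHC isotype channels, DAPI, GFP, an activity probe and
collagen), stored on disk as one grayscale TIFF per channel plus a JSON
sidecar carrying the pixel size and sample identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

# Canonical channel names used throughout the package.
LAMININ = "laminin"
MYHC_2B = "myhc_2b"
MYHC_2X = "myhc_2x"
MYHC_2A = "myhc_2a"
MYHC_1 = "myhc_1"
MYHC_CHANNELS: tuple[str, ...] = (MYHC_2B, MYHC_2X, MYHC_2A, MYHC_1)
DAPI = "dapi"
GFP = "gfp"
PROBE = "probe"
COLLAGEN = "collagen"

SIDECAR_NAME = "section.json"
LABELS_SIDECAR = "labels.json"


@dataclass
class SampleInfo:
    """Identity of the muscle a section came from."""

    mouse: str = "m0"
    condition: str = "Scram"
    muscle: str = "TA"

    @property
    def sample_id(self) -> str:
        return f"{self.mouse}_{self.condition}"


@dataclass
class MultiChannelSection:
    """Named, co-registered 2D intensity rasters for one muscle section.

    Parameters
    ----------
    channels
        Mapping channel name -> 2D float array. All rasters must share a
        shape and be non-negative (intensities are physical).
    pixel_size_um
        Lateral pixel size in micrometres.
    sample
        Mouse / condition / muscle bookkeeping.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    sample: SampleInfo = field(default_factory=SampleInfo)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("section needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be single-plane 2D rasters")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.channels = {
            name: np.asarray(a, dtype=np.float64) for name, a in self.channels.items()
        }
        for name, a in self.channels.items():
            if a.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def save(self, directory: str | Path) -> Path:
        """Write one float32 TIFF per channel and a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, raster in sorted(self.channels.items()):
            tifffile.imwrite(directory / f"{name}.tif", raster.astype(np.float32))
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "sample": asdict(self.sample),
            "channels": sorted(self.channels),
        }
        (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "MultiChannelSection":
        directory = Path(directory)
        meta = json.loads((directory / SIDECAR_NAME).read_text())
        channels = {
            name: tifffile.imread(directory / f"{name}.tif")
            for name in meta["channels"]
        }
        return cls(
            channels=channels,
            pixel_size_um=meta["pixel_size_um"],
            sample=SampleInfo(**meta["sample"]),
        )


@dataclass
class FiberLabelMap:
    """Integer raster assigning each pixel to a myofiber (1..N) or ECM (0)."""

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-typed")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_fibers(self) -> int:
        return int(self.labels.max())

    @property
    def fiber_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def is_consecutive(self) -> bool:
        """True when labels run 1..N without holes."""
        ids = self.fiber_ids
        return ids.size == 0 or (ids[0] == 1 and ids[-1] == ids.size)

    def save(self, path: str | Path) -> Path:
        """Write as 16-bit (or 32-bit when >65535 fibers) TIFF plus sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        dtype = np.uint16 if self.labels.max() < 2**16 else np.uint32
        tifffile.imwrite(path, self.labels.astype(dtype))
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"pixel_size_um": self.pixel_size_um}, sort_keys=True)
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FiberLabelMap":
        path = Path(path)
        labels = tifffile.imread(path).astype(np.int32)
        sidecar = path.with_suffix(".json")
        pixel = 1.0
        if sidecar.exists():
            pixel = json.loads(sidecar.read_text())["pixel_size_um"]
        return cls(labels=labels, pixel_size_um=pixel)
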