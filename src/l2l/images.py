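"""Lightweight containers for multichannel leaf images and binary skeletons.

A :class:`LeafImage` is a (C, H, W) float array in [0, 1] plus the band
names, so RGB / RGNIR / single-NIR images flow through one type.  A
:class:`SkeletonImage` is a strictly binary (H, W) mask: white (1) marks
the leaf profile and veins, black (0) everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

RGB = ("R", "G", "B")
RGBNIR = ("R", "G", "B", "NIR")
RGNIR = ("R", "G", "NIR")


@dataclass
class LeafImage:
    channels: np.ndarray          # (C, H, W) float in [0, 1]
    bands: tuple[str, ...] = RGB

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3:
            raise ParameterError("LeafImage.channels must be (C, H, W)")
        if self.channels.shape[0] != len(self.bands):
            raise ParameterError(
                f"{self.channels.shape[0]} channels but {len(self.bands)} band names"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, band: str) -> np.ndarray:
        try:
            return self.channels[self.bands.index(band)]
        except ValueError as exc:
            raise ParameterError(f"no band {band!r} in {self.bands}") from exc

    def select(self, bands: tuple[str, ...]) -> "LeafImage":
        """Reorder / subset bands, e.g. RGBNIR -> RGNIR composite."""
        return LeafImage(np.stack([self.channel(b) for b in bands]), bands)


@dataclass
class SkeletonImage:
    mask: np.ndarray              # (H, W) bool

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 2:
            raise ParameterError("SkeletonImage.mask must be 2-D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ParameterError("SkeletonImage must be strictly binary")
        self.mask = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def as_float(self) -> np.ndarray:
        return self.mask.astype(np.float64)


@dataclass
class Probe:
    """Axis-aligned constant-reflectance reference region (half-open rows/cols)."""

    row0: int
    col0: int
    row1: int
    col1: int
    reflectance: float

    def region(self, arr: np.ndarray) -> np.ndarray:
        return arr[..., self.row0:self.row1, self.col0:self.col1]

    def as_dict(self) -> dict:
        return {"row0": self.row0, "col0": self.col0, "row1": self.row1,
                "col1": self.col1, "reflectance": self.reflectance}
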