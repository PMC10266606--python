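"""Core in-memory containers for calibrated images and label maps.

Conventions used throughout the package
---------------------------------------
* Coordinates are ``(row, col)``, 0-based, with pixel centers at integer
  coordinates.
* Intensity images are 2D float arrays; raw integer data is normalized by
  its dtype maximum on load so thresholds are bit-depth independent.
* Label images are 2D integer arrays with 0 = background; positive labels
  are unique per object but need not be contiguous.
* All physical quantities derive from an explicit pixel size in µm/pixel;
  there is no silent 1.0 default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np


class ChannelRole(str, enum.Enum):
    """Semantic role of a fluorescence channel."""

    NUCLEI = "nuclei"
    MEMBRANE = "membrane"
    ORGANELLE = "organelle"
    CONTENT = "content"


#: Roles that every multi-channel image must provide.
REQUIRED_ROLES = (ChannelRole.NUCLEI, ChannelRole.MEMBRANE, ChannelRole.ORGANELLE)


class LabelKind(str, enum.Enum):
    """What class of object a label image describes."""

    NUCLEUS = "nucleus"
    CELL = "cell"
    MEMBRANE = "membrane"
    ORGANELLE = "organelle"
    ORGANELLE_EXPANDED = "organelle_expanded"


@dataclass(frozen=True)
class IntensityImage:
    """One calibrated fluorescence channel.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative float intensities.
    pixel_size_um
        Physical edge length of a pixel in µm; must be positive.
    role
        Semantic channel role (nuclei / membrane / organelle / content).
    """

    pixels: np.ndarray
    pixel_size_um: float
    role: ChannelRole

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D channel, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("channel contains non-finite pixels")
        if px.size and px.min() < 0:
            raise ValueError("channel contains negative intensities")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "role", ChannelRole(self.role))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "IntensityImage":
        """Return a copy carrying new pixel data but the same calibration."""
        return IntensityImage(pixels=pixels, pixel_size_um=self.pixel_size_um, role=self.role)


@dataclass(frozen=True)
class MultiChannelImage:
    """A set of channels sharing one field of view and calibration."""

    channels: Mapping[ChannelRole, IntensityImage]
    image_id: str = ""

    def __post_init__(self) -> None:
        chans = {ChannelRole(k): v for k, v in self.channels.items()}
        missing = [r.value for r in REQUIRED_ROLES if r not in chans]
        if missing:
            raise ValueError(f"missing required channel role(s): {missing}")
        shapes = {img.shape for img in chans.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {sorted(shapes)}")
        sizes = {img.pixel_size_um for img in chans.values()}
        if len(sizes) != 1:
            raise ValueError(f"channels differ in pixel size: {sorted(sizes)}")
        object.__setattr__(self, "channels", chans)

    def __getitem__(self, role: ChannelRole | str) -> IntensityImage:
        return self.channels[ChannelRole(role)]

    def __contains__(self, role: ChannelRole | str) -> bool:
        return ChannelRole(role) in self.channels

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_size_um(self) -> float:
        return next(iter(self.channels.values())).pixel_size_um


@dataclass(frozen=True)
class LabelImage:
    """2D integer object map; 0 is background."""

    labels: np.ndarray
    kind: LabelKind
    pixel_size_um: float = field(default=1.0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"expected 2D labels, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be >= 0")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "kind", LabelKind(self.kind))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of positive labels present."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)

    def with_labels(self, labels: np.ndarray, kind: LabelKind | None = None) -> "LabelImage":
        return LabelImage(labels=labels, kind=kind or self.kind, pixel_size_um=self.pixel_size_um)
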