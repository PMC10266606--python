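"""Reading multi-channel TIFFs, intensity rescaling, and tabular/overlay export.

Channels are split on load and mapped to semantic roles (nuclei, membrane,
organelle, content).  Z-stacks are collapsed by a per-pixel maximum
projection when requested.  The pixel size is mandatory: it is either given
explicitly or recovered from the TIFF resolution tags — never defaulted.
"""

from __future__ import annotations

import os
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image, ImageDraw
from scipy import ndimage as ndi

from .core import ChannelRole, IntensityImage, LabelImage, MultiChannelImage

__all__ = [
    "read_image",
    "rescale_full_range",
    "write_tables",
    "write_overlay",
    "write_multichannel_tiff",
]

#: TIFF ResolutionUnit tag → unit length in µm.
_RES_UNIT_UM = {2: 25400.0, 3: 10000.0}  # inch, centimeter

# Max plausible number of channels; used to tell the channel axis apart from
# spatial axes when the TIFF carries no axis metadata.
_MAX_CHANNELS = 8


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    unit = int(getattr(unit, "value", unit))
    if unit not in _RES_UNIT_UM:
        return None
    ppu = float(Fraction(int(xres[0]), int(xres[1])))
    if ppu <= 0:
        return None
    return _RES_UNIT_UM[unit] / ppu


def _normalize_dtype(arr: np.ndarray) -> np.ndarray:
    """Convert to float, dividing integer data by its dtype maximum."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return arr.astype(float)


def _split_channels(arr: np.ndarray, projection: str | None) -> np.ndarray:
    """Return a (C, H, W) stack from raw TIFF data of 2–4 dimensions."""
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim == 3:
        # channel-first (C, H, W) or channel-last (H, W, C)
        if arr.shape[0] <= _MAX_CHANNELS:
            return arr
        if arr.shape[-1] <= _MAX_CHANNELS:
            return np.moveaxis(arr, -1, 0)
        raise ValueError(
            f"cannot locate a channel axis in shape {arr.shape}; "
            f"expected <= {_MAX_CHANNELS} channels"
        )
    if arr.ndim == 4:
        # (Z, C, H, W): collapse z first
        if projection != "max":
            raise ValueError(
                "input has a z dimension; pass projection='max' to collapse it"
            )
        if arr.shape[1] > _MAX_CHANNELS:
            raise ValueError(f"expected (Z, C, H, W) with C <= {_MAX_CHANNELS}, got {arr.shape}")
        return arr.max(axis=0)
    raise ValueError(f"unsupported TIFF dimensionality: {arr.shape}")


def read_image(
    path: str | os.PathLike,
    channel_map: Mapping[int, ChannelRole | str],
    pixel_size_um: float | str = "from-metadata",
    projection: str | None = None,
    image_id: str | None = None,
) -> MultiChannelImage:
    """Read a multi-channel TIFF and split it into role-mapped channels.

    Parameters
    ----------
    path
        TIFF file (single- or multi-page; 2D, (C,H,W), (H,W,C) or (Z,C,H,W)).
    channel_map
        Mapping from channel index in the file to a semantic role, e.g.
        ``{0: "nuclei", 1: "membrane", 2: "organelle"}``.
    pixel_size_um
        Pixel pitch in µm, or ``"from-metadata"`` to read the TIFF
        resolution tags.  Absent metadata is a hard error.
    projection
        ``"max"`` to collapse a z-stack by per-pixel maximum; required if
        the file has a z dimension.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta_px = _pixel_size_from_tags(tif)
    if pixel_size_um == "from-metadata":
        if meta_px is None:
            raise ValueError(
                f"{path}: no resolution metadata; pass pixel_size_um explicitly"
            )
        px_um = meta_px
    else:
        px_um = float(pixel_size_um)

    stack = _split_channels(np.asarray(arr), projection)
    n_chan = stack.shape[0]
    channels: dict[ChannelRole, IntensityImage] = {}
    for idx, role in channel_map.items():
        if not (0 <= int(idx) < n_chan):
            raise IndexError(f"channel index {idx} out of range for {n_chan}-channel image")
        plane = _normalize_dtype(stack[int(idx)])
        channels[ChannelRole(role)] = IntensityImage(
            pixels=plane, pixel_size_um=px_um, role=ChannelRole(role)
        )
    return MultiChannelImage(channels=channels, image_id=image_id or path.stem)


def rescale_full_range(img: IntensityImage) -> IntensityImage:
    """Linearly stretch intensities to the full [0, 1] range.

    A constant channel maps to all zeros (there is no contrast to stretch).
    Idempotent on its own output.
    """
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return img.with_pixels(np.zeros_like(px))
    return img.with_pixels((px - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def write_tables(
    per_image: pd.DataFrame,
    per_cell: pd.DataFrame,
    per_organelle: pd.DataFrame,
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write the three result tables as CSV with a stable column order.

    Floats are written with shortest round-trip precision and NaN as an
    empty field, so re-running on identical inputs yields byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("per_image", per_image),
        ("per_cell", per_cell),
        ("per_organelle", per_organelle),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, na_rep="")
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# QC overlay
# ---------------------------------------------------------------------------

def outline_mask(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of label pixels adjacent (8-conn) to a different value."""
    lab = np.asarray(labels)
    out = np.zeros(lab.shape, dtype=bool)
    for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)):
        shifted = np.full(lab.shape, -1, dtype=lab.dtype)
        rs = slice(max(dr, 0), lab.shape[0] + min(dr, 0))
        rd = slice(max(-dr, 0), lab.shape[0] + min(-dr, 0))
        cs = slice(max(dc, 0), lab.shape[1] + min(dc, 0))
        cd = slice(max(-dc, 0), lab.shape[1] + min(-dc, 0))
        shifted[rd, cd] = lab[rs, cs]
        out |= (lab > 0) & (shifted != lab)
    return out


_OVERLAY_COLORS = {
    "nuclei": (70, 110, 255),
    "cells": (255, 60, 60),
    "organelles": (60, 255, 60),
    "text": (200, 80, 255),
}


def write_overlay(
    img: IntensityImage,
    nuclei: LabelImage,
    cells: LabelImage,
    organelles: LabelImage,
    out_path: str | os.PathLike,
) -> Path:
    """Write a QC PNG: object outlines over the organelle channel.

    Nuclei outlines are blue, cell outlines red, organelle outlines green;
    each cell is annotated with its label number at its centroid so
    outliers can be traced back to table rows.  Pure sink: measurement
    outputs are never affected.
    """
    for lab in (nuclei, cells, organelles):
        if lab.shape != img.shape:
            raise ValueError(f"label shape {lab.shape} does not match image {img.shape}")
    base = img.pixels
    hi = base.max()
    gray = (255 * (base / hi if hi > 0 else base)).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[outline_mask(cells.labels)] = _OVERLAY_COLORS["cells"]
    rgb[outline_mask(nuclei.labels)] = _OVERLAY_COLORS["nuclei"]
    rgb[outline_mask(organelles.labels)] = _OVERLAY_COLORS["organelles"]

    im = Image.fromarray(rgb)
    draw = ImageDraw.Draw(im)
    if cells.n_objects:
        centroids = ndi.center_of_mass(
            np.ones(cells.shape), cells.labels, cells.ids
        )
        for lab_id, (r, c) in zip(cells.ids, centroids):
            draw.text((float(c), float(r)), str(int(lab_id)),
                      fill=_OVERLAY_COLORS["text"], anchor="mm")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    im.save(out_path, format="PNG")
    return out_path


def write_multichannel_tiff(
    image: MultiChannelImage,
    path: str | os.PathLike,
    channel_order: Sequence[ChannelRole | str] | None = None,
) -> Path:
    """Write channels as a (C, H, W) float32 TIFF with resolution tags.

    The pixel size is stored as pixels-per-centimeter so that
    :func:`read_image` can recover it with ``pixel_size_um="from-metadata"``.
    """
    if channel_order is None:
        channel_order = [r for r in ChannelRole if r in image]
    stack = np.stack(
        [image[ChannelRole(r)].pixels.astype(np.float32) for r in channel_order]
    )
    # exact rational pixels-per-cm so the pixel size round-trips losslessly
    ppcm = Fraction(10000) / Fraction(image.pixel_size_um).limit_denominator(10 ** 9)
    res = (ppcm.numerator, ppcm.denominator)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, stack, photometric="minisblack",
        resolution=(res, res), resolutionunit="CENTIMETER",
    )
    return path
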