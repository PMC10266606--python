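"""Per-object size, shape, intensity, and intracellular position.

Shape metrics follow the moment conventions standard in cell image
analysis:

* **eccentricity** — ``sqrt(1 - (b/a)**2)`` of the ellipse with the same
  second central moments as the object (0 = circle, -> 1 = line);
* **maximum Feret diameter** — the largest caliper distance across the
  object, computed as the maximum pairwise distance between convex-hull
  vertices of the object's *pixel centers*.  Under this convention a
  1 x N pixel segment has Feret (N - 1) pixels; conventions based on pixel
  corners differ by about one pixel and are not used here.
* **relative distance** — ``100 * d_nuc / (d_nuc + d_mem)``: 0% at the
  nucleus edge, 100% at the cell edge; undefined (missing) when both
  distances are zero.

Distances are measured from the organelle *centroid* to the nearest pixel
of the assigned cell's nucleus and of the cell's outer boundary, each via
a distance transform computed within that cell in isolation so that
neighboring cells' nuclei never interfere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .core import IntensityImage, LabelImage

__all__ = [
    "measure_shape",
    "measure_intensity",
    "max_feret_px",
    "edge_distances",
    "relative_distance",
]


def max_feret_px(coords: np.ndarray) -> float:
    """Maximum pairwise distance between pixel centers of one object.

    Computed over convex-hull vertices (all-pairs over the handful of hull
    vertices); degenerate objects (single pixel, collinear pixels) fall
    back to an exact all-pairs scan.
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # collinear: all-pairs over the raw points is exact
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).max())


def measure_shape(labels: LabelImage, pixel_size_um: float | None = None) -> pd.DataFrame:
    """Size and shape per label.

    Returns a table with one row per positive label: pixel count and area
    in µm², centroid (row, col, intensity-unweighted), moment-ellipse
    eccentricity, equivalent diameter, and the maximum Feret diameter in
    pixels and µm.
    """
    px_um = labels.pixel_size_um if pixel_size_um is None else pixel_size_um
    rows = []
    for rp in measure.regionprops(labels.labels):
        feret = max_feret_px(rp.coords)
        rows.append(
            {
                "label": int(rp.label),
                "area_px": int(rp.area),
                "area_um2": float(rp.area) * px_um ** 2,
                "centroid_r": float(rp.centroid[0]),
                "centroid_c": float(rp.centroid[1]),
                "eccentricity": float(rp.eccentricity),
                "equivalent_diameter_px": float(rp.equivalent_diameter_area),
                "max_feret_px": feret,
                "max_feret_um": feret * px_um,
            }
        )
    cols = [
        "label", "area_px", "area_um2", "centroid_r", "centroid_c",
        "eccentricity", "equivalent_diameter_px", "max_feret_px", "max_feret_um",
    ]
    return pd.DataFrame(rows, columns=cols)


def measure_intensity(
    labels: LabelImage, img: IntensityImage, channel_name: str = "channel"
) -> pd.DataFrame:
    """Mean and integrated intensity per label, in the channel's A.U. scale."""
    if labels.shape != img.shape:
        raise ValueError(f"label shape {labels.shape} does not match image {img.shape}")
    ids = labels.ids
    if ids.size == 0:
        return pd.DataFrame(
            columns=["label", f"mean_intensity_{channel_name}", f"integrated_intensity_{channel_name}"]
        )
    means = ndi.mean(img.pixels, labels.labels, ids)
    sums = ndi.sum_labels(img.pixels, labels.labels, ids)
    return pd.DataFrame(
        {
            "label": ids.astype(int),
            f"mean_intensity_{channel_name}": means,
            f"integrated_intensity_{channel_name}": sums,
        }
    )


def relative_distance(d_nuc_um, d_mem_um):
    """Percent position between nucleus (0%) and cell edge (100%).

    ``100 * d_nuc / (d_nuc + d_mem)``; NaN where both distances are zero
    (position undefined, excluded from aggregation).  Accepts scalars or
    arrays; negative inputs are rejected.
    """
    d_n = np.asarray(d_nuc_um, dtype=float)
    d_m = np.asarray(d_mem_um, dtype=float)
    if np.any(d_n < 0) or np.any(d_m < 0):
        raise ValueError("distances must be >= 0")
    total = d_n + d_m
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 100.0 * d_n / total, np.nan)
    if np.isscalar(d_nuc_um) and np.isscalar(d_mem_um):
        return float(out)
    return out


def _cell_nucleus_map(nuclei: LabelImage, cells: LabelImage) -> dict[int, list[int]]:
    """cell label -> list of nucleus labels whose pixels it contains (majority)."""
    out: dict[int, list[int]] = {}
    cell_lab = cells.labels
    for rp in measure.regionprops(nuclei.labels):
        vals = cell_lab[tuple(rp.coords.T)]
        vals = vals[vals > 0]
        if vals.size == 0:
            continue
        host = int(np.bincount(vals).argmax())
        out.setdefault(host, []).append(int(rp.label))
    return out


def edge_distances(
    organelles: pd.DataFrame,
    nuclei: LabelImage,
    cells: LabelImage,
    assignment: pd.DataFrame,
) -> pd.DataFrame:
    """Fill nucleus and cell-edge distances for assigned organelles.

    For every organelle with a valid ``cell_label`` whose cell contains
    exactly one nucleus: ``d_nuc_um`` is the distance from the organelle
    centroid to the nearest nucleus pixel (0 inside the nucleus) and
    ``d_mem_um`` the distance to the nearest pixel of the cell's outer
    boundary, both from per-cell distance transforms.  Cells with zero or
    multiple nuclei are flagged and their organelle distances left
    missing.

    Parameters
    ----------
    organelles
        Shape table from :func:`measure_shape` (needs centroid columns).
    assignment
        Relation table with ``organelle_label`` and ``cell_label``.

    Returns the assignment table with ``d_nuc_um``, ``d_mem_um``,
    ``rel_dist_pct`` and a boolean ``nucleus_flag`` column added.
    """
    px_um = cells.pixel_size_um
    rel = assignment.merge(
        organelles[["label", "centroid_r", "centroid_c"]],
        left_on="organelle_label",
        right_on="label",
        how="left",
    ).drop(columns="label")

    d_nuc = np.full(len(rel), np.nan)
    d_mem = np.full(len(rel), np.nan)
    flag = np.zeros(len(rel), dtype=bool)

    nuclei_per_cell = _cell_nucleus_map(nuclei, cells)
    cell_lab = cells.labels
    nuc_lab = nuclei.labels
    slices = ndi.find_objects(cell_lab)

    for cell_id, group in rel.groupby("cell_label"):
        cell_id = int(cell_id)
        idx = group.index.to_numpy()
        if cell_id <= 0 or cell_id > len(slices) or slices[cell_id - 1] is None:
            continue
        nucs = nuclei_per_cell.get(cell_id, [])
        if len(nucs) != 1:
            flag[idx] = True
            continue
        sl = slices[cell_id - 1]
        mask = np.pad(cell_lab[sl] == cell_id, 1)
        nuc_mask = np.pad(nuc_lab[sl] == nucs[0], 1) & mask
        # outer boundary: cell pixels with an 8-neighbor outside the cell
        interior = ndi.binary_erosion(
            mask, structure=np.ones((3, 3), bool), border_value=0
        )
        boundary = mask & ~interior
        edt_nuc = ndi.distance_transform_edt(~nuc_mask)
        edt_mem = ndi.distance_transform_edt(~boundary)
        r0, c0 = sl[0].start, sl[1].start
        coords = np.stack(
            [
                group["centroid_r"].to_numpy() - r0 + 1,
                group["centroid_c"].to_numpy() - c0 + 1,
            ]
        )
        d_nuc[idx] = ndi.map_coordinates(edt_nuc, coords, order=1, mode="nearest") * px_um
        d_mem[idx] = ndi.map_coordinates(edt_mem, coords, order=1, mode="nearest") * px_um

    rel["d_nuc_um"] = d_nuc
    rel["d_mem_um"] = d_mem
    valid = ~np.isnan(d_nuc)
    rel["rel_dist_pct"] = np.nan
    if valid.any():
        rel.loc[valid, "rel_dist_pct"] = relative_distance(d_nuc[valid], d_mem[valid])
    rel["nucleus_flag"] = flag
    return rel.drop(columns=["centroid_r", "centroid_c"])
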