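"""Parent-child assignment of organelles to cells and per-cell aggregation.

Each organelle gets exactly one parent cell: the cell under its centroid
pixel, falling back to the cell with maximal pixel overlap when the
centroid lands on background (ties to the lower cell label).  Organelles
overlapping no cell keep parent 0; they are excluded from per-cell
statistics but always counted, never silently dropped.

Reporting is two-level: per-cell summaries (the default statistical unit
for group comparisons) and a pooled per-organelle view for single-organelle
analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure

from .core import LabelImage

__all__ = ["assign_parents", "summarize"]


def assign_parents(organelles: LabelImage, cells: LabelImage) -> pd.DataFrame:
    """Assign each organelle to a cell.

    Returns a table with ``organelle_label`` and ``cell_label`` (0 =
    unassigned).  Rule: cell label at the organelle's centroid pixel
    (rounded to the nearest pixel); if that pixel is background, the cell
    with maximal pixel overlap; ties toward the lower cell label.
    """
    if organelles.shape != cells.shape:
        raise ValueError("organelle and cell label dimensions differ")
    cell_lab = cells.labels
    rows = []
    for rp in measure.regionprops(organelles.labels):
        r = int(round(rp.centroid[0]))
        c = int(round(rp.centroid[1]))
        r = min(max(r, 0), cell_lab.shape[0] - 1)
        c = min(max(c, 0), cell_lab.shape[1] - 1)
        parent = int(cell_lab[r, c])
        if parent == 0:
            overlap = cell_lab[tuple(rp.coords.T)]
            overlap = overlap[overlap > 0]
            if overlap.size:
                counts = np.bincount(overlap)
                # argmax returns the first (lowest) label on ties
                parent = int(counts.argmax())
        rows.append({"organelle_label": int(rp.label), "cell_label": parent})
    return pd.DataFrame(rows, columns=["organelle_label", "cell_label"])


def summarize(
    relations: pd.DataFrame,
    organelles: pd.DataFrame,
    cells: pd.DataFrame,
    image_id: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate organelle measurements per cell and per image.

    Parameters
    ----------
    relations
        Per-organelle table with ``organelle_label``, ``cell_label`` and
        (optionally) distance columns from :func:`~orgprof.morphometry.edge_distances`.
    organelles, cells
        Shape tables from :func:`~orgprof.morphometry.measure_shape`.

    Returns
    -------
    per_cell : DataFrame
        One row per cell: area, organelle count, and means of organelle
        length (max Feret), eccentricity, and relative distance over its
        assigned organelles; means are missing for cells with 0 organelles.
    per_image : DataFrame
        One row: cell count, organelle totals (assigned and unassigned),
        and grand means over cells.
    """
    org = relations.merge(
        organelles[["label", "max_feret_um", "eccentricity"]],
        left_on="organelle_label",
        right_on="label",
        how="left",
    ).drop(columns="label")

    per_cell = cells[["label", "area_um2"]].rename(
        columns={"label": "cell_label", "area_um2": "cell_area_um2"}
    ).copy()
    assigned = org[org["cell_label"] > 0]
    agg_spec = {"organelle_count": ("organelle_label", "size"),
                "mean_length_um": ("max_feret_um", "mean"),
                "mean_eccentricity": ("eccentricity", "mean")}
    if "rel_dist_pct" in org.columns:
        agg_spec["mean_rel_dist_pct"] = ("rel_dist_pct", "mean")
    grouped = assigned.groupby("cell_label").agg(**agg_spec).reset_index()
    per_cell = per_cell.merge(grouped, on="cell_label", how="left")
    per_cell["organelle_count"] = per_cell["organelle_count"].fillna(0).astype(int)
    per_cell.insert(0, "image_id", image_id)

    n_unassigned = int((relations["cell_label"] == 0).sum())
    per_image = pd.DataFrame(
        [
            {
                "image_id": image_id,
                "cell_count": len(cells),
                "organelle_count": len(relations),
                "organelles_assigned": len(relations) - n_unassigned,
                "organelles_unassigned": n_unassigned,
                "mean_organelles_per_cell": per_cell["organelle_count"].mean()
                if len(per_cell)
                else np.nan,
                "mean_length_um": per_cell["mean_length_um"].mean(),
                "mean_eccentricity": per_cell["mean_eccentricity"].mean(),
                "mean_rel_dist_pct": per_cell["mean_rel_dist_pct"].mean()
                if "mean_rel_dist_pct" in per_cell.columns
                else np.nan,
            }
        ]
    )
    return per_cell, per_image
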