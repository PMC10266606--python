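"""End-to-end orchestration of the organelle-profiling pipeline.

One :class:`PipelineConfig` describes one batch; the same resolved
configuration is applied to every image (acquisition and analysis
parameters must be constant across compared images, so the run writes the
fully-resolved config next to the outputs for provenance).

Per image the organelle pass (``run_op``) does:

    read -> smooth nuclei -> identify nuclei -> smooth membrane ->
    propagate cells from nucleus seeds -> tertiary membrane band ->
    rescale + enhance organelle channel -> identify organelles ->
    measure shape/intensity -> relate organelles to cells ->
    nucleus/edge distances -> per-cell and per-image summaries ->
    CSV export + QC overlay.

The content pass (``run_ocp``) additionally expands the organelle labels
(default 2 px), splits each cell into inside/outside-organelle masks on
the content channel, and appends mean-in / mean-out / corrected columns
to the per-cell table.  Content intensities are measured on the raw
(bit-depth-normalized) channel; full-range rescaling is applied only for
QC display, so reported A.U. values stay comparable across images.

Failure policy is skip-and-report: a corrupt image is logged and skipped,
the batch continues, and the run summary carries the failure count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .content import ContentParams, measure_content
from .core import ChannelRole, IntensityImage, LabelImage, LabelKind, MultiChannelImage
from .enhancement import (
    DEFAULT_NEURITE_ANGLE_STEP_DEG,
    EnhanceParams,
    enhance_organelles,
    smooth,
)
from .io import read_image, rescale_full_range, write_overlay, write_tables
from .morphometry import edge_distances, measure_intensity, measure_shape
from .relations import assign_parents, summarize
from .segmentation import (
    SegmentationParams,
    identify_primary,
    identify_secondary_propagation,
    identify_tertiary_membrane,
    threshold_global,
)

logger = logging.getLogger("orgprof")

__all__ = ["PipelineConfig", "ImageResult", "BatchResult", "process_image", "run_op", "run_ocp"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters for one batch.

    Defaults are tuned for the bundled synthetic monolayer fields; real
    data generally needs per-dataset adjustment of smoothing, thresholds
    and diameter ranges (over- vs under-segmentation trade-off).
    """

    channel_map: dict = field(
        default_factory=lambda: {0: "nuclei", 1: "membrane", 2: "organelle"}
    )
    pixel_size_um: "float | str" = "from-metadata"
    projection: "str | None" = None

    nuclei_smooth_sigma_px: float = 2.0
    membrane_smooth_sigma_px: float = 2.0
    enhancement: EnhanceParams = field(default_factory=EnhanceParams)

    nuclei: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(diameter_range_px=(10.0, 80.0))
    )
    organelles: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(diameter_range_px=(3.0, 40.0))
    )
    propagation_lambda: float = 0.05
    cell_foreground: str = "all"  # "all" or "threshold"
    membrane_width_px: int = 3
    content: ContentParams = field(default_factory=ContentParams)

    write_overlays: bool = True

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def _plain(x):
            if isinstance(x, dict):
                return {k: _plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_plain(v) for v in x]
            if isinstance(x, np.floating):
                return float(x)
            if isinstance(x, np.integer):
                return int(x)
            return x

        d = _plain(dataclasses.asdict(self))
        d["channel_map"] = {int(k): str(ChannelRole(v).value) for k, v in self.channel_map.items()}
        return d

    def to_yaml(self, path: "str | Path") -> Path:
        path = Path(path)
        doc = {"orgprof_version": __version__, "pipeline": self.to_dict()}
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("enhancement", EnhanceParams),
            ("nuclei", SegmentationParams),
            ("organelles", SegmentationParams),
            ("content", ContentParams),
        ):
            if key in d and isinstance(d[key], dict):
                block = dict(d[key])
                for tup_key in ("threshold_bounds", "diameter_range_px", "neurite_angles_deg"):
                    if tup_key in block and isinstance(block[tup_key], list):
                        block[tup_key] = tuple(block[tup_key])
                d[key] = sub(**block)
        if "channel_map" in d:
            d["channel_map"] = {int(k): str(v) for k, v in d["channel_map"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        block = doc.get("pipeline", doc) if isinstance(doc, dict) else {}
        return cls.from_dict(block)


@dataclass
class ImageResult:
    """All per-image artifacts of one pipeline pass."""

    image_id: str
    nuclei: LabelImage
    cells: LabelImage
    membrane: LabelImage
    organelles: LabelImage
    per_organelle: pd.DataFrame
    per_cell: pd.DataFrame
    per_image: pd.DataFrame
    qc: dict


@dataclass
class BatchResult:
    results: list
    per_image: pd.DataFrame
    per_cell: pd.DataFrame
    per_organelle: pd.DataFrame
    failures: dict
    exit_code: int


def process_image(
    image: MultiChannelImage, config: PipelineConfig, with_content: bool = False
) -> ImageResult:
    """Run the full single-image pipeline on an in-memory image."""
    px_um = image.pixel_size_um

    nuc_sm = smooth(image[ChannelRole.NUCLEI], config.nuclei_smooth_sigma_px)
    nuclei = identify_primary(nuc_sm, config.nuclei, kind=LabelKind.NUCLEUS)
    if nuclei.n_objects == 0:
        empty = nuclei.with_labels(np.zeros(image.shape, dtype=np.int32))
        return _empty_result(image, empty)

    mem_sm = smooth(image[ChannelRole.MEMBRANE], config.membrane_smooth_sigma_px)
    if config.cell_foreground == "all":
        fg = "all"
    elif config.cell_foreground == "threshold":
        fg = threshold_global(mem_sm, method="otsu")
    else:
        raise ValueError(f"unknown cell_foreground mode {config.cell_foreground!r}")
    cells = identify_secondary_propagation(
        nuclei, mem_sm, lam=config.propagation_lambda, foreground=fg
    )
    membrane = identify_tertiary_membrane(cells, config.membrane_width_px)

    org_rescaled = rescale_full_range(image[ChannelRole.ORGANELLE])
    org_enhanced = enhance_organelles(org_rescaled, config.enhancement)
    organelles = identify_primary(org_enhanced, config.organelles, kind=LabelKind.ORGANELLE)

    cells_shape = measure_shape(cells)
    org_shape = measure_shape(organelles)
    org_intensity = measure_intensity(organelles, org_rescaled, channel_name="organelle")

    relations = assign_parents(organelles, cells)
    relations = edge_distances(org_shape, nuclei, cells, relations)
    per_cell, per_image = summarize(relations, org_shape, cells_shape, image.image_id)

    per_organelle = (
        org_shape.rename(columns={"label": "organelle_label"})
        .merge(relations, on="organelle_label", how="left")
        .merge(
            org_intensity.rename(columns={"label": "organelle_label"}),
            on="organelle_label",
            how="left",
        )
    )
    per_organelle.insert(0, "image_id", image.image_id)
    order = [
        "image_id", "organelle_label", "cell_label", "area_um2", "eccentricity",
        "max_feret_um", "d_nuc_um", "d_mem_um", "rel_dist_pct",
        "mean_intensity_organelle",
    ]
    rest = [c for c in per_organelle.columns if c not in order]
    per_organelle = per_organelle[order + rest]

    qc = {
        "image_id": image.image_id,
        "organelles_unassigned": int((relations["cell_label"] == 0).sum()),
        "cells_with_nucleus_flag": sorted(
            int(c) for c in relations.loc[relations["nucleus_flag"], "cell_label"].unique()
        ),
    }

    if with_content:
        if ChannelRole.CONTENT not in image:
            raise ValueError(
                f"{image.image_id}: content pass requested but no content channel is mapped"
            )
        content_df = measure_content(
            image[ChannelRole.CONTENT],
            organelles,
            cells,
            nuclei=nuclei,
            params=config.content,
        )
        per_cell = per_cell.merge(content_df, on="cell_label", how="left")

    return ImageResult(
        image_id=image.image_id,
        nuclei=nuclei,
        cells=cells,
        membrane=membrane,
        organelles=organelles,
        per_organelle=per_organelle,
        per_cell=per_cell,
        per_image=per_image,
        qc=qc,
    )


def _empty_result(image: MultiChannelImage, empty: LabelImage) -> ImageResult:
    """Valid zero-object result for blank fields."""
    per_image = pd.DataFrame(
        [
            {
                "image_id": image.image_id, "cell_count": 0, "organelle_count": 0,
                "organelles_assigned": 0, "organelles_unassigned": 0,
                "mean_organelles_per_cell": np.nan, "mean_length_um": np.nan,
                "mean_eccentricity": np.nan, "mean_rel_dist_pct": np.nan,
            }
        ]
    )
    cols_cell = ["image_id", "cell_label", "cell_area_um2", "organelle_count",
                 "mean_length_um", "mean_eccentricity", "mean_rel_dist_pct"]
    cols_org = ["image_id", "organelle_label", "cell_label", "area_um2", "eccentricity",
                "max_feret_um", "d_nuc_um", "d_mem_um", "rel_dist_pct",
                "mean_intensity_organelle"]
    return ImageResult(
        image_id=image.image_id,
        nuclei=empty,
        cells=empty.with_labels(empty.labels, kind=LabelKind.CELL),
        membrane=empty.with_labels(empty.labels, kind=LabelKind.MEMBRANE),
        organelles=empty.with_labels(empty.labels, kind=LabelKind.ORGANELLE),
        per_organelle=pd.DataFrame(columns=cols_org),
        per_cell=pd.DataFrame(columns=cols_cell),
        per_image=per_image,
        qc={"image_id": image.image_id, "organelles_unassigned": 0,
            "cells_with_nucleus_flag": []},
    )


def _run_batch(
    config: PipelineConfig,
    inputs: Sequence,
    out_dir: "str | Path | None",
    with_content: bool,
) -> BatchResult:
    out = Path(out_dir) if out_dir is not None else None
    results: list[ImageResult] = []
    failures: dict[str, str] = {}
    for item in inputs:
        try:
            if isinstance(item, MultiChannelImage):
                image = item
            else:
                image = read_image(
                    item,
                    channel_map=config.channel_map,
                    pixel_size_um=config.pixel_size_um,
                    projection=config.projection,
                )
            results.append(process_image(image, config, with_content=with_content))
            if out is not None and config.write_overlays:
                res = results[-1]
                write_overlay(
                    rescale_full_range(image[ChannelRole.ORGANELLE]),
                    res.nuclei, res.cells, res.organelles,
                    out / "overlays" / f"{res.image_id}.png",
                )
        except Exception as exc:  # noqa: BLE001 - skip-and-report per image
            key = getattr(item, "image_id", str(item))
            logger.error("image %s failed: %s", key, exc)
            failures[key] = str(exc)

    def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
        frames = [f for f in frames if not f.empty]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    per_image = _concat([r.per_image for r in results])
    per_cell = _concat([r.per_cell for r in results])
    per_organelle = _concat([r.per_organelle for r in results])

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_tables(per_image, per_cell, per_organelle, out)
        config.to_yaml(out / "resolved_config.yaml")
        qc_log = {"failures": failures, "images": [r.qc for r in results]}
        (out / "qc_log.json").write_text(json.dumps(qc_log, indent=2, sort_keys=True))

    exit_code = 0 if not failures else 2
    return BatchResult(
        results=results,
        per_image=per_image,
        per_cell=per_cell,
        per_organelle=per_organelle,
        failures=failures,
        exit_code=exit_code,
    )


def run_op(
    config: PipelineConfig,
    inputs: Sequence,
    out_dir: "str | Path | None" = None,
) -> BatchResult:
    """Organelle-profiling pass over a batch of TIFF paths or in-memory images."""
    if not inputs:
        raise ValueError("run_op needs at least one image")
    return _run_batch(config, inputs, out_dir, with_content=False)


def run_ocp(
    config: PipelineConfig,
    inputs: Sequence,
    out_dir: "str | Path | None" = None,
) -> BatchResult:
    """Content-profiling pass: everything ``run_op`` does plus in/out content columns."""
    if not inputs:
        raise ValueError("run_ocp needs at least one image")
    return _run_batch(config, inputs, out_dir, with_content=True)
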