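"""Object identification: nuclei, cells, membranes, organelles.

The segmentation hierarchy follows the primary/secondary/tertiary scheme
common in cell image analysis:

* **primary** objects (nuclei, organelles) come from a global threshold on
  a filtered channel, with optional shape-based declumping;
* **secondary** objects (cells) grow outward from the nucleus seeds by
  seeded propagation on the smoothed membrane channel, stopping where a
  competing seed arrives at lower accumulated cost;
* **tertiary** objects (membranes) are the band of each cell within a
  fixed distance of its boundary.

Propagation cost: a step from pixel p to an 8-neighbor q costs
``sqrt((I(p) - I(q))**2 + lambda**2 * s**2)`` where ``s`` is the Euclidean
step length (1 or sqrt(2)).  Each foreground pixel takes the label of the
seed with minimal accumulated path cost; exact ties go to the lower seed
label.  With a constant guide this reduces to a (chamfer-metric) Voronoi
partition of the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import filters, measure, morphology
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .core import IntensityImage, LabelImage, LabelKind

__all__ = [
    "SegmentationParams",
    "threshold_global",
    "identify_primary",
    "identify_secondary_propagation",
    "identify_tertiary_membrane",
    "expand_labels",
]

# 8-connected neighborhood offsets with Euclidean step lengths.
_SQRT2 = float(np.sqrt(2.0))
_NEIGHBORS = [
    (-1, -1, _SQRT2), (-1, 0, 1.0), (-1, 1, _SQRT2),
    (0, -1, 1.0), (0, 1, 1.0),
    (1, -1, _SQRT2), (1, 0, 1.0), (1, 1, _SQRT2),
]


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters for primary object identification.

    ``diameter_range_px`` filters labeled components by equivalent
    diameter (diameter of the circle with the same pixel count), inclusive
    at both ends.  ``declump="shape"`` splits touching objects by a
    watershed on the smoothed distance transform, seeded at local maxima
    at least ``d_min`` apart.
    """

    threshold_method: str = "otsu"
    threshold_correction: float = 1.0
    threshold_bounds: tuple[float, float] = (0.0, 1.0)
    manual_threshold: float | None = None
    diameter_range_px: tuple[float, float] = (2.0, 100.0)
    declump: str = "none"
    discard_border: bool = False

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "robust_background", "manual"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if not (self.threshold_correction > 0):
            raise ValueError("threshold_correction must be > 0")
        lo, hi = self.threshold_bounds
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"threshold_bounds must satisfy 0 <= lo <= hi <= 1, got {self.threshold_bounds}")
        d_min, d_max = self.diameter_range_px
        if not (d_min < d_max):
            raise ValueError("diameter_range_px must satisfy d_min < d_max")
        if self.declump not in ("none", "shape"):
            raise ValueError(f"unknown declump mode {self.declump!r}")


def _robust_background_threshold(px: np.ndarray, trim: float = 0.05, n_sd: float = 2.0) -> float:
    """Mean + 2 SD of the intensity distribution after trimming 5% tails."""
    flat = np.sort(px.ravel())
    k = int(trim * flat.size)
    core = flat[k: flat.size - k] if flat.size - 2 * k > 0 else flat
    return float(core.mean() + n_sd * core.std())


def threshold_global(
    img: IntensityImage,
    method: str = "otsu",
    correction: float = 1.0,
    bounds: tuple[float, float] = (0.0, 1.0),
    manual_value: float | None = None,
) -> np.ndarray:
    """Global threshold: ``t = method(img) * correction`` clipped to bounds.

    Returns the boolean mask ``img > t``.  A constant image yields an
    empty mask (nothing exceeds its own value).
    """
    px = img.pixels
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual threshold method requires manual_value")
        t = float(manual_value)
    elif method == "otsu":
        if px.max() == px.min():
            t = float(px.max())
        else:
            t = float(filters.threshold_otsu(px, nbins=256))
    elif method == "robust_background":
        t = _robust_background_threshold(px)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    t = float(np.clip(t * correction, bounds[0], bounds[1]))
    return px > t


def _renumber_raster(labels: np.ndarray) -> np.ndarray:
    """Relabel 1..N by raster order of each object's first pixel."""
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    pos = ids > 0
    order = ids[pos][np.argsort(first[pos])]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[order] = np.arange(1, order.size + 1, dtype=np.int32)
    return remap[labels]


def _declump_shape(mask: np.ndarray, d_min: float) -> np.ndarray:
    """Split touching convex objects by watershed on the smoothed EDT."""
    edt = ndi.distance_transform_edt(mask)
    sm = ndi.gaussian_filter(edt, sigma=max(1.0, d_min / 4.0))
    min_dist = max(1, int(np.ceil(d_min)))
    peaks = peak_local_max(sm, min_distance=min_dist, labels=measure.label(mask, connectivity=2), exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return measure.label(mask, connectivity=2)
    return watershed(-sm, markers=markers, mask=mask, connectivity=2)


def identify_primary(
    img: IntensityImage,
    params: SegmentationParams,
    kind: LabelKind = LabelKind.NUCLEUS,
) -> LabelImage:
    """Threshold, fill holes, declump, label, and size-filter one channel.

    Pipeline: global threshold -> fill holes -> optional shape declump ->
    8-connected labeling -> remove components with equivalent diameter
    outside ``diameter_range_px`` -> optionally remove border-touching
    objects -> renumber 1..N in raster order of first pixel.  Zero objects
    is a valid outcome, not an error.
    """
    mask = threshold_global(
        img,
        method=params.threshold_method,
        correction=params.threshold_correction,
        bounds=params.threshold_bounds,
        manual_value=params.manual_threshold,
    )
    mask = ndi.binary_fill_holes(mask)
    if params.declump == "shape":
        labels = _declump_shape(mask, params.diameter_range_px[0])
    else:
        labels = measure.label(mask, connectivity=2)

    d_min, d_max = params.diameter_range_px
    counts = np.bincount(labels.ravel())
    eq_diam = np.sqrt(4.0 * counts / np.pi)
    bad = (eq_diam < d_min) | (eq_diam > d_max)
    bad[0] = False
    if bad.any():
        labels = np.where(bad[labels], 0, labels)

    if params.discard_border:
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        border = border[border > 0]
        if border.size:
            labels = np.where(np.isin(labels, border), 0, labels)

    return LabelImage(
        labels=_renumber_raster(labels), kind=kind, pixel_size_um=img.pixel_size_um
    )


# ---------------------------------------------------------------------------
# Seeded propagation (secondary objects)
# ---------------------------------------------------------------------------

def _shift_slices(dr: int, dc: int, shape: tuple[int, int]):
    """Slices (src, dst) so that dst[...] receives values moved by (dr, dc)."""
    H, W = shape
    rs = slice(max(-dr, 0), H + min(-dr, 0))
    rd = slice(max(dr, 0), H + min(dr, 0))
    cs = slice(max(-dc, 0), W + min(-dc, 0))
    cd = slice(max(dc, 0), W + min(dc, 0))
    return (rs, cs), (rd, cd)


def identify_secondary_propagation(
    seeds: LabelImage,
    guide: IntensityImage,
    lam: float = 0.05,
    foreground: "np.ndarray | str" = "all",
) -> LabelImage:
    """Grow cell labels outward from nucleus seeds on a guide image.

    Every foreground pixel receives the label of the seed reaching it with
    minimal accumulated path cost, where a step between 8-neighbors p -> q
    costs ``sqrt((I(p)-I(q))**2 + lam**2 * s**2)`` (``s`` = 1 or sqrt(2)).
    Exact cost ties are broken toward the lower seed label; seed pixels
    always keep their own label.

    Implemented as vectorized label-correcting relaxation iterated to its
    fixed point, which is the lexicographic (cost, label) minimum over all
    paths — identical to a Dijkstra solution with the same tie rule.

    Parameters
    ----------
    foreground
        ``"all"`` to label every pixel (confluent monolayer), or a boolean
        mask restricting the cells (sparse cultures); seed pixels are
        always part of the foreground.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if seeds.shape != guide.shape:
        raise ValueError("seeds and guide dimensions differ")
    seed_lab = seeds.labels
    if seed_lab.max() == 0:
        raise ValueError("no seeds to propagate from")
    shape = seed_lab.shape
    if isinstance(foreground, str):
        if foreground != "all":
            raise ValueError(f"unknown foreground mode {foreground!r}")
        fg = np.ones(shape, dtype=bool)
    else:
        fg = np.asarray(foreground, dtype=bool) | (seed_lab > 0)

    g = guide.pixels
    dist = np.full(shape, np.inf)
    label = np.zeros(shape, dtype=np.int32)
    is_seed = seed_lab > 0
    dist[is_seed] = 0.0
    label[is_seed] = seed_lab[is_seed]

    # Per-shift edge costs are constant across iterations: precompute.
    edges = []
    for dr, dc, s in _NEIGHBORS:
        (rs_, cs_), (rd_, cd_) = _shift_slices(dr, dc, shape)
        cost = np.sqrt((g[rs_, cs_] - g[rd_, cd_]) ** 2 + (lam * s) ** 2)
        # disallow steps into or out of non-foreground pixels
        cost = np.where(fg[rs_, cs_] & fg[rd_, cd_], cost, np.inf)
        edges.append(((rs_, cs_), (rd_, cd_), cost))

    frozen = is_seed  # seeds never change hands
    for _ in range(shape[0] * shape[1]):
        updated = False
        for (rs_, cs_), (rd_, cd_), cost in edges:
            src_d = dist[rs_, cs_]
            nd = src_d + cost
            nl = label[rs_, cs_]
            d = dist[rd_, cd_]
            l = label[rd_, cd_]
            finite = np.isfinite(nd)
            better = finite & ((nd < d) | ((nd == d) & (nl < l))) & ~frozen[rd_, cd_]
            if better.any():
                d[better] = nd[better]
                l[better] = nl[better]
                dist[rd_, cd_] = d
                label[rd_, cd_] = l
                updated = True
        if not updated:
            break

    label[~fg] = 0
    return LabelImage(labels=label, kind=LabelKind.CELL, pixel_size_um=guide.pixel_size_um)


def identify_tertiary_membrane(cells: LabelImage, width_px: int = 3) -> LabelImage:
    """Per-cell membrane band: cell pixels within ``width_px`` of the cell boundary.

    Equivalent to cell minus its Euclidean erosion by ``width_px``; the
    image edge and interfaces with neighboring cells both count as
    boundary.  Each band keeps its cell's label.
    """
    if width_px < 1:
        raise ValueError(f"width_px must be >= 1, got {width_px}")
    lab = cells.labels
    out = np.zeros_like(lab)
    objects = ndi.find_objects(lab)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = np.pad(lab[sl] == idx, 1)
        edt = ndi.distance_transform_edt(mask)
        band = mask & (edt <= width_px)
        out[sl][band[1:-1, 1:-1]] = idx
    return cells.with_labels(out, kind=LabelKind.MEMBRANE)


def expand_labels(labels: LabelImage, n_px: int) -> LabelImage:
    """Dilate each label into background by Euclidean distance ``n_px``.

    Background pixels within distance ``n_px`` of any object take the
    label of the nearest object pixel; exact distance ties (compared on
    integer squared distances) go to the lower label.  Existing labels are
    never overwritten and distinct labels never merge.
    """
    if n_px < 0:
        raise ValueError(f"n_px must be >= 0, got {n_px}")
    lab = labels.labels
    out = lab.copy()
    if n_px == 0 or lab.max() == 0:
        return labels.with_labels(out)

    fg = lab > 0
    dist = ndi.distance_transform_edt(~fg)
    cand = (~fg) & (dist <= n_px + 1e-9)
    if not cand.any():
        return labels.with_labels(out)

    fg_coords = np.argwhere(fg)
    fg_labels = lab[fg]
    tree = cKDTree(fg_coords)
    q = np.argwhere(cand)

    n_fg = fg_coords.shape[0]
    k = min(8, n_fg)
    while True:
        d, idx = tree.query(q, k=k)
        if k == 1:
            d, idx = d[:, None], idx[:, None]
        # exact integer squared distances for tie comparison
        diff = fg_coords[idx] - q[:, None, :]
        sq = (diff ** 2).sum(axis=2)
        min_sq = sq.min(axis=1, keepdims=True)
        if k < n_fg and np.any(sq[:, -1] == min_sq[:, 0]):
            k = min(2 * k, n_fg)
            continue
        cand_labels = np.where(sq == min_sq, fg_labels[idx], np.iinfo(np.int32).max)
        chosen = cand_labels.min(axis=1)
        break

    within = min_sq[:, 0] <= n_px * n_px
    rows, cols = q[within, 0], q[within, 1]
    out[rows, cols] = chosen[within]
    return labels.with_labels(out)
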