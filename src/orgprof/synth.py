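"""Synthetic confluent-monolayer fields with full ground truth.

The generator emulates the imaging regime the pipeline is built for: a
confluent endothelial monolayer where every pixel belongs to some cell,
each cell holds one elliptical nucleus, a junctional membrane stain forms
a ridge along every cell-cell border, and the organelle channel shows
rod-shaped ("cigar-shaped") secretory organelles rendered as capsules
(rectangle plus semicircular caps).  An optional content channel carries a
secondary marker at a set level inside the organelles (plus a small halo,
emulating a membrane-bound marker) and a lower cytoplasmic level outside.

All channels are rendered in [0, 1], blurred by a Gaussian PSF, and
corrupted with additive Gaussian noise clipped at zero.  Ground truth
(cell tessellation, nucleus parameters, per-organelle center/orientation/
length/eccentricity/radial position, content levels) is recorded before
blur and noise, so every pipeline stage can be validated by parameter
recovery.

The capsule's moment-ellipse eccentricity has a closed form
(:func:`capsule_eccentricity`); group presets therefore accept a target
eccentricity and solve for the capsule width at the mean length.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .core import ChannelRole, IntensityImage, LabelImage, LabelKind, MultiChannelImage

__all__ = [
    "SynthParams",
    "SyntheticGroundTruth",
    "TwoGroupExperiment",
    "capsule_eccentricity",
    "capsule_width_for_eccentricity",
    "generate_field",
    "make_two_group_experiment",
    "group1_wpb_params",
    "group3_wpb_params",
    "nocodazole_control_params",
    "nocodazole_treated_params",
    "content_experiment_params",
]


# ---------------------------------------------------------------------------
# Capsule geometry
# ---------------------------------------------------------------------------

def _capsule_moments(length: float, width: float) -> tuple[float, float, float]:
    """(area, Ix, Iy) of a capsule: axis-aligned, tip-to-tip ``length``.

    ``a`` is the half-length of the rectangular body, ``r`` the cap
    radius; second area moments are about the centroid, x along the long
    axis.
    """
    r = width / 2.0
    a = max((length - width) / 2.0, 0.0)
    area = 4.0 * a * r + np.pi * r ** 2
    ix = (4.0 / 3.0) * a ** 3 * r + np.pi * a ** 2 * r ** 2 \
        + (8.0 / 3.0) * a * r ** 3 + np.pi * r ** 4 / 4.0
    iy = (4.0 / 3.0) * a * r ** 3 + np.pi * r ** 4 / 4.0
    return area, ix, iy


def capsule_eccentricity(length: float, width: float) -> float:
    """Moment-ellipse eccentricity of a capsule, in closed form.

    The eccentricity of the ellipse with the same second central moments:
    ``sqrt(1 - Iy/Ix)``.  0 for ``length <= width`` (a disk).
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if length <= width:
        return 0.0
    _, ix, iy = _capsule_moments(length, width)
    return float(np.sqrt(1.0 - iy / ix))


def capsule_width_for_eccentricity(length: float, ecc: float) -> float:
    """Capsule width giving the requested moment eccentricity at ``length``."""
    if not (0 < ecc < 1):
        raise ValueError("target eccentricity must be in (0, 1)")
    return float(
        brentq(lambda w: capsule_eccentricity(length, w) - ecc, 1e-6 * length, length * (1 - 1e-9))
    )


# ---------------------------------------------------------------------------
# Parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthParams:
    """Full specification of one synthetic field.

    Exactly one of ``width_um`` / ``eccentricity_target`` must be given;
    a target eccentricity is converted to a capsule width at the mean
    length.  ``organelles_per_cell`` is (mean, dispersion): dispersion 0
    gives exactly ``round(mean)`` per cell, otherwise counts are
    gamma-Poisson with variance ``mean + dispersion * mean**2``.
    """

    field_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    n_cells: int = 12
    nucleus_axes_um: tuple[float, float] = (1.6, 1.1)  # semi-axes (a, b)
    membrane_width_px: int = 2
    organelles_per_cell: tuple[float, float] = (6.0, 0.0)
    length_um_mean: float = 1.38
    length_um_sd: float = 0.21
    length_um_min: float = 0.3
    width_um: float | None = None
    eccentricity_target: float | None = 0.78
    radial_fraction_range: tuple[float, float] = (0.35, 0.9)
    content_levels: tuple[float, float] | None = None  # (mu_in, mu_out)
    content_halo_px: int = 2
    psf_sigma_px: float = 0.5
    noise_sigma: float = 0.01
    allow_overlap: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if (self.width_um is None) == (self.eccentricity_target is None):
            raise ValueError("give exactly one of width_um / eccentricity_target")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        lo, hi = self.radial_fraction_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("radial_fraction_range must be within [0, 1] with lo < hi")
        if self.content_levels is not None:
            mi, mo = self.content_levels
            if not (0 <= mi <= 1 and 0 <= mo <= 1):
                raise ValueError("content levels must be within [0, 1]")

    @property
    def resolved_width_um(self) -> float:
        if self.width_um is not None:
            return self.width_um
        return capsule_width_for_eccentricity(
            self.length_um_mean, float(self.eccentricity_target)
        )


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """True generative parameters of one field, recorded pre-blur/noise."""

    cells: pd.DataFrame          # cell_id, center_r, center_c, area_px, nucleus geometry
    organelles: pd.DataFrame     # organelle_id, cell_id, center, theta, length/width/ecc, radial_fraction
    cell_labels: LabelImage
    nucleus_labels: LabelImage
    organelle_labels: LabelImage
    content_levels: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------

def _poisson_disk_centers(
    rng: np.random.Generator, shape: tuple[int, int], n: int, margin: float
) -> np.ndarray:
    """Dart-throwing sampler: n centers with pairwise separation enforced."""
    H, W = shape
    min_sep = 0.58 * np.sqrt(H * W / n)
    for _ in range(200):  # relax separation if packing fails
        pts: list[np.ndarray] = []
        for _ in range(20000):
            if len(pts) == n:
                break
            cand = np.array(
                [rng.uniform(margin, H - margin), rng.uniform(margin, W - margin)]
            )
            if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
                pts.append(cand)
        if len(pts) == n:
            arr = np.array(pts)
            order = np.lexsort((arr[:, 1], arr[:, 0]))  # raster order of centers
            return arr[order]
        min_sep *= 0.9
    raise RuntimeError(f"could not place {n} cell centers in field {shape}")


def _segment_distance(
    rr: np.ndarray, cc: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    """Distance from pixel centers (rr, cc) to the segment p0-p1."""
    d = p1 - p0
    len2 = float(d @ d)
    vr, vc = rr - p0[0], cc - p0[1]
    if len2 == 0:
        return np.hypot(vr, vc)
    t = np.clip((vr * d[0] + vc * d[1]) / len2, 0.0, 1.0)
    return np.hypot(vr - t * d[0], vc - t * d[1])


def _render_capsule(
    shape: tuple[int, int], center: np.ndarray, theta: float, length_px: float, width_px: float
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """(anti-aliased intensities, hard mask, bbox slices) for one capsule."""
    r = width_px / 2.0
    h = max((length_px - width_px) / 2.0, 0.0)
    u = np.array([np.sin(theta), np.cos(theta)])  # (dr, dc); theta from +col axis
    p0, p1 = center - h * u, center + h * u
    pad = int(np.ceil(r)) + 2
    r0 = max(int(np.floor(min(p0[0], p1[0]))) - pad, 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]))) + pad + 1, shape[0])
    c0 = max(int(np.floor(min(p0[1], p1[1]))) - pad, 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]))) + pad + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = _segment_distance(rr.astype(float), cc.astype(float), p0, p1)
    aa = np.clip(r + 0.5 - dist, 0.0, 1.0)
    hard = dist <= r
    return aa, hard, (slice(r0, r1), slice(c0, c1))


def _ray_extent(mask: np.ndarray, center: np.ndarray, phi: float) -> float:
    """Length of the ray from center to the cell boundary along phi."""
    H, W = mask.shape
    step = np.array([np.sin(phi), np.cos(phi)])
    t = 0.0
    while True:
        p = center + (t + 1.0) * step
        r, c = int(round(p[0])), int(round(p[1]))
        if not (0 <= r < H and 0 <= c < W) or not mask[r, c]:
            return t
        t += 1.0
        if t > H + W:
            return t


def _sample_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return int(round(mean))
    shape_k = 1.0 / dispersion
    lam = rng.gamma(shape_k, mean / shape_k)
    return int(rng.poisson(lam))


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float, lower: float) -> float:
    for _ in range(10000):
        x = rng.normal(mu, sd)
        if x > lower:
            return float(x)
    raise RuntimeError("truncated normal sampling failed; check parameters")


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------

def generate_field(params: SynthParams) -> tuple[MultiChannelImage, SyntheticGroundTruth]:
    """Render one synthetic multi-channel field plus its ground truth.

    The same seed always produces bit-identical images.  Raises if the
    requested organelle load cannot be placed without overlap after
    bounded retries.
    """
    rng = np.random.default_rng(params.rng_seed)
    H, W = params.field_px
    px_um = params.pixel_size_um

    nuc_a = params.nucleus_axes_um[0] / px_um
    nuc_b = params.nucleus_axes_um[1] / px_um
    margin = nuc_a + 3
    centers = _poisson_disk_centers(rng, (H, W), params.n_cells, margin)

    # cell tessellation: nearest center (Euclidean)
    tree = cKDTree(centers)
    rr, cc = np.mgrid[0:H, 0:W]
    _, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    cell_lab = (nearest + 1).reshape(H, W).astype(np.int32)

    # nuclei: ellipses at cell centers, clipped inside the eroded cell
    nuc_lab = np.zeros((H, W), dtype=np.int32)
    nuc_rows = []
    for i, (cr, ccen) in enumerate(centers, start=1):
        theta = rng.uniform(0, np.pi)
        cell_mask = cell_lab == i
        interior = ndi.binary_erosion(cell_mask, np.ones((3, 3), bool), iterations=2, border_value=0)
        dr, dc = rr - cr, cc - ccen
        x = dc * np.cos(theta) + dr * np.sin(theta)
        y = -dc * np.sin(theta) + dr * np.cos(theta)
        ell = (x / nuc_a) ** 2 + (y / nuc_b) ** 2 <= 1.0
        nuc_lab[ell & interior] = i
        nuc_rows.append(
            {
                "cell_id": i,
                "center_r": cr,
                "center_c": ccen,
                "nucleus_a_um": params.nucleus_axes_um[0],
                "nucleus_b_um": params.nucleus_axes_um[1],
                "nucleus_theta": theta,
            }
        )

    # membrane ridge on cell-cell borders and image edge
    ridge = find_boundaries(cell_lab, mode="thick", connectivity=1)
    if params.membrane_width_px > 2:
        extra = (params.membrane_width_px - 2 + 1) // 2
        ridge = ndi.binary_dilation(ridge, ndi.generate_binary_structure(2, 2), iterations=extra)

    # organelles: capsules placed on center->boundary rays
    width_um = params.resolved_width_um
    org_channel = np.zeros((H, W))
    org_lab = np.zeros((H, W), dtype=np.int32)
    occupied = np.zeros((H, W), dtype=bool)  # placed capsules dilated by the gap
    gap_px = 2
    org_rows = []
    org_id = 0
    mean_n, disp_n = params.organelles_per_cell
    for i in range(1, params.n_cells + 1):
        n_org = _sample_count(rng, mean_n, disp_n)
        cell_mask = cell_lab == i
        placeable = ndi.binary_erosion(cell_mask, np.ones((3, 3), bool), iterations=2, border_value=0)
        center = centers[i - 1]
        for _ in range(n_org):
            # length drawn once per organelle; only the pose is retried, so
            # placement rejection cannot bias the realized length
            # distribution.  Only when a length exhausts every pose is it
            # redrawn (bounded), which can truncate extreme draws in very
            # crowded fields.
            placed = False
            for _redraw in range(5):
                length_um = _truncated_normal(
                    rng, params.length_um_mean, params.length_um_sd, params.length_um_min
                )
                w_um = min(width_um, 0.95 * length_um)
                L_px, w_px = length_um / px_um, w_um / px_um
                for _attempt in range(300):
                    theta = rng.uniform(0, np.pi)
                    phi = rng.uniform(0, 2 * np.pi)
                    f = rng.uniform(*params.radial_fraction_range)
                    t_max = _ray_extent(cell_mask, center, phi)
                    pos = center + f * t_max * np.array([np.sin(phi), np.cos(phi)])
                    aa, hard, sl = _render_capsule((H, W), pos, theta, L_px, w_px)
                    if not hard.any():
                        continue
                    if not np.all(placeable[sl][hard]):
                        continue
                    if not params.allow_overlap and np.any(occupied[sl][hard]):
                        continue
                    placed = True
                    break
                if placed:
                    break
            if placed:
                org_id += 1
                np.maximum(org_channel[sl], aa, out=org_channel[sl])
                org_lab[sl][hard] = org_id
                grown = ndi.binary_dilation(
                    hard, ndi.generate_binary_structure(2, 2), iterations=gap_px
                )
                occupied[sl] |= grown
                org_rows.append(
                    {
                        "organelle_id": org_id,
                        "cell_id": i,
                        "center_r": pos[0],
                        "center_c": pos[1],
                        "theta": theta,
                        "true_length_um": length_um,
                        "true_width_um": w_um,
                        "true_eccentricity": capsule_eccentricity(L_px, w_px),
                        "radial_fraction": f,
                    }
                )
            else:
                raise RuntimeError(
                    f"could not place organelle {org_id + 1} in cell {i}: "
                    "field too crowded for the requested organelle load"
                )

    channels: dict[ChannelRole, np.ndarray] = {
        ChannelRole.NUCLEI: (nuc_lab > 0).astype(float),
        ChannelRole.MEMBRANE: ridge.astype(float),
        ChannelRole.ORGANELLE: org_channel,
    }
    if params.content_levels is not None:
        mu_in, mu_out = params.content_levels
        halo = ndi.distance_transform_edt(org_lab == 0) <= params.content_halo_px
        content = np.full((H, W), mu_out)
        content[halo | (org_lab > 0)] = mu_in
        channels[ChannelRole.CONTENT] = content

    # blur + noise, in fixed role order for determinism
    final: dict[ChannelRole, IntensityImage] = {}
    for role in ChannelRole:
        if role not in channels:
            continue
        plane = channels[role]
        if params.psf_sigma_px > 0:
            plane = ndi.gaussian_filter(plane, params.psf_sigma_px, mode="reflect")
        if params.noise_sigma > 0:
            plane = plane + rng.normal(0.0, params.noise_sigma, size=plane.shape)
        plane = np.clip(plane, 0.0, None)
        final[role] = IntensityImage(pixels=plane, pixel_size_um=px_um, role=role)

    image = MultiChannelImage(channels=final, image_id=f"synth-{params.rng_seed}")
    cells_df = pd.DataFrame(nuc_rows)
    areas = np.bincount(cell_lab.ravel(), minlength=params.n_cells + 1)
    cells_df["area_px"] = areas[1:]
    cells_df["area_um2"] = cells_df["area_px"] * px_um ** 2
    org_cols = [
        "organelle_id", "cell_id", "center_r", "center_c", "theta",
        "true_length_um", "true_width_um", "true_eccentricity", "radial_fraction",
    ]
    truth = SyntheticGroundTruth(
        cells=cells_df,
        organelles=pd.DataFrame(org_rows, columns=org_cols),
        cell_labels=LabelImage(cell_lab, LabelKind.CELL, px_um),
        nucleus_labels=LabelImage(nuc_lab, LabelKind.NUCLEUS, px_um),
        organelle_labels=LabelImage(org_lab, LabelKind.ORGANELLE, px_um),
        content_levels=params.content_levels,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Two-group experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoGroupExperiment:
    """Seeded image sets for a two-condition comparison."""

    images: dict  # group name -> list[MultiChannelImage]
    truths: dict  # group name -> list[SyntheticGroundTruth]
    truth_table: pd.DataFrame  # pooled per-organelle truth with a 'group' column


def make_two_group_experiment(
    group_a: SynthParams,
    group_b: SynthParams,
    n_images: int,
    seed: int,
    names: tuple[str, str] = ("a", "b"),
) -> TwoGroupExperiment:
    """Generate ``n_images`` fields per condition with derived per-image seeds."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) % (2 ** 31) for s in ss.generate_state(2 * n_images)]
    images: dict[str, list] = {names[0]: [], names[1]: []}
    truths: dict[str, list] = {names[0]: [], names[1]: []}
    tables = []
    for g, (name, base) in enumerate(zip(names, (group_a, group_b))):
        for j in range(n_images):
            p = dataclasses.replace(base, rng_seed=child_seeds[g * n_images + j])
            img, truth = generate_field(p)
            images[name].append(img)
            truths[name].append(truth)
            t = truth.organelles.copy()
            t.insert(0, "image_id", img.image_id)
            t.insert(0, "group", name)
            tables.append(t)
    return TwoGroupExperiment(
        images=images, truths=truths, truth_table=pd.concat(tables, ignore_index=True)
    )


# ---------------------------------------------------------------------------
# Presets: published group conditions used as simulation inputs
# ---------------------------------------------------------------------------

def group1_wpb_params(**overrides) -> SynthParams:
    """Elongated-organelle phenotype: length 1.38 ± 0.21 µm, eccentricity 0.78."""
    return SynthParams(
        length_um_mean=1.38, length_um_sd=0.21, eccentricity_target=0.78, **overrides
    )


def group3_wpb_params(**overrides) -> SynthParams:
    """Short/round phenotype: length 1.10 ± 0.27 µm, eccentricity 0.63."""
    return SynthParams(
        length_um_mean=1.10, length_um_sd=0.27, eccentricity_target=0.63, **overrides
    )


def nocodazole_control_params(**overrides) -> SynthParams:
    """Vehicle-treated condition: length 1.54 ± 0.17 µm, eccentricity 0.87."""
    return SynthParams(
        length_um_mean=1.54, length_um_sd=0.17, eccentricity_target=0.87, **overrides
    )


def nocodazole_treated_params(**overrides) -> SynthParams:
    """Microtubule-disrupted condition: length 1.17 ± 0.18 µm, eccentricity 0.76."""
    return SynthParams(
        length_um_mean=1.17, length_um_sd=0.18, eccentricity_target=0.76, **overrides
    )


def content_experiment_params(enriched: bool = True, **overrides) -> SynthParams:
    """Content-channel field for in/out quantification.

    ``enriched=True`` models an organelle-membrane marker (content level
    0.08 inside the organelle + halo, 0.05 in the cytoplasm); ``False``
    models an endoplasmic-reticulum-like marker with no organelle
    association (equal levels).  The content step is rendered sharp
    (no PSF blur) so the masking/correction arithmetic can be validated
    in isolation; blur sensitivity is a documented bias, not part of this
    scenario.
    """
    levels = (0.08, 0.05) if enriched else (0.065, 0.065)
    defaults = dict(content_levels=levels, psf_sigma_px=0.0)
    defaults.update(overrides)
    return SynthParams(
        length_um_mean=1.38, length_um_sd=0.21, eccentricity_target=0.78, **defaults
    )
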