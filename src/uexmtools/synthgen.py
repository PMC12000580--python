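"""Synthetic expanded-centriole data with known ground truth.

Renders the structures seen in U-ExM of centrioles: in side view the
tubulin wall projects to two parallel bars, in bottom view to a ring
(annulus); proximal markers are modelled as a cap (solid block at the
proximal end), a proximal ring, or a sleeve surrounding the wall.
Structures are drawn in continuous coordinates in expanded (gel) space
(biological dimensions times the expansion factor), area-sampled onto the
pixel grid, blurred with a Gaussian PSF and degraded with Poisson shot
noise, Gaussian read noise and a constant background offset.

One-dimensional ideal profiles (plateaus and two-bump ring sections) are
computed analytically — a box convolved with a Gaussian and averaged over
each pixel has a closed form — so geometry tests carry no aliasing bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr

from .profilekit import EXPANDED, ImagePlane, LineProfile
from . import cystline

__all__ = [
    "CentrioleTruth",
    "ImagingModel",
    "Pose",
    "GrowthRecord",
    "generate_profile",
    "generate_centriole_image",
    "generate_growth_series",
    "generate_cyst_counts",
    "generate_quantification_dataset",
]

MARKER_MODELS = ("cap", "proximal_ring", "sleeve", "absent")


@dataclass
class CentrioleTruth:
    """Ground-truth geometry of one centriole, in biological nm.

    Defaults follow the measured mature-centriole geometry this package
    targets: tubulin wall ~390 nm long and ~240 nm in (wall-centre)
    diameter, with a proximal marker cap ~108 nm long at matching
    diameter.  ``marker_offset_nm`` is the marker start relative to the
    proximal tubulin end and may be negative (cap protruding below the
    wall).
    """

    view: str = "side"  # "side" | "bottom"
    tubulin_length_nm: float = 390.0
    tubulin_diameter_nm: float = 240.0
    wall_thickness_nm: float = 40.0
    marker_model: str = "cap"
    marker_length_nm: float = 108.0
    marker_diameter_nm: float = 240.0
    marker_offset_nm: float = 0.0
    intensity_scale: Dict[str, float] = field(
        default_factory=lambda: {"tubulin": 1.0, "marker": 1.0}
    )

    def __post_init__(self) -> None:
        if self.view not in ("side", "bottom"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.marker_model not in MARKER_MODELS:
            raise ValueError(f"unknown marker model {self.marker_model!r}")
        if (self.marker_length_nm == 0) != (self.marker_model == "absent"):
            raise ValueError("marker_length_nm must be 0 iff marker_model is 'absent'")
        for name, v in (
            ("tubulin_length_nm", self.tubulin_length_nm),
            ("tubulin_diameter_nm", self.tubulin_diameter_nm),
            ("wall_thickness_nm", self.wall_thickness_nm),
            ("marker_diameter_nm", self.marker_diameter_nm),
        ):
            if not v > 0:
                raise ValueError(f"{name} must be positive")
        if self.marker_length_nm < 0:
            raise ValueError("marker_length_nm must be >= 0")
        for ch, s in self.intensity_scale.items():
            if not s > 0:
                raise ValueError(f"intensity_scale[{ch!r}] must be positive")


@dataclass
class ImagingModel:
    """Acquisition model: sampling, PSF, noise and gel expansion.

    ``pixel_size_nm`` and ``psf_sigma_nm`` are in expanded (gel) space.
    Noise: ``Poisson(photon_scale * ideal) + Normal(0, read_noise_sd) +
    background_offset`` in camera counts; ``shot_noise=False`` disables
    the Poisson draw (returning the scaled ideal), so noiseless renders
    are expressible.  Identical parameters and seed give bit-identical
    output.
    """

    pixel_size_nm: float = 105.0
    psf_sigma_nm: float = 60.0
    background_offset: float = 10.0
    photon_scale: float = 200.0
    read_noise_sd: float = 3.0
    expansion_factor: float = 4.0
    rng_seed: int = 0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.psf_sigma_nm < 0 or self.background_offset < 0 or self.read_noise_sd < 0:
            raise ValueError("psf_sigma_nm, background_offset, read_noise_sd must be >= 0")
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be positive")
        if not self.expansion_factor > 0:
            raise ValueError("expansion_factor must be positive")

    @property
    def noiseless(self) -> bool:
        return not self.shot_noise and self.read_noise_sd == 0


@dataclass
class Pose:
    """In-plane placement of a structure: centre (px) and angle (deg)."""

    x_px: float
    y_px: float
    angle_deg: float = 0.0


@dataclass
class GrowthRecord:
    """One procentriole of a growth series with presence ground truth."""

    truth: CentrioleTruth
    present: bool
    detectable: bool


# ---------------------------------------------------------------------------
# analytic 1D rendering
# ---------------------------------------------------------------------------


def _psi(t: np.ndarray) -> np.ndarray:
    # antiderivative of the normal CDF: psi(t) = t*Phi(t) + phi(t)
    return t * ndtr(t) + np.exp(-0.5 * t * t) / math.sqrt(2 * math.pi)


def _box_blur_integral(x: np.ndarray, a: float, b: float, sigma: float) -> np.ndarray:
    """Antiderivative at ``x`` of a unit box on [a, b] convolved with N(0, sigma)."""
    if sigma == 0:
        return np.clip(x, a, b) - a
    return sigma * (_psi((x - a) / sigma) - _psi((x - b) / sigma))


def _sample_boxes(
    centers: np.ndarray, boxes: Sequence[Tuple[float, float, float]],
    sigma: float, h: float,
) -> np.ndarray:
    """Pixel-averaged Gaussian-blurred sum of boxes (a, b, height)."""
    out = np.zeros_like(centers)
    for a, b, height in boxes:
        if b <= a:
            continue
        upper = _box_blur_integral(centers + h / 2, a, b, sigma)
        lower = _box_blur_integral(centers - h / 2, a, b, sigma)
        out += height * (upper - lower) / h
    return out


def _marker_boxes_longitudinal(t: CentrioleTruth, e: float) -> List[Tuple[float, float, float]]:
    if t.marker_model == "absent":
        return []
    scale = t.intensity_scale.get("marker", 1.0)
    a = t.marker_offset_nm * e
    return [(a, a + t.marker_length_nm * e, scale)]


def _marker_boxes_radial(t: CentrioleTruth, e: float) -> List[Tuple[float, float, float]]:
    if t.marker_model == "absent":
        return []
    scale = t.intensity_scale.get("marker", 1.0)
    rm = t.marker_diameter_nm * e / 2
    if t.marker_model == "cap":  # solid disc seen end-on
        return [(-rm, rm, scale)]
    w = t.wall_thickness_nm * e / 2
    return [(-rm - w, -rm + w, scale), (rm - w, rm + w, scale)]


def _apply_noise(ideal: np.ndarray, model: ImagingModel, rng: np.random.Generator) -> np.ndarray:
    counts = model.photon_scale * np.clip(ideal, 0, None)
    if model.shot_noise:
        counts = rng.poisson(counts).astype(float)
    if model.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, model.read_noise_sd, size=counts.shape)
    return counts + model.background_offset


def generate_profile(
    truth: CentrioleTruth,
    model: ImagingModel,
    axis: str = "longitudinal",
) -> Tuple[LineProfile, CentrioleTruth]:
    """Ideal-plus-noise line profile along or across a centriole.

    ``axis='longitudinal'`` (side view) yields plateaus for the wall and
    the marker; ``axis='radial'`` (bottom view) yields a two-bump ring
    section.  The noiseless ideal is computed analytically (box * Gaussian
    averaged per pixel); positions are in expanded-space nm with the
    structure's proximal edge (longitudinal) or centre (radial) at 0.
    The ground truth is echoed back for test harnesses.
    """
    if axis == "longitudinal" and truth.view != "side":
        raise ValueError("longitudinal profiles require a side-view truth")
    if axis == "radial" and truth.view != "bottom":
        raise ValueError("radial profiles require a bottom-view truth")
    if axis not in ("longitudinal", "radial"):
        raise ValueError(f"unknown axis {axis!r}")
    e = model.expansion_factor
    h = model.pixel_size_nm
    sigma = model.psf_sigma_nm
    margin = (math.ceil((3 * sigma) / h) + 3) * h

    if axis == "longitudinal":
        span = truth.tubulin_length_nm * e
        lo = min(0.0, truth.marker_offset_nm * e)
        hi = max(span, (truth.marker_offset_nm + truth.marker_length_nm) * e)
        start = lo - margin
        n = int(math.ceil((hi - lo + 2 * margin) / h))
        centers = start + (np.arange(n) + 0.5) * h
        tub_boxes = [(0.0, span, truth.intensity_scale.get("tubulin", 1.0))]
        mk_boxes = _marker_boxes_longitudinal(truth, e)
    else:
        rw = (truth.tubulin_diameter_nm + truth.wall_thickness_nm) * e / 2
        rm = (truth.marker_diameter_nm + truth.wall_thickness_nm) * e / 2
        half = math.ceil((max(rw, rm) + margin) / h) * h
        n = int(round(2 * half / h))
        centers = -half + (np.arange(n) + 0.5) * h
        w = truth.wall_thickness_nm * e / 2
        rc = truth.tubulin_diameter_nm * e / 2
        s = truth.intensity_scale.get("tubulin", 1.0)
        tub_boxes = [(-rc - w, -rc + w, s), (rc - w, rc + w, s)]
        mk_boxes = _marker_boxes_radial(truth, e)

    rng = np.random.default_rng(model.rng_seed)
    intensities = {}
    for name, boxes in (("tubulin", tub_boxes), ("marker", mk_boxes)):
        ideal = _sample_boxes(centers, boxes, sigma, h)
        if model.noiseless:
            intensities[name] = model.photon_scale * ideal + model.background_offset
        else:
            intensities[name] = _apply_noise(ideal, model, rng)
    profile = LineProfile(centers, intensities, h, width_px=1, space=EXPANDED)
    return profile, truth


# ---------------------------------------------------------------------------
# 2D rendering
# ---------------------------------------------------------------------------

_SUPERSAMPLE = 4


def _indicator_side(u: np.ndarray, v: np.ndarray, t: CentrioleTruth, e: float) -> Dict[str, np.ndarray]:
    half_l = t.tubulin_length_nm * e / 2
    rc = t.tubulin_diameter_nm * e / 2
    w = t.wall_thickness_nm * e / 2
    wall = (np.abs(u) <= half_l) & (np.abs(np.abs(v) - rc) <= w)
    chans = {"tubulin": wall.astype(float) * t.intensity_scale.get("tubulin", 1.0)}
    if t.marker_model == "absent":
        chans["marker"] = np.zeros_like(u)
        return chans
    a = -half_l + t.marker_offset_nm * e
    b = a + t.marker_length_nm * e
    rm = t.marker_diameter_nm * e / 2
    inside_u = (u >= a) & (u <= b)
    if t.marker_model == "cap":
        mk = inside_u & (np.abs(v) <= rm)
    else:  # proximal_ring / sleeve: wall-like shells at the marker diameter
        mk = inside_u & (np.abs(np.abs(v) - rm) <= w)
    chans["marker"] = mk.astype(float) * t.intensity_scale.get("marker", 1.0)
    return chans


def _indicator_bottom(u: np.ndarray, v: np.ndarray, t: CentrioleTruth, e: float) -> Dict[str, np.ndarray]:
    r = np.hypot(u, v)
    rc = t.tubulin_diameter_nm * e / 2
    w = t.wall_thickness_nm * e / 2
    chans = {"tubulin": (np.abs(r - rc) <= w).astype(float) * t.intensity_scale.get("tubulin", 1.0)}
    if t.marker_model == "absent":
        chans["marker"] = np.zeros_like(u)
        return chans
    rm = t.marker_diameter_nm * e / 2
    if t.marker_model == "cap":
        mk = r <= rm
    else:
        mk = np.abs(r - rm) <= w
    chans["marker"] = mk.astype(float) * t.intensity_scale.get("marker", 1.0)
    return chans


def _bounding_radius_nm(t: CentrioleTruth, e: float) -> float:
    if t.view == "side":
        half_l = t.tubulin_length_nm * e / 2
        lo = min(-half_l, -half_l + t.marker_offset_nm * e)
        hi = max(half_l, -half_l + (t.marker_offset_nm + t.marker_length_nm) * e)
        u_max = max(abs(lo), abs(hi))
        v_max = (max(t.tubulin_diameter_nm, t.marker_diameter_nm) + t.wall_thickness_nm) * e / 2
        return math.hypot(u_max, v_max)
    return (max(t.tubulin_diameter_nm, t.marker_diameter_nm) + t.wall_thickness_nm) * e / 2


def generate_centriole_image(
    truth: CentrioleTruth,
    model: ImagingModel,
    canvas_px: Tuple[int, int] = (64, 64),
    pose: Optional[Pose] = None,
) -> Tuple[ImagePlane, CentrioleTruth]:
    """Render one centriole into a two-channel image.

    Channel ``tubulin`` carries the wall (bars or ring per view), channel
    ``marker`` the marker model.  Structures are drawn in continuous
    coordinates, area-sampled onto the pixel grid (4x4 supersampling),
    PSF-blurred, then noise is applied per the imaging model.  Raises if
    the structure plus 3 PSF sigma does not fit the canvas.
    """
    ny, nx = int(canvas_px[0]), int(canvas_px[1])
    if pose is None:
        pose = Pose((nx - 1) / 2.0, (ny - 1) / 2.0, 0.0)
    e = model.expansion_factor
    h = model.pixel_size_nm
    reach_px = (_bounding_radius_nm(truth, e) + 3 * model.psf_sigma_nm) / h
    if (
        pose.x_px - reach_px < -0.5
        or pose.x_px + reach_px > nx - 0.5
        or pose.y_px - reach_px < -0.5
        or pose.y_px + reach_px > ny - 0.5
    ):
        raise ValueError("structure (plus 3 sigma PSF) exceeds the canvas")

    ss = _SUPERSAMPLE
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    xs = (np.arange(nx)[:, None] + sub[None, :]).ravel()  # px coords of sub-samples
    ys = (np.arange(ny)[:, None] + sub[None, :]).ravel()
    X, Y = np.meshgrid(xs, ys)
    dx = (X - pose.x_px) * h
    dy = (Y - pose.y_px) * h
    th = math.radians(pose.angle_deg)
    u = math.cos(th) * dx + math.sin(th) * dy  # along-axis coordinate, nm
    v = -math.sin(th) * dx + math.cos(th) * dy

    if truth.view == "side":
        fine = _indicator_side(u, v, truth, e)
    else:
        fine = _indicator_bottom(u, v, truth, e)

    rng = np.random.default_rng(model.rng_seed)
    sigma_px = model.psf_sigma_nm / h
    channels = {}
    for name in ("tubulin", "marker"):
        img = fine[name].reshape(ny, ss, nx, ss).mean(axis=(1, 3))
        if sigma_px > 0:
            img = gaussian_filter(img, sigma_px, mode="constant")
        if model.noiseless:
            channels[name] = model.photon_scale * img + model.background_offset
        else:
            channels[name] = _apply_noise(img, model, rng)
    plane = ImagePlane(
        channels=channels,
        pixel_size_nm=h,
        expansion_factor=e,
        provenance=f"synthetic {truth.view} view, seed={model.rng_seed}",
    )
    return plane, truth


# ---------------------------------------------------------------------------
# growth series / cyst counts / quantification dataset
# ---------------------------------------------------------------------------


def _cap_peak_snr(length_nm: float, model: ImagingModel, scale: float = 1.0) -> float:
    """Predicted peak SNR of a marker cap of the given biological length."""
    le = length_nm * model.expansion_factor
    if le <= 0:
        return 0.0
    if model.psf_sigma_nm == 0:
        frac = 1.0
    else:
        frac = 2 * ndtr(le / (2 * model.psf_sigma_nm)) - 1
    peak = model.photon_scale * scale * frac
    noise = math.sqrt(peak + model.background_offset + model.read_noise_sd**2)
    return peak / noise if noise > 0 else math.inf


def generate_growth_series(
    n: int,
    length_range_nm: Tuple[float, float] = (40.0, 400.0),
    onset_nm: float = 120.0,
    model: Optional[ImagingModel] = None,
    seed: int = 0,
    marker_length_max_nm: float = 110.0,
    snr_floor: float = 5.0,
) -> List[GrowthRecord]:
    """Procentriole growth series with marker presence tied to an onset.

    Lengths are uniform over ``length_range_nm``; the marker is present
    iff length >= ``onset_nm`` and its extent grows linearly as
    ``min(marker_length_max_nm, 0.5 * (length - onset))``.  Each record
    carries a ``detectable`` flag: present markers whose predicted peak
    SNR under the imaging model falls below ``snr_floor`` (extents much
    shorter than the PSF) are flagged as below the detection limit.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    lo, hi = length_range_nm
    if not (0 < lo < hi):
        raise ValueError("length range must be positive and increasing")
    if not (lo <= onset_nm <= hi):
        warnings.warn("onset_nm lies outside the sampled length range", stacklevel=2)
    if model is None:
        model = ImagingModel(rng_seed=seed)
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(lo, hi, size=n)
    records: List[GrowthRecord] = []
    for i, L in enumerate(lengths):
        present = bool(L >= onset_nm)
        mlen = min(marker_length_max_nm, 0.5 * (L - onset_nm)) if present else 0.0
        truth = CentrioleTruth(
            view="side",
            tubulin_length_nm=float(L),
            marker_model="cap" if present and mlen > 0 else "absent",
            marker_length_nm=float(mlen) if present else 0.0,
        )
        detectable = present and _cap_peak_snr(mlen, model) >= snr_floor
        records.append(GrowthRecord(truth=truth, present=present, detectable=detectable))
    return records


def generate_cyst_counts(
    n_cells: int, mixture_f: float, seed: int = 0
) -> Dict[str, int]:
    """Sample a centriole-count table from the cyst-lineage mixture.

    Cells are drawn from the predicted distribution with a fraction
    ``mixture_f`` of final cells descending from 4-cell-stage duplication
    failures (the rest from 8-cell-stage failures).
    """
    if not 0 <= mixture_f <= 1:
        raise ValueError("mixture_f must be in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    probs = cystline.predict_distribution(mixture_f)
    classes = sorted(probs)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_cells, [probs[c] for c in classes])
    return {c: int(k) for c, k in zip(classes, draws)}


def generate_quantification_dataset(
    n_per_stage: int = 10,
    stages: Sequence[str] = ("SG", "early_SC", "late_SC"),
    genotypes: Sequence[str] = ("control", "mutant"),
    effect: float = 0.6,
    model: Optional[ImagingModel] = None,
    seed: int = 0,
    canvas_px: Tuple[int, int] = (33, 33),
    spot_radius_px: float = 2.5,
    target_amplitude: float = 1.0,
    control_amplitude: float = 1.0,
    brightness_cv: float = 0.2,
) -> Tuple[Dict[str, ImagePlane], pd.DataFrame]:
    """Synthetic two-genotype spot images for intensity quantification.

    Each centriole is a blurred disc at the centre of its own small image
    with a ``target`` channel (amplitude scaled by ``effect`` in the
    mutant) and a ``control`` channel (internal control, same amplitude in
    both genotypes).  A per-cell log-normal brightness factor is applied
    to both channels, emulating staining/acquisition variability that
    internal-control normalization removes.  Returns the images keyed by
    id and an annotation table (image, x, y, stage, genotype, roi_kind).
    """
    if model is None:
        model = ImagingModel(psf_sigma_nm=0.0, rng_seed=seed)
    rng = np.random.default_rng(seed)
    ny, nx = canvas_px
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    disc = (np.hypot(xx - cx, yy - cy) <= spot_radius_px).astype(float)
    disc = gaussian_filter(disc, 1.0)
    images: Dict[str, ImagePlane] = {}
    rows = []
    for genotype in genotypes:
        amp_t = target_amplitude * (effect if genotype != genotypes[0] else 1.0)
        for stage in stages:
            for i in range(n_per_stage):
                cell_factor = float(rng.lognormal(0.0, brightness_cv))
                ideal_t = disc * amp_t * cell_factor
                ideal_c = disc * control_amplitude * cell_factor
                chans = {
                    "target": _apply_noise(ideal_t, model, rng),
                    "control": _apply_noise(ideal_c, model, rng),
                }
                img_id = f"{genotype}_{stage}_{i:03d}"
                images[img_id] = ImagePlane(
                    channels=chans,
                    pixel_size_nm=model.pixel_size_nm,
                    expansion_factor=model.expansion_factor,
                    provenance=f"synthetic spot, seed={seed}",
                )
                rows.append(
                    {
                        "image": img_id,
                        "x": cx,
                        "y": cy,
                        "stage": stage,
                        "genotype": genotype,
                        "roi_kind": "threshold",
                    }
                )
    return images, pd.DataFrame(rows)
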