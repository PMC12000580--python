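"""Line-profile measurement engine for expanded centrioles.

Implements the measurement chain used for U-ExM centriole morphometry:
line-scan extraction with width averaging, sub-pixel up-sampling (pixel
subdivision), half-maximum signal-extent detection with linear
interpolation, gel expansion-factor calibration and correction, side-view
length and bottom-view diameter measurement, and tubulin-referenced
relative positioning of marker proteins.

All positions are physical distances in nanometres.  Images and profiles
live in *expanded* (gel) space until an :class:`ExpansionCalibration` is
applied, after which quantities are in biological ("real") space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from skimage.measure import profile_line

__all__ = [
    "ImagePlane",
    "LineProfile",
    "SignalExtent",
    "CentrioleMeasurement",
    "RelativePositionRecord",
    "PositionSummary",
    "ExpansionCalibration",
    "extract_line_profile",
    "resample_profile",
    "detect_extent",
    "calibrate_expansion",
    "correct_measurement",
    "measure_side_view",
    "measure_bottom_view",
    "relative_position",
    "summarize_positions",
]

EXPANDED = "expanded"
CORRECTED = "corrected"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImagePlane:
    """Multi-channel 2D projected image with physical calibration.

    ``channels`` maps channel name to a 2D intensity array; all channels
    must share dimensions.  ``pixel_size_nm`` is the pixel pitch in
    expanded (gel) space.
    """

    channels: Dict[str, np.ndarray]
    pixel_size_nm: float
    expansion_factor: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImagePlane requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if not self.expansion_factor > 0:
            raise ValueError("expansion_factor must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LineProfile:
    """Per-channel intensity versus position along a sampled line."""

    positions_nm: np.ndarray
    intensities: Dict[str, np.ndarray]
    sampling_step_nm: float
    width_px: int = 1
    space: str = EXPANDED

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.intensities = {k: np.asarray(v, dtype=float) for k, v in self.intensities.items()}
        n = self.positions_nm.size
        if n < 2:
            raise ValueError("profile needs at least two samples")
        for name, vals in self.intensities.items():
            if vals.size != n:
                raise ValueError(f"channel {name!r} length {vals.size} != positions {n}")
        steps = np.diff(self.positions_nm)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(steps, self.sampling_step_nm, rtol=1e-6, atol=1e-9):
            raise ValueError("positions must be equally spaced at sampling_step_nm")
        if not self.sampling_step_nm > 0:
            raise ValueError("sampling_step_nm must be positive")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.positions_nm.size


@dataclass
class SignalExtent:
    """Half-maximum start/end of one channel's signal along a profile."""

    channel: str
    start_nm: float
    end_nm: float
    peak_value: float
    threshold_value: float
    half_fraction: float = 0.5
    baseline_value: float = 0.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError("start_nm must be < end_nm")

    @property
    def length_nm(self) -> float:
        return self.end_nm - self.start_nm


@dataclass
class CentrioleMeasurement:
    """Assembled extents, lengths and diameters for one centriole."""

    id: str
    view: str  # "side" | "bottom"
    extents: Dict[str, Optional[SignalExtent]]
    length_nm: Dict[str, float] = field(default_factory=dict)
    diameter_nm: Dict[str, float] = field(default_factory=dict)
    diameter_mode: Optional[str] = None
    expansion_factor: float = 1.0
    space: str = EXPANDED


@dataclass
class RelativePositionRecord:
    """Marker start/end relative to the tubulin start (set to 0)."""

    tubulin_length_nm: float
    marker_start_rel_nm: Optional[float]
    marker_end_rel_nm: Optional[float]
    present: bool

    def __post_init__(self) -> None:
        if self.present and not (self.marker_end_rel_nm > self.marker_start_rel_nm):
            raise ValueError("present marker requires end > start")


@dataclass
class PositionSummary:
    """Mean +/- sd of relative marker positions, plus growth curves."""

    mean_start_nm: float
    sd_start_nm: float
    mean_end_nm: float
    sd_end_nm: float
    n_present: int
    single_record: bool
    curve: pd.DataFrame  # per-centriole scatter sorted by tubulin length
    binned: Optional[pd.DataFrame] = None  # binned means when bin width given


@dataclass
class ExpansionCalibration:
    """Gel expansion factor from the standardised biopsy-punch disk.

    ``factor = measured_disk_mm / punch_diameter_mm``.  The EM reference
    band (outer centriole diameter 200 +/- 12 nm) is carried along for
    isotropy checks.
    """

    measured_disk_mm: float
    punch_diameter_mm: float = 4.0
    em_reference_nm: Tuple[float, float] = (200.0, 12.0)

    def __post_init__(self) -> None:
        if not self.measured_disk_mm > 0 or not self.punch_diameter_mm > 0:
            raise ValueError("disk and punch diameters must be positive")

    @property
    def factor(self) -> float:
        return self.measured_disk_mm / self.punch_diameter_mm


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_line_profile(
    image: ImagePlane,
    start_xy: Sequence[float],
    end_xy: Sequence[float],
    width_px: int = 1,
) -> LineProfile:
    """Sample all channels along a line, averaging over ``width_px`` offsets.

    Endpoints are (x, y) pixel coordinates (pixel centres at integers).
    One sample is taken per pixel step along the line; positions are
    converted to nm in expanded space, starting at 0 at the first sample.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    x0, y0 = float(start_xy[0]), float(start_xy[1])
    x1, y1 = float(end_xy[0]), float(end_xy[1])
    dist_px = math.hypot(x1 - x0, y1 - y0)
    if dist_px == 0:
        raise ValueError("line endpoints coincide")
    h, w = image.shape
    # perpendicular unit vector for width offsetting
    ux, uy = (x1 - x0) / dist_px, (y1 - y0) / dist_px
    px, py = -uy, ux
    half = (width_px - 1) / 2.0
    for ex, ey in ((x0, y0), (x1, y1)):
        for s in (-half, half):
            ox, oy = ex + s * px, ey + s * py
            if not (0 <= ox <= w - 1 and 0 <= oy <= h - 1):
                raise ValueError("line (after width offsetting) exits the image")
    intensities = {}
    for name, arr in image.channels.items():
        vals = profile_line(
            arr, (y0, x0), (y1, x1), linewidth=width_px, order=1, mode="constant"
        )
        intensities[name] = np.asarray(vals, dtype=float)
    n = next(iter(intensities.values())).size
    step_nm = dist_px / (n - 1) * image.pixel_size_nm
    positions = np.arange(n) * step_nm
    return LineProfile(positions, intensities, step_nm, width_px=width_px)


def resample_profile(profile: LineProfile, subdivision: int = 3) -> LineProfile:
    """Artificially decrease the sampling step by ``subdivision``.

    Positions are subdivided by the factor and intensities linearly
    interpolated; ``subdivision=1`` is the identity.
    """
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    if subdivision == 1:
        return LineProfile(
            profile.positions_nm.copy(),
            {k: v.copy() for k, v in profile.intensities.items()},
            profile.sampling_step_nm,
            width_px=profile.width_px,
            space=profile.space,
        )
    n_new = (profile.n_samples - 1) * subdivision + 1
    step = profile.sampling_step_nm / subdivision
    new_pos = profile.positions_nm[0] + np.arange(n_new) * step
    new_int = {
        k: np.interp(new_pos, profile.positions_nm, v)
        for k, v in profile.intensities.items()
    }
    return LineProfile(new_pos, new_int, step, width_px=profile.width_px, space=profile.space)


def _baseline(values: np.ndarray, tail_fraction: float = 0.1) -> Tuple[float, float]:
    """Baseline level and noise sd from the outer tails of a profile.

    Returns the median and sample sd (ddof=1) of the first and last
    ``tail_fraction`` of samples (at least one sample per end).
    """
    n = values.size
    k = max(1, int(round(tail_fraction * n)))
    tails = np.concatenate([values[:k], values[-k:]])
    sd = float(np.std(tails, ddof=1)) if tails.size > 1 else 0.0
    return float(np.median(tails)), sd


def detect_extent(
    profile: LineProfile,
    channel: str,
    half_fraction: float = 0.5,
) -> Optional[SignalExtent]:
    """Locate the signal start/end at ``half_fraction`` of the peak.

    The threshold is ``baseline + half_fraction * (peak - baseline)`` with
    the baseline taken as the median of the outer 10% of samples at each
    profile end (reduces to the plain 50%-of-peak rule for zero baseline).
    Scanning inward from each profile end, the first threshold crossing is
    localised sub-pixel by linear interpolation between the bracketing
    samples.  Returns ``None`` ("no signal") when the peak does not rise
    above the baseline.
    """
    if channel not in profile.intensities:
        raise KeyError(f"channel {channel!r} not in profile")
    if not 0 < half_fraction < 1:
        raise ValueError("half_fraction must be in (0, 1)")
    y = profile.intensities[channel]
    if y.size < 3:
        raise ValueError("profile needs at least 3 samples")
    base, _ = _baseline(y)
    peak = float(np.max(y))
    if not peak > base:
        return None
    thr = base + half_fraction * (peak - base)
    pos = profile.positions_nm

    above = y >= thr
    if not above.any():  # pathological: peak==max but fp issues
        return None
    first = int(np.argmax(above))
    last = int(y.size - 1 - np.argmax(above[::-1]))
    if first == 0:
        start = float(pos[0])
    else:
        y0, y1 = y[first - 1], y[first]
        start = float(pos[first - 1] + (thr - y0) / (y1 - y0) * (pos[first] - pos[first - 1]))
    if last == y.size - 1:
        end = float(pos[-1])
    else:
        y0, y1 = y[last], y[last + 1]
        end = float(pos[last] + (y0 - thr) / (y0 - y1) * (pos[last + 1] - pos[last]))
    if not start < end:  # single-sample spike at an edge
        return None
    return SignalExtent(
        channel=channel,
        start_nm=start,
        end_nm=end,
        peak_value=peak,
        threshold_value=thr,
        half_fraction=half_fraction,
        baseline_value=base,
    )


def calibrate_expansion(
    measured_disk_mm: float, punch_diameter_mm: float = 4.0
) -> ExpansionCalibration:
    """Expansion factor from the expanded gel disk cut with a 4-mm punch."""
    return ExpansionCalibration(measured_disk_mm=measured_disk_mm,
                                punch_diameter_mm=punch_diameter_mm)


def _scaled_extent(e: Optional[SignalExtent], factor: float) -> Optional[SignalExtent]:
    if e is None:
        return None
    return replace(
        e,
        start_nm=e.start_nm / factor,
        end_nm=e.end_nm / factor,
    )


def correct_measurement(
    m: CentrioleMeasurement, cal: ExpansionCalibration
) -> CentrioleMeasurement:
    """Divide all nm quantities by the expansion factor (gel -> real space).

    Correcting an already-corrected measurement is an error (idempotence
    guard): the expansion factor must be applied exactly once.
    """
    if m.space == CORRECTED:
        raise ValueError("measurement is already in corrected space")
    f = cal.factor
    return CentrioleMeasurement(
        id=m.id,
        view=m.view,
        extents={k: _scaled_extent(e, f) for k, e in m.extents.items()},
        length_nm={k: v / f for k, v in m.length_nm.items()},
        diameter_nm={k: v / f for k, v in m.diameter_nm.items()},
        diameter_mode=m.diameter_mode,
        expansion_factor=f,
        space=CORRECTED,
    )


def measure_side_view(
    profile: LineProfile,
    cal: Optional[ExpansionCalibration] = None,
    subdivision: int = 3,
    half_fraction: float = 0.5,
    tubulin_channel: str = "tubulin",
    id: str = "",
) -> CentrioleMeasurement:
    """Lengths of all channels from a longitudinal (side-view) profile.

    The profile is up-sampled by ``subdivision``, then the half-maximum
    extent is located per channel; channel length = extent end - start.
    Channels without signal are recorded as absent (``None`` extent), not
    zero length.  Raises if the tubulin channel shows no signal.  When a
    calibration is given the result is returned in corrected space.
    """
    if tubulin_channel not in profile.intensities:
        raise KeyError(f"tubulin channel {tubulin_channel!r} missing")
    fine = resample_profile(profile, subdivision)
    extents: Dict[str, Optional[SignalExtent]] = {}
    lengths: Dict[str, float] = {}
    for name in fine.intensities:
        ext = detect_extent(fine, name, half_fraction)
        extents[name] = ext
        if ext is not None:
            lengths[name] = ext.length_nm
    if extents[tubulin_channel] is None:
        raise ValueError("no tubulin signal in side-view profile")
    m = CentrioleMeasurement(
        id=id, view="side", extents=extents, length_nm=lengths, space=EXPANDED
    )
    return correct_measurement(m, cal) if cal is not None else m


def _quadratic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample peak offset by a 3-point parabola around index ``i``."""
    if i == 0 or i == y.size - 1:
        return 0.0
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    d = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(d, -0.5, 0.5))


def measure_bottom_view(
    profile: LineProfile,
    cal: Optional[ExpansionCalibration] = None,
    mode: str = "peak_to_peak",
    subdivision: int = 3,
    half_fraction: float = 0.5,
    id: str = "",
) -> CentrioleMeasurement:
    """Ring diameters from a radial (bottom-view) profile through the centroid.

    ``peak_to_peak`` takes the distance between the two wall peaks, each
    refined by a 3-point quadratic fit (wall-centre convention);
    ``outer_half_max`` takes the distance between the outermost half-max
    crossings.  A ring must cross the line twice: channels without two
    local maxima above the half-max threshold (e.g. a solid cap, which
    projects to a single central peak) get no diameter; if no channel
    shows two peaks the profile is rejected.
    """
    if mode not in ("peak_to_peak", "outer_half_max"):
        raise ValueError(f"unknown diameter mode {mode!r}")
    fine = resample_profile(profile, subdivision)
    extents: Dict[str, Optional[SignalExtent]] = {}
    diameters: Dict[str, float] = {}
    for name, y in fine.intensities.items():
        ext = detect_extent(fine, name, half_fraction)
        extents[name] = ext
        if ext is None:
            continue
        peaks, _ = find_peaks(y, height=ext.threshold_value)
        if peaks.size < 2:
            continue  # not ring-like along this line (single peak)
        if peaks.size > 2:
            heights = y[peaks]
            keep = np.sort(peaks[np.argsort(heights)[-2:]])
        else:
            keep = peaks
        if mode == "peak_to_peak":
            refined = [p + _quadratic_refine(y, p) for p in keep]
            diameters[name] = float((refined[1] - refined[0]) * fine.sampling_step_nm)
        else:
            diameters[name] = float(ext.length_nm)
    if not diameters:
        raise ValueError(
            "no channel shows the two peaks of a ring crossing in this profile"
        )
    m = CentrioleMeasurement(
        id=id,
        view="bottom",
        extents=extents,
        diameter_nm=diameters,
        diameter_mode=mode,
        space=EXPANDED,
    )
    return correct_measurement(m, cal) if cal is not None else m


def relative_position(
    m: CentrioleMeasurement,
    marker_channel: str,
    tubulin_channel: str = "tubulin",
) -> RelativePositionRecord:
    """Marker start/end with the tubulin start shifted to 0.

    The tubulin is the reference protein: its starting coordinate is set
    to 0 and the same shift is applied to the marker.  Negative marker
    starts are permitted (marker capping below the wall).
    """
    if m.view != "side":
        raise ValueError("relative positioning requires a side-view measurement")
    tub = m.extents.get(tubulin_channel)
    if tub is None:
        raise ValueError("tubulin extent missing")
    mk = m.extents.get(marker_channel)
    if mk is None:
        return RelativePositionRecord(tub.length_nm, None, None, present=False)
    return RelativePositionRecord(
        tubulin_length_nm=tub.length_nm,
        marker_start_rel_nm=mk.start_nm - tub.start_nm,
        marker_end_rel_nm=mk.end_nm - tub.start_nm,
        present=True,
    )


def summarize_positions(
    records: Iterable[RelativePositionRecord],
    bin_width_nm: Optional[float] = None,
) -> PositionSummary:
    """Average relative marker position and its evolution with growth.

    Mean +/- sample sd (ddof=1; a single record reports sd 0 with a flag)
    of marker start and end among records where the marker is present,
    plus the per-centriole start/end versus tubulin length curve sorted by
    length, and optionally the same curve binned to ``bin_width_nm``.
    """
    present = [r for r in records if r.present]
    if not present:
        raise ValueError("no records with marker present")
    starts = np.array([r.marker_start_rel_nm for r in present])
    ends = np.array([r.marker_end_rel_nm for r in present])
    lengths = np.array([r.tubulin_length_nm for r in present])
    single = len(present) == 1
    sd_s = 0.0 if single else float(np.std(starts, ddof=1))
    sd_e = 0.0 if single else float(np.std(ends, ddof=1))
    order = np.argsort(lengths, kind="stable")
    curve = pd.DataFrame(
        {
            "tubulin_length_nm": lengths[order],
            "marker_start_rel_nm": starts[order],
            "marker_end_rel_nm": ends[order],
        }
    ).reset_index(drop=True)
    binned = None
    if bin_width_nm is not None:
        if not bin_width_nm > 0:
            raise ValueError("bin_width_nm must be positive")
        bins = np.floor(curve["tubulin_length_nm"] / bin_width_nm).astype(int)
        grouped = curve.groupby(bins).mean()
        grouped.index = (grouped.index + 0.5) * bin_width_nm
        grouped.index.name = "bin_center_nm"
        binned = grouped.reset_index()
    return PositionSummary(
        mean_start_nm=float(np.mean(starts)),
        sd_start_nm=sd_s,
        mean_end_nm=float(np.mean(ends)),
        sd_end_nm=sd_e,
        n_present=len(present),
        single_record=single,
        curve=curve,
        binned=binned,
    )
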