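"""Fluorescence intensity quantification at centrioles.

Centriole signals are quantified inside either a thresholded connected
component around a seed point (Otsu on a local window, or a fixed
threshold) or an axis-aligned square ROI.  The per-pixel background —
the median of an annulus around the ROI by default, or a global
percentile — is subtracted, and the net intensity may be normalized to
an internal-control channel quantified on the same mask.  Batch mode
produces tidy per-stage tables and supports blind scoring: sample
identities can be anonymised with a sealed key table written separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .profilekit import ImagePlane

__all__ = ["ROIQuant", "segment_roi", "square_roi", "quantify_roi", "batch_quantify"]


@dataclass
class ROIQuant:
    """One quantified ROI: raw, background-corrected and normalized."""

    image_id: str
    centriole_id: str
    stage: str
    roi_kind: str  # "threshold" | "square"
    area_px: int
    integrated_intensity: float
    background_per_px: float
    net_intensity: float
    control_net_intensity: Optional[float] = None
    normalized: Optional[float] = None

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("area_px must be positive")


def segment_roi(
    image: ImagePlane,
    channel: str,
    seed_point: Tuple[float, float],
    method: str = "otsu",
    fixed_value: Optional[float] = None,
    window_px: int = 64,
) -> np.ndarray:
    """Thresholded connected component containing the seed point.

    ``seed_point`` is (x, y) in pixels.  The Otsu threshold is computed on
    a ``window_px`` square window centred on the seed (centriole spots are
    sparse in large fields); ``method='fixed'`` uses ``fixed_value``
    directly.  Raises when the component at the seed is empty.
    """
    arr = image.channels[channel]
    h, w = arr.shape
    x, y = int(round(seed_point[0])), int(round(seed_point[1]))
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError("seed point outside image")
    if method == "otsu":
        half = window_px // 2
        win = arr[max(0, y - half):y + half + 1, max(0, x - half):x + half + 1]
        if np.ptp(win) == 0:
            raise ValueError("empty ROI: constant window, no threshold")
        thr = threshold_otsu(win)
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed threshold requires fixed_value")
        thr = float(fixed_value)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    binary = arr > thr
    if not binary[y, x]:
        raise ValueError("empty ROI: seed pixel below threshold")
    labels = label(binary, connectivity=2)
    return labels == labels[y, x]


def square_roi(
    shape: Tuple[int, int], center: Tuple[float, float], half_width_px: int
) -> np.ndarray:
    """Axis-aligned square mask of side ``2*half_width_px + 1``."""
    if half_width_px < 0:
        raise ValueError("half_width_px must be >= 0")
    h, w = shape
    x, y = int(round(center[0])), int(round(center[1]))
    if x - half_width_px < 0 or y - half_width_px < 0 \
            or x + half_width_px >= w or y + half_width_px >= h:
        raise ValueError("square ROI exits the image")
    mask = np.zeros(shape, dtype=bool)
    mask[y - half_width_px:y + half_width_px + 1,
         x - half_width_px:x + half_width_px + 1] = True
    return mask


def _background_per_px(
    arr: np.ndarray, mask: np.ndarray, background: str,
    annulus_inner: int = 2, annulus_outer: int = 5, percentile: float = 10.0,
) -> float:
    if background == "annulus":
        outer = ndimage.binary_dilation(mask, iterations=annulus_outer)
        inner = ndimage.binary_dilation(mask, iterations=annulus_inner)
        ann = outer & ~inner
        if not ann.any():
            raise ValueError("annulus is empty (ROI fills the image)")
        return float(np.median(arr[ann]))
    if background == "global_percentile":
        return float(np.percentile(arr, percentile))
    raise ValueError(f"unknown background method {background!r}")


def quantify_roi(
    image: ImagePlane,
    channel: str,
    mask: np.ndarray,
    background: str = "annulus",
    control_channel: Optional[str] = None,
    image_id: str = "",
    centriole_id: str = "",
    stage: str = "",
    roi_kind: str = "threshold",
) -> ROIQuant:
    """Integrated, background-subtracted (and normalized) ROI intensity.

    ``net = integrated - background_per_px * area``.  When a control
    channel is given it is quantified on the *same* mask with the same
    background method and ``normalized = net / control_net`` (internal-
    control normalization).
    """
    if not mask.any():
        raise ValueError("empty mask")
    arr = image.channels[channel]
    if mask.shape != arr.shape:
        raise ValueError("mask shape does not match image")
    area = int(mask.sum())
    integrated = float(arr[mask].sum())
    bg = _background_per_px(arr, mask, background)
    net = integrated - bg * area
    control_net = None
    normalized = None
    if control_channel is not None:
        if control_channel not in image.channels:
            raise KeyError(f"control channel {control_channel!r} missing")
        carr = image.channels[control_channel]
        cbg = _background_per_px(carr, mask, background)
        control_net = float(carr[mask].sum()) - cbg * area
        normalized = net / control_net if control_net != 0 else np.nan
    return ROIQuant(
        image_id=image_id,
        centriole_id=centriole_id,
        stage=stage,
        roi_kind=roi_kind,
        area_px=area,
        integrated_intensity=integrated,
        background_per_px=bg,
        net_intensity=net,
        control_net_intensity=control_net,
        normalized=normalized,
    )


def batch_quantify(
    images: Mapping[str, ImagePlane],
    annotations: pd.DataFrame,
    channel: str = "target",
    background: str = "annulus",
    control_channel: Optional[str] = None,
    n_per_stage: int = 10,
    square_half_width_px: int = 5,
    anonymize: bool = False,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Quantify an annotation table of centrioles across images.

    Annotations need columns ``image, x, y, stage, roi_kind`` and
    optionally ``genotype``.  Groups with fewer than ``n_per_stage``
    annotations are processed with a warning.  With ``anonymize=True``
    (blind scoring) the measurement table carries shuffled anonymous ids
    and no genotype column; the returned key table maps anonymous ids back
    to sample identities and is meant to be written separately.
    """
    required = {"image", "x", "y", "stage", "roi_kind"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    group_cols = ["stage"] + (["genotype"] if "genotype" in annotations.columns else [])
    for keys, grp in annotations.groupby(group_cols):
        if len(grp) < n_per_stage:
            warnings.warn(
                f"group {keys}: {len(grp)} annotations < {n_per_stage} per stage",
                stacklevel=2,
            )
    rows = []
    for i, ann in annotations.reset_index(drop=True).iterrows():
        img_id = ann["image"]
        if img_id not in images:
            raise KeyError(f"annotation references missing image {img_id!r}")
        img = images[img_id]
        seed_pt = (float(ann["x"]), float(ann["y"]))
        if ann["roi_kind"] == "square":
            mask = square_roi(img.shape, seed_pt, square_half_width_px)
        else:
            mask = segment_roi(img, channel, seed_pt, method="otsu")
        q = quantify_roi(
            img, channel, mask, background=background,
            control_channel=control_channel,
            image_id=str(img_id), centriole_id=f"c{i:04d}",
            stage=str(ann["stage"]), roi_kind=str(ann["roi_kind"]),
        )
        row = {
            "centriole_id": q.centriole_id,
            "image": q.image_id,
            "stage": q.stage,
            "roi_kind": q.roi_kind,
            "area_px": q.area_px,
            "integrated_intensity": q.integrated_intensity,
            "background_per_px": q.background_per_px,
            "net_intensity": q.net_intensity,
            "control_net_intensity": q.control_net_intensity,
            "normalized": q.normalized,
        }
        if "genotype" in annotations.columns:
            row["genotype"] = ann["genotype"]
        rows.append(row)
    table = pd.DataFrame(rows)
    if not anonymize:
        return table, None
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    anon_ids = [f"anon{j:04d}" for j in perm]
    key_cols = ["centriole_id", "image"] + (
        ["genotype"] if "genotype" in table.columns else []
    )
    key = table[key_cols].copy()
    key.insert(0, "anon_id", anon_ids)
    blind = table.drop(columns=[c for c in ("genotype", "image") if c in table.columns])
    blind = blind.rename(columns={"centriole_id": "true_id"})
    blind.insert(0, "anon_id", anon_ids)
    blind = blind.drop(columns=["true_id"])
    blind = blind.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
    return blind, key
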