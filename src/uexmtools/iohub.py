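"""Formats and configuration: OME-TIFF images, tidy CSV tables, YAML config.

All public tables are in nm; columns holding expanded-space (gel)
quantities are suffixed ``_expanded_nm``.  Measurement CSVs start with a
schema-version header comment and round-trip byte-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .profilekit import CentrioleMeasurement, ImagePlane

__all__ = [
    "RunConfig",
    "load_config",
    "CalibrationError",
    "read_image",
    "write_image",
    "write_measurements",
    "read_measurements",
]

MEASUREMENT_SCHEMA = "uexmtools-measurements-v1"


class CalibrationError(ValueError):
    """Missing or invalid physical calibration (pixel size)."""


@dataclass
class RunConfig:
    """Validated per-run analysis parameters."""

    pixel_size_nm: Optional[float] = None
    expansion_factor: Optional[float] = None
    measured_disk_mm: Optional[float] = None
    punch_diameter_mm: float = 4.0
    subdivision: int = 3
    half_fraction: float = 0.5
    diameter_mode: str = "peak_to_peak"
    k_sigma: float = 3.0
    background: str = "annulus"
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.pixel_size_nm is not None and not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.expansion_factor is not None and not self.expansion_factor > 0:
            raise ValueError("expansion_factor must be positive")
        if self.measured_disk_mm is not None and not self.measured_disk_mm > 0:
            raise ValueError("measured_disk_mm must be positive")
        if not self.punch_diameter_mm > 0:
            raise ValueError("punch_diameter_mm must be positive")
        if self.subdivision < 1:
            raise ValueError("subdivision must be >= 1")
        if not 0 < self.half_fraction < 1:
            raise ValueError("half_fraction must be in (0, 1)")
        if self.diameter_mode not in ("peak_to_peak", "outer_half_max"):
            raise ValueError("diameter_mode must be peak_to_peak or outer_half_max")
        if not self.k_sigma > 0:
            raise ValueError("k_sigma must be positive")
        if self.background not in ("annulus", "global_percentile"):
            raise ValueError("background must be annulus or global_percentile")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image(image: ImagePlane, path: Union[str, Path]) -> None:
    """Write an :class:`ImagePlane` as OME-TIFF with physical metadata.

    Channels become planes of a CYX stack; pixel size (nm) goes into the
    OME PhysicalSizeX/Y fields, channel names into the Channel elements,
    and the expansion factor and provenance into the image Description as
    JSON.
    """
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    desc = json.dumps(
        {"expansion_factor": image.expansion_factor, "provenance": image.provenance}
    )
    tifffile.imwrite(
        str(path),
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": image.pixel_size_nm,
            "PhysicalSizeXUnit": "nm",
            "PhysicalSizeY": image.pixel_size_nm,
            "PhysicalSizeYUnit": "nm",
            "Channel": {"Name": names},
            "Description": desc,
        },
    )


_UNIT_TO_NM = {"nm": 1.0, "µm": 1000.0, "um": 1000.0, "micron": 1000.0, "mm": 1e6}


def read_image(
    path: Union[str, Path], pixel_size_override_nm: Optional[float] = None
) -> ImagePlane:
    """Read a (OME-)TIFF into an :class:`ImagePlane`.

    Pixel size comes from OME metadata; a plain TIFF without calibration
    requires ``pixel_size_override_nm`` — there is no silent default.
    """
    try:
        tf = tifffile.TiffFile(str(path))
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    with tf:
        data = tf.asarray()
        pixel_nm = None
        names: Optional[List[str]] = None
        expansion = 1.0
        provenance = ""
        if tf.ome_metadata:
            meta = tifffile.xml2dict(tf.ome_metadata)
            img = meta.get("OME", {}).get("Image", {})
            if isinstance(img, list):
                img = img[0]
            pix = img.get("Pixels", {})
            size = pix.get("PhysicalSizeX")
            if size is not None:
                unit = pix.get("PhysicalSizeXUnit", "µm")
                pixel_nm = float(size) * _UNIT_TO_NM.get(unit, 1000.0)
            chans = pix.get("Channel", [])
            if isinstance(chans, dict):
                chans = [chans]
            if chans and all("Name" in c for c in chans):
                names = [c["Name"] for c in chans]
            desc = img.get("Description")
            if desc:
                try:
                    extra = json.loads(desc)
                    expansion = float(extra.get("expansion_factor", 1.0))
                    provenance = str(extra.get("provenance", ""))
                except (json.JSONDecodeError, TypeError, ValueError):
                    provenance = str(desc)
    if pixel_size_override_nm is not None:
        if not pixel_size_override_nm > 0:
            raise CalibrationError("pixel size override must be positive")
        pixel_nm = float(pixel_size_override_nm)
    if pixel_nm is None:
        raise CalibrationError(
            f"{path}: no pixel size in metadata and no override given"
        )
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.ndim == 2:
        data = data[None, :, :]
    if names is None or len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    channels = {n: data[i] for i, n in enumerate(names)}
    return ImagePlane(
        channels=channels,
        pixel_size_nm=pixel_nm,
        expansion_factor=expansion,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

_MEAS_COLUMNS = [
    "id",
    "view",
    "space",
    "expansion_factor",
    "channel",
    "start_nm",
    "end_nm",
    "length_nm",
    "diameter_nm",
    "diameter_mode",
    "peak_value",
    "threshold_value",
    "present",
]


def measurements_to_frame(records: Sequence[CentrioleMeasurement]) -> pd.DataFrame:
    """Tidy one-row-per-channel DataFrame for measurement records."""
    rows = []
    for m in records:
        for ch, ext in m.extents.items():
            rows.append(
                {
                    "id": m.id,
                    "view": m.view,
                    "space": m.space,
                    "expansion_factor": m.expansion_factor,
                    "channel": ch,
                    "start_nm": ext.start_nm if ext else np.nan,
                    "end_nm": ext.end_nm if ext else np.nan,
                    "length_nm": m.length_nm.get(ch, np.nan),
                    "diameter_nm": m.diameter_nm.get(ch, np.nan),
                    "diameter_mode": m.diameter_mode or "",
                    "peak_value": ext.peak_value if ext else np.nan,
                    "threshold_value": ext.threshold_value if ext else np.nan,
                    "present": ext is not None,
                }
            )
    return pd.DataFrame(rows, columns=_MEAS_COLUMNS)


def write_measurements(
    records: Union[Sequence[CentrioleMeasurement], pd.DataFrame],
    path: Union[str, Path],
) -> None:
    """Write a measurement table as CSV with a schema-version header.

    Column order is deterministic; ``write -> read -> write`` is
    byte-identical.
    """
    df = records if isinstance(records, pd.DataFrame) else measurements_to_frame(records)
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema={MEASUREMENT_SCHEMA}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_measurements(path: Union[str, Path]) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path, comment="#")
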