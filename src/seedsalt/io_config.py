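"""Image, configuration and feature-table I/O.

A plate is one petri dish of Camelina seeds photographed under one of three
illumination modes: fluorescent (``FLUO``, 400-500 nm excitation, signal
mostly in the red channel), back-lit visible light (``VISBACK``, bright
background / dark seeds) and top-lit visible light (``VISFRONT``).  This
module holds the two root data types (:class:`PlateImage` and
:class:`SegmentationConfig`), reads and writes images, JSON detection-setup
configs and per-seed feature CSV tables, and ships one reusable preset
configuration per illumination mode.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

MODES = ("FLUO", "VISBACK", "VISFRONT")
CHANNELS = ("red", "green", "blue", "grey")
POLARITIES = ("bright_objects", "dark_objects")

CONFIG_VERSION = 1


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration content."""


class InputError(ValueError):
    """Raised for unreadable or malformed input data."""


@dataclass
class PlateImage:
    """An RGB plate raster plus its acquisition metadata.

    ``pixels`` is an H x W x 3 uint8 array in red/green/blue channel order.
    ``px_per_cm`` is the optional pixel-to-metric scale (pixel aspect ratio
    is assumed to be one).
    """

    id: str
    pixels: np.ndarray
    mode: str
    px_per_cm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputError("PlateImage pixels must be an HxWx3 array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InputError("PlateImage must have at least one pixel")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise InputError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.px_per_cm is not None and not self.px_per_cm > 0:
            raise ConfigError("px_per_cm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class SegmentationConfig:
    """Seed-detection setup: how to binarize a plate and gate the regions.

    ``threshold`` is either an integer in [0, 255] or the string ``"otsu"``
    (threshold computed from the image histogram by exhaustive between-class
    variance maximization).  ``polarity`` states whether seeds are brighter
    (``bright_objects``) or darker (``dark_objects``) than the background on
    the selected channel.  ``roi`` optionally restricts the search region to
    a circle ``(center_row, center_col, radius_px)`` — typically the dish.
    """

    name: str
    channel: str
    threshold: int | str
    polarity: str
    min_area: int
    max_area: int
    roi: Optional[tuple[float, float, float]] = None
    px_per_cm: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad: list[str] = []
        if self.channel not in CHANNELS:
            bad.append(f"channel={self.channel!r} (expected one of {CHANNELS})")
        if isinstance(self.threshold, str):
            if self.threshold != "otsu":
                bad.append(f"threshold={self.threshold!r} (string must be 'otsu')")
        elif not (isinstance(self.threshold, (int, np.integer)) and 0 <= self.threshold <= 255):
            bad.append(f"threshold={self.threshold!r} (numeric must be an integer in [0,255])")
        if self.polarity not in POLARITIES:
            bad.append(f"polarity={self.polarity!r} (expected one of {POLARITIES})")
        if not (0 <= self.min_area <= self.max_area):
            bad.append(f"min_area={self.min_area}, max_area={self.max_area} (need 0 <= min <= max)")
        if self.roi is not None:
            self.roi = tuple(float(v) for v in self.roi)  # type: ignore[assignment]
            if len(self.roi) != 3:
                bad.append("roi (need (center_row, center_col, radius))")
            elif not self.roi[2] > 0:
                bad.append(f"roi radius={self.roi[2]} (must be > 0)")
        if self.px_per_cm is not None and not self.px_per_cm > 0:
            bad.append(f"px_per_cm={self.px_per_cm} (must be > 0)")
        if bad:
            raise ConfigError("invalid segmentation config: " + "; ".join(bad))


_CONFIG_FIELDS = {"name", "channel", "threshold", "polarity", "min_area",
                  "max_area", "roi", "px_per_cm"}

#: Built-in detection setups, one per illumination mode.  The portal this
#: package re-implements never published its numeric setup values, so these
#: are package defaults chosen to segment each mode's synthetic plates; see
#: README.  FLUO seeds fluoresce in the red channel on a dark background;
#: VISBACK/VISFRONT seeds are dark on bright/mid backgrounds.
PRESETS: dict[str, SegmentationConfig] = {
    "FLUO": SegmentationConfig(
        name="FLUO", channel="red", threshold=60, polarity="bright_objects",
        min_area=20, max_area=2000),
    "VISBACK": SegmentationConfig(
        name="VISBACK", channel="grey", threshold=150, polarity="dark_objects",
        min_area=20, max_area=2000),
    "VISFRONT": SegmentationConfig(
        name="VISFRONT", channel="grey", threshold=95, polarity="dark_objects",
        min_area=20, max_area=2000),
}


def preset(name: str) -> SegmentationConfig:
    """Return a copy of the built-in preset for ``name`` (case-insensitive)."""
    key = name.upper()
    if key not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; expected one of {tuple(PRESETS)}")
    return replace(PRESETS[key])


def save_config(config: SegmentationConfig, path: str | Path) -> None:
    """Write a detection setup to JSON so it can be reused across analyses."""
    config.validate()
    payload = {
        "version": CONFIG_VERSION,
        "name": config.name,
        "channel": config.channel,
        "threshold": config.threshold,
        "polarity": config.polarity,
        "min_area": int(config.min_area),
        "max_area": int(config.max_area),
        "roi": list(config.roi) if config.roi is not None else None,
        "px_per_cm": config.px_per_cm,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_config(path: str | Path) -> SegmentationConfig:
    """Load a detection setup saved by :func:`save_config`."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigError(f"config {path} is not a JSON object")
    payload = dict(payload)
    payload.pop("version", None)
    unknown = set(payload) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    missing = {"name", "channel", "threshold", "polarity", "min_area", "max_area"} - set(payload)
    if missing:
        raise ConfigError(f"missing config keys: {sorted(missing)}")
    if payload.get("roi") is not None:
        payload["roi"] = tuple(payload["roi"])
    return SegmentationConfig(**payload)


def load_image(path: str | Path, mode: str) -> PlateImage:
    """Load a PNG/TIFF/JPEG plate image as an 8-bit RGB :class:`PlateImage`.

    Greyscale sources are replicated across the three channels; alpha
    channels are dropped; 16-bit rasters are rescaled to 0-255 by integer
    division (floor(v / 257)).  The plate id defaults to the file stem.
    """
    mode = str(mode).upper()
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}; expected one of {MODES}")
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise InputError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    elif arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    else:
        raise InputError(f"image {path} has unsupported shape {arr.shape}")
    if arr.dtype == np.uint8:
        pass
    elif arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    else:
        raise InputError(f"image {path} has unsupported dtype {arr.dtype}; expected 8- or 16-bit")
    return PlateImage(id=path.stem, pixels=arr, mode=mode)


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write an image array (uint8 RGB or uint16 label raster) to disk."""
    iio.imwrite(Path(path), np.asarray(pixels))


def write_feature_csv(records: Sequence, path: str | Path) -> None:
    """Write per-seed feature records to CSV (RFC-4180, 6-decimal floats).

    The header is ``plate,id,<7 morphological>,<16 colorimetric>`` plus a
    trailing ``condition`` column when any record carries a salt/non-salt
    label.  An empty record list writes the header only.
    """
    from .features import records_to_frame

    frame = records_to_frame(records)
    try:
        frame.to_csv(Path(path), index=False, float_format="%.6f")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def read_feature_csv(path: str | Path) -> list:
    """Read back a feature CSV written by :func:`write_feature_csv`."""
    import pandas as pd

    from .features import frame_to_records

    try:
        frame = pd.read_csv(Path(path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read feature table {path}: {exc}") from exc
    return frame_to_records(frame)


def truncate2(x: float) -> float:
    """Truncate toward zero at two decimals (the display convention used for
    printed px/cm scales, e.g. 846.50/8.50 -> 99.58)."""
    return math.trunc(x * 100) / 100
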