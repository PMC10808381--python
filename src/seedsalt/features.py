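"""Per-seed morpho-colorimetric features.

Seven morphological features (area, perimeter, circularity, compactness,
major/minor axis, eccentricity) and sixteen colorimetric features (grey
histogram peak, grey and per-channel quartiles, dominant hue class at 16,
32 and 64 divisions of the HSB hue circle) are computed for each segmented
seed.  Conventions, chosen once and used consistently:

* a seed is the interior of its outer contour — holes (e.g. glare in
  back-lit images) are filled before any feature is computed;
* perimeter is the polygonal length of the closed Moore contour through
  pixel centers (axial step 1, diagonal step sqrt(2)); a one-pixel region
  is assigned perimeter 1 so ratios stay finite;
* circularity = perimeter^2 / area, compactness = area / perimeter;
* major/minor are 2*sqrt(eigenvalue) of the second central moment matrix
  of the pixel coordinates, i.e. the semi-axes of the matched solid
  ellipse; eccentricity = major / minor (>= 1, not the classical ellipse
  eccentricity);
* quartiles interpolate linearly between closest ranks; the grey histogram
  uses rounded integer intensities; hue is degrees in [0, 360) with
  undefined (zero-saturation) hue mapped to 0, class ties broken toward
  the smallest index.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_config import InputError, PlateImage, SegmentationConfig
from .segmentation import SeedRegion, segment

MORPHO_COLUMNS = ["area", "perimeter", "circularity", "compactness",
                  "major", "minor", "eccentricity"]
COLOR_COLUMNS = ["hisgreypeak", "q1grey", "q2grey", "q3grey",
                 "q1r", "q2r", "q3r", "q1g", "q2g", "q3g",
                 "q1b", "q2b", "q3b", "hue16max", "hue32max", "hue64max"]
FEATURE_COLUMNS = MORPHO_COLUMNS + COLOR_COLUMNS


@dataclass
class MorphoFeatures:
    area: int
    perimeter: float
    circularity: float
    compactness: float
    major: float
    minor: float
    eccentricity: float


@dataclass
class ColorFeatures:
    hisgreypeak: int
    q1grey: float
    q2grey: float
    q3grey: float
    q1r: float
    q2r: float
    q3r: float
    q1g: float
    q2g: float
    q3g: float
    q1b: float
    q2b: float
    q3b: float
    hue16max: int
    hue32max: int
    hue64max: int


@dataclass
class SeedRecord:
    """One row of the per-seed trait table: plate id, seed label, the 7+16
    features and an optional salt/non-salt condition label."""

    plate: str
    label: int
    morpho: MorphoFeatures
    color: ColorFeatures
    condition: Optional[str] = None

    def values(self, columns: Sequence[str] = FEATURE_COLUMNS) -> np.ndarray:
        pool = {**vars(self.morpho), **vars(self.color)}
        return np.array([pool[c] for c in columns], dtype=np.float64)


def _filled_pixels(region: SeedRegion) -> np.ndarray:
    """Region pixels with interior holes filled, as an (N, 2) array of
    absolute (row, col) coordinates."""
    r0, c0, _, _ = region.bbox
    filled = ndimage.binary_fill_holes(region.mask())
    rr, cc = np.nonzero(filled)
    return np.column_stack((rr + r0, cc + c0))


def _contour_length(contour: np.ndarray) -> float:
    if len(contour) <= 1:
        return 1.0  # degenerate one-pixel contour: one closed step
    closed = np.vstack([contour, contour[:1]])
    steps = np.abs(np.diff(closed, axis=0))
    return float(np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0).sum())


def morphological_features(region: SeedRegion) -> MorphoFeatures:
    """Compute the seven shape features of one seed region."""
    if region.area == 0:
        raise InputError("cannot compute features of an empty region")
    pix = _filled_pixels(region).astype(np.float64)
    area = len(pix)
    perimeter = _contour_length(region.outer_contour)
    centered = pix - pix.mean(axis=0)
    cov = centered.T @ centered / area
    eig = np.linalg.eigvalsh(cov)  # ascending
    minor = max(2.0 * float(np.sqrt(max(eig[0], 0.0))), 0.5)
    major = max(2.0 * float(np.sqrt(max(eig[1], 0.0))), minor)
    return MorphoFeatures(
        area=area,
        perimeter=perimeter,
        circularity=perimeter**2 / area,
        compactness=area / perimeter,
        major=major,
        minor=minor,
        eccentricity=major / minor,
    )


def _hue_degrees(rgb: np.ndarray) -> np.ndarray:
    """HSB hue per pixel in degrees [0, 360); zero-saturation pixels -> 0."""
    v = rgb.astype(np.float64)
    mx = v.max(axis=1)
    mn = v.min(axis=1)
    delta = mx - mn
    r, g, b = v[:, 0], v[:, 1], v[:, 2]
    hue = np.zeros(len(v))
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (60.0 * (g - b) / delta) % 360.0
        hg = 60.0 * (b - r) / delta + 120.0
        hb = 60.0 * (r - g) / delta + 240.0
    sat = delta > 0
    hue[sat & (mx == r)] = hr[sat & (mx == r)]
    use_g = sat & (mx == g) & (mx != r)
    hue[use_g] = hg[use_g]
    use_b = sat & (mx == b) & (mx != r) & (mx != g)
    hue[use_b] = hb[use_b]
    return hue


def colorimetric_features(region: SeedRegion, image: PlateImage) -> ColorFeatures:
    """Compute the sixteen color features of one seed region."""
    pix = _filled_pixels(region)
    h, w = image.shape
    if pix[:, 0].max() >= h or pix[:, 1].max() >= w:
        raise InputError("region lies outside the image raster")
    rgb = image.pixels[pix[:, 0], pix[:, 1], :].astype(np.float64)
    grey = rgb.mean(axis=1)
    peak = int(np.bincount(np.rint(grey).astype(np.intp), minlength=256).argmax())
    quart = {}
    for name, vals in (("grey", grey), ("r", rgb[:, 0]), ("g", rgb[:, 1]), ("b", rgb[:, 2])):
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        quart[name] = (float(q1), float(q2), float(q3))
    hue = _hue_degrees(rgb)
    hue_max = {}
    for k in (16, 32, 64):
        cls = np.minimum((hue * k / 360.0).astype(np.intp), k - 1)
        hue_max[k] = int(np.bincount(cls, minlength=k).argmax())
    return ColorFeatures(
        hisgreypeak=peak,
        q1grey=quart["grey"][0], q2grey=quart["grey"][1], q3grey=quart["grey"][2],
        q1r=quart["r"][0], q2r=quart["r"][1], q3r=quart["r"][2],
        q1g=quart["g"][0], q2g=quart["g"][1], q3g=quart["g"][2],
        q1b=quart["b"][0], q2b=quart["b"][1], q3b=quart["b"][2],
        hue16max=hue_max[16], hue32max=hue_max[32], hue64max=hue_max[64],
    )


def extract_plate_table(image: PlateImage, config: SegmentationConfig,
                        condition: Optional[str] = None) -> list[SeedRecord]:
    """Segment a plate and compute both feature blocks per surviving seed,
    ordered by label."""
    records = []
    for region in segment(image, config):
        records.append(SeedRecord(
            plate=image.id,
            label=region.label,
            morpho=morphological_features(region),
            color=colorimetric_features(region, image),
            condition=condition,
        ))
    return records


def records_to_frame(records: Sequence[SeedRecord]) -> pd.DataFrame:
    """Per-seed records as a DataFrame with the canonical column order."""
    cols = ["plate", "id"] + FEATURE_COLUMNS
    labeled = any(r.condition is not None for r in records)
    rows = []
    for r in records:
        row = [r.plate, r.label] + list(r.values())
        if labeled:
            row.append(r.condition if r.condition is not None else "")
        rows.append(row)
    return pd.DataFrame(rows, columns=cols + (["condition"] if labeled else []))


def frame_to_records(frame: pd.DataFrame) -> list[SeedRecord]:
    """Inverse of :func:`records_to_frame`."""
    missing = [c for c in ["plate", "id"] + FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"feature table missing columns: {missing}")
    morpho_fields = [f.name for f in fields(MorphoFeatures)]
    color_fields = [f.name for f in fields(ColorFeatures)]
    int_fields = {"area", "hisgreypeak", "hue16max", "hue32max", "hue64max"}
    records = []
    for _, row in frame.iterrows():
        morpho = MorphoFeatures(**{f: (int(row[f]) if f in int_fields else float(row[f]))
                                   for f in morpho_fields})
        color = ColorFeatures(**{f: (int(row[f]) if f in int_fields else float(row[f]))
                                 for f in color_fields})
        cond = row.get("condition")
        if cond is not None and (pd.isna(cond) or cond == ""):
            cond = None
        records.append(SeedRecord(plate=str(row["plate"]), label=int(row["id"]),
                                  morpho=morpho, color=color, condition=cond))
    return records
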