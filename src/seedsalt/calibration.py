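"""Pixel-to-metric conversion and plate-level phenotype summaries.

The scale is derived from an object of known physical size in the image —
in practice the inner diameter of the petri dish (8.50 cm).  Seed length
and width in millimeters are taken as twice the major and minor semi-axes
(the matched-ellipse full axes).  All values are kept at full precision;
the two-decimal truncated display mirrors how px/cm scales are printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .features import SeedRecord
from .io_config import truncate2


@dataclass
class ScaleCalibration:
    px_per_cm: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.px_per_cm > 0:
            raise ValueError("px_per_cm must be positive")

    @property
    def display(self) -> float:
        """Two-decimal truncated px/cm, the printed-report convention."""
        return truncate2(self.px_per_cm)


@dataclass
class PlateSummary:
    plate: str
    n_seeds: int
    mean_area_px: Optional[float] = None
    mean_area_mm2: Optional[float] = None
    mean_length_mm: Optional[float] = None
    mean_width_mm: Optional[float] = None
    mean_circularity: Optional[float] = None


def pixels_per_cm(diameter_px: float, diameter_cm: float,
                  source: str = "dish inner diameter") -> ScaleCalibration:
    """Scale from a measured diameter, e.g. 846.50 px / 8.50 cm -> 99.58."""
    if not (diameter_px > 0 and diameter_cm > 0):
        raise ValueError("diameters must be positive")
    return ScaleCalibration(px_per_cm=diameter_px / diameter_cm, source=source)


def seed_dimensions(morpho, cal: ScaleCalibration) -> tuple[float, float]:
    """(length, width) in mm: double the semi-axes, converted by the scale."""
    length = 2.0 * morpho.major / cal.px_per_cm * 10.0
    width = 2.0 * morpho.minor / cal.px_per_cm * 10.0
    return length, width


def plate_summary(records: Sequence[SeedRecord],
                  cal: Optional[ScaleCalibration] = None,
                  plate: Optional[str] = None) -> PlateSummary:
    """Seed count and mean size/shape for one plate; metric fields are
    present only when a calibration is supplied."""
    plate_id = plate if plate is not None else (records[0].plate if records else "")
    n = len(records)
    if n == 0:
        return PlateSummary(plate=plate_id, n_seeds=0)
    mean_area = sum(r.morpho.area for r in records) / n
    summary = PlateSummary(
        plate=plate_id,
        n_seeds=n,
        mean_area_px=mean_area,
        mean_circularity=sum(r.morpho.circularity for r in records) / n,
    )
    if cal is not None:
        dims = [seed_dimensions(r.morpho, cal) for r in records]
        summary.mean_area_mm2 = mean_area / cal.px_per_cm**2 * 100.0
        summary.mean_length_mm = sum(d[0] for d in dims) / n
        summary.mean_width_mm = sum(d[1] for d in dims) / n
    return summary
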