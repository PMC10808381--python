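"""Synthetic seed-plate generator with ground truth.

Each synthetic plate is a circular dish on a rectangular raster holding
non-overlapping filled ellipses ("seeds") with per-seed size, aspect,
orientation and color drawn from class-dependent distributions, plus
per-pixel Gaussian noise.  The three illumination modes are emulated by
their color regimes: FLUO has a dark background with red-dominant,
near-zero-blue seed signal; VISBACK a bright background with dark seeds;
VISFRONT a mid-grey background with darker, textured seeds.

Defaults mirror the real study conditions: ~90 seeds per 0.1 g plate, a
dish of radius 425 px at ~100 px/cm (8.5 cm inner diameter), seed
semi-major axis ~9.8 px with aspect ratio ~1.9.  The default salt effect
— the class signal the classifiers must learn — is a 30% larger mean
semi-major axis and a +40 shift of the mean red intensity.

Every plate carries its ground-truth label raster and per-seed truth
records, so segmentation, feature extraction and classification can all
be validated without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io_config import MODES, ConfigError, PlateImage

DEFAULT_SALT_SIZE_FACTOR = 1.3
DEFAULT_SALT_RED_SHIFT = 40.0

#: Per-mode color regimes: (background RGB, seed mean RGB, per-seed channel
#: sd, extra in-seed texture sd).
_MODE_COLORS = {
    "FLUO": ((8, 6, 4), (150, 60, 5), 12.0, 0.0),
    "VISBACK": ((230, 230, 230), (90, 60, 40), 10.0, 0.0),
    "VISFRONT": ((120, 120, 120), (110, 70, 40), 10.0, 8.0),
}


class GenerationError(RuntimeError):
    """Raised when seeds cannot be placed without overlap."""


@dataclass
class SyntheticPlateSpec:
    """Distributional description of one synthetic plate."""

    mode: str = "FLUO"
    condition: str = "non-salt"
    height: int = 1024
    width: int = 1024
    dish_center: tuple[float, float] = (512.0, 512.0)
    dish_radius: float = 425.0
    n_seeds: int = 90
    semi_major_mean: float = 9.8
    semi_major_sd: float = 1.2
    aspect_mean: float = 1.9
    aspect_sd: float = 0.15
    seed_rgb_mean: Optional[tuple[float, float, float]] = None  # default from mode
    seed_rgb_sd: Optional[float] = None
    background_rgb: Optional[tuple[float, float, float]] = None
    noise_sd: float = 6.0
    texture_sd: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        bg, fg, sd, tex = _MODE_COLORS[self.mode]
        if self.background_rgb is None:
            self.background_rgb = bg
        if self.seed_rgb_mean is None:
            self.seed_rgb_mean = fg
        if self.seed_rgb_sd is None:
            self.seed_rgb_sd = sd
        if self.texture_sd is None:
            self.texture_sd = tex
        if not all(0 <= v <= 255 for v in (*self.background_rgb, *self.seed_rgb_mean)):
            raise ConfigError("intensity means must lie in [0, 255]")
        if self.n_seeds < 0:
            raise ConfigError("n_seeds must be >= 0")


@dataclass
class SeedTruth:
    """Ground truth for one generated seed."""

    label: int
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # radians, [0, pi)
    condition: str

    @property
    def area(self) -> float:
        """Continuous ellipse area pi*a*b."""
        return math.pi * self.semi_major * self.semi_minor


@dataclass
class SyntheticPlate:
    image: PlateImage
    labels: np.ndarray  # uint16 ground-truth label raster
    truth: list[SeedTruth]
    condition: str


def default_spec(mode: str = "FLUO", condition: str = "non-salt", seed: int = 0,
                 size_factor: float = DEFAULT_SALT_SIZE_FACTOR,
                 red_shift: float = DEFAULT_SALT_RED_SHIFT,
                 **overrides) -> SyntheticPlateSpec:
    """Study-condition spec for one plate; the salt class gets the default
    size and red-intensity effect applied on top of the mode's regime."""
    spec = SyntheticPlateSpec(mode=mode, condition=condition, seed=seed, **overrides)
    if condition == "salt":
        r, g, b = spec.seed_rgb_mean
        spec = replace(spec,
                       semi_major_mean=spec.semi_major_mean * size_factor,
                       seed_rgb_mean=(min(r + red_shift, 255.0), g, b))
    return spec


def _place_seeds(spec: SyntheticPlateSpec, rng: np.random.Generator) -> list[SeedTruth]:
    placed: list[SeedTruth] = []
    cr, cc = spec.dish_center
    max_tries = 200 * max(spec.n_seeds, 1)
    tries = 0
    while len(placed) < spec.n_seeds:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {spec.n_seeds} non-overlapping seeds after "
                f"{max_tries} attempts; use fewer or smaller seeds")
        tries += 1
        a = max(float(rng.normal(spec.semi_major_mean, spec.semi_major_sd)), 2.0)
        aspect = max(float(rng.normal(spec.aspect_mean, spec.aspect_sd)), 1.0)
        b = max(a / aspect, 1.0)
        theta = float(rng.uniform(0.0, math.pi))
        margin = spec.dish_radius - a - 2.0
        if margin <= 0:
            raise GenerationError("dish too small for the requested seed size")
        # uniform position within the allowed disc
        rad = margin * math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * math.pi)
        center = (cr + rad * math.sin(ang), cc + rad * math.cos(ang))
        ok = True
        for other in placed:
            dr = center[0] - other.center[0]
            dc = center[1] - other.center[1]
            if math.hypot(dr, dc) <= a + other.semi_major + 2.0:
                ok = False
                break
        if ok:
            placed.append(SeedTruth(label=len(placed) + 1, center=center,
                                    semi_major=a, semi_minor=b,
                                    orientation=theta, condition=spec.condition))
    return placed


def _rasterize(truth: SeedTruth, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of the pixels whose centers fall inside the ellipse."""
    a, b = truth.semi_major, truth.semi_minor
    cr, cc = truth.center
    ext = int(math.ceil(a)) + 1
    r0, r1 = max(int(cr) - ext, 0), min(int(cr) + ext + 1, shape[0])
    c0, c1 = max(int(cc) - ext, 0), min(int(cc) + ext + 1, shape[1])
    rows = np.arange(r0, r1)[:, None] - cr
    cols = np.arange(c0, c1)[None, :] - cc
    ct, st = math.cos(truth.orientation), math.sin(truth.orientation)
    u = rows * st + cols * ct
    v = -rows * ct + cols * st
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    rr, cc_idx = np.nonzero(inside)
    return rr + r0, cc_idx + c0


def generate_plate(spec: SyntheticPlateSpec, plate_id: Optional[str] = None) -> SyntheticPlate:
    """Generate one plate image, its label raster and per-seed truth.

    Deterministic for a given spec (including its rng seed).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background_rgb, dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.uint16)
    truth = _place_seeds(spec, rng)
    for seed_truth in truth:
        rr, cc = _rasterize(seed_truth, (h, w))
        color = rng.normal(spec.seed_rgb_mean, spec.seed_rgb_sd, size=3)
        img[rr, cc, :] = np.clip(color, 0, 255)
        if spec.texture_sd and spec.texture_sd > 0:
            img[rr, cc, :] += rng.normal(0.0, spec.texture_sd, size=(len(rr), 3))
        labels[rr, cc] = seed_truth.label
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    pid = plate_id if plate_id is not None else f"{spec.mode.lower()}_{spec.condition}_{spec.seed}"
    image = PlateImage(id=pid, pixels=pixels, mode=spec.mode,
                       px_per_cm=2.0 * spec.dish_radius / 8.5)
    return SyntheticPlate(image=image, labels=labels, truth=truth,
                          condition=spec.condition)


def generate_dataset(n_plates_per_class: int,
                     salt_spec: SyntheticPlateSpec,
                     nonsalt_spec: SyntheticPlateSpec,
                     seed: int = 0) -> list[SyntheticPlate]:
    """Balanced labeled dataset; per-plate rng seeds derive from ``seed``."""
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_plates_per_class)
    plates = []
    for i in range(n_plates_per_class):
        for j, base in enumerate((nonsalt_spec, salt_spec)):
            spec = replace(base, seed=int(child_seeds[2 * i + j] % (2**31)))
            pid = f"{base.mode.lower()}_{base.condition}_{i:03d}"
            plates.append(generate_plate(spec, plate_id=pid))
    return plates
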