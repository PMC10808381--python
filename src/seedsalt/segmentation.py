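"""Seed segmentation: thresholding and contour-tracing region labeling.

Binarization selects one channel (or the grey mean), applies a fixed or
Otsu threshold with a stated polarity, and optionally restricts the search
to a circular region of interest (the dish).  Connected components are then
found with a combined contour tracing / region labeling pass: a single
raster scan that, at each unvisited boundary pixel, launches a clockwise
Moore-neighborhood trace of the component's contour and propagates labels
to interior pixels.  The outer contour of every region is retained, since
the shape features downstream are defined on it.

Foreground connectivity is 8, background 4 (the standard companion of
Moore tracing).  Touching seeds form a single region; no splitting is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_config import PlateImage, SegmentationConfig

# Moore neighborhood in clockwise order for image coordinates
# (row increases downward): E, SE, S, SW, W, NW, N, NE.
_DIRS = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


@dataclass
class SeedRegion:
    """One labeled 8-connected region and its traced outer contour.

    ``pixels`` is an (N, 2) array of (row, col) coordinates; ``outer_contour``
    an ordered (M, 2) array of boundary pixel centers forming a closed
    clockwise cycle (the successor of the last point is the first).
    """

    label: int
    pixels: np.ndarray
    outer_contour: np.ndarray

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.pixels.mean(axis=0)
        return float(r), float(c)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        mn = self.pixels.min(axis=0)
        mx = self.pixels.max(axis=0)
        return int(mn[0]), int(mn[1]), int(mx[0]), int(mx[1])

    def mask(self) -> np.ndarray:
        """Boolean mask of the region within its bounding box."""
        r0, c0, r1, c1 = self.bbox
        m = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
        m[self.pixels[:, 0] - r0, self.pixels[:, 1] - c0] = True
        return m


def _select_channel(pixels: np.ndarray, channel: str) -> np.ndarray:
    if channel == "grey":
        return np.rint(pixels.mean(axis=2)).astype(np.uint8)
    idx = {"red": 0, "green": 1, "blue": 2}[channel]
    return pixels[:, :, idx]


def _roi_mask(shape: tuple[int, int], roi) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    cr, cc, rad = roi
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= rad**2


def otsu_threshold(values: np.ndarray, polarity: str = "bright_objects") -> int:
    """Exhaustive Otsu threshold for the given foreground polarity.

    Scans every split of the 0-255 histogram and returns the threshold T
    maximizing the between-class variance, expressed so that the standard
    foreground rule (``v >= T`` for bright objects, ``v <= T`` for dark
    objects) realizes the optimal split.  Ties take the smallest T.
    """
    hist = np.bincount(np.asarray(values, dtype=np.uint8).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if total == 0:
        return 0
    bins = np.arange(256, dtype=np.float64)
    w_lo = np.cumsum(hist)  # w_lo[t] = #pixels <= t
    s_lo = np.cumsum(hist * bins)
    best_var = -1.0
    best_split = 0
    # split s: low class = values < s, high class = values >= s, s in 1..255
    for s in range(1, 256):
        n_lo = w_lo[s - 1]
        n_hi = total - n_lo
        if n_lo == 0 or n_hi == 0:
            continue
        mu_lo = s_lo[s - 1] / n_lo
        mu_hi = (s_lo[255] - s_lo[s - 1]) / n_hi
        var = n_lo * n_hi * (mu_lo - mu_hi) ** 2
        if var > best_var + 1e-12 * max(best_var, 1.0):
            best_var = var
            best_split = s
    if best_var < 0:  # single-valued histogram
        best_split = int(np.flatnonzero(hist)[0]) + 1
    return best_split if polarity == "bright_objects" else best_split - 1


def binarize(image: PlateImage, config: SegmentationConfig) -> np.ndarray:
    """Threshold the plate into a boolean foreground mask.

    A pixel is foreground iff its selected channel value is >= threshold
    (``bright_objects``) or <= threshold (``dark_objects``); pixels outside
    the roi circle are always background.  ``threshold="otsu"`` computes the
    threshold from the (roi-restricted) histogram.
    """
    config.validate()
    channel = _select_channel(image.pixels, config.channel)
    roi = _roi_mask(channel.shape, config.roi) if config.roi is not None else None
    if config.threshold == "otsu":
        values = channel[roi] if roi is not None else channel
        thr = otsu_threshold(values, config.polarity)
    else:
        thr = int(config.threshold)
    if config.polarity == "bright_objects":
        mask = channel >= thr
    else:
        mask = channel <= thr
    if roi is not None:
        mask &= roi
    return mask


def _trace_contour(mask: np.ndarray, labels: np.ndarray,
                   start: tuple[int, int], d0: int, label: int) -> list[tuple[int, int]]:
    """Moore-neighborhood trace from ``start`` searching clockwise from
    direction index ``d0``; labels contour pixels and marks visited
    background pixels with -1.  Returns the closed contour (start repeated
    only implicitly)."""

    def next_point(p, d_init):
        r, c = p
        for i in range(8):
            d = (d_init + i) % 8
            dr, dc = _DIRS[d]
            rr, cc = r + dr, c + dc
            if mask[rr, cc]:
                return (rr, cc), d
            labels[rr, cc] = -1
        return None, -1

    labels[start] = label
    second, d = next_point(start, d0)
    if second is None:  # isolated pixel
        return [start]
    contour = [start]
    p, prev_d = second, d
    while True:
        labels[p] = label
        contour.append(p)
        nxt, d = next_point(p, (prev_d + 6) % 8)
        if p == start and nxt == second:
            contour.pop()  # drop the duplicated start point
            break
        p, prev_d = nxt, d
    return contour


def label_regions(mask: np.ndarray) -> list[SeedRegion]:
    """Label 8-connected foreground components by combined contour tracing
    and region labeling.

    A single raster scan assigns labels in first-encounter order: an
    unlabeled pixel with background above starts a new external contour
    trace (clockwise); a pixel with unvisited background below starts an
    internal contour trace (so holes never spawn spurious labels); any
    other unlabeled foreground pixel inherits its left neighbor's label.
    The union of the region pixel sets equals the foreground set.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    labels = np.zeros((h + 2, w + 2), dtype=np.int32)
    contours: list[list[tuple[int, int]]] = []

    for r in range(1, h + 1):
        for c in np.flatnonzero(padded[r]):
            if labels[r, c] == 0 and not padded[r - 1, c]:
                # new external contour (first encounter of a component)
                contours.append(_trace_contour(padded, labels, (r, c), 7, len(contours) + 1))
            # a pixel can lie on both the external contour and a hole's
            # internal contour, so this is not an elif
            if not padded[r + 1, c] and labels[r + 1, c] == 0:
                # internal contour around a hole
                if labels[r, c] == 0:
                    labels[r, c] = labels[r, c - 1]
                _trace_contour(padded, labels, (r, c), 3, labels[r, c])
            elif labels[r, c] == 0:
                labels[r, c] = labels[r, c - 1]

    core = labels[1:-1, 1:-1]
    regions: list[SeedRegion] = []
    flat = core.ravel()
    fg = np.flatnonzero(flat > 0)
    order = np.argsort(flat[fg], kind="stable")
    bounds = np.searchsorted(flat[fg][order], np.arange(1, len(contours) + 2))
    coords = np.column_stack(np.unravel_index(fg[order], core.shape))
    for lbl in range(1, len(contours) + 1):
        pix = coords[bounds[lbl - 1]:bounds[lbl]]
        contour = np.array(contours[lbl - 1], dtype=np.int64) - 1  # undo padding offset
        regions.append(SeedRegion(label=lbl, pixels=pix, outer_contour=contour))
    return regions


def label_raster(regions: list[SeedRegion], shape: tuple[int, int]) -> np.ndarray:
    """Render regions as a uint16 label image (0 = background)."""
    out = np.zeros(shape, dtype=np.uint16)
    for reg in regions:
        out[reg.pixels[:, 0], reg.pixels[:, 1]] = reg.label
    return out


def filter_regions(regions: list[SeedRegion], config: SegmentationConfig) -> list[SeedRegion]:
    """Keep regions with min_area <= area <= max_area and centroid inside the
    roi (when set); survivors are relabeled consecutively from 1 in scan
    order."""
    config.validate()
    kept = []
    for reg in regions:
        if not (config.min_area <= reg.area <= config.max_area):
            continue
        if config.roi is not None:
            cr, cc, rad = config.roi
            r, c = reg.centroid
            if (r - cr) ** 2 + (c - cc) ** 2 > rad**2:
                continue
        kept.append(reg)
    return [SeedRegion(label=i + 1, pixels=reg.pixels, outer_contour=reg.outer_contour)
            for i, reg in enumerate(kept)]


def segment(image: PlateImage, config: SegmentationConfig) -> list[SeedRegion]:
    """Full segmentation: binarize, label, size/roi gate."""
    return filter_regions(label_regions(binarize(image, config)), config)


def count_objects(image: PlateImage, config: SegmentationConfig) -> int:
    """Number of detected objects (seeds, pods, ...) on the plate."""
    return len(segment(image, config))
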