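"""Synthetic side-view images of a pinned chamber and height measurement.

The generator renders, in orthographic projection, the circular-segment
profile of a cap of known height sitting on a substrate line, together
with a dispensing needle of known outer diameter (210 um) hanging into the
frame as the scale reference.  ``measure_height`` recovers the cap height
the way the bench workflow does: locate the needle to calibrate um/px,
find the substrate line and the cap apex, and convert their separation to
a physical height.  Lens and meniscus optics are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import median

from ..geometry import DepinningError, InvalidSpecError, curvature_radius


class ScaleError(ValueError):
    """The needle scale reference could not be located."""


@dataclass
class SideViewImage:
    """Grayscale side view (float in [0, 1], bright background)."""

    pixels: np.ndarray
    h_true_mm: float
    needle_diameter_um: float
    noise: float
    pixel_size_um: float  # ground truth, not used by measure_height


# fixed render geometry (pixels)
_NEEDLE_ROWS = 30
_SUBSTRATE_MARGIN = 30
_FOREGROUND = 0.15
_BACKGROUND = 0.95


def gen_sideview(
    h_true_mm: float,
    a_mm: float,
    needle_diameter_um: float = 210.0,
    noise: float = 0.03,
    seed: int = 0,
    pixel_size_um: float = 5.0,
    theta_adv_deg: float = 70.0,
) -> SideViewImage:
    """Render a cap of height ``h_true_mm`` on footprint radius ``a_mm``.

    Raises DepinningError when the requested height exceeds the pinned
    maximum for the given advancing angle.  Deterministic given ``seed``.
    """
    if h_true_mm < 0 or a_mm <= 0:
        raise InvalidSpecError("need h >= 0 and a > 0")
    h_max_mm = a_mm * math.tan(math.radians(theta_adv_deg) / 2.0)
    if h_true_mm > h_max_mm * (1 + 1e-12):
        raise DepinningError(
            f"h={h_true_mm} mm exceeds the pinned maximum {h_max_mm:.3f} mm"
        )
    px = pixel_size_um
    needle_w_px = int(round(needle_diameter_um / px))
    if needle_w_px <= 10:
        raise InvalidSpecError(
            "needle must span > 10 px for reliable scale recovery; decrease pixel_size_um"
        )
    a_px = a_mm * 1e3 / px
    h_px_max = h_max_mm * 1e3 / px

    needle_region = needle_w_px + 40
    width = int(needle_region + 2 * a_px + 60)
    height = int(_NEEDLE_ROWS + h_px_max + _SUBSTRATE_MARGIN + 60)
    img = np.full((height, width), _BACKGROUND)

    sub_row = height - _SUBSTRATE_MARGIN
    img[sub_row : sub_row + 3, :] = _FOREGROUND  # substrate line

    # needle: vertical bar at the left, top rows only
    img[:_NEEDLE_ROWS, 20 : 20 + needle_w_px] = _FOREGROUND

    # drop profile: circular segment through (+-a, 0) and (0, h)
    h_m = h_true_mm * 1e-3
    a_m = a_mm * 1e-3
    cx = needle_region + a_px + 10
    if h_m > 0:
        R = curvature_radius(h_m, a_m)
        z0 = h_m - R  # circle centre height (negative below substrate)
        cols = np.arange(width)
        x_m = (cols - cx) * px * 1e-6
        inside = np.abs(x_m) <= a_m
        y_m = np.zeros(width)
        y_m[inside] = np.sqrt(np.maximum(R * R - x_m[inside] ** 2, 0.0)) + z0
        top_rows = sub_row - np.round(y_m / (px * 1e-6)).astype(int)
        for c in np.nonzero(inside)[0]:
            img[top_rows[c] : sub_row, c] = _FOREGROUND

    if noise > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return SideViewImage(
        pixels=img,
        h_true_mm=h_true_mm,
        needle_diameter_um=needle_diameter_um,
        noise=noise,
        pixel_size_um=px,
    )


def measure_height(img: SideViewImage, flipped: bool = False) -> float:
    """Recover the cap height (mm) from a side-view image.

    Steps: median-filter and threshold; measure the needle's width in
    pixels near the top of the frame to calibrate um/px from its known
    outer diameter; find the substrate as the widest dark row; take the cap
    apex as the topmost dark pixel below the needle.  ``flipped=True``
    handles upside-down acquisitions.
    """
    pixels = img.pixels[::-1].copy() if flipped else img.pixels
    smooth = median(pixels, np.ones((3, 3), dtype=bool))
    dark = smooth < 0.5

    # needle width from the top rows
    widths = []
    for r in range(3, _NEEDLE_ROWS - 3):
        runs = _longest_run(dark[r])
        if runs > 0:
            widths.append(runs)
    if not widths:
        raise ScaleError("needle not found in the top rows of the frame")
    needle_w_px = float(np.median(widths))
    if needle_w_px <= 10:
        raise ScaleError("needle too small in frame for a reliable scale")
    um_per_px = img.needle_diameter_um / needle_w_px

    # substrate: the row with the widest dark extent (spans the full frame)
    row_counts = dark.sum(axis=1)
    sub_row = int(np.argmax(row_counts))
    # apex: topmost dark pixel below the needle rows and above the substrate
    body = dark[_NEEDLE_ROWS:sub_row]
    rows_with_dark = np.nonzero(body.any(axis=1))[0]
    if rows_with_dark.size == 0:
        return 0.0
    apex_row = int(rows_with_dark[0]) + _NEEDLE_ROWS
    return (sub_row - apex_row) * um_per_px * 1e-3


def _longest_run(row: np.ndarray) -> int:
    """Length of the longest run of True values in a 1D boolean array."""
    if not row.any():
        return 0
    padded = np.concatenate([[0], row.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return int((ends - starts).max())
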