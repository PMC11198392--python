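"""Neurite coverage metrics over the dumbbell footprint.

Inputs are binary coverage masks (thresholding of the raw fluorescence is
upstream and out of scope here; a fixed-threshold helper is provided for
convenience only).  Physical coordinates are micrometres with the origin
at the left chamber/conduit junction and x increasing toward the distal
chamber; a pixel belongs to a region of interest when its *centre* falls
inside the half-open rectangle [x_min, x_max) x [y_min, y_max).

Metrics implemented:

* covered area of a mask within an ROI (um^2);
* outgrowth index (A_d20 - A_d0)/A_d0 of conduit coverage;
* per-batch fold-difference against a control group;
* the post-axotomy regeneration zone (abutting the proximal damage line,
  conduit width x 300 um into the cleared area) and the regrowth fraction
  series normalised to pre-axotomy coverage, with exclusion of
  incompletely severed preparations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import InvalidSpecError


@dataclass
class NeuriteMask:
    """Binary coverage raster with physical calibration.

    data            2D boolean array (rows = y, cols = x)
    pixel_size_um   edge of one square pixel (um)
    origin_um       physical (x, y) of the *corner* of pixel [0, 0] (um)
    day             acquisition label (e.g. day number or hours post-axotomy)
    """

    data: np.ndarray
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    day: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise InvalidSpecError("mask must be 2D")
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1, 255))):
                raise InvalidSpecError("mask raster must be binary (0/1 or 0/255)")
            self.data = self.data > 0
        if self.pixel_size_um <= 0:
            raise InvalidSpecError("pixel size must be > 0")

    @property
    def x_centers_um(self) -> np.ndarray:
        return self.origin_um[0] + (np.arange(self.data.shape[1]) + 0.5) * self.pixel_size_um

    @property
    def y_centers_um(self) -> np.ndarray:
        return self.origin_um[1] + (np.arange(self.data.shape[0]) + 0.5) * self.pixel_size_um

    @property
    def extent_um(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the pixel grid."""
        h, w = self.data.shape
        x0, y0 = self.origin_um
        return (x0, x0 + w * self.pixel_size_um, y0, y0 + h * self.pixel_size_um)

    # ---- IO: TIFF/PNG raster + JSON sidecar --------------------------------

    def save(self, path: str | Path) -> None:
        """Write the raster (uint8 0/255) plus a JSON sidecar with calibration."""
        path = Path(path)
        raster = (self.data.astype(np.uint8)) * 255
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, raster)
        else:
            from PIL import Image

            Image.fromarray(raster).save(path)
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "origin_um": list(self.origin_um),
            "day": self.day,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "NeuriteMask":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            raster = tifffile.imread(path)
        else:
            from PIL import Image

            raster = np.asarray(Image.open(path))
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            data=raster > 0,
            pixel_size_um=float(meta["pixel_size_um"]),
            origin_um=tuple(meta.get("origin_um", (0.0, 0.0))),
            day=meta.get("day"),
        )


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangle in physical um coordinates, half-open bounds."""

    x_min_um: float
    x_max_um: float
    y_min_um: float
    y_max_um: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.x_max_um < self.x_min_um or self.y_max_um < self.y_min_um:
            raise InvalidSpecError("ROI must have non-negative extents")

    @property
    def width_um(self) -> float:
        return self.y_max_um - self.y_min_um

    @property
    def area_um2(self) -> float:
        return (self.x_max_um - self.x_min_um) * (self.y_max_um - self.y_min_um)


def conduit_roi(length_um: float = 1000.0, width_um: float = 200.0) -> ROISpec:
    """ROI covering the conduit: [0, L] x [-w/2, w/2] in the standard frame."""
    return ROISpec(0.0, length_um, -width_um / 2.0, width_um / 2.0, label="conduit")


def covered_area(mask: NeuriteMask, roi: ROISpec) -> float:
    """Area (um^2) of positive pixels whose centres fall inside the ROI.

    An ROI partially outside the mask frame is clipped with a warning; an
    ROI with no overlap returns 0 with a warning.
    """
    fx0, fx1, fy0, fy1 = mask.extent_um
    if roi.x_min_um < fx0 or roi.x_max_um > fx1 or roi.y_min_um < fy0 or roi.y_max_um > fy1:
        warnings.warn(f"ROI {roi.label!r} extends beyond the mask frame; clipping")
    in_x = (mask.x_centers_um >= roi.x_min_um) & (mask.x_centers_um < roi.x_max_um)
    in_y = (mask.y_centers_um >= roi.y_min_um) & (mask.y_centers_um < roi.y_max_um)
    if not in_x.any() or not in_y.any():
        warnings.warn(f"ROI {roi.label!r} does not overlap the mask frame")
        return 0.0
    count = int(mask.data[np.ix_(in_y, in_x)].sum())
    return count * mask.pixel_size_um**2


@dataclass(frozen=True)
class OutgrowthResult:
    """Conduit-coverage change between two timepoints."""

    A_d0_um2: float
    A_d20_um2: float
    delta_A_um2: float
    normalized: float  # (A_d20 - A_d0) / A_d0


def outgrowth_index(
    mask_d0: NeuriteMask, mask_d20: NeuriteMask, roi: ROISpec
) -> OutgrowthResult:
    """Outgrowth as coverage gained in the ROI, normalised by the day-0 area.

    Normalising by A_d0 decouples the index from the number of seeded cells,
    which sets the initial coverage.
    """
    if mask_d0.data.shape != mask_d20.data.shape:
        raise InvalidSpecError("masks must share a frame (shape mismatch)")
    if not np.isclose(mask_d0.pixel_size_um, mask_d20.pixel_size_um):
        raise InvalidSpecError("masks must share a pixel size")
    a0 = covered_area(mask_d0, roi)
    a20 = covered_area(mask_d20, roi)
    if a0 == 0.0:
        raise InvalidSpecError("outgrowth index undefined: day-0 coverage is zero")
    return OutgrowthResult(
        A_d0_um2=a0, A_d20_um2=a20, delta_A_um2=a20 - a0, normalized=(a20 - a0) / a0
    )


def fold_difference(values: Sequence[float], control_values: Sequence[float]) -> np.ndarray:
    """Each value divided by the mean of its batch's control group."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise InvalidSpecError("control group is empty")
    mean = control.mean()
    if mean <= 0:
        raise InvalidSpecError("control mean must be > 0")
    return np.asarray(values, dtype=float) / mean


def regeneration_zone(
    damage_line_x_um: float,
    conduit: ROISpec,
    extent_um: float = 300.0,
    width_um: Optional[float] = None,
) -> ROISpec:
    """Scoring zone for regrowth after axotomy.

    The rectangle abuts the proximal damage line, shares the conduit's
    width (200 um by default) and extends ``extent_um`` (300 um) into the
    cleared area on the distal side: a 200 x 300 um = 6e4 um^2 zone.
    """
    if extent_um < 0:
        raise InvalidSpecError("zone extent must be >= 0")
    if width_um is None:
        y0, y1 = conduit.y_min_um, conduit.y_max_um
    else:
        yc = 0.5 * (conduit.y_min_um + conduit.y_max_um)
        y0, y1 = yc - width_um / 2.0, yc + width_um / 2.0
    return ROISpec(
        damage_line_x_um, damage_line_x_um + extent_um, y0, y1, label="regeneration_zone"
    )


@dataclass
class RegenerationResult:
    """Regrowth fraction series for one dumbbell."""

    times: list[float]
    areas_um2: list[float]
    reference_area_um2: float
    fractions: Optional[list[float]]
    excluded: bool = False
    exclusion_reason: str = ""


def regrowth_fraction(
    series: Sequence[NeuriteMask],
    reference_d20: NeuriteMask,
    zone: ROISpec,
    severance_threshold: float = 0.05,
) -> RegenerationResult:
    """Fraction of the axotomised zone re-covered over time.

    ``series`` is chronological with the first mask taken immediately
    post-axotomy.  fraction(t) = covered(zone, t) / covered(zone, d20
    pre-axotomy).  If residual post-axotomy coverage exceeds
    ``severance_threshold`` of the reference, the preparation is flagged
    excluded ("incomplete severing") and no fractions are reported, as is a
    preparation whose reference coverage is zero.
    """
    if not series:
        raise InvalidSpecError("empty mask series")
    ref = covered_area(reference_d20, zone)
    times = [float(m.day) if m.day is not None else float(i) for i, m in enumerate(series)]
    areas = [covered_area(m, zone) for m in series]
    if ref == 0.0:
        return RegenerationResult(
            times, areas, ref, None, excluded=True,
            exclusion_reason="reference coverage is zero",
        )
    if areas[0] > severance_threshold * ref:
        return RegenerationResult(
            times, areas, ref, None, excluded=True,
            exclusion_reason="incomplete severing",
        )
    return RegenerationResult(times, areas, ref, [a / ref for a in areas])


def threshold_mask(
    image: np.ndarray, pixel_size_um: float, threshold: float,
    origin_um: tuple[float, float] = (0.0, 0.0), day: Optional[float] = None,
) -> NeuriteMask:
    """Fixed-threshold binarisation of a grayscale image (convenience only;
    the reference pipeline segments fluorescence upstream with dedicated
    image-analysis software, which this helper does not reproduce)."""
    return NeuriteMask(np.asarray(image) > threshold, pixel_size_um, origin_um, day)


def results_table(records: Sequence[dict]) -> pd.DataFrame:
    """Tidy metric export: dumbbell_id, condition, batch, metric, value."""
    df = pd.DataFrame.from_records(records)
    required = {"dumbbell_id", "condition", "batch", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidSpecError(f"results records missing fields {sorted(missing)}")
    return df[sorted(df.columns, key=lambda c: (c not in required, c))]
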