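"""Synthetic neurite coverage masks with programmed growth and regrowth.

Axons are modelled as biased random-walk polylines launched from a start
line in the left chamber and elongating into the conduit at a per-axon
rate; they are rasterised at a stated thickness.  No biology is claimed:
the generator's only job is controllable coverage with exact ground truth,
so every quantification stage can be validated against bookkeeping.

All generators are deterministic under a fixed seed and return the
per-timepoint true covered area per ROI alongside the rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from ..geometry import DumbbellSpec, InvalidSpecError
from ..quantify import NeuriteMask, ROISpec, conduit_roi


@dataclass(frozen=True)
class GrowthModelParams:
    """Controls of the random-walk growth model (um and days).

    elongation is the mean tip speed; each axon draws its own speed from a
    normal spread (clipped at zero).  ``wander_um`` scales lateral
    diffusion of the tip per 10 um of advance.
    """

    seed: int
    n_axons: int = 30
    elongation_um_per_day: float = 50.0
    elongation_spread: float = 10.0
    wander_um: float = 6.0
    thickness_um: float = 4.0
    start_x_um: float = -150.0
    initial_length_um: float = 200.0

    def __post_init__(self) -> None:
        if self.n_axons < 1:
            raise InvalidSpecError("need at least one axon")
        for name in ("elongation_um_per_day", "elongation_spread", "wander_um",
                     "thickness_um", "initial_length_um"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AxotomyParams:
    """Controls of the cleared-band regrowth model (um and hours).

    The jet clears the band [cut_position - half_width, cut_position +
    half_width]; the proximal damage line is its left edge.  After
    ``regrowth_delay_h`` the regrown front advances from the proximal line
    at ``regrowth_rate_um_per_day``.  ``residual_fraction`` leaves that
    fraction of the band's pre-cut pixels in place to exercise the
    incomplete-severing exclusion path.
    """

    seed: int
    cut_position_um: float = 500.0
    cleared_halfwidth_um: float = 200.0
    regrowth_delay_h: float = 12.0
    regrowth_rate_um_per_day: float = 100.0
    residual_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.cleared_halfwidth_um <= 0:
            raise InvalidSpecError("cleared half-width must be > 0")
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise InvalidSpecError("residual fraction must be in [0, 1]")

    @property
    def proximal_line_um(self) -> float:
        return self.cut_position_um - self.cleared_halfwidth_um

    @property
    def distal_line_um(self) -> float:
        return self.cut_position_um + self.cleared_halfwidth_um


def _frame(
    dumbbell: DumbbellSpec, pixel_size_um: float, margin_um: float
) -> tuple[tuple[float, float], tuple[int, int]]:
    """Raster window covering the conduit plus a margin into both chambers."""
    L_um = dumbbell.conduit.length_m * 1e6
    w_um = dumbbell.conduit.width_m * 1e6
    x0 = -margin_um
    y0 = -(w_um / 2.0 + margin_um)
    n_cols = int(np.ceil((L_um + 2 * margin_um) / pixel_size_um))
    n_rows = int(np.ceil((w_um + 2 * margin_um) / pixel_size_um))
    return (x0, y0), (n_rows, n_cols)


def gen_neurite_series(
    dumbbell: DumbbellSpec,
    params: GrowthModelParams,
    timepoints_days: Sequence[float],
    pixel_size_um: float = 2.0,
    rois: Optional[Sequence[ROISpec]] = None,
    margin_um: float = 300.0,
) -> tuple[list[NeuriteMask], pd.DataFrame]:
    """Generate a chronological series of coverage masks plus ground truth.

    Returns masks (one per timepoint, cumulative growth) and a tidy table
    (day, roi, area_um2) of true covered areas computed by direct pixel
    bookkeeping on the rasters.
    """
    if sorted(timepoints_days) != list(timepoints_days):
        raise InvalidSpecError("timepoints must be chronological")
    rng = np.random.default_rng(params.seed)
    if rois is None:
        rois = [conduit_roi(dumbbell.conduit.length_m * 1e6, dumbbell.conduit.width_m * 1e6)]

    origin, shape = _frame(dumbbell, pixel_size_um, margin_um)
    w_um = dumbbell.conduit.width_m * 1e6

    # per-axon polylines, generated once to their maximum length
    step_um = 2.0
    rates = np.clip(
        rng.normal(params.elongation_um_per_day, params.elongation_spread, params.n_axons),
        0.0,
        None,
    )
    max_len = params.initial_length_um + rates.max() * max(timepoints_days)
    n_steps = int(np.ceil(max_len / step_um)) + 1
    paths = []
    for i in range(params.n_axons):
        y = rng.uniform(-0.4 * w_um, 0.4 * w_um)
        xs = params.start_x_um + np.arange(n_steps) * step_um
        dy = rng.normal(0.0, params.wander_um * np.sqrt(step_um / 10.0), n_steps)
        ys = y + np.concatenate([[0.0], np.cumsum(dy[1:])])
        paths.append((xs, ys))

    selem = disk(max(int(round(params.thickness_um / 2.0 / pixel_size_um)), 1))
    masks: list[NeuriteMask] = []
    records = []
    for day in timepoints_days:
        raster = np.zeros(shape, dtype=bool)
        for i, (xs, ys) in enumerate(paths):
            length = params.initial_length_um + rates[i] * day
            k = min(int(length / step_um) + 1, n_steps)
            _rasterize_polyline(raster, xs[:k], ys[:k], origin, pixel_size_um)
        raster = dilation(raster, selem)
        mask = NeuriteMask(raster, pixel_size_um, origin, day=day)
        masks.append(mask)
        for roi in rois:
            records.append(
                {"day": day, "roi": roi.label, "area_um2": _true_area(mask, roi)}
            )
    return masks, pd.DataFrame.from_records(records)


def _rasterize_polyline(raster, xs_um, ys_um, origin_um, px) -> None:
    rows = np.floor((ys_um - origin_um[1]) / px).astype(int)
    cols = np.floor((xs_um - origin_um[0]) / px).astype(int)
    h, w = raster.shape
    for i in range(len(rows) - 1):
        rr, cc = draw_line(rows[i], cols[i], rows[i + 1], cols[i + 1])
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        raster[rr[keep], cc[keep]] = True


def _true_area(mask: NeuriteMask, roi: ROISpec) -> float:
    """Ground-truth bookkeeping: naive per-pixel loop-free count by centre."""
    x0, y0 = mask.origin_um
    px = mask.pixel_size_um
    total = 0
    for r in range(mask.data.shape[0]):
        yc = y0 + (r + 0.5) * px
        if not (roi.y_min_um <= yc < roi.y_max_um):
            continue
        for c in range(mask.data.shape[1]):
            xc = x0 + (c + 0.5) * px
            if roi.x_min_um <= xc < roi.x_max_um and mask.data[r, c]:
                total += 1
    return total * px * px


def gen_axotomy_series(
    pre_mask: NeuriteMask,
    params: AxotomyParams,
    timepoints_h: Sequence[float],
    zone: Optional[ROISpec] = None,
) -> tuple[list[NeuriteMask], pd.DataFrame]:
    """Clear the axotomy band from ``pre_mask`` and regrow it over time.

    At t = 0 the band is cleared (optionally leaving a residual pixel
    fraction); afterwards the pre-cut coverage is restored column by column
    from the proximal damage line at the programmed front speed.  Returns
    the mask series and the ground-truth covered area per timepoint inside
    ``zone`` (defaults to the standard regeneration zone of the cut).
    """
    x0, _ = pre_mask.origin_um
    px = pre_mask.pixel_size_um
    fx0, fx1, _, _ = pre_mask.extent_um
    if not (fx0 <= params.proximal_line_um and params.distal_line_um <= fx1):
        raise InvalidSpecError("cut band must lie within the mask frame")
    if zone is None:
        from ..quantify import regeneration_zone

        ext = pre_mask.extent_um
        zone = regeneration_zone(
            params.proximal_line_um,
            ROISpec(ext[0], ext[1], -100.0, 100.0, label="conduit"),
        )
    rng = np.random.default_rng(params.seed)

    xc = pre_mask.x_centers_um
    band = (xc >= params.proximal_line_um) & (xc < params.distal_line_um)
    residual = np.zeros_like(pre_mask.data)
    if params.residual_fraction > 0:
        keep = rng.random(pre_mask.data.shape) < params.residual_fraction
        residual[:, band] = pre_mask.data[:, band] & keep[:, band]

    masks: list[NeuriteMask] = []
    records = []
    for t_h in timepoints_h:
        regrown_um = max(0.0, (t_h - params.regrowth_delay_h) / 24.0) * params.regrowth_rate_um_per_day
        front = params.proximal_line_um + regrown_um
        data = pre_mask.data.copy()
        cleared = band & (xc >= front)
        data[:, cleared] = False
        data |= residual
        mask = NeuriteMask(data, px, pre_mask.origin_um, day=t_h)
        masks.append(mask)
        records.append({"t_h": t_h, "area_um2": _true_area(mask, zone)})
    truth = pd.DataFrame.from_records(records)
    truth["reference_area_um2"] = _true_area(pre_mask, zone)
    return masks, truth
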