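"""Dish-scale array layout and axotomy toolpath kinematics.

A 6 cm dish carries a rows x cols grid of dumbbells (7 x 3 = 21 by
default), conduits all parallel to x.  The axotomy toolpath visits each
conduit once with a straight cut perpendicular to the conduit axis, using
serpentine ordering to keep travel short; total time follows from segment
lengths and the traverse speed (acceleration and jet on/off dwell are
ignored by default and configurable).

Bench units (mm, mm/min, s) throughout this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .geometry import DumbbellSpec, InvalidSpecError, Pose, default_dumbbell, rebuilt_dumbbell


class PackingError(ValueError):
    """A layout does not fit the dish or overlaps itself."""


@dataclass
class ArrayLayout:
    """Grid of dumbbell poses in a circular dish (mm)."""

    dish_diameter_mm: float
    rows: int
    cols: int
    dumbbell: DumbbellSpec
    pitch_mm: tuple[float, float]  # (along conduit axis x, across y)
    margin_mm: float
    poses: list[Pose] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.poses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"index": i, "x_mm": p.x_mm, "y_mm": p.y_mm, "theta_deg": p.theta_deg}
             for i, p in enumerate(self.poses)]
        )


def layout_array(
    dumbbell: Optional[DumbbellSpec] = None,
    dish_diameter_mm: float = 60.0,
    rows: int = 3,
    cols: int = 7,
    pitch_mm: tuple[float, float] = (7.5, 7.0),
    margin_mm: float = 2.0,
) -> ArrayLayout:
    """Centred rows x cols grid of dumbbells inside the dish.

    ``cols`` counts positions along the conduit axis (x).  Raises
    PackingError naming the first pose whose footprint leaves the dish
    (keeping ``margin_mm`` clear of the rim) or overlaps a neighbour.
    """
    if dumbbell is None:
        dumbbell = default_dumbbell()
    hx, hy = dumbbell.half_extents_mm()
    px, py = pitch_mm
    if px < 2 * hx or py < 2 * hy:
        raise PackingError(
            f"pitch {pitch_mm} mm smaller than the dumbbell footprint "
            f"({2 * hx:.2f} x {2 * hy:.2f} mm): neighbouring footprints overlap"
        )
    r_fit = dish_diameter_mm / 2.0 - margin_mm
    poses = []
    for i in range(rows):
        for j in range(cols):
            x = (j - (cols - 1) / 2.0) * px
            y = (i - (rows - 1) / 2.0) * py
            # all four footprint corners must stay inside the margin circle
            r_corner = math.hypot(abs(x) + hx, abs(y) + hy)
            if r_corner > r_fit:
                raise PackingError(
                    f"dumbbell at row {i}, col {j} (x={x:.1f}, y={y:.1f} mm) exits the "
                    f"dish margin (corner radius {r_corner:.1f} > {r_fit:.1f} mm)"
                )
            poses.append(Pose(x_mm=x, y_mm=y))
    return ArrayLayout(
        dish_diameter_mm=dish_diameter_mm,
        rows=rows,
        cols=cols,
        dumbbell=dumbbell,
        pitch_mm=pitch_mm,
        margin_mm=margin_mm,
        poses=poses,
    )


def rebuild_layout(original: ArrayLayout) -> ArrayLayout:
    """Layout of the enlarged dumbbells printed around axotomised ones.

    Each new dumbbell (3.5 mm chambers, 0.5 mm x 400 um conduit) is
    concentric with its original; the new walls must lie strictly outside
    the old footprint and must not overlap neighbouring enlarged
    footprints.
    """
    big = rebuilt_dumbbell(original.dumbbell)
    hx_old, hy_old = original.dumbbell.half_extents_mm()
    hx, hy = big.half_extents_mm()
    if hx <= hx_old or hy <= hy_old:
        raise PackingError("rebuilt dumbbell does not strictly contain the original")
    px, py = original.pitch_mm
    if px < 2 * hx or py < 2 * hy:
        raise PackingError("enlarged footprints overlap at the original pitch")
    return ArrayLayout(
        dish_diameter_mm=original.dish_diameter_mm,
        rows=original.rows,
        cols=original.cols,
        dumbbell=big,
        pitch_mm=original.pitch_mm,
        margin_mm=original.margin_mm,
        poses=list(original.poses),
    )


@dataclass
class Toolpath:
    """Ordered waypoints with per-segment move kinds and speeds."""

    waypoints: list[tuple[float, float]]  # (x_mm, y_mm), len n+1 for n segments
    kinds: list[str]  # 'travel' | 'cut', one per segment
    cut_speed_mm_min: float
    travel_speed_mm_min: float
    dwell_s_per_cut: float = 0.0

    def segment_lengths_mm(self) -> list[float]:
        return [
            math.dist(self.waypoints[i], self.waypoints[i + 1])
            for i in range(len(self.kinds))
        ]

    @property
    def total_length_mm(self) -> float:
        return sum(self.segment_lengths_mm())

    @property
    def cut_length_mm(self) -> float:
        return sum(l for l, k in zip(self.segment_lengths_mm(), self.kinds) if k == "cut")

    @property
    def total_time_s(self) -> float:
        t = 0.0
        for length, kind in zip(self.segment_lengths_mm(), self.kinds):
            speed = self.cut_speed_mm_min if kind == "cut" else self.travel_speed_mm_min
            t += length / speed * 60.0
        t += self.dwell_s_per_cut * self.kinds.count("cut")
        return t

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, kind in enumerate(self.kinds):
            (x0, y0), (x1, y1) = self.waypoints[i], self.waypoints[i + 1]
            rows.append(
                {"segment": i, "kind": kind, "x0_mm": x0, "y0_mm": y0,
                 "x1_mm": x1, "y1_mm": y1}
            )
        return pd.DataFrame(rows)


def axotomy_toolpath(
    layout: ArrayLayout,
    cut_margin_mm: float = 1.4,
    speed_mm_min: float = 960.0,
    travel_speed_mm_min: Optional[float] = None,
    dwell_s_per_cut: float = 0.0,
) -> Toolpath:
    """One perpendicular cut per conduit, serpentine-ordered.

    Each cut is a straight segment across the conduit of length
    conduit width + 2 * cut_margin, centred on the dumbbell pose.  Rows
    are traversed boustrophedon and cut directions alternate so the nozzle
    always starts the next cut from the nearer end.
    """
    if travel_speed_mm_min is None:
        travel_speed_mm_min = speed_mm_min
    w_mm = layout.dumbbell.conduit.width_m * 1e3
    half = w_mm / 2.0 + cut_margin_mm

    # serpentine order over the grid
    ordered: list[Pose] = []
    for i in range(layout.rows):
        row = layout.poses[i * layout.cols : (i + 1) * layout.cols]
        ordered.extend(row if i % 2 == 0 else row[::-1])

    waypoints: list[tuple[float, float]] = []
    kinds: list[str] = []
    sign = 1.0
    for pose in ordered:
        start = (pose.x_mm, pose.y_mm - sign * half)
        end = (pose.x_mm, pose.y_mm + sign * half)
        if waypoints:
            # pick the cut direction whose start is nearer the current position
            cur = waypoints[-1]
            if math.dist(cur, (pose.x_mm, pose.y_mm + sign * half)) < math.dist(cur, start):
                start, end = end, start
            waypoints.append(start)
            kinds.append("travel")
        else:
            waypoints.append(start)
        waypoints.append(end)
        kinds.append("cut")
        sign = 1.0 if end[1] < pose.y_mm else -1.0  # next default: move away from last end
    return Toolpath(
        waypoints=waypoints,
        kinds=kinds,
        cut_speed_mm_min=speed_mm_min,
        travel_speed_mm_min=travel_speed_mm_min,
        dwell_s_per_cut=dwell_s_per_cut,
    )
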