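"""Pressure-driven equilibration of the two chambers of a dumbbell.

After unequal volumes are pipetted into the two chambers, the pressure
difference between their caps drives Poiseuille flow through the conduit
until the caps reach equal pressure.  The dynamics are a single stiff ODE:

    dV_L/dt = +dP/R_h,   dV_R/dt = -dP/R_h,   dP = P_right - P_left

with R_h the hydraulic resistance of the shallow rectangular conduit.
Flow Q is reported signed, positive for right -> left flow — the direction
that keeps freshly seeded cells in the left chamber.

The conduit is treated as a rigid rectangle and its dead volume (a few nl)
is excluded from the chamber mass balance.  Deposition events (adding or
removing medium) are instantaneous and perfectly mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import units
from .geometry import (
    ChamberState,
    ConduitSpec,
    DepinningError,
    DumbbellSpec,
    FluidProperties,
    InvalidSpecError,
    UnsupportedRegimeError,
    chamber_pressure,
    max_pinned_volume,
    pressure_difference,
)

#: FC40 free-surface height above the dish floor used when reporting
#: absolute chamber pressures (m).  It cancels in every pressure difference.
DEFAULT_H_FC40_M = 2.0e-3


def hydraulic_resistance(conduit: ConduitSpec, fluids: FluidProperties) -> float:
    """Hydraulic resistance of a shallow rectangular channel (Pa s / m^3).

    Lubrication-theory result for height << width:

        R_h = 12 mu L / (w h^3 (1 - 0.63 h/w))

    This is a modelling choice: the platform only needs the *direction* of
    flow, so the absolute resistance sets timescales, not outcomes.
    """
    h, w, L = conduit.height_m, conduit.width_m, conduit.length_m
    if h > w:
        raise UnsupportedRegimeError("shallow-channel law requires height <= width")
    return 12.0 * fluids.mu_med * L / (w * h**3 * (1.0 - 0.63 * h / w))


@dataclass(frozen=True)
class DepositionEvent:
    """Instantaneous addition (dV_ul > 0) or removal (dV_ul < 0) of medium."""

    time_s: float
    chamber: str  # 'left' | 'right'
    dV_ul: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.chamber not in ("left", "right"):
            raise InvalidSpecError(f"unknown chamber {self.chamber!r}")


@dataclass
class FlowTrajectory:
    """Dense output of an equilibration run (SI arrays on a common grid).

    Q_m3_s is the conduit volumetric flow, signed positive for
    right -> left flow; deltaP_pa = P_right - P_left.
    """

    t_s: np.ndarray
    V_left_m3: np.ndarray
    V_right_m3: np.ndarray
    h_left_m: np.ndarray
    h_right_m: np.ndarray
    P_left_pa: np.ndarray
    P_right_pa: np.ndarray
    deltaP_pa: np.ndarray
    Q_m3_s: np.ndarray
    event_times_s: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dataframe(self) -> pd.DataFrame:
        """Bench-unit export: t_s, heights in mm, volumes in ul, pressures in Pa,
        flow in nl/s."""
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "hL_mm": self.h_left_m * 1e3,
                "hR_mm": self.h_right_m * 1e3,
                "VL_ul": self.V_left_m3 * units.UL_PER_M3,
                "VR_ul": self.V_right_m3 * units.UL_PER_M3,
                "PL_Pa": self.P_left_pa,
                "PR_Pa": self.P_right_pa,
                "dP_Pa": self.deltaP_pa,
                "Q_nl_s": self.Q_m3_s * 1e12,
            }
        )


def _states(dumbbell: DumbbellSpec, V_L: float, V_R: float, fluids: FluidProperties):
    left = ChamberState.from_volume(dumbbell.left.effective_radius_m, V_L)
    right = ChamberState.from_volume(dumbbell.right.effective_radius_m, V_R)
    return left, right


def _delta_p(dumbbell: DumbbellSpec, V_L: float, V_R: float, fluids: FluidProperties) -> float:
    left, right = _states(dumbbell, V_L, V_R, fluids)
    return pressure_difference(left, right, fluids)


def _check_pinned(dumbbell: DumbbellSpec, V_L: float, V_R: float, fluids: FluidProperties, context: str) -> None:
    if fluids.theta_adv_deg > 90.0:
        return
    for name, spec, V in (("left", dumbbell.left, V_L), ("right", dumbbell.right, V_R)):
        vmax = max_pinned_volume(spec.effective_radius_m, fluids.theta_adv_deg)
        if V > vmax * (1 + 1e-12):
            raise DepinningError(
                f"{context}: {name} chamber volume {V * 1e9:.3g} ul exceeds the "
                f"pinned maximum {vmax * 1e9:.3g} ul"
            )
        if V < 0:
            raise InvalidSpecError(f"{context}: {name} chamber volume negative")


def simulate_equilibration(
    dumbbell: DumbbellSpec,
    fluids: FluidProperties,
    events: Sequence[DepositionEvent],
    duration_s: float,
    rtol: float = 1e-10,
    output_dt_s: float = 1800.0,
    h_fc40_m: float = DEFAULT_H_FC40_M,
    V0_left_ul: float = 0.0,
    V0_right_ul: float = 0.0,
) -> FlowTrajectory:
    """Integrate two-chamber equilibration through a deposition protocol.

    Events are applied instantaneously in chronological order; between
    events the stiff ODE is integrated with an adaptive implicit solver and
    sampled on a fixed grid (default 30 min, the side-imaging cadence).
    Samples that coincide with an event time reflect the post-event state.
    """
    events = sorted(events, key=lambda e: e.time_s)
    if any(e.time_s < 0 or e.time_s > duration_s for e in events):
        raise InvalidSpecError("event times must lie within [0, duration]")

    R_h = hydraulic_resistance(dumbbell.conduit, fluids)

    def rhs(t, y):
        q = _delta_p(dumbbell, y[0], y[1], fluids) / R_h
        return (q, -q)

    t_grid = np.arange(0.0, duration_s + 0.5 * output_dt_s, output_dt_s)
    t_grid = np.unique(np.concatenate([t_grid, [duration_s], [e.time_s for e in events]]))

    V_L = units.ul_to_m3(V0_left_ul)
    V_R = units.ul_to_m3(V0_right_ul)
    ts: list[float] = []
    VLs: list[float] = []
    VRs: list[float] = []

    # apply any events at t=0 first
    idx = 0
    while idx < len(events) and events[idx].time_s == 0.0:
        V_L, V_R = _apply_event(events[idx], V_L, V_R)
        idx += 1
    _check_pinned(dumbbell, V_L, V_R, fluids, "initial state")
    ts.append(0.0)
    VLs.append(V_L)
    VRs.append(V_R)

    remaining = events[idx:]
    seg_edges = sorted({0.0, duration_s, *[e.time_s for e in remaining]})
    for seg_start, seg_end in zip(seg_edges[:-1], seg_edges[1:]):
        sol = solve_ivp(
            rhs,
            (seg_start, seg_end),
            [V_L, V_R],
            method="LSODA",
            rtol=rtol,
            atol=1e-18,
            dense_output=True,
        )
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise RuntimeError(f"equilibration solver failed: {sol.message}")
        for t in t_grid[(t_grid > seg_start) & (t_grid < seg_end)]:
            y = sol.sol(t)
            ts.append(float(t))
            VLs.append(float(y[0]))
            VRs.append(float(y[1]))
        V_L, V_R = float(sol.y[0, -1]), float(sol.y[1, -1])
        for e in remaining:
            if e.time_s == seg_end:
                V_L, V_R = _apply_event(e, V_L, V_R)
                _check_pinned(
                    dumbbell, V_L, V_R, fluids,
                    f"event at t={e.time_s} s ({e.note or e.chamber})",
                )
        ts.append(seg_end)
        VLs.append(V_L)
        VRs.append(V_R)

    t_arr = np.array(ts)
    VL_arr = np.array(VLs)
    VR_arr = np.array(VRs)
    a_L = dumbbell.left.effective_radius_m
    a_R = dumbbell.right.effective_radius_m

    hL = np.empty_like(VL_arr)
    hR = np.empty_like(VR_arr)
    PL = np.empty_like(VL_arr)
    PR = np.empty_like(VR_arr)
    dP = np.empty_like(VL_arr)
    for i, (vl, vr) in enumerate(zip(VL_arr, VR_arr)):
        left = ChamberState.from_volume(a_L, max(vl, 0.0))
        right = ChamberState.from_volume(a_R, max(vr, 0.0))
        hL[i] = left.h_m
        hR[i] = right.h_m
        PL[i] = chamber_pressure(left, fluids, h_fc40_m)
        PR[i] = chamber_pressure(right, fluids, h_fc40_m)
        dP[i] = pressure_difference(left, right, fluids)
    Q = dP / R_h
    return FlowTrajectory(
        t_s=t_arr,
        V_left_m3=VL_arr,
        V_right_m3=VR_arr,
        h_left_m=hL,
        h_right_m=hR,
        P_left_pa=PL,
        P_right_pa=PR,
        deltaP_pa=dP,
        Q_m3_s=Q,
        event_times_s=np.array([e.time_s for e in events]),
    )


def _apply_event(event: DepositionEvent, V_L: float, V_R: float) -> tuple[float, float]:
    dv = units.ul_to_m3(event.dV_ul)
    if event.chamber == "left":
        if V_L + dv < -1e-18:
            raise InvalidSpecError(
                f"event at t={event.time_s} s removes more than the left chamber holds"
            )
        V_L = max(V_L + dv, 0.0)
    else:
        if V_R + dv < -1e-18:
            raise InvalidSpecError(
                f"event at t={event.time_s} s removes more than the right chamber holds"
            )
        V_R = max(V_R + dv, 0.0)
    return V_L, V_R


def equilibrium_state(
    dumbbell: DumbbellSpec, fluids: FluidProperties, V_total_ul: float
) -> tuple[ChamberState, ChamberState]:
    """Zero-flow split of a total volume between the two chambers.

    Root-finds the split with P_right = P_left.  For identical chamber
    specs the split is exactly half-and-half, which is returned without
    root-finding so the symmetry is exact.
    """
    V_tot = units.ul_to_m3(V_total_ul)
    a_L = dumbbell.left.effective_radius_m
    a_R = dumbbell.right.effective_radius_m
    vmax_L = max_pinned_volume(a_L, min(fluids.theta_adv_deg, 90.0))
    vmax_R = max_pinned_volume(a_R, min(fluids.theta_adv_deg, 90.0))
    if V_tot > vmax_L + vmax_R:
        raise DepinningError("total volume exceeds the combined pinning capacity")
    if dumbbell.left == dumbbell.right:
        V_L = V_R = V_tot / 2.0
    else:
        lo = max(0.0, V_tot - vmax_R)
        hi = min(vmax_L, V_tot)

        def f(V_L):
            return _delta_p(dumbbell, V_L, V_tot - V_L, fluids)

        f_lo, f_hi = f(lo), f(hi)
        if f_lo * f_hi > 0:
            raise DepinningError("no pinned equilibrium split exists for this volume")
        V_L = brentq(f, lo, hi, rtol=8.9e-16)
        V_R = V_tot - V_L
    left = ChamberState.from_volume(a_L, V_L, fluids)
    right = ChamberState.from_volume(a_R, V_R, fluids)
    return left, right


@dataclass(frozen=True)
class BackflowReport:
    """Result of checking a trajectory for flow against a protected direction."""

    ok: bool
    protected_chamber: str
    first_violation_time_s: Optional[float] = None
    max_violation_m3_s: float = 0.0


def assert_no_backflow(
    trajectory: FlowTrajectory, protect: str, q_floor_m3_s: Optional[float] = None
) -> BackflowReport:
    """Check that flow never runs *out of* the protected chamber.

    protect='left' forbids rightward flow (Q < 0); protect='right' forbids
    leftward flow (Q > 0).  |Q| below the solver noise floor (by default
    1e-9 of the peak |Q|) counts as zero.
    """
    if protect not in ("left", "right"):
        raise InvalidSpecError(f"unknown chamber {protect!r}")
    Q = trajectory.Q_m3_s
    if q_floor_m3_s is None:
        q_floor_m3_s = 1e-9 * (np.max(np.abs(Q)) if Q.size else 0.0)
    violating = -Q if protect == "left" else Q
    bad = violating > q_floor_m3_s
    if not np.any(bad):
        return BackflowReport(ok=True, protected_chamber=protect)
    i = int(np.argmax(bad))
    return BackflowReport(
        ok=False,
        protected_chamber=protect,
        first_violation_time_s=float(trajectory.t_s[i]),
        max_violation_m3_s=float(np.max(violating[bad])),
    )


def time_to_equilibration(trajectory: FlowTrajectory, fraction: float = 0.9) -> float:
    """Time at which the volume imbalance has decayed by ``fraction``.

    Progress is measured on |V_R - V_R(eq)| relative to its value just
    after the last deposition event, with V_R(eq) taken from the end of the
    trajectory.  Returns inf if the fraction is never reached.
    """
    t = trajectory.t_s
    if trajectory.event_times_s.size:
        t0 = trajectory.event_times_s.max()
    else:
        t0 = t[0]
    i0 = int(np.searchsorted(t, t0))
    V_eq = 0.5 * (trajectory.V_left_m3[-1] + trajectory.V_right_m3[-1])
    dev = np.abs(trajectory.V_right_m3 - V_eq)
    target = (1.0 - fraction) * dev[i0]
    for i in range(i0, len(t)):
        if dev[i] <= target:
            return float(t[i] - t0)
    return float("inf")


def read_events_csv(path) -> list[DepositionEvent]:
    """Read a deposition protocol (fields time_s, chamber, dV_ul[, note])
    from CSV, or from JSON (list of records) when the suffix is .json."""
    path = str(path)
    df = pd.read_json(path) if path.endswith(".json") else pd.read_csv(path)
    required = {"time_s", "chamber", "dV_ul"}
    if not required.issubset(df.columns):
        raise InvalidSpecError(f"events file must have columns {sorted(required)}")
    return [
        DepositionEvent(
            time_s=float(r.time_s),
            chamber=str(r.chamber),
            dV_ul=float(r.dV_ul),
            note=str(getattr(r, "note", "") or ""),
        )
        for r in df.itertuples()
    ]
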