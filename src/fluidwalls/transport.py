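"""Solute gradients along the conduit between two well-mixed chambers.

Once chamber volumes are equal there is no pressure-driven flow, and mass
transport between the chambers of a dumbbell happens only by diffusion
through the conduit.  The conduit (length L, cross-section w x h_c) is
discretised into finite-volume cells flux-coupled at each end to a
well-mixed chamber reservoir; media changes (remove spent medium, add
fresh) are instantaneous mixed dilutions.

Because the pure-diffusion system is linear, the default propagator is a
dense matrix exponential per inter-event segment, which conserves total
solute mass to roundoff and has no step-size constraint.  An optional
advective coupling (conduit flow fed from an equilibration trajectory)
falls back to an implicit ODE solver, and an explicit-Euler path with a
hard CFL check is available for cross-checking.

Concentrations are ng/ml at the interface and internally (the unit is
arbitrary for a linear model); geometry is SI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from . import units
from .geometry import DumbbellSpec, InvalidSpecError


@dataclass(frozen=True)
class SoluteSpec:
    """A diffusible solute and its initial chamber concentrations.

    D_m2_s: diffusion coefficient in medium (m^2/s).  The default used for
    BDNF throughout the package is 1.0e-10 m^2/s — a typical value for a
    ~27 kDa globular protein in water at room temperature — and is an
    assumption, not a measured value.
    """

    name: str
    D_m2_s: float
    C_left_ng_ml: float = 0.0
    C_right_ng_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.D_m2_s <= 0:
            raise InvalidSpecError("diffusion coefficient must be > 0")
        if self.C_left_ng_ml < 0 or self.C_right_ng_ml < 0:
            raise InvalidSpecError("concentrations must be >= 0")


@dataclass(frozen=True)
class MediaChangeEvent:
    """Remove ``remove_ul`` of mixed medium, then add ``add_ul`` at
    ``add_conc_ng_ml`` to one chamber."""

    time_s: float
    chamber: str  # 'left' | 'right'
    remove_ul: float
    add_ul: float
    add_conc_ng_ml: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.chamber not in ("left", "right"):
            raise InvalidSpecError(f"unknown chamber {self.chamber!r}")
        if self.remove_ul < 0 or self.add_ul < 0 or self.add_conc_ng_ml < 0:
            raise InvalidSpecError("media-change volumes and concentration must be >= 0")


@dataclass
class GradientProfile:
    """Concentration field along the conduit plus chamber series.

    x_m are cell centres (0 at the left chamber/conduit junction); C has
    shape (len(t_s), len(x_m)).  V_left/V_right track chamber volumes
    (piecewise constant between events).
    """

    x_m: np.ndarray
    t_s: np.ndarray
    C: np.ndarray
    C_left: np.ndarray
    C_right: np.ndarray
    V_left_m3: np.ndarray
    V_right_m3: np.ndarray
    cross_section_m2: float
    event_times_s: np.ndarray

    @property
    def dx_m(self) -> float:
        return float(self.x_m[1] - self.x_m[0]) if self.x_m.size > 1 else 0.0

    def total_mass_ng(self, i: int) -> float:
        """Model mass at time index i: reservoirs + finite-volume conduit sum.

        Concentration is ng/ml = 1e6 ng/m^3? No — ng/ml * (volume in ml).
        Volumes are m^3, so mass = C * V * 1e6 (1 m^3 = 1e6 ml); the factor
        cancels in every relative comparison and is kept for unit honesty.
        """
        ml_per_m3 = 1e6
        conduit = float(np.sum(self.C[i]) * self.cross_section_m2 * self.dx_m) * ml_per_m3
        return (
            self.C_left[i] * self.V_left_m3[i] * ml_per_m3
            + self.C_right[i] * self.V_right_m3[i] * ml_per_m3
            + conduit
        )

    def profile_frame(self) -> pd.DataFrame:
        """Long-format export: t_s, x_um, C_ng_ml."""
        tt, xx = np.meshgrid(self.t_s, self.x_m, indexing="ij")
        return pd.DataFrame(
            {"t_s": tt.ravel(), "x_um": xx.ravel() * 1e6, "C_ng_ml": self.C.ravel()}
        )

    def chamber_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "C_left_ng_ml": self.C_left,
                "C_right_ng_ml": self.C_right,
                "V_left_ul": self.V_left_m3 * units.UL_PER_M3,
                "V_right_ul": self.V_right_m3 * units.UL_PER_M3,
            }
        )


def characteristic_times(
    dumbbell: DumbbellSpec, solute: SoluteSpec, V_chamber_ul: float = 4.0
) -> dict[str, float]:
    """Closed-form timescales used for grid/step selection and reporting.

    conduit_diffusion_s = L^2/D      (time to establish the conduit gradient)
    chamber_turnover_s  = V L/(D w h_c)  (time for diffusion through the
    conduit to turn over one chamber volume)
    """
    L = dumbbell.conduit.length_m
    A = dumbbell.conduit.cross_section_m2
    V = units.ul_to_m3(V_chamber_ul)
    return {
        "conduit_diffusion_s": L * L / solute.D_m2_s,
        "chamber_turnover_s": V * L / (solute.D_m2_s * A),
    }


def _system_matrix(
    n: int, D: float, A: float, dx: float, V_L: float, V_R: float, clamped: bool
) -> np.ndarray:
    """Generator matrix M of dC/dt = M C for state [C_L, C_1..C_n, C_R].

    Conductances: g = D A / dx between neighbouring cells, g0 = 2 D A / dx
    between a reservoir and the adjacent half-cell.  Columns of (volumes @ M)
    sum to zero, so total mass is a linear invariant of the flow.
    """
    g = D * A / dx
    g0 = 2.0 * D * A / dx
    v_cell = A * dx
    m = np.zeros((n + 2, n + 2))
    # left reservoir <-> cell 1
    m[0, 0] -= g0 / V_L
    m[0, 1] += g0 / V_L
    m[1, 0] += g0 / v_cell
    m[1, 1] -= g0 / v_cell
    # interior faces
    for i in range(1, n):
        m[i, i] -= g / v_cell
        m[i, i + 1] += g / v_cell
        m[i + 1, i + 1] -= g / v_cell
        m[i + 1, i] += g / v_cell
    # cell n <-> right reservoir
    m[n, n] -= g0 / v_cell
    m[n, n + 1] += g0 / v_cell
    m[n + 1, n] += g0 / V_R
    m[n + 1, n + 1] -= g0 / V_R
    if clamped:
        m[0, :] = 0.0
        m[n + 1, :] = 0.0
    return m


def simulate_gradient(
    dumbbell: DumbbellSpec,
    solute: SoluteSpec,
    schedule: Sequence[MediaChangeEvent],
    duration_s: float,
    n_cells: int = 41,
    V_left_ul: float = 4.0,
    V_right_ul: float = 4.0,
    output_dt_s: float = 6 * 3600.0,
    method: str = "expm",
    dt_s: Optional[float] = None,
    clamped: bool = False,
    flow_m3_s: Optional[Callable[[float], float]] = None,
    rtol: float = 1e-10,
) -> GradientProfile:
    """Simulate the conduit concentration field under a media-change schedule.

    method='expm' (default) propagates the linear system exactly per
    segment; 'bdf' uses an implicit ODE solver (required when
    ``flow_m3_s`` supplies an advective conduit flow, positive
    right -> left); 'explicit' uses forward Euler with step ``dt_s`` and
    refuses steps violating the diffusive CFL condition.
    """
    if n_cells < 4:
        raise InvalidSpecError("n_cells must be >= 4 to resolve the conduit")
    if flow_m3_s is not None and method == "expm":
        method = "bdf"
    schedule = sorted(schedule, key=lambda e: e.time_s)
    if any(e.time_s < 0 or e.time_s > duration_s for e in schedule):
        raise InvalidSpecError("schedule times must lie within [0, duration]")

    L = dumbbell.conduit.length_m
    A = dumbbell.conduit.cross_section_m2
    D = solute.D_m2_s
    dx = L / n_cells
    x = (np.arange(n_cells) + 0.5) * dx

    if method == "explicit":
        if dt_s is None:
            raise InvalidSpecError("explicit method requires dt_s")
        dt_cfl = 0.5 * (dx / 2.0) ** 2 / D  # half-cell reservoir faces set the limit
        if dt_s > dt_cfl:
            raise InvalidSpecError(
                f"dt_s={dt_s:.3g} s violates the diffusive stability limit "
                f"{dt_cfl:.3g} s for n_cells={n_cells}; reduce dt_s or n_cells"
            )
    elif method not in ("expm", "bdf"):
        raise InvalidSpecError(f"unknown method {method!r}")

    V_L = units.ul_to_m3(V_left_ul)
    V_R = units.ul_to_m3(V_right_ul)
    y = np.empty(n_cells + 2)
    y[0] = solute.C_left_ng_ml
    y[-1] = solute.C_right_ng_ml
    y[1:-1] = np.linspace(solute.C_left_ng_ml, solute.C_right_ng_ml, n_cells + 2)[1:-1]

    t_grid = np.unique(
        np.concatenate(
            [
                np.arange(0.0, duration_s + 0.5 * output_dt_s, output_dt_s),
                [duration_s],
                [e.time_s for e in schedule],
            ]
        )
    )

    ts: list[float] = [0.0]
    Cs: list[np.ndarray] = [y[1:-1].copy()]
    CLs: list[float] = [y[0]]
    CRs: list[float] = [y[-1]]
    VLs: list[float] = [V_L]
    VRs: list[float] = [V_R]

    idx = 0
    while idx < len(schedule) and schedule[idx].time_s == 0.0:
        y[0], y[-1], V_L, V_R = _apply_media_change(schedule[idx], y[0], y[-1], V_L, V_R)
        idx += 1
    remaining = schedule[idx:]
    ts[0], Cs[0], CLs[0], CRs[0], VLs[0], VRs[0] = 0.0, y[1:-1].copy(), y[0], y[-1], V_L, V_R

    seg_edges = sorted({0.0, duration_s, *[e.time_s for e in remaining]})
    for seg_start, seg_end in zip(seg_edges[:-1], seg_edges[1:]):
        interior = t_grid[(t_grid > seg_start) & (t_grid < seg_end)]
        sample_times = np.concatenate([interior, [seg_end]])
        y = _propagate(
            y, seg_start, sample_times, method, n_cells, D, A, dx, V_L, V_R,
            clamped, flow_m3_s, dt_s, rtol,
            on_sample=lambda t, yy, vl, vr: (
                ts.append(float(t)),
                Cs.append(yy[1:-1].copy()),
                CLs.append(float(yy[0])),
                CRs.append(float(yy[-1])),
                VLs.append(vl),
                VRs.append(vr),
            ),
        )
        V_L, V_R = VLs[-1], VRs[-1]
        for e in remaining:
            if e.time_s == seg_end:
                y[0], y[-1], V_L, V_R = _apply_media_change(e, y[0], y[-1], V_L, V_R)
                # overwrite the seg_end sample with the post-event state
                CLs[-1], CRs[-1], VLs[-1], VRs[-1] = y[0], y[-1], V_L, V_R

    C = np.array(Cs)
    if C.min() < -1e-9 * max(C.max(), 1.0):
        raise RuntimeError("numerical failure: concentration significantly negative")
    return GradientProfile(
        x_m=x,
        t_s=np.array(ts),
        C=np.clip(C, 0.0, None),
        C_left=np.array(CLs),
        C_right=np.array(CRs),
        V_left_m3=np.array(VLs),
        V_right_m3=np.array(VRs),
        cross_section_m2=A,
        event_times_s=np.array([e.time_s for e in schedule]),
    )


def _propagate(
    y, t0, sample_times, method, n, D, A, dx, V_L, V_R, clamped, flow, dt_s, rtol,
    on_sample,
):
    if method == "expm":
        M = _system_matrix(n, D, A, dx, V_L, V_R, clamped)
        prop_cache: dict[float, np.ndarray] = {}
        t_prev = t0
        for t in sample_times:
            step = round(float(t - t_prev), 9)
            if step > 0:
                P = prop_cache.get(step)
                if P is None:
                    P = expm(M * step)
                    prop_cache[step] = P
                y = P @ y
            on_sample(t, y, V_L, V_R)
            t_prev = t
        return y

    if method == "explicit":
        M = _system_matrix(n, D, A, dx, V_L, V_R, clamped)
        t = t0
        for t_target in sample_times:
            while t < t_target - 1e-9:
                step = min(dt_s, t_target - t)
                y = y + step * (M @ y)
                t += step
            on_sample(t_target, y, V_L, V_R)
            t = t_target
        return y

    # Implicit ODE path; supports an advective conduit flow Q(t) (m^3/s,
    # positive right -> left, i.e. velocity in -x).  The flow also moves
    # volume between the chambers, so the state carries V_L and the
    # chamber equations are written as mass balances.
    v_cell = A * dx
    g = D * A / dx
    g0 = 2.0 * D * A / dx
    V_pair = V_L + V_R
    yy0 = np.concatenate([y, [V_L]])

    def rhs(t, state):
        C_L, C_R, vl = state[0], state[n + 1], state[-1]
        vr = V_pair - vl
        c = state[1 : n + 1]
        q = flow(t) if flow is not None else 0.0
        u = -q / A  # velocity along +x
        # face fluxes in +x (concentration * m^3/s)
        flux = np.empty(n + 1)
        flux[0] = -g0 * (c[0] - C_L)
        flux[1:-1] = -g * (c[1:] - c[:-1])
        flux[-1] = -g0 * (C_R - c[-1])
        if u != 0.0:
            uA = u * A
            up = np.empty(n + 1)
            if u > 0:
                up[0] = C_L
                up[1:] = c
            else:
                up[:-1] = c
                up[-1] = C_R
            flux = flux + uA * up
        d = np.empty_like(state)
        d[0] = (-flux[0] - C_L * q) / vl if not clamped else 0.0
        d[1 : n + 1] = (flux[:-1] - flux[1:]) / v_cell
        d[n + 1] = (flux[-1] + C_R * q) / vr if not clamped else 0.0
        d[-1] = q
        return d

    t_prev = t0
    yy = yy0
    for t in sample_times:
        if t > t_prev:
            sol = solve_ivp(
                rhs, (t_prev, t), yy, method="BDF", rtol=rtol,
                atol=1e-12 * max(1.0, float(np.max(np.abs(yy)))),
            )
            if not sol.success:  # pragma: no cover
                raise RuntimeError(f"transport solver failed: {sol.message}")
            yy = sol.y[:, -1]
        vl = float(yy[-1])
        on_sample(t, yy[:-1], vl, V_pair - vl)
        t_prev = t
    return yy[:-1]


def _apply_media_change(
    event: MediaChangeEvent, C_L: float, C_R: float, V_L: float, V_R: float
):
    v_rem = units.ul_to_m3(event.remove_ul)
    v_add = units.ul_to_m3(event.add_ul)
    if event.chamber == "left":
        if v_rem > V_L * (1 + 1e-12):
            raise InvalidSpecError(
                f"media change at t={event.time_s} s removes more than the left chamber holds"
            )
        V_new = V_L - v_rem + v_add
        C_L = (C_L * (V_L - v_rem) + event.add_conc_ng_ml * v_add) / V_new
        V_L = V_new
    else:
        if v_rem > V_R * (1 + 1e-12):
            raise InvalidSpecError(
                f"media change at t={event.time_s} s removes more than the right chamber holds"
            )
        V_new = V_R - v_rem + v_add
        C_R = (C_R * (V_R - v_rem) + event.add_conc_ng_ml * v_add) / V_new
        V_R = V_new
    return C_L, C_R, V_L, V_R


def max_chamber_concentration(profile: GradientProfile, chamber: str) -> float:
    """Maximum over time of one chamber's concentration series (ng/ml)."""
    if chamber == "left":
        return float(np.max(profile.C_left))
    if chamber == "right":
        return float(np.max(profile.C_right))
    raise InvalidSpecError(f"unknown chamber {chamber!r}")


def read_schedule_csv(path) -> list[MediaChangeEvent]:
    """Read a media-change schedule (fields time_h, chamber, remove_ul,
    add_ul, add_conc_ng_ml[, note]) from CSV, or from JSON (list of
    records) when the suffix is .json."""
    path = str(path)
    df = pd.read_json(path) if path.endswith(".json") else pd.read_csv(path)
    required = {"time_h", "chamber", "remove_ul", "add_ul", "add_conc_ng_ml"}
    if not required.issubset(df.columns):
        raise InvalidSpecError(f"schedule file must have columns {sorted(required)}")
    return [
        MediaChangeEvent(
            time_s=float(r.time_h) * 3600.0,
            chamber=str(r.chamber),
            remove_ul=float(r.remove_ul),
            add_ul=float(r.add_ul),
            add_conc_ng_ml=float(r.add_conc_ng_ml),
            note=str(getattr(r, "note", "") or ""),
        )
        for r in df.itertuples()
    ]
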