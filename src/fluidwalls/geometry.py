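"""Spherical-cap geometry and pressures of pinned fluid-walled chambers.

A chamber jet-printed on a Petri dish is a sessile drop of culture medium
whose contact line is pinned at a fixed footprint (effective radius ``a``)
and which is overlaid by the denser, immiscible fluorocarbon FC40.  For
volumes below the depinning limit the medium:FC40 interface is the cap of a
sphere, so apex height ``h``, curvature radius ``R``, volume ``V`` and the
pressure at the dish floor are related in closed form:

    R      = (a^2 + h^2) / (2 h)
    P_L    = 2 gamma / R                       (Laplace pressure)
    P      = P_L + rho_med g h + rho_FC40 g (h_FC40 - h)
    V      = (pi h / 6) (3 a^2 + h^2)

where ``h_FC40`` is the height of the FC40 free surface above the dish
floor.  In the difference between two chambers of a dumbbell the FC40
surface term cancels, leaving only the two cap geometries:

    dP = P_R - P_L
       = 2 gamma (1/R_R - 1/R_L) + (rho_med - rho_FC40) g (h_R - h_L)

The model is valid while the cap stays spherical (Bond number of order 1
or below) and the contact line stays pinned (apparent contact angle not
exceeding the advancing angle).  Units are SI throughout this module;
angles are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional


class InvalidSpecError(ValueError):
    """A geometric specification violates its invariants."""


class DepinningError(ValueError):
    """Requested volume would push the contact angle past the advancing angle."""


class ConfigurationError(ValueError):
    """Inconsistent physical configuration (e.g. FC40 surface below the cap apex)."""


class UnsupportedRegimeError(ValueError):
    """Parameter outside the regime the spherical-cap model supports."""


@dataclass(frozen=True)
class FluidProperties:
    """Constants of the medium/FC40 fluid pair.

    Defaults are literature-typical values for serum-containing culture
    medium against FC40 at room temperature; none of them is a measured
    property of a particular batch, and all are configurable.

    gamma        medium:FC40 interfacial tension (N/m)
    rho_med      medium density (kg/m^3)
    rho_fc40     FC40 density (kg/m^3); FC40 is denser and sinks
    g            gravitational acceleration (m/s^2)
    mu_med       medium dynamic viscosity (Pa s)
    theta_adv_deg  advancing contact angle of the pinned interface (deg)
    """

    gamma: float = 0.013
    rho_med: float = 1007.0
    rho_fc40: float = 1855.0
    g: float = 9.81
    mu_med: float = 8.9e-4
    theta_adv_deg: float = 70.0

    def __post_init__(self) -> None:
        for name in ("gamma", "rho_med", "rho_fc40", "g", "mu_med", "theta_adv_deg"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"FluidProperties.{name} must be > 0")
        if self.rho_fc40 <= self.rho_med:
            raise InvalidSpecError("rho_fc40 must exceed rho_med (FC40 sinks around the medium)")
        if not 0.0 < self.theta_adv_deg < 180.0:
            raise InvalidSpecError("theta_adv_deg must lie in (0, 180)")


@dataclass(frozen=True)
class ChamberSpec:
    """Footprint of one pinned chamber.

    footprint_kind   'circle' or 'square'
    footprint_size_m circle radius or square side (m)
    radius_mode      how a square maps to the effective circular radius used by
                     the cap model: 'equal_area' (side/sqrt(pi), default) or
                     'inscribed' (side/2)
    """

    footprint_kind: str
    footprint_size_m: float
    radius_mode: str = "equal_area"

    def __post_init__(self) -> None:
        if self.footprint_kind not in ("circle", "square"):
            raise InvalidSpecError(f"unknown footprint kind {self.footprint_kind!r}")
        if self.footprint_size_m <= 0:
            raise InvalidSpecError("footprint size must be > 0")
        if self.radius_mode not in ("equal_area", "inscribed"):
            raise InvalidSpecError(f"unknown radius mode {self.radius_mode!r}")

    @property
    def effective_radius_m(self) -> float:
        return effective_radius(self)

    @property
    def extent_m(self) -> float:
        """Footprint width along either planar axis (bounding-box side)."""
        if self.footprint_kind == "circle":
            return 2.0 * self.footprint_size_m
        return self.footprint_size_m


def effective_radius(spec: ChamberSpec) -> float:
    """Effective circular footprint radius ``a`` of a chamber (m).

    Circles keep their radius.  Squares are mapped to a circle of equal
    area by default (a = side/sqrt(pi)), since the cap-pressure model
    assumes a circular contact line; the inscribed-circle alternative
    (a = side/2) can be selected via ``radius_mode``.
    """
    if spec.footprint_kind == "circle":
        return spec.footprint_size_m
    if spec.radius_mode == "inscribed":
        return spec.footprint_size_m / 2.0
    return spec.footprint_size_m / math.sqrt(math.pi)


def cap_volume(h: float, a: float) -> float:
    """Volume of a spherical cap of apex height ``h`` on footprint radius ``a`` (m^3)."""
    if a <= 0:
        raise InvalidSpecError("footprint radius must be > 0")
    if h < 0:
        raise InvalidSpecError("cap height must be >= 0")
    return math.pi * h * (3.0 * a * a + h * h) / 6.0


def cap_height_from_volume(V: float, a: float) -> float:
    """Invert the cap-volume relation: unique h >= 0 with cap_volume(h, a) = V.

    The cubic (pi/6)(3 a^2 h + h^3) = V is strictly increasing in h, so the
    root is unique; it is bracketed by [0, 2V/(pi a^2)] because
    V >= (pi/2) a^2 h for every cap.
    """
    if a <= 0:
        raise InvalidSpecError("footprint radius must be > 0")
    if V < 0:
        raise InvalidSpecError("volume must be >= 0")
    if V == 0.0:
        return 0.0
    from scipy.optimize import brentq

    hi = 2.0 * V / (math.pi * a * a)
    return float(
        brentq(
            lambda h: cap_volume(h, a) - V,
            0.0,
            hi * (1 + 1e-12),
            rtol=8.9e-16,
            xtol=1e-24,
        )
    )


def curvature_radius(h: float, a: float) -> float:
    """Radius of curvature of the cap (m); ``inf`` for a flat interface (h = 0)."""
    if a <= 0:
        raise InvalidSpecError("footprint radius must be > 0")
    if h < 0:
        raise InvalidSpecError("cap height must be >= 0")
    if h == 0.0:
        return math.inf
    return (a * a + h * h) / (2.0 * h)


def apparent_contact_angle(h: float, a: float) -> float:
    """Apparent contact angle of the cap at the pinning line (degrees)."""
    if a <= 0:
        raise InvalidSpecError("footprint radius must be > 0")
    if h < 0:
        raise InvalidSpecError("cap height must be >= 0")
    return math.degrees(2.0 * math.atan(h / a))


def max_pinned_volume(a: float, theta_adv_deg: float) -> float:
    """Largest volume the pinned contact line can hold before depinning (m^3).

    Supported for advancing angles up to 90 deg (caps no taller than a
    hemisphere); beyond that the free surface would bulge past the pinning
    line and the spherical-cap-on-fixed-footprint model no longer applies.
    """
    if not 0.0 < theta_adv_deg <= 90.0:
        raise UnsupportedRegimeError(
            "max_pinned_volume supports advancing angles in (0, 90] degrees"
        )
    h_max = a * math.tan(math.radians(theta_adv_deg) / 2.0)
    return cap_volume(h_max, a)


def laplace_pressure(h: float, a: float, fluids: FluidProperties) -> float:
    """Laplace pressure 2*gamma/R across the cap interface (Pa); 0 when flat."""
    R = curvature_radius(h, a)
    if math.isinf(R):
        return 0.0
    return 2.0 * fluids.gamma / R


@dataclass(frozen=True)
class ChamberState:
    """Instantaneous state of one filled chamber.

    a_m, V_m3, h_m, R_m, theta_app_deg are mutually consistent via the cap
    relations; P_pa (gauge pressure at the dish floor) is populated when a
    FC40 surface height is known, else None.
    """

    a_m: float
    V_m3: float
    h_m: float
    R_m: float
    theta_app_deg: float
    P_pa: Optional[float] = None

    @classmethod
    def from_volume(
        cls,
        a: float,
        V: float,
        fluids: Optional[FluidProperties] = None,
        h_fc40: Optional[float] = None,
    ) -> "ChamberState":
        """Build a consistent state from footprint radius and volume.

        When ``fluids`` is given the pinning invariant is enforced:
        exceeding max_pinned_volume raises DepinningError.  When both
        ``fluids`` and ``h_fc40`` are given, P_pa is filled in.
        """
        h = cap_height_from_volume(V, a)
        if fluids is not None and fluids.theta_adv_deg <= 90.0:
            if V > max_pinned_volume(a, fluids.theta_adv_deg) * (1 + 1e-12):
                raise DepinningError(
                    f"volume {V:.3e} m^3 exceeds the pinned maximum for a={a:.3e} m "
                    f"at theta_adv={fluids.theta_adv_deg} deg"
                )
        state = cls(
            a_m=a,
            V_m3=V,
            h_m=h,
            R_m=curvature_radius(h, a),
            theta_app_deg=apparent_contact_angle(h, a),
        )
        if fluids is not None and h_fc40 is not None:
            state = replace(state, P_pa=chamber_pressure(state, fluids, h_fc40))
        return state


def chamber_pressure(state: ChamberState, fluids: FluidProperties, h_fc40: float) -> float:
    """Gauge pressure at the dish floor under a chamber (Pa).

    Sum of the Laplace pressure across the cap and the two hydrostatic
    heads: medium of height h, FC40 from the cap apex up to the FC40 free
    surface at ``h_fc40`` above the dish floor.
    """
    if h_fc40 < state.h_m:
        raise ConfigurationError("FC40 free surface must lie above the cap apex")
    p_laplace = 0.0 if math.isinf(state.R_m) else 2.0 * fluids.gamma / state.R_m
    return (
        p_laplace
        + fluids.rho_med * fluids.g * state.h_m
        + fluids.rho_fc40 * fluids.g * (h_fc40 - state.h_m)
    )


def pressure_difference(
    left: ChamberState, right: ChamberState, fluids: FluidProperties
) -> float:
    """Pressure difference P_right - P_left between the chambers (Pa).

    The FC40 free-surface height is common to both chambers and cancels,
    leaving the Laplace terms and the density-contrast head of the two cap
    heights.  Positive dP drives flow right -> left through the conduit.
    """
    inv_r_r = 0.0 if math.isinf(right.R_m) else 1.0 / right.R_m
    inv_r_l = 0.0 if math.isinf(left.R_m) else 1.0 / left.R_m
    return 2.0 * fluids.gamma * (inv_r_r - inv_r_l) + (
        fluids.rho_med - fluids.rho_fc40
    ) * fluids.g * (right.h_m - left.h_m)


def bond_number(a: float, fluids: FluidProperties) -> float:
    """Bond number (rho_FC40 - rho_med) g a^2 / gamma of a chamber footprint."""
    if a <= 0:
        raise InvalidSpecError("footprint radius must be > 0")
    return (fluids.rho_fc40 - fluids.rho_med) * fluids.g * a * a / fluids.gamma


@dataclass(frozen=True)
class ConduitSpec:
    """Rectangular conduit between the two chambers (SI metres).

    length_m along the flow axis, width_m across it, height_m the FC40
    ceiling height.  Invariant height <= width <= length (shallow channel).
    """

    length_m: float
    width_m: float
    height_m: float

    def __post_init__(self) -> None:
        if min(self.length_m, self.width_m, self.height_m) <= 0:
            raise InvalidSpecError("conduit dimensions must be > 0")
        if not self.height_m <= self.width_m <= self.length_m:
            raise InvalidSpecError("conduit requires height <= width <= length")

    @property
    def cross_section_m2(self) -> float:
        return self.width_m * self.height_m


@dataclass(frozen=True)
class Pose:
    """Planar placement of a dumbbell footprint (bench units: mm, deg)."""

    x_mm: float = 0.0
    y_mm: float = 0.0
    theta_deg: float = 0.0


@dataclass(frozen=True)
class DumbbellSpec:
    """Two chambers joined by a conduit; the unit micro-environment."""

    left: ChamberSpec
    right: ChamberSpec
    conduit: ConduitSpec
    pose: Pose = Pose()

    def __post_init__(self) -> None:
        if self.conduit.width_m > min(self.left.extent_m, self.right.extent_m):
            raise InvalidSpecError("conduit wider than the chambers it connects")

    @property
    def span_x_m(self) -> float:
        """Total extent along the conduit axis (m)."""
        return self.left.extent_m + self.conduit.length_m + self.right.extent_m

    @property
    def span_y_m(self) -> float:
        """Total extent across the conduit axis (m)."""
        return max(self.left.extent_m, self.right.extent_m)

    def half_extents_mm(self) -> tuple[float, float]:
        return (self.span_x_m / 2.0 * 1e3, self.span_y_m / 2.0 * 1e3)


def default_dumbbell(
    chamber_side_mm: float = 3.0,
    conduit_length_mm: float = 1.0,
    conduit_width_um: float = 200.0,
    conduit_height_um: float = 10.0,
    radius_mode: str = "equal_area",
) -> DumbbellSpec:
    """The as-printed dumbbell: two 3 mm square chambers and a
    1 mm x 200 um x 10 um conduit."""
    chamber = ChamberSpec("square", chamber_side_mm * 1e-3, radius_mode)
    conduit = ConduitSpec(conduit_length_mm * 1e-3, conduit_width_um * 1e-6, conduit_height_um * 1e-6)
    return DumbbellSpec(left=chamber, right=chamber, conduit=conduit)


def rebuilt_dumbbell(
    original: DumbbellSpec,
    chamber_side_mm: float = 3.5,
    conduit_length_mm: float = 0.5,
    conduit_width_um: float = 400.0,
) -> DumbbellSpec:
    """The slightly larger dumbbell jet-printed around an axotomised one.

    Chambers grow to 3.5 mm squares and the conduit becomes shorter and
    wider (0.5 mm x ~400 um) so the new walls clear the attached cells.
    """
    chamber = ChamberSpec("square", chamber_side_mm * 1e-3, original.left.radius_mode)
    conduit = ConduitSpec(
        conduit_length_mm * 1e-3, conduit_width_um * 1e-6, original.conduit.height_m
    )
    return DumbbellSpec(left=chamber, right=chamber, conduit=conduit, pose=original.pose)
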