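"""Configuration files for circuits and fluids.

YAML or JSON, bench units (mm/um/ul/deg), round-trippable.  Unknown keys
are ignored with a warning so configs stay forward-compatible without
silently absorbing typos.

Layout::

    fluids:
      gamma_n_m: 0.013
      rho_med_kg_m3: 1007
      rho_fc40_kg_m3: 1855
      g_m_s2: 9.81
      mu_med_pa_s: 0.00089
      theta_adv_deg: 70
    chamber:
      footprint_kind: square
      footprint_size_mm: 3.0
      radius_mode: equal_area
    conduit:
      length_mm: 1.0
      width_um: 200.0
      height_um: 10.0
    volumes:
      left_ul: 1.0
      right_ul: 4.0
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import yaml

from .geometry import ChamberSpec, ConduitSpec, DumbbellSpec, FluidProperties, InvalidSpecError

_FLUID_KEYS = {
    "gamma_n_m": "gamma",
    "rho_med_kg_m3": "rho_med",
    "rho_fc40_kg_m3": "rho_fc40",
    "g_m_s2": "g",
    "mu_med_pa_s": "mu_med",
    "theta_adv_deg": "theta_adv_deg",
}
_CHAMBER_KEYS = {"footprint_kind", "footprint_size_mm", "radius_mode"}
_CONDUIT_KEYS = {"length_mm", "width_um", "height_um"}
_VOLUME_KEYS = {"left_ul", "right_ul"}
_TOP_KEYS = {"fluids", "chamber", "conduit", "volumes"}


def default_config() -> dict[str, Any]:
    """The documented default circuit: 3 mm square chambers,
    1 mm x 200 um x 10 um conduit, 4 ul right / 1 ul left seeding."""
    f = FluidProperties()
    return {
        "fluids": {
            "gamma_n_m": f.gamma,
            "rho_med_kg_m3": f.rho_med,
            "rho_fc40_kg_m3": f.rho_fc40,
            "g_m_s2": f.g,
            "mu_med_pa_s": f.mu_med,
            "theta_adv_deg": f.theta_adv_deg,
        },
        "chamber": {
            "footprint_kind": "square",
            "footprint_size_mm": 3.0,
            "radius_mode": "equal_area",
        },
        "conduit": {"length_mm": 1.0, "width_um": 200.0, "height_um": 10.0},
        "volumes": {"left_ul": 1.0, "right_ul": 4.0},
    }


def _warn_unknown(mapping: dict, known: set[str], where: str) -> None:
    unknown = set(mapping) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON config and fill in defaults for missing blocks."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise InvalidSpecError(f"config {path} is not a mapping")
    _warn_unknown(raw, _TOP_KEYS, "top level")
    cfg = default_config()
    for block, known in (
        ("fluids", set(_FLUID_KEYS)),
        ("chamber", _CHAMBER_KEYS),
        ("conduit", _CONDUIT_KEYS),
        ("volumes", _VOLUME_KEYS),
    ):
        user = raw.get(block, {})
        if not isinstance(user, dict):
            raise InvalidSpecError(f"config block {block!r} must be a mapping")
        _warn_unknown(user, known, block)
        cfg[block].update({k: v for k, v in user.items() if k in known})
    return cfg


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def fluids_from_config(cfg: dict[str, Any]) -> FluidProperties:
    block = cfg["fluids"]
    return FluidProperties(**{attr: block[key] for key, attr in _FLUID_KEYS.items()})


def dumbbell_from_config(cfg: dict[str, Any]) -> DumbbellSpec:
    ch = cfg["chamber"]
    co = cfg["conduit"]
    chamber = ChamberSpec(
        footprint_kind=ch["footprint_kind"],
        footprint_size_m=ch["footprint_size_mm"] * 1e-3,
        radius_mode=ch.get("radius_mode", "equal_area"),
    )
    conduit = ConduitSpec(
        length_m=co["length_mm"] * 1e-3,
        width_m=co["width_um"] * 1e-6,
        height_m=co["height_um"] * 1e-6,
    )
    return DumbbellSpec(left=chamber, right=chamber, conduit=conduit)
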