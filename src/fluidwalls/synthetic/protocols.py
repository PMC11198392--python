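"""Protocol schedules for the three culture conditions.

Encodes the dumbbell bench timeline from day -6 (seeding) to day 25 as
deposition events (volumes, for the equilibration model) and media-change
events (volumes + BDNF concentration, for the transport model):

* d -6: 4 ul medium into the right chamber, then 1 ul cell suspension into
  the left — the no-backflow seeding order (for the MSN seeding on d 0 the
  roles are mirrored);
* d -3: 2 ul (lentivirus) into the left, 1 ul into the right;
* d -2: wash — remove 4 ul and add back 4 ul fresh medium in each chamber;
* d 0: remove 4 ul from both; 4 ul CN medium into the left, 1 ul of the
  condition medium into the right;
* d 2: full change — remove 4 ul, add 4 ul in each chamber;
* every 48 h thereafter: half change — remove 2 ul, add back 2 ul;
* d 8 (CNs-MSNs only): full change in the distal chamber (MSN medium
  switch).

BDNF content of the added media: CN medium 10 ng/ml; BDNF medium
100 ng/ml (10x); MSN medium 0 ng/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .. import units
from ..equilibration import DepositionEvent
from ..geometry import InvalidSpecError
from ..transport import MediaChangeEvent

CONDITIONS = ("CNs-CN", "CNs-BDNF", "CNs-MSN")

#: BDNF content (ng/ml) of the medium added to each chamber per condition.
BDNF_CN_MEDIUM = 10.0
BDNF_BDNF_MEDIUM = 100.0
BDNF_MSN_MEDIUM = 0.0

_DISTAL_CONC = {
    "CNs-CN": BDNF_CN_MEDIUM,
    "CNs-BDNF": BDNF_BDNF_MEDIUM,
    "CNs-MSN": BDNF_MSN_MEDIUM,
}


@dataclass
class ProtocolSchedule:
    """Full event list of one condition, times in seconds from day -6."""

    condition: str
    start_day: int
    end_day: int
    depositions: list[DepositionEvent] = field(default_factory=list)
    media_changes: list[MediaChangeEvent] = field(default_factory=list)

    def depositions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"time_s": e.time_s, "chamber": e.chamber, "dV_ul": e.dV_ul, "note": e.note}
                for e in self.depositions
            ]
        )

    def media_changes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "time_h": e.time_s / 3600.0,
                    "chamber": e.chamber,
                    "remove_ul": e.remove_ul,
                    "add_ul": e.add_ul,
                    "add_conc_ng_ml": e.add_conc_ng_ml,
                    "note": e.note,
                }
                for e in self.media_changes
            ]
        )


def _t(day: float, start_day: float) -> float:
    return units.days_to_s(day - start_day)


def gen_protocol(condition: str, start_day: int = -6, end_day: int = 25) -> ProtocolSchedule:
    """Enumerate the deposition and media-change events of one condition.

    Times are seconds from ``start_day`` (default day -6).  Events before
    ``start_day`` or after ``end_day`` are omitted.
    """
    if condition not in CONDITIONS:
        raise InvalidSpecError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    distal = _DISTAL_CONC[condition]
    cn = BDNF_CN_MEDIUM

    dep: list[tuple[float, str, float, str]] = [
        (-6, "right", 4.0, "CN medium (pressure guard)"),
        (-6, "left", 1.0, "CN cell suspension"),
        (-3, "left", 2.0, "lentivirus in CN medium"),
        (-3, "right", 1.0, "CN medium top-up"),
    ]
    mc: list[tuple[float, str, float, float, float, str]] = [
        (-2, "left", 4.0, 4.0, cn, "wash"),
        (-2, "right", 4.0, 4.0, cn, "wash"),
        (0, "left", 4.0, 4.0, cn, "condition start"),
        (0, "right", 4.0, 1.0, distal, "condition medium"),
        (2, "left", 4.0, 4.0, cn, "full change"),
        (2, "right", 4.0, 4.0, distal, "full change"),
    ]
    day = 4
    while day <= 24:
        if condition == "CNs-MSN" and day == 8:
            mc.append((8, "left", 2.0, 2.0, cn, "half change"))
            mc.append((8, "right", 4.0, 4.0, distal, "MSN medium switch"))
        else:
            mc.append((day, "left", 2.0, 2.0, cn, "half change"))
            mc.append((day, "right", 2.0, 2.0, distal, "half change"))
        day += 2

    schedule = ProtocolSchedule(condition=condition, start_day=start_day, end_day=end_day)
    for d, chamber, dv, note in dep:
        if start_day <= d <= end_day:
            schedule.depositions.append(
                DepositionEvent(_t(d, start_day), chamber, dv, note)
            )
    for d, chamber, rem, add, conc, note in mc:
        if start_day <= d <= end_day:
            schedule.media_changes.append(
                MediaChangeEvent(_t(d, start_day), chamber, rem, add, conc, note)
            )
            # media changes also move volume; mirror them as depositions
            schedule.depositions.append(
                DepositionEvent(_t(d, start_day), chamber, -rem, f"{note} (remove)")
            )
            schedule.depositions.append(
                DepositionEvent(_t(d, start_day), chamber, add, f"{note} (add)")
            )
    schedule.depositions.sort(key=lambda e: e.time_s)
    schedule.media_changes.sort(key=lambda e: e.time_s)
    return schedule


def bdnf_exposure_schedule(
    condition: str = "CNs-BDNF", start_day: int = 0, end_day: int = 20
) -> tuple[float, float, list[MediaChangeEvent]]:
    """Initial chamber BDNF concentrations and media changes for a
    transport run over [start_day, end_day].

    At d 0 both chambers hold 4 ul: the left (CN) chamber at the CN-medium
    baseline of 10 ng/ml, the right at the condition concentration.
    Events strictly after d 0 are returned with times from ``start_day``.
    """
    if condition not in CONDITIONS:
        raise InvalidSpecError(f"unknown condition {condition!r}")
    full = gen_protocol(condition, start_day=start_day, end_day=end_day)
    events = [e for e in full.media_changes if e.time_s > 0.0]
    return BDNF_CN_MEDIUM, _DISTAL_CONC[condition], events
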