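"""Two-chamber equilibration dynamics and the no-backflow protocol."""

import math

import numpy as np
import pytest

import fluidwalls as fw
from fluidwalls import units
from fluidwalls.equilibration import (
    DepositionEvent,
    assert_no_backflow,
    equilibrium_state,
    hydraulic_resistance,
    read_events_csv,
    simulate_equilibration,
    time_to_equilibration,
)
from fluidwalls.geometry import ConduitSpec, DepinningError, InvalidSpecError

SEED_PROTOCOL = [
    DepositionEvent(0.0, "right", 4.0, "medium"),
    DepositionEvent(0.0, "left", 1.0, "cells"),
]


class TestHydraulicResistance:
    def test_hand_evaluation(self, fluids):
        c = ConduitSpec(1e-3, 200e-6, 10e-6)
        expected = 12 * fluids.mu_med * 1e-3 / (200e-6 * (10e-6) ** 3 * (1 - 0.63 * 0.05))
        assert hydraulic_resistance(c, fluids) == pytest.approx(expected, rel=1e-12)

    def test_cubic_height_scaling(self, fluids):
        r10 = hydraulic_resistance(ConduitSpec(1e-3, 200e-6, 10e-6), fluids)
        r5 = hydraulic_resistance(ConduitSpec(1e-3, 200e-6, 5e-6), fluids)
        bracket = (1 - 0.63 * 10e-6 / 200e-6) / (1 - 0.63 * 5e-6 / 200e-6)
        assert r5 / r10 == pytest.approx(8.0 * bracket, rel=1e-12)

    def test_wide_channel_parallel_plate_limit(self, fluids):
        c = ConduitSpec(1e-3, 1e-3, 1e-6)
        plate = 12 * fluids.mu_med * 1e-3 / (1e-3 * (1e-6) ** 3)
        assert hydraulic_resistance(c, fluids) == pytest.approx(plate, rel=1e-2)


class TestSimulateEquilibration:
    def test_equal_volumes_no_flow(self, dumbbell, fluids):
        events = [
            DepositionEvent(0.0, "right", 2.5),
            DepositionEvent(0.0, "left", 2.5),
        ]
        traj = simulate_equilibration(dumbbell, fluids, events, 6 * 3600.0)
        assert np.allclose(traj.Q_m3_s, 0.0, atol=1e-25)
        assert np.allclose(traj.V_left_m3, units.ul_to_m3(2.5), rtol=1e-12)

    def test_volume_conserved_and_signs(self, dumbbell, fluids):
        traj = simulate_equilibration(dumbbell, fluids, SEED_PROTOCOL, 24 * 3600.0)
        total = traj.V_left_m3 + traj.V_right_m3
        assert np.max(np.abs(total - units.ul_to_m3(5.0))) / units.ul_to_m3(5.0) < 1e-12
        # flow follows the pressure difference sample by sample
        assert np.all(np.sign(traj.Q_m3_s) == np.sign(traj.deltaP_pa))
        # dP stays positive (right higher) and decays monotonically
        assert np.all(traj.deltaP_pa > 0)
        assert np.all(np.diff(traj.deltaP_pa) <= 1e-12 * traj.deltaP_pa[0])

    def test_volumes_almost_equalise_by_24h(self, dumbbell, fluids):
        traj = simulate_equilibration(dumbbell, fluids, SEED_PROTOCOL, 24 * 3600.0)
        assert abs(traj.V_right_m3[-1] - traj.V_left_m3[-1]) < 0.2 * units.ul_to_m3(1.0)

    def test_solver_refinement_stability(self, dumbbell, fluids):
        coarse = simulate_equilibration(dumbbell, fluids, SEED_PROTOCOL, 12 * 3600.0, rtol=1e-8)
        fine = simulate_equilibration(dumbbell, fluids, SEED_PROTOCOL, 12 * 3600.0, rtol=1e-11)
        assert abs(fine.V_left_m3[-1] - coarse.V_left_m3[-1]) / fine.V_left_m3[-1] < 1e-6

    def test_mid_run_events_bookkept_exactly(self, dumbbell, fluids):
        events = SEED_PROTOCOL + [DepositionEvent(6 * 3600.0, "left", -0.5, "sample")]
        traj = simulate_equilibration(dumbbell, fluids, events, 12 * 3600.0)
        after = traj.t_s >= 6 * 3600.0
        total = traj.V_left_m3 + traj.V_right_m3
        assert np.allclose(total[after], units.ul_to_m3(4.5), rtol=1e-12)
        assert np.allclose(total[~after], units.ul_to_m3(5.0), rtol=1e-12)

    def test_overfill_names_event(self, dumbbell, fluids):
        events = [DepositionEvent(0.0, "right", 8.0, "overfill")]
        with pytest.raises(DepinningError):
            simulate_equilibration(dumbbell, fluids, events, 3600.0)

    def test_over_removal_rejected(self, dumbbell, fluids):
        events = [
            DepositionEvent(0.0, "right", 1.0),
            DepositionEvent(100.0, "right", -2.0),
        ]
        with pytest.raises(InvalidSpecError):
            simulate_equilibration(dumbbell, fluids, events, 3600.0)

    def test_linearized_decay_rate(self, dumbbell, fluids):
        """A small perturbation about equilibrium decays at the closed-form
        rate k = (1/R_h) dDeltaP/dV_R, within 1%."""
        V_eq = units.ul_to_m3(2.5)
        eps = units.ul_to_m3(0.02)
        events = [
            DepositionEvent(0.0, "right", units.m3_to_ul(V_eq + eps)),
            DepositionEvent(0.0, "left", units.m3_to_ul(V_eq - eps)),
        ]
        traj = simulate_equilibration(
            dumbbell, fluids, events, 4 * 3600.0, output_dt_s=600.0, rtol=1e-11
        )
        dev = traj.V_right_m3 - V_eq
        slope = np.polyfit(traj.t_s, np.log(dev), 1)[0]
        # finite-difference linearisation of dP about the equilibrium split
        a = dumbbell.left.effective_radius_m
        dv = units.ul_to_m3(1e-4)

        def delta_p(v_r):
            right = fw.ChamberState.from_volume(a, v_r)
            left = fw.ChamberState.from_volume(a, 2 * V_eq - v_r)
            return fw.pressure_difference(left, right, fluids)

        dpdv = (delta_p(V_eq + dv) - delta_p(V_eq - dv)) / (2 * dv)
        k = dpdv / hydraulic_resistance(dumbbell.conduit, fluids)
        assert -slope == pytest.approx(k, rel=0.01)

    def test_equilibration_timescale_brackets_the_24h_observation(self, fluids):
        """With the default constants a conduit near the top of the printed
        '<10 um' height range equilibrates 90% in hours-to-a-day; a 5 um
        conduit is ~8x slower (resistance ~ 1/h^3)."""
        d10 = fw.default_dumbbell(conduit_height_um=10.0)
        traj10 = simulate_equilibration(d10, fluids, SEED_PROTOCOL, 48 * 3600.0)
        t90_10 = time_to_equilibration(traj10, 0.9) / 3600.0
        assert 3.0 <= t90_10 <= 30.0
        d5 = fw.default_dumbbell(conduit_height_um=5.0)
        traj5 = simulate_equilibration(d5, fluids, SEED_PROTOCOL, 300 * 3600.0)
        t90_5 = time_to_equilibration(traj5, 0.9) / 3600.0
        assert t90_5 > t90_10
        assert t90_5 / t90_10 == pytest.approx(8.0, rel=0.25)


class TestEquilibriumState:
    def test_identical_chambers_split_evenly(self, dumbbell, fluids):
        left, right = equilibrium_state(dumbbell, fluids, 5.0)
        assert left.V_m3 == pytest.approx(units.ul_to_m3(2.5), rel=1e-12)
        assert right.V_m3 == pytest.approx(units.ul_to_m3(2.5), rel=1e-12)

    def test_simulation_limit_matches(self, dumbbell, fluids):
        traj = simulate_equilibration(dumbbell, fluids, SEED_PROTOCOL, 200 * 3600.0)
        left, right = equilibrium_state(dumbbell, fluids, 5.0)
        assert traj.V_left_m3[-1] == pytest.approx(left.V_m3, rel=1e-4)

    def test_larger_footprint_holds_more(self, fluids):
        small = fw.ChamberSpec("square", 2.5e-3)
        large = fw.ChamberSpec("square", 3.5e-3)
        conduit = ConduitSpec(1e-3, 200e-6, 10e-6)
        d = fw.DumbbellSpec(left=small, right=large, conduit=conduit)
        left, right = equilibrium_state(d, fluids, 5.0)
        assert right.V_m3 > left.V_m3
        # oracle: scan splits, the returned one has the smallest |dP|
        vs = np.linspace(0.05, 4.95, 197)
        dps = []
        for v in vs:
            l = fw.ChamberState.from_volume(small.effective_radius_m, units.ul_to_m3(v))
            r = fw.ChamberState.from_volume(large.effective_radius_m, units.ul_to_m3(5 - v))
            dps.append(abs(fw.pressure_difference(l, r, fluids)))
        v_scan = vs[int(np.argmin(dps))]
        assert left.V_m3 == pytest.approx(units.ul_to_m3(v_scan), abs=units.ul_to_m3(0.05))

    def test_depinning_total_rejected(self, dumbbell, fluids):
        with pytest.raises(DepinningError):
            equilibrium_state(dumbbell, fluids, 20.0)


class TestNoBackflow:
    def test_seeding_protocol_protects_left(self, dumbbell, fluids):
        traj = simulate_equilibration(dumbbell, fluids, SEED_PROTOCOL, 24 * 3600.0)
        assert assert_no_backflow(traj, "left").ok

    def test_reversed_protocol_fails_at_time_zero(self, dumbbell, fluids):
        events = [
            DepositionEvent(0.0, "left", 4.0),
            DepositionEvent(0.0, "right", 1.0),
        ]
        traj = simulate_equilibration(dumbbell, fluids, events, 24 * 3600.0)
        report = assert_no_backflow(traj, "left")
        assert not report.ok
        assert report.first_violation_time_s == 0.0
        # ... but it protects the right chamber (the MSN seeding order)
        assert assert_no_backflow(traj, "right").ok

    def test_zero_flow_passes_both(self, dumbbell, fluids):
        events = [DepositionEvent(0.0, "right", 2.0), DepositionEvent(0.0, "left", 2.0)]
        traj = simulate_equilibration(dumbbell, fluids, events, 3600.0)
        assert assert_no_backflow(traj, "left").ok
        assert assert_no_backflow(traj, "right").ok


def test_events_csv_round_trip(tmp_path, dumbbell, fluids):
    import pandas as pd

    path = tmp_path / "events.csv"
    pd.DataFrame(
        [
            {"time_s": 0.0, "chamber": "right", "dV_ul": 4.0, "note": "medium"},
            {"time_s": 0.0, "chamber": "left", "dV_ul": 1.0, "note": "cells"},
        ]
    ).to_csv(path, index=False)
    events = read_events_csv(path)
    assert [e.chamber for e in events] == ["right", "left"]
    traj = simulate_equilibration(dumbbell, fluids, events, 3600.0)
    assert traj.V_right_m3[0] == pytest.approx(units.ul_to_m3(4.0), rel=1e-12)


def test_trajectory_export_columns(dumbbell, fluids):
    traj = simulate_equilibration(dumbbell, fluids, SEED_PROTOCOL, 3600.0)
    df = traj.to_dataframe()
    assert list(df.columns) == [
        "t_s", "hL_mm", "hR_mm", "VL_ul", "VR_ul", "PL_Pa", "PR_Pa", "dP_Pa", "Q_nl_s",
    ]
    assert df.VR_ul.iloc[0] == pytest.approx(4.0, rel=1e-9)
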