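"""Lumped-parameter dissection network: elements, solver, occlusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import root

from dissectflow.network import DissectionNetwork, NetworkStepper, Outlet, \
    Segment, Tear, build_network, occlude_tear, report_metrics, \
    segment_resistance, segment_inertance, solve, tear_element, \
    tear_pressure_drop
from dissectflow.pipeline import calibrate_case_outlets, scenario_inflow
from dissectflow.rheology import PowerLawParams
from dissectflow.synthetic import make_case, make_inlet_waveform
from dissectflow.waveform import FlowWaveform
from dissectflow.windkessel import PressureTargets, WindkesselParams


def _steady(q=3.0, period=1.0, n=8):
    t = period * np.arange(n) / n
    return FlowWaveform(t, np.full(n, q), period)


def _simple_network(inflow, tear=None, r2_segment=False):
    """inlet -> segment -> node N -> RCR outlet (optionally a second
    parallel segment and a tear)."""
    segs = [Segment("S1", "IN", "N", 1e7, 0.0)]
    nodes = ["IN", "N"]
    tears = []
    if r2_segment:
        segs.append(Segment("S2", "IN", "N", 2e7, 0.0))
    if tear is not None:
        nodes.append("F")
        tears.append(tear)
        segs.append(Segment("SF", "F", "N", 5e6, 0.0))
    outlets = [Outlet("out", "N", WindkesselParams(1.0, 0.002, 19.0, 10.0))]
    return DissectionNetwork(nodes=nodes, segments=segs, tears=tears,
                             outlets=outlets, inlet_node="IN",
                             inflow=inflow)


class TestElements:
    def test_newtonian_segment_resistance_closed_form(self):
        params = PowerLawParams(consistency_index_K=0.004, exponent_n=1.0)
        r = segment_resistance(100.0, 5.0, params)
        expected = 8 * 0.004 * 0.1 / (math.pi * 0.005**4)
        assert r == pytest.approx(expected, rel=1e-12)

    def test_doubling_radius_divides_resistance_by_16(self, plparams):
        assert segment_resistance(80.0, 4.0, plparams) \
            == pytest.approx(16 * segment_resistance(80.0, 8.0, plparams))

    def test_power_law_resistance_uses_reference_viscosity(self, plparams):
        # independent log-space viscosity oracle at 100 1/s
        eta = 0.08 * math.exp(-0.45 * math.log(100.0))
        r = segment_resistance(50.0, 6.0, plparams,
                               reference_shear_rate=100.0)
        assert r == pytest.approx(8 * eta * 0.05 / (math.pi * 0.006**4),
                                  rel=1e-12)

    def test_inertance_closed_form(self):
        assert segment_inertance(100.0, 10.0, 1022.0) == pytest.approx(
            1022.0 * 0.1 / (math.pi * 0.01**2), rel=1e-12)

    def test_tear_zero_flow_zero_drop(self):
        r_lin, k = tear_element(5.0)
        assert tear_pressure_drop(0.0, r_lin, k) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(1e-8, 1e-3))
    def test_tear_drop_is_odd_in_flow(self, q):
        r_lin, k = tear_element(5.0)
        assert tear_pressure_drop(-q, r_lin, k) \
            == pytest.approx(-tear_pressure_drop(q, r_lin, k), rel=1e-12)

    def test_tear_drop_strictly_increasing(self):
        r_lin, k = tear_element(5.0)
        q = np.linspace(-1e-4, 1e-4, 201)
        assert np.all(np.diff(tear_pressure_drop(q, r_lin, k)) > 0)

    def test_quadratic_coefficient_matches_hand_evaluation(self):
        # rho/(2 Cd^2 A^2) Q^2 at Q = 1 L/min, d = 5 mm, Cd = 0.6
        r_lin, k = tear_element(5.0, discharge_coefficient=0.6,
                                density=1022.0)
        area = math.pi * 0.0025**2
        k_hand = 1022.0 / (2.0 * 0.36 * area**2)
        q = 1.0 / 60000.0
        quad = tear_pressure_drop(q, r_lin, k) - r_lin * q
        assert quad == pytest.approx(k_hand * q * q, rel=1e-12)


class TestSolver:
    def test_single_tube_steady_series_resistances(self):
        net = _simple_network(_steady(3.0))
        sol = solve(net, dt=0.005, periodicity_tol=1e-6)
        q_si = 3.0 / 60000.0
        p_out_face = 10.0 + 3.0 * 20.0  # Pout + Q (Rp + Rd), mmHg
        assert sol.node_pressure_mean("N") == pytest.approx(p_out_face,
                                                            rel=1e-3)
        p_in = p_out_face + q_si * 1e7 / 133.322
        assert sol.node_pressure_mean("IN") == pytest.approx(p_in, rel=1e-3)

    def test_parallel_branches_split_as_current_divider(self):
        net = _simple_network(_steady(3.0), r2_segment=True)
        sol = solve(net, dt=0.005, periodicity_tol=1e-6)
        q1 = np.mean(sol.flows_L_min["S1"])
        q2 = np.mean(sol.flows_L_min["S2"])
        assert q1 / q2 == pytest.approx(2.0, rel=1e-6)  # R2 : R1
        assert q1 + q2 == pytest.approx(3.0, rel=1e-6)

    def test_kirchhoff_residual_below_tolerance_on_full_case(self):
        case = make_case("S1-like")
        inflow = scenario_inflow(case)
        outlets = calibrate_case_outlets(case, inflow,
                                         PressureTargets(60.0, 25.0), 0.05)
        net = build_network(case, outlets, inflow)
        sol = solve(net, dt=0.002)
        assert sol.max_rel_residual <= 1e-9

    def test_dense_solver_equivalence_at_random_steps(self):
        """Newton step vs scipy root on the same nonlinear nodal system."""
        inflow = make_inlet_waveform(0.8, 6.0, 0.4, 20)
        r_lin, k = tear_element(6.0)
        tear = Tear("tr", "IN", "F", r_lin, k)
        net = _simple_network(inflow, tear=tear)
        dt = 0.002
        stepper = NetworkStepper(net, dt)
        n_steps = int(round(0.8 / dt))
        t_ext = np.append(inflow.time_s, 0.8)
        q_ext = np.append(inflow.flow_L_min, inflow.flow_L_min[0])
        q_in = np.interp(dt * np.arange(n_steps + 1) % 0.8, t_ext, q_ext) \
            / 60000.0
        rng = np.random.default_rng(11)
        check_at = set(rng.integers(1, n_steps, size=10).tolist())
        p = np.full(len(net.nodes), 8000.0)
        for kstep in range(1, n_steps + 1):
            p_new, _, _ = stepper.newton_step(p, q_in[kstep], tol_abs=1e-18)
            if kstep in check_at:
                guess = p_new * (1 + 1e-3 * rng.standard_normal(p.size))
                res = root(lambda x: stepper.residual(x, q_in[kstep]), guess,
                           method="hybr", tol=1e-14)
                # hybr can flag slow progress at machine precision; what
                # matters is that it found a genuine root of the system
                assert np.abs(stepper.residual(res.x, q_in[kstep])).max() \
                    < 1e-15
                np.testing.assert_allclose(res.x, p_new, rtol=1e-8)
            p = p_new
            stepper.commit(p)

    def test_halving_dt_changes_mean_pressures_below_half_percent(self):
        inflow = make_inlet_waveform(0.8, 6.0, 0.4, 20)
        r_lin, k = tear_element(6.0)
        net = _simple_network(inflow, tear=Tear("tr", "IN", "F", r_lin, k))
        means = []
        for dt in (0.002, 0.001):
            sol = solve(net, dt=dt, periodicity_tol=1e-5)
            means.append(np.array([sol.node_pressure_mean(n)
                                   for n in net.nodes]))
        assert np.max(np.abs(means[1] - means[0]) / np.abs(means[1])) < 0.005

    def test_disconnected_network_rejected(self):
        with pytest.raises(ValueError, match="disconnected"):
            DissectionNetwork(
                nodes=["IN", "N", "X"],
                segments=[Segment("S1", "IN", "N", 1e7, 0.0)],
                tears=[], outlets=[Outlet("o", "N",
                                          WindkesselParams(1, 0.01, 19))],
                inlet_node="IN", inflow=_steady(1.0))


class TestOcclusion:
    def test_occluding_reentry1_reproduces_the_occluded_case(self):
        case = make_case("S2-like")
        inflow = scenario_inflow(case)
        outlets = calibrate_case_outlets(case, inflow,
                                         PressureTargets(60.0, 25.0), 0.05)
        net_s2 = build_network(case, outlets, inflow)
        net_mod = occlude_tear(net_s2, "reentry1")
        ref = build_network(make_case("S2mod-like"), outlets, inflow)
        assert [(t.name, t.open) for t in net_mod.tears] \
            == [(t.name, t.open) for t in ref.tears]
        assert [(s.name, s.resistance) for s in net_mod.segments] \
            == [(s.name, s.resistance) for s in ref.segments]

    def test_occluded_tear_carries_zero_flow_and_others_differ(self):
        case = make_case("S2-like")
        inflow = scenario_inflow(case)
        outlets = calibrate_case_outlets(case, inflow,
                                         PressureTargets(60.0, 25.0), 0.05)
        net = build_network(case, outlets, inflow)
        net_mod = occlude_tear(net, "reentry1")
        sol = solve(net_mod, dt=0.002, periodicity_tol=1e-4)
        assert np.all(sol.flows_L_min["reentry1"] == 0)
        # distal TL fraction shifts by a strictly nonzero amount
        sol_full = solve(net, dt=0.002, periodicity_tol=1e-4)
        m_mod = report_metrics(sol, case.stations)["P6"]["tl_percent"]
        m_full = report_metrics(sol_full, case.stations)["P6"]["tl_percent"]
        assert abs(m_full - m_mod) > 1e-6

    def test_occluding_closed_or_unknown_tear_rejected(self):
        case = make_case("S1-like")
        inflow = scenario_inflow(case)
        outlets = calibrate_case_outlets(case, inflow,
                                         PressureTargets(60.0, 25.0), 0.05)
        net = build_network(case, outlets, inflow)
        with pytest.raises(ValueError, match="already closed"):
            occlude_tear(net, "reentry1")
        with pytest.raises(KeyError):
            occlude_tear(net, "no-such-tear")

    def test_dead_end_false_lumen_carries_no_net_flow(self):
        """Only the entry tear open: the rigid FL pouch admits no flow."""
        case = make_case("S1-like")
        inflow = scenario_inflow(case)
        outlets = calibrate_case_outlets(case, inflow,
                                         PressureTargets(60.0, 25.0), 0.05)
        net = occlude_tear(build_network(case, outlets, inflow), "distal")
        assert not net.sealed_pouch  # still reachable through the entry
        sol = solve(net, dt=0.002, periodicity_tol=1e-4)
        assert np.max(np.abs(sol.flows_L_min["entry"])) < 1e-9

    def test_fully_sealed_pouch_is_flagged_and_solvable(self):
        case = make_case("S1-like")
        inflow = scenario_inflow(case)
        outlets = calibrate_case_outlets(case, inflow,
                                         PressureTargets(60.0, 25.0), 0.05)
        net = build_network(case, outlets, inflow)
        net = occlude_tear(occlude_tear(net, "entry"), "distal")
        assert net.sealed_pouch
        assert set(net.sealed_nodes) == {"F0", "F1", "F2", "F3",
                                         "Fm1", "Fm2"}
        sol = solve(net, dt=0.002, periodicity_tol=1e-4)
        assert sol.sealed_pouch
        for name in ("FL1a", "FL2", "FL3b"):
            assert np.max(np.abs(sol.flows_L_min[name])) < 1e-12


class TestReportMetrics:
    def test_symmetric_lumina_have_zero_clpd(self):
        """Identical parallel chains joined by identical tears."""
        inflow = make_inlet_waveform(0.8, 6.0, 0.4, 20)
        r_lin, k = tear_element(8.0)
        nodes = ["IN", "A", "B", "N"]
        segs = [
            Segment("SA1", "IN", "A", 1e7, 1e5, "TL"),
            Segment("SB1", "IN", "B", 1e7, 1e5, "FL"),
            Segment("SA2", "A", "N", 1e7, 1e5, "TL"),
            Segment("SB2", "B", "N", 1e7, 1e5, "FL"),
        ]
        tears = [Tear("t1", "A", "B", r_lin, k)]
        outlets = [Outlet("o", "N", WindkesselParams(1.0, 0.002, 19.0))]
        net = DissectionNetwork(nodes=nodes, segments=segs, tears=tears,
                                outlets=outlets, inlet_node="IN",
                                inflow=inflow)
        sol = solve(net, dt=0.002, periodicity_tol=1e-5)
        stations = {"mid": {"tl_node": "A", "fl_node": "B",
                            "tl_element": "SA2", "fl_element": "SB2"}}
        m = report_metrics(sol, stations)["mid"]
        assert m["tl_percent"] == pytest.approx(50.0, abs=1e-6)
        assert np.max(np.abs(m["clpd_mmHg"])) < 1e-9

    def test_unknown_station_node_raises(self):
        net = _simple_network(_steady(2.0))
        sol = solve(net, dt=0.005, periodicity_tol=1e-5)
        stations = {"bad": {"tl_node": "ZZ", "fl_node": "N",
                            "tl_element": "S1", "fl_element": "S1"}}
        with pytest.raises(KeyError, match="bad"):
            report_metrics(sol, stations)
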