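"""Plane flow rates, RFI, flow distribution, branch split, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dissectflow.fields import VelocityField4D
from dissectflow.flow_metrics import AnalysisPlane, branch_flow_split, \
    extract_inlet_profile, flow_distribution, peak_velocity, \
    plane_flow_rate, rfi, tear_rfi
from dissectflow.synthetic import PhantomSpec, AcquisitionParams, \
    make_inlet_waveform, make_phantom_field
from dissectflow.waveform import FlowWaveform

from conftest import uniform_axial_field


def _waveform(values, period=1.0):
    values = np.asarray(values, dtype=float)
    t = period * np.arange(values.size) / values.size
    return FlowWaveform(t, values, period)


class TestPlaneFlowRate:
    def test_uniform_field_gives_v_times_area(self):
        field = uniform_axial_field(speed=0.5, radius_mm=10.0, voxel_mm=1.25)
        plane = AnalysisPlane((0, 0, 5.0), (0, 0, 1.0), lumen="TL")
        wf = plane_flow_rate(field, plane)
        area_m2 = (field.mask[:, :, 4] == 1).sum() * (1.25e-3) ** 2
        expected = 0.5 * area_m2 * 60000.0
        np.testing.assert_allclose(wf.flow_L_min, expected, rtol=0.01)

    def test_flipped_normal_negates_waveform_exactly(self, tube_field):
        _, _, field = tube_field
        up = plane_flow_rate(field, AnalysisPlane((0, 0, 20.0), (0, 0, 1.0),
                                                  lumen="TL"))
        down = plane_flow_rate(field, AnalysisPlane(
            (0, 0, 20.0), (0, 0, -1.0), lumen="TL"))
        np.testing.assert_array_equal(up.flow_L_min, -down.flow_L_min)

    def test_linear_in_the_field(self, tube_field):
        _, _, field = tube_field
        scaled = VelocityField4D(2.5 * field.velocity, field.mask,
                                 field.affine, field.time_s, field.period_s)
        plane = AnalysisPlane((0, 0, 20.0), (0, 0, 1.0), lumen="TL")
        q1 = plane_flow_rate(field, plane).flow_L_min
        q2 = plane_flow_rate(scaled, plane).flow_L_min
        np.testing.assert_allclose(q2, 2.5 * q1, rtol=1e-12)

    def test_empty_intersection_names_the_plane(self, tube_field):
        _, _, field = tube_field
        plane = AnalysisPlane((0, 0, 20.0), (0, 0, 1.0), lumen="FL",
                              label="mid-FL")
        with pytest.raises(ValueError, match="mid-FL"):
            plane_flow_rate(field, plane)


class TestRFI:
    def test_sign_cases(self):
        assert rfi(_waveform([1.0, 2.0, 1.5, 3.0])) == 0.0
        assert rfi(_waveform([-1.0, -2.0, -1.5, -3.0])) == 100.0
        t = np.arange(64) / 64.0
        assert rfi(FlowWaveform(t, np.sin(2 * np.pi * t), 1.0)) \
            == pytest.approx(50.0, abs=1e-9)

    def test_all_zero_waveform_is_zero_by_convention(self):
        assert rfi(_waveform([0.0, 0.0, 0.0, 0.0])) == 0.0

    def test_half_period_two_minus_one_against_fine_grid_oracle(self):
        # Q = +2 on [0, T/2), -1 on [T/2, T): |rev| = T/2, |fwd| = T
        T, eps = 1.0, 1e-9
        wf = FlowWaveform(
            np.array([0.0, T / 2 - eps, T / 2, T - eps]),
            np.array([2.0, 2.0, -1.0, -1.0]), T)
        # independent fine-grid (rectangle rule) integration oracle
        tt = (np.arange(4_000_000) + 0.5) * T / 4_000_000
        q = np.where(tt < T / 2, 2.0, -1.0)
        dt = T / tt.size
        fwd = np.sum(np.maximum(q, 0)) * dt
        rev = -np.sum(np.minimum(q, 0)) * dt
        oracle = 100.0 * rev / (rev + fwd)
        assert rfi(wf) == pytest.approx(oracle, abs=1e-6)
        assert oracle == pytest.approx(100.0 / 3.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=4,
                    max_size=32))
    def test_range_and_reflection_property(self, values):
        wf = _waveform(values)
        r = rfi(wf)
        assert 0.0 <= r <= 100.0
        t, q = wf._closed_cycle()
        total = np.trapezoid(np.abs(q), t)
        if total > 1e-9:
            assert rfi(wf.negated()) == pytest.approx(100.0 - r, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rfi(FlowWaveform(np.array([0.0, 0.4]), np.array([1.0, 1.0]), 1.0))


class TestTearRFI:
    def test_entry_tear_forward_flow_has_zero_rfi(self):
        assert tear_rfi(_waveform([1.0, 2.0, 1.0, 0.5]), "entry") == 0.0

    def test_reentry_tear_fl_to_tl_flow_has_zero_rfi(self):
        # negative samples = FL->TL, the forward direction for re-entries
        assert tear_rfi(_waveform([-1.0, -2.0, -1.0, -0.5]), "re-entry") \
            == 0.0

    def test_reentry_tear_tl_to_fl_flow_is_full_reversal(self):
        assert tear_rfi(_waveform([1.0, 2.0, 1.0, 0.5]), "re-entry") == 100.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            tear_rfi(_waveform([1.0, 1.0, 1.0, 1.0]), "side")


class TestFlowDistribution:
    def test_fifty_six_forty_four(self):
        d = flow_distribution(_waveform([5.6] * 4), _waveform([4.4] * 4))
        assert d.tl_percent == pytest.approx(56.0)
        assert d.fl_percent == pytest.approx(44.0)
        assert not d.flagged

    def test_zero_fl_flow(self):
        d = flow_distribution(_waveform([3.0] * 4), _waveform([0.0] * 4))
        assert d.tl_percent == pytest.approx(100.0)
        assert d.flagged  # FL net flow is not forward

    def test_zero_total_flow_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            flow_distribution(_waveform([1.0] * 4), _waveform([-1.0] * 4))

    def test_mismatched_time_base_rejected(self):
        with pytest.raises(ValueError):
            flow_distribution(_waveform([1.0] * 4), _waveform([1.0] * 5))


class TestPeakVelocity:
    def test_uniform_magnitude(self):
        field = uniform_axial_field(speed=0.73)
        per_frame, vmax = peak_velocity(field, AnalysisPlane(
            (0, 0, 5.0), (0, 0, 1.0), lumen="TL"))
        assert vmax == pytest.approx(73.0)  # cm/s

    def test_parabolic_centerline_speed(self, tube_field):
        spec, acq, field = tube_field
        per_frame, vmax = peak_velocity(field, AnalysisPlane(
            (0, 0, 20.0), (0, 0, 1.0), lumen="TL"))
        # analytic centerline speed of the scaled parabola at peak frame
        k = int(np.argmax(per_frame))
        wf = plane_flow_rate(field, AnalysisPlane((0, 0, 20.0), (0, 0, 1.0),
                                                  lumen="TL"))
        q_m3s = wf.flow_L_min[k] / 60000.0
        area = (field.mask[:, :, 0] > 0).sum() * (acq.voxel_size_mm * 1e-3)**2
        centerline_cm_s = 2.0 * q_m3s / area * 100.0
        # discrete profile normalization sits a few percent above the
        # continuum 2Q/A at this resolution
        assert vmax == pytest.approx(centerline_cm_s, rel=0.05)

    def test_zero_field_gives_zero(self):
        field = uniform_axial_field(speed=0.0)
        _, vmax = peak_velocity(field, AnalysisPlane((0, 0, 5.0), (0, 0, 1.0),
                                                     lumen="TL"))
        assert vmax == 0.0


class TestBranchFlowSplit:
    def test_area_proportional_split(self):
        flows, flagged = branch_flow_split(_waveform([10.0] * 4),
                                           _waveform([5.0] * 4), [1, 2, 2])
        np.testing.assert_allclose(flows, [1.0, 2.0, 2.0])
        assert not flagged

    def test_equal_areas_equal_flows(self):
        flows, _ = branch_flow_split(_waveform([8.0] * 4),
                                     _waveform([2.0] * 4), [3, 3, 3, 3])
        np.testing.assert_allclose(flows, 1.5)

    def test_three_seven_split_matches_rational_oracle(self):
        flows, _ = branch_flow_split(_waveform([6.2] * 4),
                                     _waveform([2.0] * 4), [3, 7])
        # exact rational arithmetic: 4.2 * 3/10 and 4.2 * 7/10
        np.testing.assert_allclose(flows, [1.26, 2.94], rtol=1e-12)

    def test_conservation_to_machine_precision(self):
        before = _waveform([3.123456, 7.1, 0.5, 2.2])
        after = _waveform([1.1, 2.9, 0.1, 0.9])
        areas = [1.7, 2.9, 0.313, 8.0]
        flows, _ = branch_flow_split(before, after, areas)
        assert flows.sum() + after.cycle_mean() \
            == pytest.approx(before.cycle_mean(), abs=1e-14)

    def test_net_backflow_is_flagged(self):
        _, flagged = branch_flow_split(_waveform([1.0] * 4),
                                       _waveform([2.0] * 4), [1, 1])
        assert flagged

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            branch_flow_split(_waveform([1.0] * 4), _waveform([0.5] * 4),
                              [1.0, 0.0])


@pytest.fixture(scope="module")
def phantom():
    spec = PhantomSpec(kind="straight_tube", radius_mm=10.0)
    acq = AcquisitionParams(voxel_size_mm=1.25,
                            noise_sd_fraction_of_venc=0.0)
    field, _ = make_phantom_field(spec, acq)
    plane = AnalysisPlane((0, 0, 20.0), (0, 0, 1.0), lumen="TL",
                          label="inlet")
    return field, plane


class TestInletProfileExtraction:
    @staticmethod
    def _disk_points(pitch, radius=9.0, z=20.0):
        c = np.arange(-radius, radius + pitch / 2, pitch)
        X, Y = np.meshgrid(c, c, indexing="ij")
        sel = X**2 + Y**2 < radius**2
        return np.stack([X[sel], Y[sel], np.full(sel.sum(), z)], axis=1)

    def test_uniform_source_gives_uniform_profile(self):
        field = uniform_axial_field(speed=0.4)
        plane = AnalysisPlane((0, 0, 5.0), (0, 0, 1.0), lumen="TL")
        pts = self._disk_points(1.0, radius=7.0, z=5.0)
        profiles, report = extract_inlet_profile(field, plane, pts)
        assert report["n_outside"] == 0
        spread = profiles[0, :, 2].max() - profiles[0, :, 2].min()
        assert spread == pytest.approx(0.0, abs=1e-12)

    def test_flux_preserved_after_rescaling(self, phantom):
        field, plane = phantom
        pts = self._disk_points(1.7)
        profiles, report = extract_inlet_profile(field, plane, pts)
        source = report["source_waveform"]
        # recompute target flux with the same uniform weights
        inside = field.sample_mask(pts) > 0
        from dissectflow.flow_metrics import _PlaneSampling
        s = _PlaneSampling(field, plane)
        w = np.full(pts.shape[0],
                    s.area_mm2 * int(s.in_lumen.sum()) / inside.sum())
        flux = (profiles[:, :, 2] * w[None, :]).sum(axis=1) * 1e-6 * 60000.0
        np.testing.assert_allclose(flux, source.flow_L_min, rtol=1e-6,
                                   atol=1e-12)

    def test_raw_flux_error_decreases_under_refinement(self, phantom):
        field, plane = phantom
        errs = []
        for pitch in (3.0, 1.5, 0.75):
            _, report = extract_inlet_profile(field, plane,
                                              self._disk_points(pitch))
            k = int(np.argmax(report["source_waveform"].flow_L_min))
            errs.append(abs(report["scale_factors"][k] - 1.0))
        assert errs[0] > errs[1] > errs[2]

    def test_zero_field_gives_zero_profile(self):
        field = uniform_axial_field(speed=0.0)
        plane = AnalysisPlane((0, 0, 5.0), (0, 0, 1.0), lumen="TL")
        profiles, _ = extract_inlet_profile(field, plane,
                                            self._disk_points(2.0, 7.0, 5.0))
        assert np.all(profiles == 0)

    def test_outside_points_zero_filled_and_counted(self, phantom):
        field, plane = phantom
        pts = np.array([[0.0, 0.0, 20.0], [40.0, 40.0, 20.0]])
        profiles, report = extract_inlet_profile(field, plane, pts)
        assert report["n_outside"] == 1
        assert np.all(profiles[:, 1, :] == 0)
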