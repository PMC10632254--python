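"""Wave separation: Zc estimation, decomposition, RM, Tr, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavesep import (
    Waveform,
    WaveSeparation,
    calibrate_area_to_pressure,
    detect_landmarks,
    estimate_zc,
    reflection_magnitude,
    return_time_centroid,
    separate,
)
from wavesep.errors import DegenerateInputError, InvalidInputError
from wavesep.separation import WaveSeparationResults
from wavesep.synthetic import SimulationGroundTruth, forward_wave, simulate_beat

from conftest import smooth_tube_beat


def pulse_waveform(center, width=60.0, scale=1.0, n=400, cycle=800.0):
    t = np.linspace(0.0, cycle, n)
    x = (t - center) / width
    v = scale * np.where(np.abs(x) < 1, np.cos(np.pi * x / 2) ** 2, 0.0)
    return Waveform(t, v, "pressure", cycle)


class TestEstimateZc:
    def test_exact_linear_relation(self, beat):
        _, q, _ = beat
        p = q.with_values(2.0 * q.v, kind="pressure")
        assert estimate_zc(p, q) == pytest.approx(2.0, rel=1e-12)

    def test_affine_relation_absorbs_intercept(self, beat):
        _, q, _ = beat
        p = q.with_values(3.0 * q.v + 5.0, kind="pressure")
        assert estimate_zc(p, q) == pytest.approx(3.0, rel=1e-12)

    def test_tube_load_recovery_within_3pct(self):
        """Reflection-free early upstroke exposes the true impedance."""
        gt = SimulationGroundTruth(gamma=0.5, delay_ms=150.0, zc_true=0.1)
        p, q, _ = simulate_beat(gt)
        assert estimate_zc(p, q) == pytest.approx(0.1, rel=0.03)

    def test_grid_mismatch_rejected(self, beat):
        p, q, _ = beat
        other = Waveform(q.t[:-1] + 1.0, q.v[:-1], "flow", q.cycle_length)
        with pytest.raises(InvalidInputError):
            estimate_zc(p, other)

    def test_degenerate_negative_slope(self, beat):
        p, q, _ = beat
        neg = p.with_values(-p.v + 2 * p.v.max())
        with pytest.raises(DegenerateInputError):
            estimate_zc(neg, q)


class TestSeparate:
    def test_pure_forward_gives_zero_backward(self, beat):
        _, q, _ = beat
        zc = 0.37
        p = q.with_values(zc * q.v, kind="pressure")
        res = separate(p, q, zc)
        np.testing.assert_allclose(res.pb.v, 0.0, atol=1e-12)
        assert res.rm == pytest.approx(0.0, abs=1e-12)

    def test_closed_valve_limit(self):
        """With zero flow, forward and backward each carry half of P."""
        t = np.linspace(0, 600, 64)
        p = Waveform(t, 80 + 20 * np.sin(np.pi * t / 600), "pressure", 600)
        q = Waveform(t, np.zeros(64), "flow", 600)
        res = separate(p, q, zc=1.0)
        np.testing.assert_allclose(res.pf.v, p.v / 2, atol=1e-12)
        np.testing.assert_allclose(res.pb.v, p.v / 2, atol=1e-12)

    def test_tube_load_backward_recovery_exact(self):
        """Separation at the true Zc returns Pb = gamma * F(t - delay)."""
        gt = SimulationGroundTruth(gamma=0.4, delay_ms=120.0, baseline=0.0)
        p, q, _ = simulate_beat(gt)
        res = separate(p, q, gt.zc_true)
        expected_pb = gt.gamma * forward_wave(gt, p.t - gt.delay_ms)
        np.testing.assert_allclose(res.pb.v, expected_pb, atol=1e-10)

    def test_conservation_identity(self, beat):
        p, q, _ = beat
        res = separate(p, q, 0.1, p_ud=12.0)
        np.testing.assert_allclose(
            res.pf.v + res.pb.v, p.v - 12.0, atol=1e-12 * np.max(np.abs(p.v))
        )

    def test_grid_mismatch_rejected(self, beat):
        p, q, _ = beat
        other = Waveform(q.t * 1.01, q.v, "flow", q.cycle_length * 1.01)
        with pytest.raises(InvalidInputError):
            separate(p, other, 0.1)


class TestReflectionMagnitude:
    def test_ratio_definition(self, beat):
        p, q, _ = beat
        res = separate(p, q, 0.1)
        assert reflection_magnitude(res) == pytest.approx(res.dpb / res.dpf)

    def test_tube_load_partial_overlap(self):
        """Gamma is recovered from component amplitudes despite overlap."""
        gt = SimulationGroundTruth(gamma=0.4, delay_ms=100.0)
        p, q, _ = simulate_beat(gt)
        res = separate(p, q, gt.zc_true)
        assert res.rm == pytest.approx(0.4, rel=0.02)

    def test_zero_forward_amplitude_rejected(self):
        t = np.linspace(0, 600, 64)
        flat = Waveform(t, np.full(64, 5.0), "pressure", 600)
        q = Waveform(t, np.zeros(64), "flow", 600)
        res = separate(flat, q, 1.0)
        with pytest.raises(DegenerateInputError):
            reflection_magnitude(res)


class TestReturnTimeCentroid:
    def test_shifted_identical_pulses(self):
        pf_in = pulse_waveform(100.0)
        pb = pulse_waveform(300.0)
        res = WaveSeparationResults(
            zc=1.0, p_ud=0.0, pressure=pf_in, flow=pf_in,
            pf=pf_in, pb=pb, pf_in=pf_in,
        )
        # exact in the continuum; trapezoidal quadrature on 400 samples
        assert return_time_centroid(res) == pytest.approx(200.0, abs=1e-3)

    def test_scaled_copy_has_zero_delay(self):
        pf_in = pulse_waveform(250.0)
        pb = pulse_waveform(250.0, scale=0.3)
        res = WaveSeparationResults(
            zc=1.0, p_ud=0.0, pressure=pf_in, flow=pf_in,
            pf=pf_in, pb=pb, pf_in=pf_in,
        )
        assert return_time_centroid(res) == pytest.approx(0.0, abs=1e-9)

    def test_zero_integral_rejected(self):
        t = np.linspace(0, 600, 64)
        flat = Waveform(t, np.zeros(64), "pressure", 600)
        res = WaveSeparationResults(
            zc=1.0, p_ud=0.0, pressure=flat, flow=flat,
            pf=flat, pb=flat, pf_in=flat,
        )
        with pytest.raises(DegenerateInputError):
            return_time_centroid(res)

    @given(shift=st.floats(min_value=50.0, max_value=380.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_centroid_shift_property(self, shift):
        """Tr of a shifted scaled copy equals the shift, within a sample."""
        pf_in = pulse_waveform(100.0)
        pb = pulse_waveform(100.0 + shift, scale=0.5)
        res = WaveSeparationResults(
            zc=1.0, p_ud=0.0, pressure=pf_in, flow=pf_in,
            pf=pf_in, pb=pb, pf_in=pf_in,
        )
        dt = pf_in.t[1] - pf_in.t[0]
        assert abs(return_time_centroid(res) - shift) < dt


class TestCalibration:
    def test_two_point_solve(self):
        t = np.linspace(0, 600, 64)
        # engineered so that mean = 500 and min = 450
        v = 450 + 100 * np.abs(np.sin(np.pi * t / 600))
        v = 450 + (v - v.min()) * 50 / (v.mean() - v.min())
        a = Waveform(t, v, "area", 600)
        out = calibrate_area_to_pressure(a, 90.0, 60.0)
        assert np.mean(out.v) == pytest.approx(90.0)
        assert np.min(out.v) == pytest.approx(60.0)
        # alpha = (90-60)/(mean-min) = 0.6, beta = 90 - 0.6*mean = -210
        alpha = (out.v[5] - out.v[3]) / (a.v[5] - a.v[3])
        assert alpha == pytest.approx(0.6)
        assert out.v[5] - alpha * a.v[5] == pytest.approx(-210.0)

    def test_recalibration_to_own_scale_is_identity(self, beat):
        p, _, _ = beat
        out = calibrate_area_to_pressure(p, float(np.mean(p.v)), float(np.min(p.v)))
        np.testing.assert_allclose(out.v, p.v, atol=1e-12 * np.max(p.v))

    def test_rm_invariant_under_calibration(self, beat):
        """Calibrating the area surrogate cannot change RM (Zc rescales)."""
        _, q, a = beat
        res_raw = WaveSeparation(a, q).fit()
        cal = calibrate_area_to_pressure(a, 93.0, 61.0)
        res_cal = WaveSeparation(cal, q).fit()
        assert res_cal.rm == pytest.approx(res_raw.rm, rel=1e-12)
        assert res_cal.tr == pytest.approx(res_raw.tr, rel=1e-9)

    def test_flat_waveform_rejected(self):
        t = np.linspace(0, 600, 64)
        flat = Waveform(t, np.full(64, 500.0), "area", 600)
        with pytest.raises(DegenerateInputError):
            calibrate_area_to_pressure(flat, 90.0, 60.0)


class TestScaleInvariance:
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_flow_amplitude_scaling(self, c):
        p, q = smooth_tube_beat()
        base = WaveSeparation(p, q).fit()
        scaled = WaveSeparation(p, q.with_values(c * q.v)).fit()
        assert scaled.rm == pytest.approx(base.rm, rel=1e-10)
        assert scaled.tr == pytest.approx(base.tr, rel=1e-10)
        assert scaled.zc == pytest.approx(base.zc / c, rel=1e-9)

    def test_pressure_affine_recalibration(self):
        p, q = smooth_tube_beat()
        base = WaveSeparation(p, q).fit()
        recal = WaveSeparation(p.with_values(1.7 * p.v - 40.0), q).fit()
        assert recal.rm == pytest.approx(base.rm, rel=1e-10)
        assert recal.tr == pytest.approx(base.tr, rel=1e-10)


class TestModelInterface:
    def test_from_dataframe_matches_direct(self, beat):
        import pandas as pd

        p, q, _ = beat
        df = pd.DataFrame({"time_ms": p.t, "pressure": p.v, "flow": q.v})
        res1 = WaveSeparation.from_dataframe(df, cycle_length=p.cycle_length).fit()
        res2 = WaveSeparation(p, q).fit()
        assert res1.zc == pytest.approx(res2.zc)
        assert res1.rm == pytest.approx(res2.rm)

    def test_summary_mentions_key_indices(self, beat):
        p, q, _ = beat
        text = WaveSeparation(p, q).fit().summary()
        for token in ("Zc", "RM", "Tr", "dPf", "dPb"):
            assert token in text

    def test_reconstruction_error_is_machine_precision(self, beat):
        p, q, _ = beat
        assert WaveSeparation(p, q).fit().reconstruction_error() < 1e-12
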