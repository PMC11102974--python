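"""Gait-cycle resampling, summary parameters and group comparison."""

import numpy as np
import pytest

from biomechkit import SampledSignal
from biomechkit.errors import InvalidParameterError
from biomechkit.gait import (
    GaitCycleSeries,
    compare_groups_pointwise,
    detect_heel_strikes,
    jcf_peaks,
    normalize_outputs,
    resample_cycle,
    sagittal_rom,
    subject_jcf_peaks,
    subject_rom,
    walking_speed,
)
from biomechkit.synthetic import gen_gait_curves


class TestNormalizeOutputs:
    def test_force_to_body_weight(self):
        sig = SampledSignal(np.full(10, 2060.1), rate_hz=100.0, units="N")
        out = normalize_outputs(sig, 70.0, "force_n")
        assert out.samples[0] == pytest.approx(2060.1 / (70.0 * 9.81))
        assert out.units == "BW"

    def test_moment_per_mass(self):
        sig = SampledSignal(np.full(10, 70.0), rate_hz=100.0, units="Nm")
        out = normalize_outputs(sig, 70.0, "moment_nm")
        assert np.allclose(out.samples, 1.0)

    def test_angles_pass_through(self):
        sig = SampledSignal(np.linspace(0, 60, 10), rate_hz=100.0, units="deg")
        out = normalize_outputs(sig, 70.0, "angle_deg")
        assert out is sig

    def test_homogeneity_in_mass(self):
        sig = SampledSignal(np.full(10, 100.0), rate_hz=100.0, units="N")
        half = normalize_outputs(sig, 35.0, "force_n").samples
        full = normalize_outputs(sig, 70.0, "force_n").samples
        assert np.allclose(half, 2 * full)

    def test_unknown_quantity_rejected(self):
        sig = SampledSignal(np.ones(10), rate_hz=100.0)
        with pytest.raises(InvalidParameterError):
            normalize_outputs(sig, 70.0, "impulse")


class TestResampleCycle:
    def test_output_always_101_points(self):
        sig = SampledSignal(np.random.default_rng(0).random(137), rate_hz=100.0)
        cyc = resample_cycle(sig, (0.0, 1.0))
        assert cyc.values.shape == (101,)

    def test_linear_ramp_preserved(self):
        sig = SampledSignal(np.linspace(0.0, 10.0, 251), rate_hz=250.0)
        cyc = resample_cycle(sig, (0.0, 1.0))
        assert np.allclose(cyc.values, np.linspace(0.0, 10.0, 101), atol=1e-12)

    def test_endpoints_preserved_exactly(self):
        rng = np.random.default_rng(1)
        sig = SampledSignal(rng.random(250), rate_hz=250.0)
        cyc = resample_cycle(sig, (0.0, 249 / 250.0))
        assert cyc.values[0] == sig.samples[0]
        assert cyc.values[-1] == sig.samples[-1]

    def test_sine_interpolation_error_small(self):
        t = np.linspace(0.0, 1.0, 250)
        sig = SampledSignal(np.sin(2 * np.pi * t), rate_hz=249.0)
        cyc = resample_cycle(sig, (0.0, 1.0))
        exact = np.sin(2 * np.pi * np.arange(101) / 100.0)
        assert np.max(np.abs(cyc.values - exact)) < 1e-3

    def test_cycle_outside_support_rejected(self):
        sig = SampledSignal(np.zeros(100), rate_hz=100.0)
        with pytest.raises(InvalidParameterError):
            resample_cycle(sig, (0.5, 2.0))


class TestSagittalRom:
    def test_constant_curve_zero(self):
        curve = GaitCycleSeries(np.full(101, 12.0), quantity="angle_deg")
        assert sagittal_rom(curve) == 0.0

    def test_range_of_constructed_curve(self):
        values = 5.0 + 64.0 * np.sin(np.pi * np.arange(101) / 100.0)
        curve = GaitCycleSeries(values, quantity="angle_deg")
        assert sagittal_rom(curve) == pytest.approx(64.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.random(101) * 30
        a = sagittal_rom(GaitCycleSeries(values, quantity="angle_deg"))
        b = sagittal_rom(GaitCycleSeries(values + 17.0, quantity="angle_deg"))
        assert a == pytest.approx(b)

    def test_rom_commutes_with_resampling(self):
        t = np.linspace(0.0, 1.0, 400)
        angles = 30 + 32 * np.sin(2 * np.pi * t) ** 2
        sig = SampledSignal(angles, rate_hz=399.0, units="deg")
        cyc = resample_cycle(sig, (0.0, 1.0))
        rom_orig = angles.max() - angles.min()
        assert sagittal_rom(cyc) == pytest.approx(rom_orig, rel=0.005)

    def test_non_angle_rejected(self):
        curve = GaitCycleSeries(np.zeros(101), quantity="jcf_bw")
        with pytest.raises(InvalidParameterError):
            sagittal_rom(curve)


class TestWalkingSpeed:
    def make_track(self, speed, sway=0.0, duration=4.0, n=400):
        t = np.linspace(0.0, duration, n)
        pos = np.column_stack([
            speed * t,
            sway * np.sin(2 * np.pi * 1.0 * t),
            0.02 * np.cos(2 * np.pi * 1.0 * t),
        ])
        return pos, t

    def test_straight_line(self):
        pos, t = self.make_track(1.25)
        assert walking_speed(pos, t) == pytest.approx(1.25)

    def test_lateral_sway_ignored(self):
        pos, t = self.make_track(1.25, sway=0.05)
        assert walking_speed(pos, t) == pytest.approx(1.25, rel=0.01)

    def test_stationary_is_zero(self):
        pos = np.zeros((400, 3))
        t = np.linspace(0.0, 4.0, 400)
        assert walking_speed(pos, t) == 0.0

    def test_short_window_rejected(self):
        pos, t = self.make_track(1.25, duration=0.5)
        with pytest.raises(InvalidParameterError):
            walking_speed(pos, t)


class TestJcfPeaks:
    def test_double_bump_peaks(self):
        p = np.arange(101.0)
        values = (3.1 * np.exp(-0.5 * ((p - 25) / 5) ** 2)
                  + 2.6 * np.exp(-0.5 * ((p - 55) / 5) ** 2))
        curve = GaitCycleSeries(values, quantity="jcf_bw")
        p1, p2, unimodal = jcf_peaks(curve)
        assert p1 == pytest.approx(3.1, rel=1e-3)
        assert p2 == pytest.approx(2.6, rel=1e-3)
        assert not unimodal

    def test_single_bump_flagged(self):
        p = np.arange(101.0)
        curve = GaitCycleSeries(np.exp(-0.5 * ((p - 40) / 8) ** 2), quantity="jcf_bw")
        _, _, unimodal = jcf_peaks(curve)
        assert unimodal

    def test_flat_curve_flagged_and_equal(self):
        curve = GaitCycleSeries(np.full(101, 2.0), quantity="jcf_bw")
        p1, p2, unimodal = jcf_peaks(curve)
        assert p1 == p2 == 2.0
        assert unimodal

    def test_peaks_stable_under_grid_refinement(self):
        # resampling a smooth JCF time-series onto the grid barely moves peaks
        t = np.linspace(0.0, 1.0, 500)
        values = (3.1 * np.exp(-0.5 * ((t * 100 - 25) / 5) ** 2)
                  + 2.6 * np.exp(-0.5 * ((t * 100 - 55) / 5) ** 2))
        sig = SampledSignal(values, rate_hz=499.0, units="BW")
        cyc = resample_cycle(sig, (0.0, 1.0), quantity="jcf_bw")
        p1, p2, _ = jcf_peaks(cyc)
        assert p1 == pytest.approx(3.1, rel=0.005)
        assert p2 == pytest.approx(2.6, rel=0.005)


class TestHeelStrikes:
    def test_rising_threshold_crossings(self):
        rate = 1000.0
        t = np.arange(int(3 * rate)) / rate
        vgrf = 800.0 * (((t > 0.5) & (t < 1.1)) | ((t > 1.6) & (t < 2.2)))
        sig = SampledSignal(vgrf, rate_hz=rate, units="N")
        strikes = detect_heel_strikes(sig)
        assert len(strikes) == 2
        assert strikes[0] == pytest.approx(0.5, abs=2e-3)


class TestSubjectReducers:
    def test_rom_and_peaks_recovered_from_generator(self):
        curves, truth = gen_gait_curves(seed=12)
        rom = subject_rom(curves["knee_angle"])
        assert rom == pytest.approx(64.0, rel=0.02)
        p1, p2 = subject_jcf_peaks(curves["knee_jcf"])
        assert p1 == pytest.approx(3.08, rel=0.02)
        assert p2 == pytest.approx(3.14, rel=0.02)


class TestCompareGroups:
    def make_groups(self, seed, offset=0.0, n_per_group=10):
        rng = np.random.default_rng(seed)
        p = np.arange(101.0)
        template = 60 * np.exp(-0.5 * ((p - 70) / 10) ** 2)
        mask = (p >= 20) & (p < 40)
        a = [template + rng.normal(0, 1.0, 101) for _ in range(n_per_group)]
        b = [template + offset * mask + rng.normal(0, 1.0, 101)
             for _ in range(n_per_group)]
        return a, b

    def test_identical_groups_no_clusters(self):
        a, b = self.make_groups(seed=3)
        res = compare_groups_pointwise(a, b, seed=3)
        assert res.clusters == ()

    def test_large_offset_detected_on_its_interval(self):
        a, b = self.make_groups(seed=4, offset=10.0)  # 10 x pooled SD
        res = compare_groups_pointwise(a, b, seed=4)
        assert res.any_significant
        covered = set()
        for start, stop in res.clusters:
            covered.update(range(start, stop))
        assert covered.issuperset(range(22, 38))
        assert covered.issubset(range(18, 42))

    def test_null_distribution_label_invariance(self):
        # swapping the groups flips the t sign but not the clusters
        a, b = self.make_groups(seed=5, offset=10.0)
        res_ab = compare_groups_pointwise(a, b, seed=7)
        res_ba = compare_groups_pointwise(b, a, seed=7)
        assert np.allclose(res_ab.t_values, -res_ba.t_values)
        assert res_ab.clusters == res_ba.clusters

    def test_degenerate_variance_point_is_zero(self):
        a = [np.zeros(101) for _ in range(5)]
        b = [np.zeros(101) for _ in range(5)]
        res = compare_groups_pointwise(a, b, seed=0, n_permutations=50)
        assert np.allclose(res.t_values, 0.0)

    def test_too_few_curves_rejected(self):
        with pytest.raises(InvalidParameterError):
            compare_groups_pointwise([np.zeros(101)], [np.zeros(101)] * 3)
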