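"""EMG linear envelopes and the co-contraction index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biomechkit import (
    SampledSignal,
    cci_by_phase,
    compute_cci,
    compute_envelope,
    normalize_envelope,
)
from biomechkit.errors import CannotNormalizeError, InvalidParameterError
from biomechkit.synthetic import gen_emg

from .conftest import interior


def cci_of(a, b, rate=100.0):
    sa = SampledSignal(np.asarray(a, float), rate_hz=rate)
    sb = SampledSignal(np.asarray(b, float), rate_hz=rate)
    return compute_cci(sa, sb).samples


class TestComputeEnvelope:
    def test_zero_in_zero_out(self, rate):
        sig = SampledSignal(np.zeros(8000), rate_hz=rate, units="mV")
        assert np.allclose(compute_envelope(sig).samples, 0.0, atol=1e-9)

    def test_carrier_sine_envelope_near_rectified_mean(self, sine_factory):
        # a 110 Hz carrier (inside the band, off the mains harmonics)
        # rectifies to mean 2/pi, which the 2 Hz low-pass preserves
        env = compute_envelope(sine_factory(110.0, units="mV"))
        assert np.mean(interior(env)) == pytest.approx(2 / np.pi, rel=0.05)

    def test_rate_too_low_rejected(self):
        sig = SampledSignal(np.zeros(1000), rate_hz=500.0, units="mV")
        with pytest.raises(InvalidParameterError):
            compute_envelope(sig)

    def test_envelope_tracks_activation_peak(self, rate):
        # triangular activation peaking at 5 s: the envelope peak is an
        # unbiased but jittery estimate of the profile peak (the 2 Hz
        # smoother of a stochastic carrier has ~0.1-0.2 s location noise),
        # so individual trials stay within 0.4 s and the ensemble mean
        # lands within 0.1 s
        n = int(10 * rate)
        t = np.arange(n) / rate
        profile = np.clip(1.0 - np.abs(t - 5.0) / 3.0, 0.0, 1.0)
        locations = []
        for seed in range(10):
            sigs, _ = gen_emg({"VL": profile}, rate_hz=rate, seed=seed)
            env = compute_envelope(sigs["VL"])
            peak_s = np.argmax(interior(env)) / rate + 1.0
            assert abs(peak_s - 5.0) <= 0.4
            locations.append(peak_s)
        assert abs(np.mean(locations) - 5.0) <= 0.1

    def test_envelope_is_nonnegative(self, rate):
        sigs, _ = gen_emg({"VL": np.full(8000, 0.3)}, rate_hz=rate, seed=0)
        assert np.min(compute_envelope(sigs["VL"]).samples) >= 0.0


class TestNormalizeEnvelope:
    def test_max_becomes_one(self, rate):
        env = SampledSignal(np.linspace(0, 0.8, 1000), rate_hz=rate)
        out = normalize_envelope(env)
        assert np.max(out.samples) == 1.0

    def test_unit_max_unchanged(self, rate):
        env = SampledSignal(np.linspace(0, 1.0, 1000), rate_hz=rate)
        assert np.allclose(normalize_envelope(env).samples, env.samples)

    def test_trials_normalized_independently(self, rate):
        for peak in (0.4, 1.7):
            env = SampledSignal(peak * np.linspace(0, 1, 1000), rate_hz=rate)
            assert np.max(normalize_envelope(env).samples) == pytest.approx(1.0)

    def test_all_zero_rejected(self, rate):
        with pytest.raises(CannotNormalizeError):
            normalize_envelope(SampledSignal(np.zeros(100), rate_hz=rate))


class TestComputeCci:
    def test_full_activation_reaches_two(self):
        assert np.allclose(cci_of(np.ones(50), np.ones(50)), 2.0)

    def test_silent_channel_gives_zero(self):
        assert np.allclose(cci_of(np.zeros(50), np.full(50, 0.7)), 0.0)

    def test_hand_worked_value(self):
        assert cci_of([0.25], [0.5])[0] == pytest.approx(0.375)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(200), rng.random(200)
        assert np.array_equal(cci_of(a, b), cci_of(b, a))

    def test_equal_envelopes_closed_form(self):
        # CCI(a, a) = (a/a)*(a+a) = 2a on the Rudolph form
        a = np.linspace(0.0, 1.0, 101)
        expected = np.where(a > 0, 2 * a, 0.0)
        assert np.allclose(cci_of(a, a), expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_bounds_zero_to_two(self, a, b):
        value = cci_of([a], [b])[0]
        assert 0.0 <= value <= 2.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            cci_of(np.ones(10), np.ones(11))

    def test_values_well_above_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            cci_of([1.5], [0.5])

    def test_baseline_noise_gives_negligible_cci(self, rate):
        # 30 s resting recording: tiny activation -> summary CCI below 0.05
        n = int(30 * rate)
        rest = np.full(n, 0.01)
        sigs, _ = gen_emg({"VL": rest, "BFL": rest}, rate_hz=rate, mains_amp=0.005, seed=9)
        env_a = compute_envelope(sigs["VL"])
        env_b = compute_envelope(sigs["BFL"])
        cci = compute_cci(env_a.with_samples(np.clip(interior(env_a), 0, 1)),
                          env_b.with_samples(np.clip(interior(env_b), 0, 1)))
        assert float(np.mean(cci.samples)) < 0.05

    def test_pipeline_cci_of_matched_constant_profiles(self, rate):
        # both muscles at a constant activation level: CCI ~ 2 * level
        n = int(10 * rate)
        profile = np.full(n, 0.5)
        sigs, _ = gen_emg({"VL": profile, "BFL": profile}, rate_hz=rate, seed=0)
        env_a = compute_envelope(sigs["VL"])
        env_b = compute_envelope(sigs["BFL"])
        a = np.clip(interior(env_a), 0, 1)
        b = np.clip(interior(env_b), 0, 1)
        cci = compute_cci(env_a.with_samples(a), env_b.with_samples(b))
        level = (np.mean(a) + np.mean(b)) / 2
        assert np.mean(cci.samples) == pytest.approx(2 * level, rel=0.10)

    def test_mains_contamination_removed_before_cci(self, rate):
        n = int(10 * rate)
        profile = np.full(n, 0.5)
        means = []
        for amp in (0.0, 5.0):  # clean vs 10x-carrier mains
            sigs, _ = gen_emg({"VL": profile, "BFL": profile}, rate_hz=rate,
                              mains_amp=amp, seed=0)
            env_a = compute_envelope(sigs["VL"])
            env_b = compute_envelope(sigs["BFL"])
            cci = compute_cci(env_a.with_samples(np.clip(interior(env_a), 0, 1)),
                              env_b.with_samples(np.clip(interior(env_b), 0, 1)))
            means.append(float(np.mean(cci.samples)))
        assert means[1] == pytest.approx(means[0], rel=0.10)


class TestCciByPhase:
    def test_constant_series_same_in_every_phase(self):
        phases = cci_by_phase(np.full(101, 0.5))
        assert all(v == pytest.approx(0.5) for v in phases.values())

    def test_indicator_on_initial_double_support(self):
        series = np.zeros(101)
        series[0:10] = 1.0  # percent [0, 10)
        phases = cci_by_phase(series)
        assert phases["initial_double_support"] == pytest.approx(1.0)
        assert phases["single_support"] == 0.0
        assert phases["pre_swing"] == 0.0
        assert phases["swing"] == 0.0

    def test_phase_sample_counts_on_grid(self):
        # half-open intervals on the 101-grid: 10 / 40 / 10 / 41 samples
        grid = np.arange(101.0)
        counts = {
            "initial_double_support": np.sum((grid >= 0) & (grid < 10)),
            "single_support": np.sum((grid >= 10) & (grid < 50)),
            "pre_swing": np.sum((grid >= 50) & (grid < 60)),
            "swing": np.sum((grid >= 60) & (grid <= 100)),
        }
        assert list(counts.values()) == [10, 40, 10, 41]
        series = np.arange(101.0)
        phases = cci_by_phase(series)
        assert phases["swing"] == pytest.approx(np.mean(series[60:101]))

    def test_wrong_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            cci_by_phase(np.zeros(100))
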