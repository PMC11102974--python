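import numpy as np
import pytest

from biomechkit import SampledSignal


@pytest.fixture
def rate() -> float:
    return 2000.0


@pytest.fixture
def sine_factory(rate):
    """Factory for unit sinusoids at the EMG sampling rate."""

    def make(freq_hz: float, duration_s: float = 10.0, amplitude: float = 1.0,
             units: str = "") -> SampledSignal:
        t = np.arange(int(duration_s * rate)) / rate
        return SampledSignal(amplitude * np.sin(2 * np.pi * freq_hz * t),
                             rate_hz=rate, units=units, label=f"sine{freq_hz}")

    return make


def interior(sig_or_array, rate_hz: float = 2000.0, trim_s: float = 1.0):
    """Samples with the filter edge transients trimmed off."""
    samples = getattr(sig_or_array, "samples", sig_or_array)
    k = int(trim_s * rate_hz)
    return samples[k:-k]
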