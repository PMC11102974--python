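"""Uniformly sampled signals and zero-phase filtering primitives.

Every processing stage in the toolkit (torque conditioning, EMG envelopes,
stimulation analysis) shares the :class:`SampledSignal` container and the
zero-phase IIR filters defined here.  Zero-phase operation is obtained by
forward-backward application (``sosfiltfilt``/``filtfilt``) with reflective
edge padding, which removes the group delay of the underlying causal filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError, SignalTooShortError

__all__ = ["SampledSignal", "FilterSpec", "apply_filter", "remove_mains", "rectify"]

log = logging.getLogger(__name__)

FilterKind = Literal[
    "butterworth_lowpass",
    "butterworth_highpass",
    "chebyshev_lowpass",
    "chebyshev_highpass",
    "comb_notch",
]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled 1-D time series.

    Parameters
    ----------
    samples
        Real-valued samples; stored as a float64 array.
    rate_hz
        Sampling frequency in Hz; must be positive.
    units
        Free-text physical units carried as metadata ("V", "Nm", "mV",
        "deg", "BW", ...).
    label
        Channel name (e.g. "torque", "VL", "stim_trigger").
    t0_s
        Time of the first sample, in seconds.
    """

    samples: np.ndarray
    rate_hz: float
    units: str = ""
    label: str = ""
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidParameterError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("samples must be finite")
        if not (self.rate_hz > 0):
            raise InvalidParameterError(f"rate_hz must be positive, got {self.rate_hz}")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return (self.n - 1) / self.rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.rate_hz / 2.0

    def time_s(self) -> np.ndarray:
        """Sample times in seconds (``t0_s`` offset included)."""
        return self.t0_s + np.arange(self.n) / self.rate_hz

    def with_samples(self, samples: np.ndarray, units: str | None = None) -> "SampledSignal":
        """Copy of this signal with new sample values (metadata preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       units=self.units if units is None else units)

    def index_at(self, t_s: float) -> int:
        """Nearest sample index for an absolute time, clipped to range."""
        idx = int(round((t_s - self.t0_s) * self.rate_hz))
        return min(max(idx, 0), self.n - 1)


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one IIR filter stage.

    ``ripple_db`` only applies to Chebyshev (type I) designs; 0.1 dB is the
    default passband ripple.  ``zero_phase`` selects forward-backward
    application, doubling the effective order and cancelling group delay.
    """

    kind: FilterKind
    order: int
    cutoff_hz: float | tuple[float, float]
    ripple_db: float = 0.1
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidParameterError("filter order must be >= 1")
        cutoffs = np.atleast_1d(np.asarray(self.cutoff_hz, dtype=float))
        if np.any(cutoffs <= 0):
            raise InvalidParameterError("cutoff frequencies must be positive")


def _design_sos(spec: FilterSpec, rate_hz: float) -> np.ndarray:
    nyq = rate_hz / 2.0
    cutoffs = np.atleast_1d(np.asarray(spec.cutoff_hz, dtype=float))
    if np.any(cutoffs >= nyq):
        raise InvalidParameterError(
            f"cutoff {spec.cutoff_hz} Hz not strictly below Nyquist ({nyq} Hz)"
        )
    wn = cutoffs / nyq
    wn = wn if wn.size > 1 else float(wn[0])
    if spec.kind == "butterworth_lowpass":
        return sps.butter(spec.order, wn, btype="lowpass", output="sos")
    if spec.kind == "butterworth_highpass":
        return sps.butter(spec.order, wn, btype="highpass", output="sos")
    if spec.kind == "chebyshev_lowpass":
        return sps.cheby1(spec.order, spec.ripple_db, wn, btype="lowpass", output="sos")
    if spec.kind == "chebyshev_highpass":
        return sps.cheby1(spec.order, spec.ripple_db, wn, btype="highpass", output="sos")
    raise InvalidParameterError(f"unsupported filter kind {spec.kind!r}")


def _padlen(spec: FilterSpec) -> int:
    # reflective edge padding of 3x the filter order (per second-order section
    # chain this is a conservative, reproducible choice)
    return 3 * (2 * spec.order + 1)


def apply_filter(sig: SampledSignal, spec: FilterSpec) -> SampledSignal:
    """Apply one IIR filter stage to a signal.

    Zero-phase specs are applied forward-backward (``sosfiltfilt``) so the
    output has no group delay; causal specs use a single forward pass.
    Length, rate and units are preserved.

    Raises
    ------
    InvalidParameterError
        If any cutoff is at or above the Nyquist frequency.
    SignalTooShortError
        If the signal is shorter than the edge-padding requirement.
    """
    sos = _design_sos(spec, sig.rate_hz)
    if spec.zero_phase:
        padlen = _padlen(spec)
        if sig.n <= padlen:
            raise SignalTooShortError(
                f"signal of {sig.n} samples is too short for zero-phase "
                f"filtering (needs > {padlen} samples)"
            )
        out = sps.sosfiltfilt(sos, sig.samples, padtype="even", padlen=padlen)
    else:
        out = sps.sosfilt(sos, sig.samples)
    return sig.with_samples(out)


def remove_mains(
    sig: SampledSignal,
    mains_hz: float = 50.0,
    n_harmonics: int = 5,
    bandwidth_hz: float = 2.0,
) -> SampledSignal:
    """Suppress power-line interference at the mains frequency and harmonics.

    A cascade of second-order IIR notches is placed at ``mains_hz``,
    ``2*mains_hz``, ... up to ``n_harmonics`` components, each applied
    zero-phase (forward-backward).  Harmonics at or above Nyquist are
    skipped with a log note rather than raising.

    Parameters
    ----------
    mains_hz
        Power-line fundamental (50 Hz in Europe).
    n_harmonics
        Number of spectral lines to notch, counting the fundamental.
    bandwidth_hz
        -3 dB width of each notch.
    """
    if mains_hz <= 0 or n_harmonics < 1:
        raise InvalidParameterError("mains_hz must be > 0 and n_harmonics >= 1")
    out = sig.samples.copy()
    nyq = sig.nyquist_hz
    for k in range(1, n_harmonics + 1):
        f0 = k * mains_hz
        if f0 >= nyq:
            log.info("skipping mains harmonic %.1f Hz at/above Nyquist %.1f Hz", f0, nyq)
            continue
        q = f0 / bandwidth_hz
        b, a = sps.iirnotch(f0, q, fs=sig.rate_hz)
        out = sps.filtfilt(b, a, out, padtype="even")
    return sig.with_samples(out)


def rectify(sig: SampledSignal) -> SampledSignal:
    """Full-wave rectification: elementwise absolute value, units unchanged."""
    return sig.with_samples(np.abs(sig.samples))
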