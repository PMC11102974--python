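"""Surface-EMG linear envelopes and the Rudolph co-contraction index.

The envelope chain is the conventional one for surface EMG sampled at
2000 Hz: band-limiting to 20-300 Hz (zero-phase Chebyshev type I
high-pass then low-pass), removal of the 50 Hz mains line and its
harmonics with a cascade of IIR notches, full-wave rectification, and a
2 Hz zero-phase 4th-order Butterworth low-pass.  Envelopes are normalized
to the task maximum, so the co-contraction index (CCI) of an antagonist
pair

    CCI(t) = (input_L / input_H) * (input_L + input_H)

(L = less active, H = more active muscle) ranges from 0 to 2, reaching 2
only when both muscles are fully active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core_signal import FilterSpec, SampledSignal, apply_filter, rectify, remove_mains
from .errors import CannotNormalizeError, InvalidParameterError

__all__ = [
    "EnvelopeParams",
    "CCIResult",
    "GAIT_PHASES",
    "compute_envelope",
    "normalize_envelope",
    "compute_cci",
    "cci_by_phase",
]

log = logging.getLogger(__name__)

#: Gait-cycle phases as half-open percent intervals (swing includes 100%).
GAIT_PHASES: dict[str, tuple[float, float]] = {
    "initial_double_support": (0.0, 10.0),
    "single_support": (10.0, 50.0),
    "pre_swing": (50.0, 60.0),
    "swing": (60.0, 100.0),
}


@dataclass(frozen=True)
class EnvelopeParams:
    """Filter-chain parameters for the linear envelope."""

    band_hz: tuple[float, float] = (20.0, 300.0)
    hp_order: int = 5
    lp_order: int = 8
    ripple_db: float = 0.1
    mains_hz: float = 50.0
    n_harmonics: int = 5
    envelope_cutoff_hz: float = 2.0
    envelope_order: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise InvalidParameterError("band_hz must satisfy 0 < low < high")


@dataclass(frozen=True)
class CCIResult:
    """Per-sample CCI series plus its scalar summaries."""

    series: SampledSignal
    summary: float
    by_phase: dict[str, float] = field(default_factory=dict)


def compute_envelope(raw: SampledSignal, params: EnvelopeParams = EnvelopeParams()) -> SampledSignal:
    """Linear envelope of a raw EMG channel.

    Chain: high-pass at the band's low corner, low-pass at the high corner
    (both zero-phase Chebyshev I), mains-harmonic notches, rectification,
    2 Hz zero-phase Butterworth low-pass.  The output is clipped at zero
    (the smoothing filter's ripple can undershoot slightly).
    """
    lo, hi = params.band_hz
    if raw.rate_hz < 2 * hi:
        raise InvalidParameterError(
            f"sampling rate {raw.rate_hz} Hz too low for the {hi} Hz band edge"
        )
    sig = apply_filter(raw, FilterSpec("chebyshev_highpass", params.hp_order, lo,
                                       ripple_db=params.ripple_db))
    sig = apply_filter(sig, FilterSpec("chebyshev_lowpass", params.lp_order, hi,
                                       ripple_db=params.ripple_db))
    sig = remove_mains(sig, mains_hz=params.mains_hz, n_harmonics=params.n_harmonics)
    sig = rectify(sig)
    sig = apply_filter(sig, FilterSpec("butterworth_lowpass", params.envelope_order,
                                       params.envelope_cutoff_hz))
    return sig.with_samples(np.maximum(sig.samples, 0.0))


def normalize_envelope(env: SampledSignal) -> SampledSignal:
    """Rescale an envelope so its task maximum is exactly 1."""
    peak = float(np.max(env.samples))
    if peak <= 0:
        raise CannotNormalizeError("envelope has no strictly positive maximum")
    return env.with_samples(env.samples / peak, units="")


def compute_cci(env_a: SampledSignal, env_b: SampledSignal, clip_tol: float = 0.05) -> SampledSignal:
    """Per-sample co-contraction index of two normalized envelopes.

    Inputs must share length and rate and lie in [0, 1]; values marginally
    above 1 (zero-phase filtering ripple, up to ``clip_tol``) are clipped
    with a log note.  Where both envelopes are zero the CCI is defined as
    its limit value 0.
    """
    if env_a.n != env_b.n or not np.isclose(env_a.rate_hz, env_b.rate_hz):
        raise InvalidParameterError("envelopes must share length and sampling rate")
    a, b = env_a.samples, env_b.samples
    over = max(float(a.max(initial=0.0)), float(b.max(initial=0.0))) - 1.0
    if over > clip_tol:
        raise InvalidParameterError(
            f"envelope values exceed 1 by {over:.3g}; normalize to task maximum first"
        )
    if over > 0:
        log.info("clipping %d envelope samples marginally above 1",
                 int(np.sum((a > 1) | (b > 1))))
    if a.min(initial=0.0) < 0 or b.min(initial=0.0) < 0:
        raise InvalidParameterError("envelopes must be non-negative")
    a = np.clip(a, 0.0, 1.0)
    b = np.clip(b, 0.0, 1.0)
    low = np.minimum(a, b)
    high = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        cci = np.where(high > 0, (low / np.where(high > 0, high, 1.0)) * (low + high), 0.0)
    return SampledSignal(cci, rate_hz=env_a.rate_hz, units="", label="CCI", t0_s=env_a.t0_s)


def cci_by_phase(series: np.ndarray | SampledSignal,
                 phases: Mapping[str, tuple[float, float]] = GAIT_PHASES) -> dict[str, float]:
    """Mean CCI over each gait-cycle phase.

    ``series`` must live on the 101-point percent grid (0, 1, ..., 100).
    Phases are half-open percent intervals, except the last which includes
    its upper bound so the 100% sample belongs to swing.
    """
    values = series.samples if isinstance(series, SampledSignal) else np.asarray(series, float)
    if values.size != 101:
        raise InvalidParameterError("phase split requires the 101-point gait-cycle grid")
    grid = np.arange(101.0)
    upper = max(hi for _, hi in phases.values())
    out: dict[str, float] = {}
    for name, (lo, hi) in phases.items():
        mask = (grid >= lo) & ((grid <= hi) if hi == upper else (grid < hi))
        out[name] = float(np.mean(values[mask]))
    return out
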