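"""Isometric dynamometry: torque conversion, contraction segmentation, MVIC.

The dynamometer outputs a voltage proportional to torque.  Processing
follows the standard chain for maximal voluntary isometric contraction
(MVIC) trials: zero-phase 20 Hz low-pass conditioning, conversion to Nm
through the vendor factors, segmentation of the repetitions by a threshold
derived from the quiescent baseline (mean + k*SD of the no-contraction
noise), and peak extraction on a 2 Hz-smoothed trace so that short bursts
do not inflate the maximal torque.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core_signal import FilterSpec, SampledSignal, apply_filter
from .errors import InvalidParameterError, NoContractionError, UnitMismatchError

__all__ = [
    "TorqueConversion",
    "SegmentationParams",
    "ContractionWindow",
    "MVICResult",
    "convert_torque",
    "compute_threshold",
    "segment_contractions",
    "extract_mvic",
    "lowpass_20hz",
    "smooth_2hz",
]

log = logging.getLogger(__name__)

#: Conditioning filter applied to raw torque before thresholding.
TORQUE_LOWPASS = FilterSpec("butterworth_lowpass", order=4, cutoff_hz=20.0)
#: Smoothing filter used for peak extraction only.
PEAK_SMOOTHING = FilterSpec("butterworth_lowpass", order=4, cutoff_hz=2.0)


def lowpass_20hz(sig: SampledSignal) -> SampledSignal:
    """Zero-phase 4th-order Butterworth low-pass at 20 Hz."""
    return apply_filter(sig, TORQUE_LOWPASS)


def smooth_2hz(sig: SampledSignal) -> SampledSignal:
    """Zero-phase 4th-order Butterworth low-pass at 2 Hz (peak smoothing)."""
    return apply_filter(sig, PEAK_SMOOTHING)


@dataclass(frozen=True)
class TorqueConversion:
    """Vendor conversion chain from dynamometer volts to newton-metres.

    The dynamometer reports foot-pounds per volt; torque in Nm is
    ``volts * volts_to_ftlb * ftlb_to_nm``.
    """

    volts_to_ftlb: float = 102.4
    ftlb_to_nm: float = 1.3558

    @property
    def combined(self) -> float:
        """Nm per volt (138.834 at the default factors)."""
        return self.volts_to_ftlb * self.ftlb_to_nm


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of threshold-based contraction segmentation.

    ``noise_window`` is a half-open sample range known to contain no
    contraction; the detection threshold is ``mean + k_sigma * SD`` of the
    (filtered) signal over that range.  Supra-threshold runs closer than
    ``min_gap_s`` are merged; runs shorter than ``min_duration_s`` are
    discarded (contractions are held for several seconds, so sub-second
    crossings are noise).
    """

    noise_window: tuple[int, int]
    k_sigma: float = 3.0
    min_duration_s: float = 1.0
    min_gap_s: float = 0.5

    def __post_init__(self) -> None:
        if self.k_sigma <= 0 or self.min_duration_s <= 0 or self.min_gap_s < 0:
            raise InvalidParameterError("k_sigma, min_duration_s must be > 0; min_gap_s >= 0")
        a, b = self.noise_window
        if b <= a:
            raise InvalidParameterError("noise_window must be a non-empty [start, end) range")


@dataclass(frozen=True)
class ContractionWindow:
    """One detected contraction: half-open sample range plus peak statistics."""

    start_idx: int
    end_idx: int
    peak_nm: float = float("nan")
    peak_time_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.start_idx >= self.end_idx:
            raise InvalidParameterError("window requires start_idx < end_idx")

    def duration_s(self, rate_hz: float) -> float:
        return (self.end_idx - self.start_idx) / rate_hz


@dataclass(frozen=True)
class MVICResult:
    """MVIC torque for one task/knee configuration.

    ``retest_flag`` mirrors the protocol rule that a further trial is
    requested when the third trial exceeds the earlier ones by 5% or more.
    """

    task: Literal["extension", "flexion"]
    knee_angle_deg: float
    per_trial_peaks_nm: tuple[float, ...]
    mvic_nm: float
    retest_flag: bool
    windows: tuple[ContractionWindow, ...] = ()


def convert_torque(sig: SampledSignal, conv: TorqueConversion = TorqueConversion()) -> SampledSignal:
    """Convert a dynamometer voltage trace to torque in Nm.

    Raises :class:`UnitMismatchError` unless the input units are volts.
    """
    if sig.units != "V":
        raise UnitMismatchError(f"expected units 'V', got {sig.units!r}")
    return sig.with_samples(sig.samples * conv.combined, units="Nm")


def compute_threshold(sig: SampledSignal, params: SegmentationParams) -> float:
    """Detection threshold ``mean + k_sigma * SD`` over the noise window.

    A zero-variance noise window is degenerate (threshold collapses to the
    mean) and is logged; a noise window containing samples more than
    10 SD above its mean likely overlaps activity and triggers a warning.
    """
    a, b = params.noise_window
    noise = sig.samples[a:b]
    if noise.size < 100:
        raise InvalidParameterError("noise window must contain at least 100 samples")
    mu = float(np.mean(noise))
    sigma = float(np.std(noise))
    if sigma == 0.0:
        log.warning("noise window has zero variance; threshold degenerates to the mean")
    elif np.any(np.abs(noise - mu) > 10.0 * sigma):
        log.warning("noise window contains samples > 10 sigma from its mean; "
                    "it may overlap contraction activity")
    return mu + params.k_sigma * sigma


def segment_contractions(
    sig: SampledSignal, threshold: float, params: SegmentationParams
) -> list[ContractionWindow]:
    """Split a (20 Hz-filtered) torque trace into contraction windows.

    Supra-threshold runs are merged when separated by less than
    ``min_gap_s`` and dropped when shorter than ``min_duration_s``.  An
    all-noise trace yields an empty list.
    """
    above = sig.samples > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(sig.n)
    runs = list(zip(starts, ends))

    min_gap = int(round(params.min_gap_s * sig.rate_hz))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_len = int(round(params.min_duration_s * sig.rate_hz))
    return [ContractionWindow(s, e) for s, e in merged if e - s >= min_len]


def extract_mvic(
    windows: Sequence[ContractionWindow],
    sig: SampledSignal,
    task: Literal["extension", "flexion"] = "extension",
    knee_angle_deg: float = 75.0,
    baseline_nm: float = 0.0,
    retest_rule: Literal["both", "any"] = "both",
) -> MVICResult:
    """Extract the MVIC torque from detected contraction windows.

    The full trace is smoothed with the zero-phase 2 Hz low-pass so sudden
    bursts do not inflate the maximum, then the per-window peaks are read
    off the smoothed trace (baseline-corrected by ``baseline_nm``, normally
    the noise-window mean).  The MVIC is the overall maximum across
    windows.  ``retest_flag`` is set when a third trial exceeds the earlier
    trials by at least 5% — against both of them by default, against any
    one of them with ``retest_rule='any'``.
    """
    if not windows:
        raise NoContractionError("no contraction windows; cannot extract MVIC")
    work = sig if sig.units != "V" else convert_torque(sig)
    smoothed = smooth_2hz(work).samples - baseline_nm

    peaked: list[ContractionWindow] = []
    for w in windows:
        seg = smoothed[w.start_idx:w.end_idx]
        rel = int(np.argmax(seg))
        peaked.append(
            ContractionWindow(
                w.start_idx, w.end_idx,
                peak_nm=float(seg[rel]),
                peak_time_s=sig.t0_s + (w.start_idx + rel) / sig.rate_hz,
            )
        )

    peaks = tuple(w.peak_nm for w in peaked)
    retest = False
    if len(peaks) >= 3:
        third, earlier = peaks[2], peaks[:2]
        hits = [third >= 1.05 * p for p in earlier]
        retest = all(hits) if retest_rule == "both" else any(hits)
    return MVICResult(
        task=task,
        knee_angle_deg=knee_angle_deg,
        per_trial_peaks_nm=peaks,
        mvic_nm=float(max(peaks)),
        retest_flag=retest,
        windows=tuple(peaked),
    )
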