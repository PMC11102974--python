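"""Central Activation Ratio from superimposed electrical stimulation.

During a maximal voluntary contraction an electrical doublet is delivered
over the muscle; any extra torque it evokes (the superimposed twitch)
reveals motor units the subject could not recruit voluntarily.  The
Central Activation Ratio is

    CAR = plateau / (plateau + twitch)

where ``plateau`` is the voluntary torque just before the stimulus and
``twitch`` the amplitude of the evoked increment.  CAR = 1 means full
voluntary activation.  Only trials in which a stimulus was actually
delivered during the contraction are scored; trials without a detectable
stimulus raise :class:`~biomechkit.errors.StimulusNotFoundError` rather
than being silently assigned CAR = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .core_signal import SampledSignal
from .dynamometry import ContractionWindow
from .errors import InsufficientPlateauError, InvalidParameterError, StimulusNotFoundError

__all__ = ["StimulusEvent", "CARResult", "detect_stimulus", "compute_car", "check_mvc25"]


@dataclass(frozen=True)
class StimulusEvent:
    """Sample index at which the stimulation was delivered."""

    onset_idx: int
    source: Literal["trigger_channel", "detected"]


@dataclass(frozen=True)
class CARResult:
    """Central Activation Ratio for one stimulated trial.

    ``car_fraction`` is the plateau/(plateau+twitch) ratio; ``car_percent``
    is the same quantity times 100.  A negative twitch estimate (noise dip)
    is clamped to zero and flagged via ``twitch_clamped``.
    """

    plateau_nm: float
    twitch_nm: float
    car_fraction: float
    twitch_clamped: bool = False

    @property
    def car_percent(self) -> float:
        return 100.0 * self.car_fraction


def detect_stimulus(
    sig: SampledSignal,
    window: ContractionWindow,
    trigger: Optional[SampledSignal] = None,
    plateau_level: float = 0.75,
    settle_s: float = 0.3,
    spike_k: float = 5.0,
) -> StimulusEvent:
    """Locate the stimulation onset within a contraction window.

    With a trigger channel, the onset is the first rising edge (crossing of
    half the channel's range) inside the window.  Without one, the onset is
    the sample of maximal positive first difference of the (already 20 Hz
    low-pass filtered) torque over the window's plateau region — samples at
    or above ``plateau_level`` of the window maximum, with the first
    ``settle_s`` seconds discarded so the steep entry into the plateau is
    not mistaken for the stimulation artefact.  The spike must
    exceed ``spike_k`` robust standard deviations of the plateau-region
    derivative, otherwise the trial is treated as unstimulated and
    :class:`StimulusNotFoundError` is raised.
    """
    if trigger is not None:
        trig = trigger.samples[window.start_idx:window.end_idx]
        lo, hi = float(trig.min()), float(trig.max())
        if hi - lo <= 0:
            raise StimulusNotFoundError("trigger channel is flat inside the window")
        above = trig > (lo + hi) / 2.0
        edges = np.flatnonzero(~above[:-1] & above[1:])
        if edges.size == 0 and above[0]:
            edges = np.array([0])
        if edges.size == 0:
            raise StimulusNotFoundError("no rising edge on the trigger channel")
        return StimulusEvent(onset_idx=window.start_idx + int(edges[0]) + 1,
                             source="trigger_channel")

    seg = sig.samples[window.start_idx:window.end_idx]
    plateau_mask = seg >= plateau_level * float(seg.max())
    idx = np.flatnonzero(plateau_mask)
    if idx.size < 10:
        raise StimulusNotFoundError("plateau region too short for derivative search")
    lo, hi = int(idx[0]) + int(round(settle_s * sig.rate_hz)), int(idx[-1])
    if hi - lo < 10:
        raise StimulusNotFoundError("plateau region too short after settle trim")
    diff = np.diff(seg[lo:hi + 1])
    # robust SD via the median absolute deviation, so the twitch spike
    # itself does not inflate the noise estimate
    mad = float(np.median(np.abs(diff - np.median(diff))))
    robust_sd = 1.4826 * mad
    peak_rel = int(np.argmax(diff))
    if robust_sd <= 0 or diff[peak_rel] <= spike_k * robust_sd:
        raise StimulusNotFoundError("no derivative spike above the plateau noise floor; "
                                    "trial appears unstimulated")
    return StimulusEvent(onset_idx=window.start_idx + lo + peak_rel, source="detected")


def compute_car(
    sig: SampledSignal,
    event: StimulusEvent,
    plateau_window_s: float = 0.1,
    twitch_horizon_s: float = 0.3,
    window: Optional[ContractionWindow] = None,
) -> CARResult:
    """Compute the Central Activation Ratio around a stimulation event.

    The signal is expected to be 20 Hz low-pass filtered and
    offset-removed.  The voluntary plateau is the mean torque over the
    ``plateau_window_s`` (default 100 ms) ending at the onset; the twitch
    is the maximum over the ``twitch_horizon_s`` (default 300 ms) after the
    onset minus the plateau, clamped at zero if the post-stimulus trace
    never exceeds the plateau.
    """
    if plateau_window_s <= 0 or twitch_horizon_s <= 0:
        raise InvalidParameterError("plateau and twitch windows must be positive")
    n_pre = int(round(plateau_window_s * sig.rate_hz))
    start_limit = window.start_idx if window is not None else 0
    if event.onset_idx - n_pre < start_limit:
        raise InsufficientPlateauError(
            "pre-stimulus plateau window extends before the contraction start"
        )
    plateau = float(np.mean(sig.samples[event.onset_idx - n_pre:event.onset_idx]))
    if plateau <= 0:
        raise InvalidParameterError("non-positive plateau torque; check offset removal")
    n_post = int(round(twitch_horizon_s * sig.rate_hz))
    stop = min(event.onset_idx + n_post, sig.n)
    post_max = float(np.max(sig.samples[event.onset_idx:stop]))
    twitch = post_max - plateau
    clamped = twitch < 0
    twitch = max(twitch, 0.0)
    return CARResult(
        plateau_nm=plateau,
        twitch_nm=twitch,
        car_fraction=plateau / (plateau + twitch),
        twitch_clamped=clamped,
    )


def check_mvc25(twitch_rest_nm: float, peak_mvic_nm: float) -> bool:
    """Whether a resting stimulated torque reaches 25% of the peak MVIC.

    Used during intensity titration: the stimulation current is increased
    until the evoked torque at rest is at least one quarter of the
    recorded voluntary peak.
    """
    if twitch_rest_nm <= 0 or peak_mvic_nm <= 0:
        raise InvalidParameterError("torques must be positive")
    return twitch_rest_nm >= 0.25 * peak_mvic_nm
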