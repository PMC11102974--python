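"""Seedable synthetic recordings with known ground truth.

No public dataset accompanies the assessment protocol, so every input
modality — dynamometer torque, superimposed-stimulation trials,
multi-channel surface EMG, gait-cycle curves and segmented muscle
surfaces — is emulated here with the parameters under which each
processing stage is expected to operate: trapezoidal contraction
plateaus with additive Gaussian noise, an alpha-function twitch
transient riding on the plateau, band-limited (20-300 Hz) amplitude-
modulated Gaussian EMG carriers with 50 Hz mains contamination, smooth
templated gait curves with prescribed ROM and contact-force peaks, and
analytic solids exported as triangulated surfaces.

Every generator is a pure function of its parameters and seed: the same
call yields bit-identical output.  Each returns its ground truth as a
plain JSON-serializable dict so recovery can be asserted end to end.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import trimesh
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .core_signal import SampledSignal
from .errors import InvalidParameterError
from .gait import PERCENT_GRID, GaitCycleSeries
from .morphometry import MuscleMesh

__all__ = [
    "gen_mvic_trace",
    "gen_snmes_trace",
    "gen_emg",
    "gen_gait_curves",
    "gen_mesh",
]

NM_PER_VOLT = 138.834  # vendor chain: 102.4 ft-lb/V * 1.3558 Nm/ft-lb


def _trapezoid(t: np.ndarray, start: float, rise: float, hold: float,
               amplitude: float) -> np.ndarray:
    """Trapezoidal pulse: linear rise, flat hold, linear fall."""
    up = np.clip((t - start) / rise, 0.0, 1.0)
    down = np.clip((t - (start + rise + hold)) / rise, 0.0, 1.0)
    return amplitude * (up - down)


def gen_mvic_trace(
    n_trials: int = 3,
    plateau_nm: float | tuple[float, ...] = 210.0,
    rise_s: float = 1.0,
    hold_s: float = 3.0,
    gap_s: float = 2.0,
    pre_s: float = 2.0,
    noise_sd: float = 1.0,
    rate_hz: float = 2000.0,
    seed: int = 0,
    units: str = "Nm",
) -> tuple[SampledSignal, dict]:
    """Synthetic MVIC dynamometry trace: trapezoidal repetitions + noise.

    Contractions are held for ``hold_s`` (>= 3 s in the protocol) and
    separated by ``gap_s`` rests; the leading ``pre_s`` seconds are pure
    baseline noise and serve as the segmentation noise window.  With
    ``units='V'`` the trace is divided by the vendor conversion constant
    so the torque-conversion stage can be exercised.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if n_trials < 1 or hold_s <= 0 or rise_s <= 0:
        raise InvalidParameterError("n_trials >= 1 and positive rise/hold required")
    plateaus = (tuple(plateau_nm) if isinstance(plateau_nm, (tuple, list))
                else (float(plateau_nm),) * n_trials)
    if len(plateaus) != n_trials:
        raise InvalidParameterError("one plateau per trial required")

    trial_len = 2 * rise_s + hold_s
    total_s = pre_s + n_trials * trial_len + n_trials * gap_s
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz

    clean = np.zeros(n)
    trial_windows = []
    for i, amp in enumerate(plateaus):
        start = pre_s + i * (trial_len + gap_s)
        clean += _trapezoid(t, start, rise_s, hold_s, amp)
        trial_windows.append((start, start + trial_len))

    rng = np.random.default_rng(seed)
    trace = clean + rng.normal(0.0, noise_sd, size=n)
    if units == "V":
        trace = trace / NM_PER_VOLT
    elif units != "Nm":
        raise InvalidParameterError("units must be 'Nm' or 'V'")

    truth = {
        "seed": seed,
        "plateaus_nm": list(plateaus),
        "trial_windows_s": trial_windows,
        "noise_window_s": (0.0, pre_s),
        "noise_sd": noise_sd,
        "rate_hz": rate_hz,
    }
    return SampledSignal(trace, rate_hz=rate_hz, units=units, label="torque"), truth


def gen_snmes_trace(
    plateau_nm: float = 96.0,
    twitch_nm: float = 4.0,
    onset_s: float | None = None,
    rise_s: float = 0.5,
    hold_s: float = 3.0,
    pre_s: float = 1.0,
    post_s: float = 1.0,
    twitch_tau_s: float = 0.05,
    noise_sd: float = 1.0,
    rate_hz: float = 2000.0,
    seed: int = 0,
) -> tuple[SampledSignal, SampledSignal, dict]:
    """Superimposed-stimulation trial: plateau + alpha-function twitch.

    The stimulation is delivered once the plateau has been held (default
    onset: 1.5 s into the hold).  The evoked increment is modelled as an
    alpha function ``A * (t/tau) * exp(1 - t/tau)``, which peaks at
    ``tau`` with amplitude exactly ``A`` — only the amplitude matters for
    the activation ratio.  A trigger channel carries a 10 ms TTL pulse at
    the onset.
    """
    if twitch_nm < 0:
        raise InvalidParameterError("twitch_nm must be non-negative")
    if onset_s is None:
        onset_s = pre_s + rise_s + 1.5
    if not (pre_s + rise_s < onset_s < pre_s + rise_s + hold_s):
        raise InvalidParameterError("stimulation onset must lie inside the plateau")

    total_s = pre_s + 2 * rise_s + hold_s + post_s
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz
    clean = _trapezoid(t, pre_s, rise_s, hold_s, plateau_nm)
    dt = t - onset_s
    alpha = np.where(dt > 0, (dt / twitch_tau_s) * np.exp(1.0 - dt / twitch_tau_s), 0.0)
    clean = clean + twitch_nm * alpha

    rng = np.random.default_rng(seed)
    trace = clean + rng.normal(0.0, noise_sd, size=n)
    trigger = np.where((t >= onset_s) & (t < onset_s + 0.010), 5.0, 0.0)

    truth = {
        "seed": seed,
        "plateau_nm": plateau_nm,
        "twitch_nm": twitch_nm,
        "car_fraction": plateau_nm / (plateau_nm + twitch_nm) if plateau_nm else None,
        "onset_s": onset_s,
        "contraction_window_s": (pre_s, pre_s + 2 * rise_s + hold_s),
        "rate_hz": rate_hz,
    }
    return (
        SampledSignal(trace, rate_hz=rate_hz, units="Nm", label="torque"),
        SampledSignal(trigger, rate_hz=rate_hz, units="V", label="stim_trigger"),
        truth,
    )


def gen_emg(
    profiles: Mapping[str, np.ndarray],
    rate_hz: float = 2000.0,
    band_hz: tuple[float, float] = (20.0, 300.0),
    mains_amp: float = 0.1,
    mains_hz: float = 50.0,
    seed: int = 0,
) -> tuple[dict[str, SampledSignal], dict]:
    """Activation-modulated band-limited EMG with mains contamination.

    Each channel is zero-mean Gaussian noise band-passed to ``band_hz``,
    amplitude-modulated by its activation profile (values in [0, 1]) and
    scaled so the linear envelope of the generated signal approximates the
    profile itself (the rectified mean of unit-variance Gaussian noise is
    sqrt(2/pi), so the carrier is scaled by sqrt(pi/2)).  A ``mains_hz``
    sinusoid of amplitude ``mains_amp`` (mV) is added to every channel.
    """
    rng = np.random.default_rng(seed)
    sos = sps.butter(4, np.array(band_hz) / (rate_hz / 2.0), btype="bandpass", output="sos")
    out: dict[str, SampledSignal] = {}
    n_ref = None
    for name, profile in profiles.items():
        profile = np.asarray(profile, dtype=float)
        if profile.min() < 0 or profile.max() > 1:
            raise InvalidParameterError(f"profile {name!r} must lie in [0, 1]")
        if n_ref is None:
            n_ref = profile.size
        elif profile.size != n_ref:
            raise InvalidParameterError("all profiles must share one length")
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(profile.size))
        carrier = carrier / np.std(carrier)
        t = np.arange(profile.size) / rate_hz
        emg = (math.sqrt(math.pi / 2.0) * profile * carrier
               + mains_amp * np.sin(2 * np.pi * mains_hz * t))
        out[name] = SampledSignal(emg, rate_hz=rate_hz, units="mV", label=name)
    truth = {
        "seed": seed,
        "channels": list(profiles.keys()),
        "rate_hz": rate_hz,
        "mains_amp": mains_amp,
        "mains_hz": mains_hz,
        "true_envelopes": {k: np.asarray(v, float).tolist() for k, v in profiles.items()},
    }
    return out, truth


def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  smooth_sigma: float = 3.0) -> np.ndarray:
    """Band-limited perturbation on the cycle grid with the requested SD."""
    if sd == 0:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.standard_normal(n), smooth_sigma, mode="nearest")
    return sd * raw / np.std(raw)


def gen_gait_curves(
    rom_deg: Mapping[str, float] | None = None,
    jcf_peaks_bw: tuple[float, float] = (3.08, 3.14),
    jcf_peak_pct: tuple[float, float] = (25.0, 55.0),
    n_trials: int = 10,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> tuple[dict[str, list[GaitCycleSeries]], dict]:
    """Templated gait-cycle curves with prescribed ROM and JCF peaks.

    Joint-angle templates are smooth two-bump shapes rescaled so the
    noiseless range of motion equals the requested value exactly; knee
    contact force is the sum of two narrow Gaussian bumps whose heights
    equal the requested characteristic peaks.  Each of ``n_trials`` trials
    adds an independent smooth perturbation whose SD is ``noise_frac``
    times the curve's scale (ROM for angles, peak value for forces),
    emulating between-trial variability.
    """
    rom_deg = dict(rom_deg or {"knee": 64.0, "hip": 40.0, "ankle": 31.0})
    p = PERCENT_GRID
    rng = np.random.default_rng(seed)

    def bump(center: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((p - center) / width) ** 2)

    shapes = {
        "knee": 0.25 * bump(15.0, 6.0) + 1.0 * bump(72.0, 9.0),
        "hip": 1.0 * bump(88.0, 18.0) + 0.3 * bump(5.0, 8.0),
        "ankle": 0.5 * bump(45.0, 8.0) + 1.0 * bump(62.0, 6.0),
    }

    curves: dict[str, list[GaitCycleSeries]] = {}
    for joint, rom in rom_deg.items():
        base = shapes.get(joint, bump(50.0, 12.0))
        base = (base - base.min()) / (base.max() - base.min())  # exact unit range
        template = rom * base
        trials = []
        for k in range(n_trials):
            noisy = template + _smooth_noise(rng, p.size, noise_frac * rom)
            trials.append(GaitCycleSeries(noisy, quantity="angle_deg", joint=joint,  # type: ignore[arg-type]
                                          trial_id=f"trial{k:02d}"))
        curves[f"{joint}_angle"] = trials

    p1, p2 = jcf_peaks_bw
    if p1 <= 0 or p2 <= 0:
        raise InvalidParameterError("JCF peaks must be positive")
    c1, c2 = jcf_peak_pct
    jcf_template = p1 * bump(c1, 6.0) + p2 * bump(c2, 6.0)
    scale = max(p1, p2)
    trials = []
    for k in range(n_trials):
        noisy = np.maximum(jcf_template + _smooth_noise(rng, p.size, noise_frac * scale), 0.0)
        trials.append(GaitCycleSeries(noisy, quantity="jcf_bw", joint="knee",
                                      trial_id=f"trial{k:02d}"))
    curves["knee_jcf"] = trials

    truth = {
        "seed": seed,
        "rom_deg": rom_deg,
        "jcf_peaks_bw": list(jcf_peaks_bw),
        "jcf_peak_pct": list(jcf_peak_pct),
        "n_trials": n_trials,
        "noise_frac": noise_frac,
    }
    return curves, truth


def gen_mesh(
    shape: str = "sphere",
    dims: Mapping[str, float] | None = None,
    subdivisions: int = 4,
) -> tuple[MuscleMesh, dict]:
    """Analytic solid exported as a watertight triangulated surface (mm).

    Shapes and their ground truth (volume in cm^3, maximal CSA in mm^2
    along the z axis):

    * ``sphere`` (radius): V = 4/3 pi r^3, CSA = pi r^2;
    * ``ellipsoid`` (a, b, c semi-axes): V = 4/3 pi abc, CSA = pi ab;
    * ``cylinder`` (radius, length, z-aligned): V = pi r^2 L, CSA = pi r^2;
    * ``fused_bumps`` (r_max, length): muscle-belly-like solid of
      revolution with a double-bump radius profile; volume by quadrature
      of pi r(z)^2, CSA = pi max(r)^2.
    """
    dims = dict(dims or {})
    if shape == "sphere":
        r = float(dims.get("radius", 10.0))
        tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=r)
        vol_mm3 = 4.0 / 3.0 * math.pi * r**3
        csa = math.pi * r**2
    elif shape == "ellipsoid":
        a = float(dims.get("a", 15.0))
        b = float(dims.get("b", 10.0))
        c = float(dims.get("c", 30.0))
        tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        tm.apply_scale([a, b, c])
        vol_mm3 = 4.0 / 3.0 * math.pi * a * b * c
        csa = math.pi * a * b
    elif shape == "cylinder":
        r = float(dims.get("radius", 10.0))
        length = float(dims.get("length", 100.0))
        sections = 64 * max(subdivisions, 1)
        tm = trimesh.creation.cylinder(radius=r, height=length, sections=sections)
        vol_mm3 = math.pi * r**2 * length
        csa = math.pi * r**2
    elif shape == "fused_bumps":
        r_max = float(dims.get("r_max", 20.0))
        length = float(dims.get("length", 120.0))
        z = np.linspace(0.0, length, 400)
        # two fused bellies: positive in the interior, zero at the ends
        profile = np.sin(np.pi * z / length) * (1.0 - 0.35 * np.cos(2 * np.pi * z / length))
        profile = r_max * profile / profile.max()
        linestring = np.column_stack([profile, z])
        linestring[0, 0] = 0.0
        linestring[-1, 0] = 0.0
        tm = trimesh.creation.revolve(linestring, sections=128 * max(subdivisions // 2, 1))
        vol_mm3 = float(np.trapezoid(math.pi * profile**2, z))
        csa = math.pi * r_max**2
    else:
        raise InvalidParameterError(f"unknown shape {shape!r}")

    mesh = MuscleMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces),
                      label=shape)
    truth = {
        "shape": shape,
        "dims": dims,
        "subdivisions": subdivisions,
        "volume_cm3": vol_mm3 / 1000.0,
        "csa_max_mm2": csa,
        "csa_axis": [0.0, 0.0, 1.0],
    }
    return mesh, truth
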