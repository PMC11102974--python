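# Methods

This note documents the models, numerical choices and limitations behind
each processing stage, and what the synthetic-data generators do and do
not emulate.

## Signal model and filtering

All time series are uniformly sampled (`SampledSignal`), with the EMG
system's 2000 Hz used as the default rate for torque and EMG channels.
Every filter is an IIR design from `scipy.signal`, applied zero-phase by
forward–backward filtering with reflective ("even") edge padding of
three times the effective filter order. Zero-phase operation squares the
magnitude response — a 4th-order Butterworth applied forward–backward
attenuates like an 8th-order filter with no group delay — which is what
the "zero-lag" conditioning of torque and EMG requires. Signals shorter
than the padding requirement raise an explicit error rather than being
silently truncated.

Chebyshev stages (EMG band-limiting) are type I with 0.1 dB passband
ripple by default; the ripple is an explicit parameter because it is
part of the filter's identity and matters for reproducibility. Mains
removal is a cascade of second-order IIR notches at 50 Hz and its
harmonics (default 5 lines, −3 dB bandwidth 2 Hz), each applied
zero-phase; harmonics at or above Nyquist are skipped with a log note.

## Dynamometry

Torque conversion uses the vendor chain 102.4 ft-lb/V × 1.3558 Nm/ft-lb
= 138.834 Nm/V, applied elementwise with a unit check. The segmentation
threshold is `mean + 3·SD` of a user-identified quiescent window (k
configurable); supra-threshold runs are merged across gaps shorter than
0.5 s and discarded below 1.0 s — contractions are held for ≥ 3 s with
≥ 2 s pauses, so these defaults separate repetitions without splitting
them on brief dips. Thresholding happens on the 20 Hz-filtered trace;
peak extraction happens on a single 2 Hz zero-phase pass over the whole
trace (filtering whole-trace rather than per-window avoids window-edge
transients; the peaks are still read inside the detected windows). The
baseline (noise-window mean) is subtracted before peak extraction so
gravity/offset does not bias the MVIC. Flexion trials should be passed
sign-inverted so the peak is always a maximum.

The retest rule flags a session when the third trial's smoothed peak is
at least 5% above **both** earlier trials (configurable to "any", since
the protocol wording is ambiguous on this point).

Note that a 2 Hz zero-phase low-pass is not a positive smoothing kernel:
on a noiseless trapezoid with a fast (≲ 0.5 s) rise it overshoots the
plateau by ~1%. On recorded contractions, whose rise is smoother and
whose noise raises the raw peak, smoothing lowers the peak as intended.

## Central Activation Ratio

CAR = plateau / (plateau + twitch). The voluntary plateau is the mean
torque over the 100 ms ending at the stimulation onset (an average, not
the instantaneous pre-stimulus sample, to be robust to noise); the
twitch is the post-onset maximum within 300 ms minus the plateau
(doublet interpulse 10 ms; the mechanical response is complete well
inside 300 ms). Negative twitch estimates — the post-stimulus trace
never exceeding the plateau — are clamped to zero with a flag, giving
CAR = 1. Both the fraction and the ×100 percent are always reported; the
fraction is the headline value since activation ratios are conventionally
quoted on a 0–1 scale.

Stimulus onsets come from a trigger channel (first rising edge through
half-range inside the contraction) when available. Without a trigger,
the onset is the maximal positive first difference of the 20 Hz-filtered
torque over the plateau region (samples ≥ 75% of the window maximum,
with the first 300 ms discarded so the plateau entry is not mistaken for
the artefact). The spike must exceed 5 robust standard deviations
(1.4826 × MAD) of the plateau derivative; otherwise the trial is
declared unstimulated and raises — unstimulated trials are never
silently scored as CAR = 1.

## EMG envelopes and co-contraction

Envelope chain: 5th-order Chebyshev high-pass at 20 Hz, 8th-order
Chebyshev low-pass at 300 Hz, mains-harmonic notches, full-wave
rectification, 4th-order Butterworth low-pass at 2 Hz, all zero-phase;
the output is clipped at zero (the final smoother can undershoot
slightly). Envelopes are normalized to the task maximum, so downstream
activations live in [0, 1]; normalization is per trial by default.

The co-contraction index is the Rudolph form
`CCI = (L/H)·(L+H)` with L/H the less/more active of the pair per
sample. Its range on normalized inputs is [0, 2], the maximum attained
only at full bilateral activation; where both envelopes are zero the
index is defined as its limit value 0. With equal envelopes the closed
form is `CCI(a, a) = 2a`. Values marginally above 1 (zero-phase ripple)
are clipped with a log note; values well above 1 are rejected as
un-normalized input. Phase-wise reporting uses the half-open percent
intervals 0–10 (initial double support), 10–50 (single support), 50–60
(pre-swing) and 60–100 (swing, inclusive of 100%), i.e. 10/40/10/41
samples of the 101-point grid.

## Morphometry

Meshes are in millimetres (DICOM-derived STL). Volume is the absolute
signed-tetrahedron sum over faces (divergence theorem), computed after
recentring on the vertex centroid; it is translation-invariant by
construction and orientation-independent through the absolute value.
Non-watertight meshes raise an error reporting the number of boundary
edges; zero-area faces are dropped with a count logged.

Maximal anatomical CSA slices the surface with planes perpendicular to a
chosen axis — default the scanner's axial (z) direction, matching axial
MRI acquisition — at 2 mm spacing (the acquisition slice thickness).
Planes are centred on the mesh's mid-extent so symmetric solids get a
slice through their widest section. Per-plane area is the summed area of
the closed intersection polygons (holes subtracted). This is anatomical,
not physiological CSA: no fiber direction information is used.
Volumes are additionally reported per BMI unit to remove the
confounding effect of stature and mass in cross-subject comparisons.

## Gait post-processing

Moments are divided by body mass (Nm/kg) and contact forces by body
weight with g = 9.81 m/s² (BW); angles pass through. One gait cycle
(between two ipsilateral heel strikes; a 20 N rising threshold on the
vertical ground-reaction force detects them when events are not
supplied) is linearly interpolated onto the canonical 101-point percent
grid — linear, not spline, so force curves cannot overshoot, and
endpoint values are preserved exactly.

Subject-level reducers: sagittal ROM is max − min of the
**ensemble-average** curve across trials (averaging first keeps
between-trial noise from inflating the range, and the mean curve is the
standard subject-level representation of gait); JCF characteristic peaks
are extracted per trial — maximum over [0, 50)% for the first peak and
[40, 70]% for the second, both windows configurable since "characteristic
peak" has no universal definition — then averaged across trials; walking
speed is net displacement along the progression axis (direction of net
horizontal displacement, so lateral sway does not inflate it) divided by
elapsed time, averaged across trials. A curve with fewer than two
interior local maxima is flagged unimodal and its two "peaks" may
coincide.

Point-wise cohort comparison: a pooled-variance two-sample t statistic
at each grid point, with family-wise error across the curve controlled
by permutation of group labels — the null distribution of the maximal
|t| over the curve is built from 1000 seeded relabelings (the identity
relabeling included, as in the exact-test construction), and points
exceeding its (1 − α) quantile form clusters. Runs shorter than 2
consecutive points are discarded: a single-point excursion on a 1% grid
has no physiological meaning, and continuum-based corrections behave
the same way on rough fields. This is a non-parametric replacement for
random-field-theory SPM and is labelled as such; zero-variance points
get t = 0 with a flag.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of parameters + seed (bit-identical
regeneration) and return JSON-serializable ground truth.

* **MVIC traces**: trapezoidal contractions (default three trials at
  210 Nm, 3 s hold) with additive white Gaussian noise, a 2 s leading
  baseline serving as the noise window, and 2 s inter-trial gaps (real
  rests are 90 s; compressing them changes nothing downstream and keeps
  fixtures small). The rise time defaults to 1.0 s — a realistic time to
  peak torque for a maximal effort. Optional output in volts (divide by
  138.834) exercises the conversion stage.
* **Stimulation trials**: plateau plus an alpha-function twitch
  `A·(t/τ)·e^{1−t/τ}` (τ = 50 ms), which peaks at exactly A so only the
  amplitude — the quantity CAR depends on — is modelled; a TTL trigger
  channel carries a 10 ms pulse at the onset.
* **EMG**: Gaussian noise band-passed to 20–300 Hz, amplitude-modulated
  by the activation profile and scaled by √(π/2) so the linear envelope
  approximates the profile; a 50 Hz sinusoid adds mains contamination.
  No motor-unit structure, firing statistics or electrode artefacts are
  simulated, so tests exercise the filter chain's fidelity, not
  physiological realism.
* **Gait curves**: smooth Gaussian-bump templates rescaled to the
  requested ROM exactly, and a two-bump contact-force template whose
  bump heights equal the requested peaks; per-trial variability is a
  smooth random perturbation (white noise smoothed with a 3-sample
  Gaussian kernel, rescaled to 1% of the curve scale by default) —
  real between-trial gait variability is waveform-correlated, which the
  smoothing imitates coarsely.
* **Meshes**: icospheres, scaled ellipsoids, cylinders and a
  double-belly solid of revolution, all watertight, with closed-form (or
  high-resolution quadrature) volume and CSA stored as ground truth.

Passing recovery tests on these inputs shows the pipeline implements its
definitions correctly under realistic noise levels; it does not validate
against human recordings, which no public dataset accompanies.

## Problem sizes and tolerances

Recovery tests run 100 seeds per scenario at the noise levels above;
recovery tolerances are 2% for MVIC/ROM/JCF peaks, ±0.01 for the CAR
fraction. Mesh oracles: icosphere volume within 0.5% of closed form at
4 subdivisions, CSA within 1%, and divergence volume within 1% of an
independent 0.5 mm voxel fill (plane sections rasterized with
point-in-polygon tests). The permutation comparison uses 10 curves per
group and 1000 permutations. These sizes are the package's test
conditions, chosen to match the study conditions each stage is meant to
operate under.

## Known limitations

* No C3D reader: gait tables are consumed as delimited text or
  OpenSim-style MOT/STO files.
* The CAR stage assumes a single stimulation per contraction window.
* CSA is anatomical, along a fixed axis; physiological CSA would need
  fiber directions.
* The permutation comparison assumes exchangeable subjects (no
  repeated-measures structure across the two groups).
* Isokinetic analysis, rate of torque development, EMG decomposition and
  musculoskeletal simulation itself are out of scope; the toolkit
  post-processes simulation outputs.
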