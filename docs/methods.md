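# Methods

## Signal model

During continuous chest compressions the sternal acceleration and the
compression-depth (CD) signal are quasi-periodic: over a short analysis
window of duration `Tw` every compression is nearly identical, so both
signals are well approximated by the first `N` harmonics of a Fourier
series at the mean compression frequency `f_cc` (no DC term; the CD signal
is referenced to the resting chest position). Differentiating the
displacement series twice and matching terms with the acceleration series
gives the exact per-harmonic relations

    S_k = 1000 · A_k / (2πk f_cc)²  [mm from m/s²],   φ_k = θ_k + π.

This converts the depth-estimation problem from a double integration (whose
output drifts quadratically under any acceleration offset) into estimating
one frequency and `N` amplitude/phase pairs per window. The model assumes
*continuous* compressions: pauses, and windows containing a start/stop
transition, violate periodicity and are reported as gaps, not estimates.

## Estimation pipeline and numerical choices

Per window: remove the mean, apply a Hamming taper, compute a zero-padded
2048-point FFT (bin spacing 100/2048 ≈ 0.0488 Hz ≈ 2.93 min⁻¹ of rate).

- **Axis combination** (`project_axes`). The device records three axes; the
  method operates on one scalar signal. Default is the per-window principal
  axis (direction of maximal variance after per-channel mean removal): it
  is invariant to rigid sensor rotation, so the 18°-tilt condition needs no
  special handling. Fixed-axis and vector-magnitude modes exist for
  comparison. The projection sign is fixed deterministically (first local
  extremum positive); rate and depth are sign-invariant anyway.
- **Fundamental pick** (`estimate_fundamental`). Largest-magnitude bin in
  the 0.6–3.5 Hz band (36–210 min⁻¹, guideline-relevant rates with
  margin). Subharmonic guard: if a local peak near half the candidate
  frequency reaches 30 % of its magnitude, the lower peak wins —
  pulse-like waveforms can put more energy into the 2nd harmonic than into
  the fundamental. Optional three-point parabolic refinement
  (`refine_peak`, default off) reduces rate quantisation from ±1.46 min⁻¹
  to < 0.3 min⁻¹; the default mirrors plain FFT-bin read-off.
- **Noise floor.** A window with no coherent peak must raise "no
  periodicity detected" rather than emit a number. The floor is the median
  magnitude over the 11–14 Hz strip: inside the 15 Hz low-pass passband but
  above the 3rd harmonic of any in-band fundamental (3 × 3.5 Hz = 10.5 Hz),
  hence noise-only. The in-band median is deliberately *not* used — during
  compressions it is dominated by spectral leakage skirts, and measured
  white-noise peak/median ratios (up to ≈ 4.8) overlap the signal case.
  The fundamental must exceed 5× the floor.
- **Harmonic read-off** (`estimate_harmonics`). For k = 1..3 the local
  magnitude maximum within ±max(1.5 bins, 0.1·f_cc) of k·f_cc is used
  (cycle-to-cycle jitter broadens and shifts harmonic peaks). Amplitudes
  are corrected by the Hamming coherent gain, `A = 2|X|/Σw`; without this
  correction depths would be biased low by ≈ 0.54×. Harmonics at Nyquist,
  below 5× the noise floor, or below 2 % of the fundamental magnitude are
  zeroed — the last guard rejects the taper's own sidelobes (≈ 1 % of the
  peak near 2·f_cc), which would otherwise masquerade as harmonics of a
  purely sinusoidal input.
- **Windows** are positioned by sample index, half-open `[start, start+Tw)`,
  nonoverlapping and consecutive; the trailing remainder of a record is
  discarded (floor rule). Estimates are windowwise-independent — no state
  is carried, which is precisely why there is no drift.

## Preprocessing

Third-order Butterworth low-pass at 15 Hz, then rational-factor polyphase
resampling to the 100 Hz analysis rate. Zero-phase (forward–backward)
filtering is the default so that method and reference windows stay
time-aligned; a causal mode exists for real-time fidelity studies. Note the
zero-phase pass squares the magnitude response: the chain is flat to < 2 %
up to ~7 Hz, which covers the 3rd harmonic of the fastest in-band
fundamental; by 9–10 Hz attenuation reaches ≈ 5 %.

## Gold-standard reference

Compressions are detected in the CD signal as local maxima above a fixed
15 mm threshold with a 0.25 s refractory period (240 min⁻¹ ceiling,
suppresses double detections). Per window, reference rate is 60 / (mean
inter-peak interval) and reference depth the mean peak depth, over peaks
whose maxima fall inside the half-open window; a median aggregate is
available. Windows with fewer than two peaks yield gaps. Peak depth is the
sample value at the maximum, i.e. depth is measured from the resting
position — valid only under full chest recoil (see limitations).

## Synthetic benchmark

The simulator emulates a manikin bench study: 20 rescuers × rates
{80, 100, 120, 140} min⁻¹ × depths {30, 50} mm × {regular, 18° tilt},
60 s of uninterrupted compressions per record, acquired at 500 Hz and
conditioned to 100 Hz — 320 records, ~35 000 compressions in total.

Each cycle is a raised-sine pulse
`s(t) = leaning + (depth − leaning)·sin²(πt/(duty·T))` held at the release
position for the rest of the period: continuous first derivative at cycle
boundaries (bounded acceleration), and duty < 1 produces the multi-harmonic
content that motivates N = 3. Per-cycle period and depth are drawn
independently with coefficients of variation 0.03 and 0.05; acceleration is
the exact discrete second derivative mapped into the sensor frame (tilt
rotation), plus a gravity vector rotated likewise, per-axis offset, and
white noise (σ = 0.3 m/s²). Gravity is included by default so the
offset-invariance of the estimator is exercised realistically.

Per-rescuer "skill" parameters make rescuers differ reproducibly: jitter
CVs ~ N(0.03, 0.008)/N(0.05, 0.012) clipped, multiplicative rate/depth
biases ~ N(1, 0.015)/N(1, 0.05) (chosen so record-level 5–95 pct spreads
resemble metronome-and-display-guided human performance), and duty cycle
~ U(0.8, 1.0) (3-harmonic truncation error of the waveform stays below 1 %
in this range). Every draw descends from a single integer seed;
config + seed → bit-identical datasets.

**What the simulator does not emulate.** Human cycle-to-cycle variability
is autocorrelated (rescuers wander slowly around the metronome), whereas
the simulator draws i.i.d. per-cycle jitter. i.i.d. jitter is the harsher
condition for *agreement* statistics: the spectral estimate is a
Hamming-weighted average over the window while the reference averages the
peaks inside it, and independent jitter maximises the sampling mismatch
between the two. Consequently the benchmark's Bland–Altman limits
(≈ ±2.1 min⁻¹ and −1.6/+2.7 mm at Tw = 3 s) are wider than those
achievable on metronome-guided human data, even though pooled RMSE stays
below 1.5 min⁻¹ and 2 mm for Tw ∈ [2, 5] s. The rate-agreement floor from
FFT-bin quantisation alone is ±1.66 min⁻¹. The simulator also omits
leaning-induced baseline shifts under load, soft-surface (mattress)
compliance, pauses and hand repositioning.

## Evaluation protocol

Differences are always method − reference. Pooled RMSE per session kind
as a function of Tw; Bland–Altman bias ± 1.96·SD (sample SD) at Tw = 3 s;
per-condition tables use the *record* as the unit (windows averaged per
record, then median and 5–95 percentiles with linear interpolation across
records; rate targets pool both depths, depth targets pool all rates),
sources compared with the two-sided Mann–Whitney U test (exact null for
small tie-free samples, tie-corrected normal approximation otherwise). A
window of < 2 compression cycles (Tw = 1 s at slow rates) breaks the
periodicity assumption; accuracy degrades sharply there, consistent with
recommending 2–5 s feedback intervals.

The drift baseline integrates acceleration twice (cumulative trapezoid,
zero initial conditions, no compensation); a constant offset `b` produces
`1000·b·t²/2` mm of spurious displacement, while the spectral estimate on
the same contaminated input changes by < 0.1 % (the window mean removal
eliminates constants exactly).

## Known limitations

- Depth is referenced to the resting chest position: incomplete recoil
  (leaning) shifts the true zero and biases any accelerometer-based depth.
  The simulator can generate leaning (`leaning_mm`) but the estimator does
  not detect it.
- Valid during continuous compressions only; real resuscitation episodes
  contain pauses, which here simply become gaps.
- Single-sensor, hard-surface geometry; soft surfaces require a second
  (back) accelerometer and differencing, which the harmonic machinery
  would support unchanged.
- Rate resolution is FFT-bin-limited (≈ 2.93 min⁻¹) unless `refine_peak`
  is enabled.
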