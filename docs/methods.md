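# Methods

`rumblecam` re-creates, end to end on synthetic data, the measurement
chain used to show that African elephant rumbles are emitted through
two distinct vocal paths — the trunk (nasal, vocal tract ≈ 2 m) and the
mouth (oral, ≈ 0.7 m): acoustic-camera source localization, tube-model
formant and vocal-tract-length (VTL) analysis, and LPC-descriptor
classification. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely
open.

## Source–filter synthesis of rumbles

A rumble is rendered as a glottal pulse train shaped by vocal-tract
resonances:

- **Source.** Pulses fire on phase wrap of an integrated F0 track; each
  pulse is an exponentially decaying transient (time constant 1 ms,
  i.e. a one-pole low-pass with ~160 Hz corner, −6 dB/oct above). This
  gives the harmonically rich, gently tilted spectrum that rumbles
  show: strong infrasonic partials plus measurable energy into the
  audible range, which the acoustic map needs for focusing.
- **F0 track.** Gaussian walk low-passed at 2 Hz, generated at a 100 Hz
  control rate and interpolated (a 2 Hz IIR filter is numerically
  degenerate at audio rate), scaled to a within-call sd of 10% of the
  call's mean F0. Rumbles are strongly frequency modulated; a ~10%
  slow wander matches published pitch tracks, and it is what lets any
  envelope estimator see between the harmonics (see below).
- **Filter.** Cascade of two-pole resonators at the quarter-wave
  resonances `F_k = (2k−1)c/(4L)` of a uniform tube closed at the
  vocal folds, with `c = 350 m/s` and bandwidths `0.3·F_k` (floor
  10 Hz). Overlapping resonator skirts pull the realized spectral
  maxima a few percent off the pole centres, so the centres are nudged
  iteratively until the cascade's envelope peaks sit on the tube
  formants — the generator's contract is that synthetic calls have
  their formants *at* the tube predictions.
- **Calibration.** The waveform is the pressure signal at the
  recording distance: core RMS (50 ms raised-cosine ramps excluded)
  scaled to the spec's dB SPL re 20 µPa. WAV files use full scale
  = 20 Pa, so levels survive a file round trip.

**Populations.** Call parameters are drawn per class from the reported
statistics of female elephant rumbles: nasal F0 ~ N(19.7, 2.7) Hz,
duration ~ N(2.94, 1.6) s (truncated at 0.5 s), SPL ~ N(51.9, 6.22) dB
at 8 m, VTL ~ U(1.80, 2.24) m; oral F0 ~ N(26.9, 4.6) Hz, duration
~ N(1.79, 1.1) s, SPL ~ N(74.45, 7.49) dB, VTL ~ U(0.63, 0.79) m.
Everything is deterministic given the seeds carried in the specs.

**What the generator does not emulate.** Real amplitude contours,
trunk-as-waveguide acoustics, atmospheric absorption, reverberation,
correlated (wind-like) background noise, and moving sources. Passing
tests therefore demonstrate that the *analysis chain* recovers known
ground truth under the reported statistical conditions — not that it
would perform identically on field recordings.

## Array, scene simulation and beamforming

The array is a 48-microphone star (3 equiangular arms × 16 mics,
maximum pairwise span exactly 3.4 m, centroid at the origin, unit
weights) in the z = 0 plane; the image plane sits parallel at 8 m. The
commercial star array's radial layout is unpublished; we use
logarithmic spacing from a quarter of the tip radius outward. The inner
radius matters: packing mics near the centre collapses the effective
aperture (0.2 dB trunk/mouth contrast at 500 Hz versus 2.4 dB for this
layout). Results that depend on placement beyond span and count are
layout-dependent.

Scene rendering delays each call to each microphone by its absolute
run time `π_i = |r_i|/v` (windowed-sinc fractional delay, 31 taps,
`v = 343 m/s` for 20 °C air — deliberately distinct from the tube
model's 350 m/s) and scales by `d_ref/|r_i|` under spherical spreading;
white Gaussian noise at a configurable dB SPL is added per channel.

Focusing advances each channel by its relative delay
`Δ_i = π_i − min π_i` and averages with weight normalisation
`1/Σw_i`, so a perfectly focused source keeps its physical amplitude
and the focused signal's RMS converts directly to dB SPL re 20 µPa.
The beamformer interpolates linearly between samples — exact on
integer-sample delays (the oracle tests exploit this) and deliberately
different from the simulator's sinc interpolator, so simulation and
analysis do not share an inverse-crime code path.

**Low-frequency focusing and the allocation band.** At 8 m a 3.4 m
aperture has essentially no directivity below ~100 Hz: the maximum
inter-mic delay is ~0.5 ms, a tiny phase across an infrasonic period.
Localization of rumbles therefore rides on their harmonics above a few
hundred Hz. Allocation maps band-pass the recording to 150–1200 Hz
(above that, white background noise outweighs the call's −6 dB/oct
spectrum; below it, the array cannot focus). SPL measurements use the
unfiltered focused signal so calibration is band-independent. Maps for
allocation are computed on recordings decimated to 6 kHz over a 0.2 s
(or shorter) mid-call window on a 48×36 or 40×30 grid — desk-scale
settings that keep a 40-call validation in minutes.

**Allocation rule.** A call is nasal/oral if the map peak falls within
0.3 m of the trunk-tip/mouth reference point (0.8 m apart), and
ambiguous otherwise — or when the peak exceeds the best pixel around
the competing point by less than 0.07 dB. That margin is calibrated to
this instrument: correct allocations measure 0.09–0.4 dB of contrast,
diffuse noise maps ripple below ~0.05 dB. The same rule reports
noise-only scenes as ambiguous rather than forcing a label.

## Per-call acoustics

- **Pitch.** Frame-wise normalised autocorrelation (0.4 s window,
  10 ms step), search band 10 Hz to a class ceiling (35 Hz nasal,
  40 Hz oral), parabolic lag refinement; a frame is voiced when peak
  correlation ≥ 0.45 and frame amplitude ≥ 3% of the call maximum.
  Those two thresholds are calibration knobs in the Praat tradition.
- **Duration.** Span where a 50 ms smoothed energy envelope exceeds
  its peak − 25 dB (threshold stated in output metadata).
- **Formants.** The hard problem at these frequencies: harmonic
  spacing (F0 ≈ 20–27 Hz) is comparable to the formant bandwidths, so
  frame-wise all-pole fits lock onto individual harmonics rather than
  the envelope (order-12 LPC at 6 kHz mis-estimated VTL by 25–300% in
  our benchmarks). The estimator instead:
  1. averages the periodogram over the whole call (0.5 s windows, 75%
     overlap) — the F0 modulation sweeps harmonics across the
     envelope;
  2. detects the harmonic tips and interpolates a monotone-cubic
     envelope through them, with +6 dB/oct tilt compensation;
  3. selects the most prominent peak pair consistent with a
     closed-open tube (F2/F1 in [2, 4.5] — the exact tube value is 3,
     published per-individual means span ~2.3–3.3 — and separation
     ≥ 1.5 F0, since two bumps within one harmonic spacing cannot be
     distinct resonances), searched inside class bands of 30–150 Hz
     (nasal) and 90–420 Hz (oral), mirroring the original practice of
     seeding the peak search from the predicted formant locations;
  4. refines each peak on the harmonic-density-normalised spectrum:
     dividing the averaged spectrum by the expected harmonic
     excitation (computed from the call's own pitch samples) removes
     the bias that drags a peak onto the nearest strong harmonic —
     this is what recovers F1 = 35 Hz under a 20 Hz fundamental.

  On six population seeds this gives 5–10% median VTL error per class
  with no measurement failures; fewer than two admissible peaks yields
  a failure record, never an exception.
- **VTL.** `c/(2(F2−F1))` with `c = 350 m/s`.

## Classification

Each call is summarised by one 26-component descriptor: order-8 LPC
envelopes on 300 ms windows every 30 ms, evaluated on 260 bins over
0–500 Hz, averaged over time, block-averaged 10:1. Calls are resampled
to 1 kHz first so the order-8 model spans exactly 0–500 Hz, and
normalised to 1 Pa RMS so the descriptor encodes spectral shape rather
than loudness (envelope values are dB re 20 µPa of the normalised
call, clipped at 0, hence non-negative). One shared config object
drives the descriptor for both classes — there is no per-class branch.

Evaluation follows the published protocol: stratified 1/3 training /
2/3 evaluation split, 10-fold cross-validated tuning (SVM cost and NN
neighbourhood size; LDA has none) on the training third, held-out
scoring, and a swap replicate with the two sets exchanged. On the
default synthetic corpus (60 + 60 calls, SNR 20 dB) all three
classifiers are at or near 100% — the synthetic classes are cleanly
separated in descriptor space, which reproduces the *mechanism* of the
original result; the original 99% on 167 real calls is a property of
recordings that are not public.

## Numerical and degenerate-input conventions

All-zero analysis windows return a `−inf` "below floor" SPL sentinel,
not an exception; silent calls measure 0 s duration with a warning;
calls without two admissible formant peaks produce failure records
that the pipeline logs and skips; LDA falls back to a shrinkage
estimator on degenerate within-class covariance; pipeline runs are
replayable byte-identically from their saved config (every output
names the config hash).

## Known limitations

- The star layout is a plausible stand-in for an unpublished
  commercial design; absolute map contrasts (and hence the ambiguity
  margin) are specific to it.
- Allocation margins are tenths of a dB at this aperture/distance;
  real acoustic cameras integrate video and operator judgement on top.
- The formant estimator leans on within-call F0 modulation; a
  hypothetical perfectly monotone rumble would defeat it (and any
  envelope method).
- White background noise is the least favourable but also least
  structured choice; correlated field noise would change the
  allocation band trade-off.
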