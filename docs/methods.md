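# Methods

This note documents the models, parameter choices and numerical decisions
behind `stsonify`, and what the synthetic test bed does and does not show
about real ECG data.

## Synthetic ECG model

The generator emulates the output of a patient-simulator ECG source: clean,
band-passed, zero-baselined 12-lead signals with a stable, controllable ST
offset per lead, at a fixed heart rate. One beat is a deterministic
template on `[0, RR)`:

- **P and T waves**: raised-cosine bumps with compact support (P: 0.15 mV
  peak, 90 ms wide, onset at 2% of RR; T: 0.30 mV, 160 ms, onset at 55% of
  RR). Compact support keeps the baseline *exactly* zero outside the wave
  supports, which makes extractor assertions sharp.
- **QRS complex**: piecewise-linear, 70 ms wide, onset at 15% of RR — a
  small Q dip (−0.10·R), the R apex (1.0 mV by default) at 30% of the QRS
  width, an S dip (−0.15·R), then a linear return to the ST level at the
  J point.
- **ST plateau**: exactly `st_offset` mV from the J point to the T onset.
  At the 80 bpm study rate the plateau spans [0.065, 0.372] of RR measured
  from the R apex, so it fully covers the extractor's default
  [0.10, 0.30) window. The generator records the apex offset and plateau
  window in the recording metadata.

Beats are tiled to the requested duration (every lead shares the template
except for its ST offset, so R spikes are aligned across leads), and
i.i.d. Gaussian noise is added per sample and lead (`numpy`
`default_rng(seed)`, so identical arguments are bit-identical). Defaults —
80 bpm, 500 Hz, 0.02 mV noise for the noisy tests — are the conditions
the reference listener study used. The default morphology assumes
RR ≥ ~0.69 s; at substantially faster rates the fixed component widths
would overlap and the generator raises instead of silently deforming.

What the model deliberately omits: heart-rate variability, baseline
wander, powerline interference, inter-lead morphology differences,
pathological rhythms, electrode artifacts. Passing round-trip tests
therefore show the pipeline is *internally* correct and noise-robust at
simulator-like data quality; they say nothing about R-peak detection or
ST estimation on ambulatory real-world recordings.

## Condition fixtures

Seven named ST profiles define the study conditions: `IE` (all zeros) and
anterior/inferior × weak/moderate/severe. Anterior conditions elevate
V1–V4 (V5 mildly in the severe case) with reciprocal suppression in
II/III/aVF; inferior conditions elevate II/III/aVF with reciprocal
suppression in I/aVL (and mild V1/V2 changes when severe). Severity
places the affected leads in the moderate (0.1, 0.2] mV or strong
(> 0.2 mV) band. Every nonzero value keeps ≥ 0.03 mV clearance from the
0.1/0.2 mV category thresholds so that an estimate within the ±0.03 mV
noisy-recovery tolerance can never flip a 5-level category. The numeric
vectors are this package's own stand-ins chosen for those category
semantics — published sources describe the conditions only graphically —
and are version-controlled here as the reproducible gold standard.

## Feature extraction

R-peaks are found on the combined power signal `Σ_k x_k²`, min-max
rescaled to [0, 1] (a constant signal maps to zeros by convention), with
`scipy.signal.find_peaks` at height 0.5 and minimum distance 30% of the
sampling rate — the distance rule keeps taller peaks first, which is the
intended thinning behaviour. Detection runs at the native rate; an
anti-aliased downsample-to-100-Hz helper exists but is off by default
because decimation before peak finding only degrades R-peak localization.

ST elevation is the per-lead median over samples whose beat-relative
position lies in `[lo, hi)` of the *actual* RR of each beat, measured from
the current R-peak, pooled across complete beats (half-open window,
0-based indices). The default window (0.10, 0.30) targets the ST segment
at 80 bpm and matches the generator's plateau; it is a configurable
choice, not a physiological constant — a whole-beat median would be
dominated by baseline. At least two peaks (one complete beat) are
required. No baseline correction is applied; a warning is logged when a
lead's full-record median exceeds 0.05 mV. Note this warning also fires
for genuinely strongly elevated leads (their plateau occupies enough of
the beat to pull the global median up) — it is a data-quality hint, not an
error.

## Mapping

Thresholds θ₁ = 0.1 mV and θ₂ = 0.2 mV split five ordered states. Band
edges are deterministic: the isoelectric band is closed `[−θ₁, θ₁]`,
moderate bands half-open outward, strong bands strictly beyond ±θ₂.
The default five-state semitone table (−8, −5, 0, +4, +7) is the
configuration evaluated in the listener study; the harmonic major-chord
variant (−9, −5, 0, +4, +7) ships as a named preset, as do the dissonant
(−11, −5, 0, +4, +8) and tristate (−5, 0, +7) tables.

The continuous mode clamps to the source interval ±0.4 mV and maps
linearly onto ±7 semitones; chromatic rounds that result
half-away-from-zero; diatonic rounds the [0, 11] index half-away-from-zero
into a fixed ascending 12-note two-octave table
(−10, −8, −7, −5, −3, −1, 0, 2, 4, 5, 7, 9) that contains 0 at the
isoelectric midpoint and is user-overridable — any concrete table must be
pinned for reproducibility. The source interval is interpreted in mV
(0.4 µV would be three orders of magnitude below the decision
thresholds and physiologically meaningless). All modes are monotone
non-decreasing in st; continuous mode is antisymmetric.

Timing semantics: *set separation* = beats between scan starts (8),
*stride* = beats between the limb and precordial groups (2); cycles
anchor at 0-based beats 0 and 2. `dt` (120 ms) is constant and
independent of heart rate. Levels: base L0 = −25 dB re full scale,
boost 0/5/15 dB scaled by dBscale = 0.2.

## Scheduling and synthesis

The QRS reference tone is under-constrained by the design (only its pitch,
f0, is fixed); this package renders it as a 30 ms, 2-harmonic, percussive
(c = −3) tone at L0 — an audible anchor that cannot mask ST tones — and
documents it as a configurable default. The first limb tone coincides
exactly with its anchoring beat; simultaneity is resolved by additive
mixing. The arpeggio design's "longer and louder" emphasis uses duration
×2 and +10 dB with 2/4/8 harmonics for suppressed/isoelectric/elevated —
explicit, testable constants for a design described only qualitatively.

Tone synthesis: `s(t) = (1/N) Σ cos(2πnft − nπ/2)` (the n-th partial is
phase-shifted so peaks align), envelope
`w_{c,d}(t) = 1 − (1 − e^{ct/d})/(1 − e^c)` with `w(0)=1`, `w(d)=0`,
strictly decreasing for c ≠ 0; |c| < 1e−9 switches to the analytic limit
`1 − t/d` to avoid catastrophic cancellation. An aliasing guard rejects
tones whose top harmonic exceeds a quarter of the sampling rate. Mixing
is linear with hard clipping at ±1 (clip count logged) rather than
normalization, so dB arithmetic stays measurable on the waveform. Output
is mono 16-bit PCM WAV, 44.1 kHz by default, full scale 1.0 → 32767.

A subtlety in spectral testing: the N partials carry equal 1/N weights, so
when the fundamental lies exactly on an FFT bin every harmonic does too
and the "dominant" partial is a spectral-leakage tie. Spectral tests
therefore choose the probe duration so the fundamental sits ~0.15 bins
off-centre; its harmonics then sit 0.30/0.45/0.60 bins off and leak
measurably more, making dominance well-defined.

## Evaluation statistics

Matrices are predicted × gold. Sensitivity = TP/column total,
specificity = TN/gold negatives, F = 2PR/(P+R) with precision P and
recall R (the harmonic mean reproduces the study's published class
tables; the alternative se·sp/(se+sp) form circulating in some reports
does not and is exposed separately as `se_sp_product_ratio`),
balanced accuracy = (se+sp)/2 exactly. The accuracy CI is the exact
Clopper–Pearson interval (`statsmodels proportion_confint(method="beta")`),
which reproduces both the study's printed intervals including the
all-correct boundary case where a Wald interval fails. κ uses
p_e = Σ row·col / n²; the degenerate p_e = 1 case returns 1 when
agreement is also perfect and NaN otherwise. Nothing is rounded
internally; rounding (half-away-from-zero) happens only in the reporting
layer.

## Problem sizes

The test suite and acceptance script use 20 s recordings at 500 Hz
(≈ 26 beats) with 0.02 mV noise and 10 seeds per condition for recovery
checks, two-cycle schedules for timing checks, and ≤ 1 s tones for
spectral checks — sizes at which every quantity is stable to well below
its assertion tolerance while the whole suite runs in seconds.

## Known limitations

- The R-peak detector presumes large, aligned R spikes; it is not a
  general QRS detector for pathological rhythms or artifact-laden data.
- ST estimation presumes a zero baseline; drifting baselines bias the
  median directly.
- Schedules anchor to nominal beat times (fixed bpm), not to measured
  R-peak times; the evaluated configuration used a constant 80 bpm.
- The percussion and vowel-formant design variants, sampled-instrument
  melodies, real-time playback and interactive exploration GUIs are out
  of scope.
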