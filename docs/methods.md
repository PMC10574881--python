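# Methods

## The wavelet front end

At a fixed integer scale `a` the continuous wavelet transform is a bandpass
filter: `W_a x (n) = Σ_k ψ_a(k) x(n−k)` with `ψ_a(t) = ψ(t/a)/a`.  The
prototype ψ is the first derivative of a fourth-order B-spline smoothing
kernel, evaluated through the B-spline derivative identity

    ψ(t) = d/dt β⁴(t) = β³(t + 1/2) − β³(t − 1/2),

an antisymmetric, zero-mean, single-cycle wavelet supported on |t| ≤ 2.5.
This prototype was chosen, among the family of derivative-of-spline
wavelets, because its −3 dB band in normalized frequency
(≈ 0.117–0.389 · Fm/a) keeps the device's three rate/scale pairings —
(250 Hz, scale 2), (500 Hz, 4), (1000 Hz, 8) — on a common passband of
about 14.7–48.6 Hz, between the dominant QRS energy and the 50/60 Hz
powerline components.  Lower spline orders put the band several hertz
higher, higher orders several hertz lower.  The `1/a` (L1) normalization
keeps modulus amplitudes comparable across scales, so detector thresholds
transfer between sampling rates.

The sampled kernel has `5a − 1` taps (exact zero end taps are trimmed) and,
being antisymmetric, a group delay of exactly its center index — 19, 9 and
4 samples at scales 8, 4, 2.  Beat indices reported by `detect_record` are
compensated by this delay.  Note that a linear-phase FIR whose passband
sits at ~0.12–0.39 · Fm/a *cannot* have a group delay much beyond ~2.5a
samples without zero padding (time–bandwidth), so the kernel delay is the
measured center of antisymmetry, full stop.

Cutoffs are measured at −3 dB of the peak magnitude response on a dense
grid (default 8192 points to Nyquist) with linear interpolation at the
crossings.  Doubling the sampling rate at a fixed scale doubles both
cutoffs exactly; `select_scale` exploits this to pick, for non-device
rates, the integer scale whose band midpoint is nearest the 14.4–48.6 Hz
target in log frequency (e.g. 2000 Hz → scale 16).

Streaming contract: `cwt_filter` is a causal FIR (`scipy.signal.lfilter`),
so each output depends on current and past inputs only.  The first
`delay_samples` outputs are computed against zero-padded history; the
detector blanks them during its learning phase.

## The streaming beat detector

Through the antisymmetric wavelet each QRS maps to a modulus pair — a
positive maximum and a negative minimum — whose zero crossing (P1) marks
the R/S peak.  The detector is a small per-sample state machine:

- **Learning** (default 2 s, minimum 1 s): the extreme positive and
  negative coefficients seen (after startup blanking) seed the two
  threshold memories at 75% of their values.  No beats are emitted.
- **Excursion tracking**: when the coefficient exceeds a memory the
  excursion's extremum is tracked until the coefficient falls back inside;
  the finalized extremum is a candidate modulus.
- **Pairing**: a candidate pairs with a previous candidate of opposite
  sign if their peaks lie within 120 ms (a QRS-width bound); the pairing is
  order-agnostic, so polarity inversions and morphology changes that swap
  Pmax/Pmin order do not move P1.  Unpaired candidates expire after the
  window.
- **P1**: the first zero crossing of the buffered coefficients after the
  first modulus, at integer sample resolution (no sub-sample
  interpolation).
- **Adaptation**: after each beat both memories move toward 75% of the
  detected pair's amplitudes with exponential weight α = 0.25, i.e. they
  adapt over roughly four beats; a pure last-beat memory would be brittle
  against a single ectopic amplitude.
- **Refractory**: 200 ms after P1 (physiological minimum RR is ~300 ms;
  200 ms also blanks T-wave energy).
- **Dropout recovery**: if no beat arrives for 1.5× the running mean RR
  (8-beat window), both memories are halved; this repeats once per further
  elapsed period, so the detector recovers even from a spike that inflated
  the thresholds by a large factor — a single halving could lock the
  detector out permanently.
- **Floor**: memories never drop below 1% of the learning-phase maximum
  modulus (with a tiny absolute floor for all-zero input), preventing
  divide-by-noise lockup on flatline.

RR is the P1-to-P1 distance in ms and `hr_bpm = 60000 / rr_ms`.  Because
the learning phase suppresses detection, the first ~2 beats of any record
are never reported; on a 5-minute record this bounds sensitivity at about
99.4% even for an otherwise perfect detector.

Tunable parameters (module constants in `qrs_detector`): threshold factor
0.75, smoothing α 0.25, refractory 200 ms, pairing window 120 ms, floor
fraction 0.01, missed-beat factor 1.5.  The 0.75 factor is the device's
design value; the rest are engineering choices documented above.

## Device arithmetic and alarms

Closed forms, all with defaults from the monitor's datasheet-level values:
full scale `±V_REF/G` (±2.4 V at unity gain), LSB
`(2·V_REF/G)/(2²⁴ − 1)` ≈ 286.10 nV, storage `15 bytes × Fm × t`
(1.296 GB ≈ 1.21 GiB for 24 h at 1000 Hz; "GiB" uses 2³⁰), battery life
`(3000 mAh × 3.7 V)/(50 mA × 3.3 V)` = 67.27 h theoretical and 47.09 h at
the 70% usable fraction imposed by the low-voltage cutoff.

The alarm engine is a pure function of its input snapshot except for the
heart-rate debounce: three consecutive beats outside 60–100 bpm are
required to raise the HR alarm (suppressing single ectopics), and one
in-range beat clears the counter.  The buzzer sounds for electrode faults,
SD disconnection *during acquisition*, a full card, or the HR alarm; low
battery is visual only.  Lead-off status is decoded from a 5-bit word
(RL, LL, LA, RA, V2, LSB first) with no hysteresis.

## Binary record format

Directory `<subject>_<YYYYMMDD>_<HHMMSS>`; `Record0000` is a UTF-8
key–value header; `Record0001`–`Record9999` hold 15-byte packets (3
channels × [3-byte big-endian two's-complement ADC code + 2-byte big-endian
HR word]).  Choices the device documentation leaves open, fixed here:
big-endian byte order; HR word as unsigned bpm × 10 fixed point with 0 =
"no beat yet"; 2¹⁶ packets per data file (~65 s at 1000 Hz); raw codes
stored with the gain recorded in the header.  Round-trips are bit-exact at
packet, file and directory level.

## Synthetic ECG

Each beat is a sum of five Gaussians (P, Q, R, S, T) with lead-II-like
default amplitudes scaled per lead (DI ×0.8, aVF ×1.0, V2 ×1.4) — a
Gaussian-template generator in the ECGSYN tradition, chosen over
dynamical-system models because the R-peak ground truth is exact by
construction.  RR intervals are `max(300 ms, Normal(60000/HR, σ_RR))` with
`σ_RR` mapped from the bpm jitter at the operating point; beat centers are
quantized to the sample grid so `r_peak_indices` is exact.  Gaussians are
truncated at ±6σ (relative error < 2·10⁻⁸).  Noise terms: white Gaussian
(directly or via a target SNR computed from the clean template power),
sinusoidal baseline wander, and 50/60 Hz powerline.  Lead-off episodes
saturate the affected leads at the +2.4 V rail and set the per-electrode
mask (RA corrupts DI and aVF, LA → DI, LL → aVF, V2 → V2, RL → all).

What the generator does *not* emulate: real QRS morphology families,
ectopy and arrhythmia, respiratory modulation of amplitude and rate,
electrode motion artifacts with realistic spectra, or muscle noise.
Passing the detection suite on this generator therefore demonstrates the
mechanics of the modulus-pair detector (thresholding, pairing, refractory,
delay compensation) under controlled SNR — not clinical-grade performance
on pathological recordings.

## Evaluation statistics

Beat matching is greedy one-to-one nearest matching within ±75 ms (a
common beat-comparison window); Se = TP/(TP+FN), P+ = TP/(TP+FP), error =
(FP+FN)/(TP+FN).  Bland–Altman limits of agreement are ±2·SD of the paired
differences with the sample (n−1) SD.  `align_and_correlate` scans integer
lags within ±max_lag for the maximum absolute cross-correlation of the
mean-removed signals and reports the Pearson correlation (×100) over the
overlap at that lag; positive lag means the second signal trails the
first.

## Problem sizes used by the checks

The acceptance script measures filter cutoffs on an 8192-point grid and
scores detection on 5-minute records (70 ± 5 bpm, 20 dB SNR), five seeds
per rate at 250/500/1000 Hz — about 5200 beats in total, which gives the
worst-lead error a resolution of ~0.3 percentage points per record while
the full run stays in the tens of seconds.  The long-duration property
test uses 7.5-minute records (≥ 500 beats) per rate.

## Known limitations

- The detector never reports beats inside the learning window.
- P1 is integer-sample; at 250 Hz this quantizes RR to 4 ms steps.
- The scale-2 kernel's discrete band sits ~1% above the large-scale limit
  of the wavelet family; sub-percent agreement with a specific hardware
  implementation's small-scale recursion is out of reach without that
  implementation.
- The alarm engine models status logic only; the analog lead-off
  excitation and comparator chain are not simulated.
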