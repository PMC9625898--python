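# Methods

This note records the scientific and numerical choices behind the package:
what each stage computes, which parameters matter, what the synthetic
stimuli do and do not emulate, and where results are known to be sensitive
to unprinted implementation details.

## Stimuli and level conventions

All stimuli are synthetic and calibrated in pascals: a level of L dB SPL
means an rms pressure of 20 µPa · 10^(L/20). Calibration is applied before
the raised-cosine ramps, so the steady portion carries the nominal level
exactly and the whole-signal rms differs by at most a few hundredths of a
dB for the default ramps (≤ 10 % of the duration). Click trains use the
peak-equivalent convention of auditory-brainstem-response work: the click
amplitude A = 2√2 · 20 µPa · 10^(peSPL/20) equals the peak-to-peak
amplitude of a sinusoid at the stated SPL (0.1789 Pa at 70 dB peSPL).

The frozen noise is synthesized in the frequency domain — unit magnitude
between the band edges, uniformly random phases from a seeded generator —
so its long-term spectrum is flat by construction and the waveform is
bit-reproducible. The default seed (12345) *defines* the package's
reference noise; "frozen" means the same waveform is reused across
analyses, exactly as a measurement campaign would reuse one noise token.

The three effective chains interpret ±1 Pa as internal amplitudes of ±0.5,
so `run_chain` attenuates inputs by 6 dB once, tracked on the stimulus so a
second application is an error.

What the generators do not emulate: speech or arbitrary audio, free-field
or ear-canal acoustics, and stochastic trial-to-trial variability. Passing
tests therefore demonstrate the deterministic stage behavior of the chains,
not their performance on natural signals.

## Cochlear stage

The place map CF_n = A0·10^(−a·x_n/1000) − A·k (A0 = 20682 Hz,
a = 61.765 m⁻¹, k = 0.85, A = 165.4188 Hz, x_n = 3.74 mm + 0.068 mm·(n−1))
supplies the discrete CFs used throughout; reported CFs are rounded to
integer Hz for display only.

The gammatone filterbank is the all-pole realization: four identical
first-order complex resonators per channel, pole radius set from the
bandwidth parameter b = 1.0186·ERB_N(CF) (the fourth-order gammatone has
ERB = 0.98175·b), output 2·Re(·), per-channel gain pinned to 0 dB at CF.
Its −3-dB (half-power) bandwidth is 0.887·ERB_N analytically. The path is
linear and time-invariant, which the battery verifies through unit I/O
slopes and level-invariant Q estimates.

The broken-stick compressor (the compressive chain) acts on instantaneous
amplitude: identity below the knee, |y| = knee·(|x|/knee)^0.3 above it,
sign-preserving and continuous. The knee is the peak amplitude of a
30-dB-SPL sinusoid after the ×0.5 input scaling; this referent is a package
decision — the source configurations state only a "calibrated knee point
(default 30 dB)".

The middle-ear stage (used by `osses2021`) is a minimum-phase Butterworth
bandpass (2nd order per skirt) matched to the published passband gain and
−3-dB cutoffs. Only those three numbers are contractual; the magnitude
between the cutoffs and the phase are approximations, with consequences
noted below. Group-delay compensation advances each gammatone channel by
its own group delay at CF (integer samples, truncated at signal start).

## IHC and adaptation

IHC transduction is half-wave rectification followed by a cascade of
identical lowpass sections, realized as bilinear-transform digital filters
of the analog all-pole prototypes *without* frequency prewarping, at the
chain sampling rate (48 kHz default). Cutoffs are measured on the digital
cascade at the half-power point (−3.01 dB) by grid evaluation (2·10⁵
points) and linear interpolation. With these conventions the published
cascade cutoffs are reproduced within 0.2 %: 7×1st-order @ 3 kHz → 966.6 Hz,
5×1st-order @ 2 kHz → 770.6 Hz, one 2nd-order section @ 1 kHz → 643.2 Hz
(the analog closed form fc·√(2^(1/N)−1) warped through
f → (fs/π)·atan(πf/fs)).

Adaptation loops follow the canonical five-loop formulation: each loop
divides the signal by a first-order-lowpass-filtered copy of its own output
(time constants 5/50/129/253/500 ms), so a stationary input v settles at
v^(1/32) — nearly logarithmic compression — while fast fluctuations pass
roughly linearly. Overshoots are limited to `overshoot_limit` times each
loop's steady-state output through the standard soft (logistic) limiter
(limit 10 for `dau1997`, 5 for `osses2021`); inputs are floored at the rms
amplitude of a 0-dB-SPL tone in the internal convention (10⁻⁵). The output
is affinely mapped to model units (MU): silence → 0 MU, stationary unit
amplitude → 100 MU. None of these constants was fitted here, and the
configuration reproduces the published onset behavior exactly: the 4-kHz
onset response saturates at 1443 MU above 50 dB SPL, with 1440.2 MU at
70 dB. The lightweight alternative (`king2019`) is a first-order 3-Hz
highpass with its −3-dB point placed exactly.

AC/DC analysis measures V_AC = V_peak,max − V_peak,min and
V_DC = (V_peak,max + V_peak,min)/2 − V_rest over a steady-state window that
excludes the ramp plus 20 ms after onset (the onset-exclusion length is a
package choice; the source procedure does not print one). A structural
consequence worth stating: for a half-wave-rectified, lowpass-filtered
output with positive impulse response and V_rest = 0, the waveform is
nonnegative, hence the ratio V_AC/V_DC ≤ 2 identically. The measured
low-frequency ratios of the 1-kHz-lowpass chain sit at 1.94–2.00, below the
2.1–5.9 band that summarizes the spread of *all* model families in the
source comparison; that band is not reachable by this model class, and the
corresponding acceptance assertion is intentionally left failing. The
high-frequency anchor is reproduced: ratio 0.80 at CF 4013 Hz for an 80-dB
tone (published 0.83, tolerance ±0.05), and ratios decrease monotonically
with frequency above 833 Hz.

## Subcortical stage

The narrow modulation filterbank places resonators so adjacent filters
intersect at their −3-dB points; for constant Q this fixes the
center-frequency ratio at (2Q+1)/(2Q−1) = 5/3 for Q = 2, giving centers
10, 16.7, 27.8, 46.3, 77.2, 128.6, … Hz. The single-filter mode used by the
MTF and click experiments picks the filter nearest 80 Hz (77.16 Hz). The
wide bank (Q = 1) spaces centers geometrically by half a bandwidth (50 %
overlap) downward from 120 Hz. Each resonator is one complex pole with
radius exp(−π·BW/fs), unity gain at its center. Filters with BMF ≥ 10 Hz
return 2·|complex output| — phase-insensitive envelope ("venelope")
processing, nonnegative by construction; lower filters return the signed
2·Re(·). The factor 2 restores real-signal amplitude in both modes; with it
the click-train peak-to-peak amplitudes of the `dau1997` chain come out at
402/435 MU against the published 407.3/437.4. A single complex pole passes
a steady input at about −12 dB re its center gain (the venelope of a
constant is constant), which is shared with the published realization as
far as the reproduced click amplitudes indicate.

SFIE cells compute excitation minus delayed, scaled inhibition, both as
convolutions with unit-area alpha kernels t·e^(−t/τ)/τ² (digital: bilinear
transform of 1/(1+sτ)²; delay rounded to samples). Unit-area normalization
makes each excitatory branch unit-DC-gain, so the cell's modulation tuning
is fully determined by (τ_exc, τ_inh, D, S) — the only printed parameters.
Half-wave rectification after the subtraction is the default; population-
response use runs without it. The analytic best modulation frequency
(argmax of |H_CN·H_IC| on a 1-Hz grid refined to 0.1 Hz over 1–500 Hz)
agrees with time-domain simulation to within the grid step.

**Known discrepancy.** With the published parameters, the analytic cascade
peaks at 81.6 Hz (CN 0.5/2 ms, D = 1 ms, S = 0.6; IC 0.5/2 ms, D = 2 ms,
S = 1.5; published 82.4 Hz) and 87.2 Hz (IC 1.11/1.67 ms, D = 1.1 ms,
S = 0.9; published 83.9 Hz). No construction we tested — kernel orders 1–3,
delay measured to kernel onset or peak, IC stage alone, discrete-time
kernels at 20/48/100 kHz, rectified time-domain simulation at several
modulation depths and response metrics — reproduces both printed values;
notably, the IC stage alone with the second parameter set peaks at 85.3 Hz,
matching the *other* value (85.4 Hz) printed elsewhere in the same source
for the same configuration. The printed BMFs are citations to earlier
papers whose computation is not specified. The package keeps the principled
construction and reports its own values; the acceptance test against the
printed pair fails and is left failing.

## Evaluation procedures

* **Reference gain.** Output levels are rms dB re the chain's internal
  unit, shifted so the on-CF response to a 1000-Hz, 100-dB-SPL tone sits at
  100 dB. Steady-state windows cover the final half of a tone excluding the
  offset ramp. Excitation patterns, I/O points and Q-estimation responses
  from the same chain and stimulus agree to numerical precision.
* **Q estimation.** Per channel, output magnitude spectra of six
  non-overlapped 500-ms windows of the 3-s frozen noise are averaged,
  smoothed by a 1/16-octave moving average, and the half-power points
  interpolated. The smoothing width is the one genuinely open parameter:
  six-average periodograms fluctuate by ~1.8 dB, and wider smoothing
  (e.g. 1/6 octave) inflates measured bandwidths well beyond the published
  0.903 ERB_N. At 1/16 octave the widening bias on the known gammatone is
  ~0.5 % (measured 0.89 vs 0.887 ERB_N analytic).
* **Filter counting.** Greedy covering of 126–8000 Hz: the first filter is
  *centered* at 126 Hz (126 Hz is itself a place-map CF, section 396), each
  next center is placed so its lower half-power edge meets the previous
  upper edge (Q interpolated log-log between measured CFs), and the filter
  that first reaches 8000 Hz is counted. The linear chain yields 34 filters
  with mean bandwidth 0.891 ERB_N at both 40 and 100 dB; the covering span
  is ≈ 33.5 filter widths, so the integer count sits near a discretization
  boundary and is stable only because the frozen noise is fixed.
* **Rate-level.** 4-kHz, 300-ms tone (2.5-ms ramps) after 50 ms of silence;
  onset = response maximum, steady = mean over 300–340 ms of the trace.
* **Synchrony capture.** Complex tone 414/650/1000 Hz at 50 dB SPL, seven
  channels at place-map sections 320…245 (≈ 1-ERB_N spacing, 415–1007 Hz),
  3 on- and 4 off-frequency. Envelopes connect local maxima above the
  channel's post-onset mean within 220–250 ms, interpolated piecewise-
  linearly on the sample grid; metric = std(envelope)/(scale/30) with
  scale 800 MU for adaptation-loop chains. Fewer than two qualifying
  maxima → metric 0.
* **MTF.** 300-ms AM tones (m = 1, 5-ms ramps) at 30 dB SPL, rates
  10–130 Hz step 5; metric = max of the on-CF stage-6 output in 190–290 ms,
  normalized to the sweep maximum. The linear chains peak at 70 Hz: the
  modulation filter sits at 77.16 Hz but the gammatone attenuates the AM
  sidebands increasingly with rate. All chains are bandpass at 30 dB.
* **Clicks.** 1-s alternating train, 10 Hz, 100-µs clicks, 70 dB peSPL;
  stage-6 outputs averaged unweighted across the default 31-channel grid
  (1-ERB_N spacing, 80–8000 Hz); peak-to-peak measured in 50-ms windows
  after the 9th (+A) and 10th (−A) click onsets. The `dau1997` amplitudes
  reproduce the published pair within 1.3 % and the −A > +A ordering holds
  for `dau1997` and `king2019`. For `osses2021` the published ordering is a
  0.9 % effect; under our middle-ear approximation it reverses by a similar
  margin (and moves either way under zero-phase or no-middle-ear variants),
  so that sub-assertion fails and is documented rather than adjusted — the
  ordering is not identifiable from the printed filter constraints.

## Problem sizes and determinism

Default sampling rate 48 kHz (the Nyquist must exceed the highest CF
analysed; the source is silent on the rate for these chains). The battery
uses 31-channel grids, 3-s noise, 1-s click trains and ≤ 0.5-s tones; the
full battery for one chain completes in a few seconds on one CPU. All
computations are deterministic given the stimulus arguments; the only
random object is the frozen-noise phase draw, fixed by its seed.

## Known limitations

* The middle-ear filter matches only passband gain and cutoffs; absolute
  waveform shape and sub-1 % polarity effects that depend on the published
  stapes FIR are outside its accuracy.
* Adaptation-loop constants are the canonical defaults, not refit; MU-
  anchored comparisons carry ±10–15 % tolerances where the source relies on
  unprinted constants.
* Transmission-line and chirp-filterbank cochleae, diffusion/power-law
  synapses, spike generation, fibre-population weighting and hearing-
  impaired configurations are out of scope; properties quoted for those
  families are covered only insofar as shared components (IHC cascades,
  SFIE, place map) reproduce them.
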