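# Methods

## Signal model and processing chains

A chest-worn IMU measures two mechanical signatures of cardiorespiratory
activity. Heart ejection launches compression waves that appear as short
(~100 ms) vibration packets with energy concentrated in 10–40 Hz, on both
the accelerometer (seismocardiogram) and the gyroscope (gyrocardiogram).
Breathing superimposes a slow oscillation at the respiratory rate
(0.1–0.7 Hz for 6–42 breaths/min) from chest-wall expansion. One axis per
sensor carries most of this content — dorso-ventral acceleration (z) and
the y angular-velocity axis — and the pipeline analyzes only those two
channels.

The pipeline is purely spectral: no beat fiducials are ever detected.
The cardiac chain converts the packet train into a near-periodic wave
whose fundamental is the beat rate:

1. **Wavelet band reconstruction, 10–40 Hz.** A continuous wavelet
   transform with an analytic Morlet (`cmor1.5-1.0`, 16 voices/octave) is
   inverted over only the scales whose centre frequencies lie in the
   band (single-integral reconstruction, Re W(s,t)/√s summed over log-
   spaced scales). Because each voice has a Gaussian frequency response,
   out-of-band tones are suppressed far more strongly than a low-order
   band-pass could (a 5 Hz tone passes ~50× weaker than through the
   order-1 Butterworth alternative, and a 0.25 Hz respiratory tone is
   attenuated below 3 %). The composite operation is linear and
   time-invariant, so its gain is calibrated once per signal geometry by
   passing a probe tone at the band's geometric centre (√(10·40) = 20 Hz)
   and scaling to unit throughput; tones at the band edges sit at roughly
   half gain, which is immaterial to peak *location*.
2. **Normalization** to unit maximum absolute value. Dominant-frequency
   estimation is scale-invariant, so this stage only standardizes
   amplitudes for inspection; a property test asserts the downstream rates
   are identical with or without it.
3. **RMS envelope, 40 samples** (333 ms at 120 Hz), centred with edge
   shrinkage, turning each packet into one smooth bump per beat.
4. **Band-pass 0.7–3 Hz** (42–180 bpm), first-order Butterworth.

The respiratory chain is a single first-order Butterworth band-pass at
0.1–0.7 Hz on the selected axis. Reference channels get the matching
filter at their native rates — ECG (250 Hz) through 0.7–3 Hz, respiration
belt (25 Hz) through 0.1–0.7 Hz. No stream is resampled; each is analyzed
on its own frequency grid.

All filters are digital Butterworth designs (bilinear transform at the
signal's own rate) applied forward–backward. Zero-phase filtering is a
package choice: peak-frequency estimation is phase-insensitive, but it
keeps mechanical and reference series time-aligned so paired windows
describe the same instants.

## Sliding-window rate estimation

Signals are segmented into fully contained L-second windows advanced 1 s
at a time (T − L + 1 windows for a T-second posture segment; six lengths
L ∈ {5, 15, 25, 35, 45, 55} s). Each window receives a single-segment
Welch estimate: Hamming taper over the whole window, 0 % overlap (which
degenerates to a modified periodogram), mean removal per segment to keep
DC leakage away from the 0.1 Hz respiratory edge. The taper choice is a
common default; peak location for well-separated spectral lines is
taper-insensitive.

The PSD is evaluated on a grid with fixed spacing Δf = 0.01/60 Hz
(0.166 mHz ≈ 0.01 bpm), i.e. the zero-padded DFT with
NFFT = round(fs/Δf): 720 000 points at 120 Hz, 1 500 000 at 250 Hz,
150 000 at 25 Hz — the same physical grid for every window length and
stream, which is what makes estimates comparable. Materializing such
transforms per window would be wasteful, so in-band estimation evaluates
exactly those DFT bins restricted to the physiological band through the
chirp-z transform (`scipy.signal.ZoomFFT`); a test asserts bin-for-bin
agreement with the explicit zero-padded `scipy.signal.welch` path, which
remains available via `welch_psd(..., band=None)`.

The rate is 60 × the in-band argmax frequency. The argmax is taken raw on
the fine grid (no quadratic interpolation — the 0.01 bpm grid already
exceeds the needed precision) and ties resolve to the lower frequency.
One caveat quantified by the tests: at L = 5 s the Hamming main lobe is
~0.26 Hz wide and interference from the negative-frequency image can
displace the peak of a pure tone by a few millihertz (~0.1 bpm); from
15 s upward the peak is grid-bin exact.

**Invalid estimates.** A window with zero total or zero in-band power
yields no rate (NaN, flagged invalid). For respiratory series an
additional amplitude gate applies when the raw (unfiltered) reference
respiration trace is supplied: windows in which its power falls below
10⁻⁶ of the whole-recording power are invalid. The gate is applied to the
raw trace rather than the filtered one because a zero-phase IIR band-pass
rings for several seconds into a breath-hold, so the *filtered* signal
inside an apnea is dominated by its own transient — spectrally plausible,
physiologically meaningless. Invalid windows are excluded pairwise from
all agreement statistics, and exclusion counts are reported per group.

## Agreement statistics

For each (vital, sensor, posture, window length), estimates from all
subjects' windows are pooled: MOD = mean(est − ref), limits of agreement
MOD ± 1.96·SD with the n−1 sample SD, and MAE = mean |est − ref|; a
per-subject MAE table mirrors the cohort breakdown. Sliding windows
overlap heavily, so consecutive differences are strongly serially
correlated; no repeated-measures correction is applied — the LOA describe
the pooled spread of window-level differences, not an inferential
confidence interval. Swapping the two methods negates MOD, mirrors the
LOA and preserves MAE (tested), and MAE ≥ |MOD| always.

## Synthetic cohort generator

The generator emulates the structure the estimator relies on, not SCG
morphology:

- **Protocol**: sitting, standing, lying segments of 120 s, each ending
  with a 20 s breath-hold during which the respiratory oscillation
  amplitude is zero (0.5 s half-cosine on/off ramps placed inside the
  hold so breathing segments are untouched).
- **Trajectories**: per-subject seeded slow sinusoids sampled to 1 s
  piecewise-linear tables — HR baseline 66–74 bpm, swing 4–6 bpm, period
  60–120 s (range 60–80 bpm); RR baseline 12–18 BrPM, swing 1.5–3 BrPM,
  period 45–90 s (range 9–21 BrPM): normocardic, eupneic adults at rest.
- **Beats**: the cumulative beat count is the integral of HR(t)/60;
  beats fall at integer crossings, with the first beat at a seeded random
  phase so packets never align artifactually with window boundaries.
- **Cardiac packets**: Gaussian-windowed 20 Hz cosines, σ = 22 ms,
  support ±60 ms (packet duration 120 ms). The width keeps ≥ 95 % of
  packet power inside 10–40 Hz; a noticeably shorter packet at the same
  carrier would leak appreciable energy below 10 Hz.
- **Reference**: an ECG-like train of sharp Gaussian spikes (σ = 8 ms) at
  the same beat instants, and a respiration-belt sinusoid sharing the
  breathing phase; both clean by default (the reference is treated as
  gold standard; optional seeded noise is available).
- **Channels**: acc-z carries (cardiac, respiratory) amplitudes
  (1.0, 0.8) and gyr-y (0.9, 1.0); the four non-analysis axes carry 0.3×
  attenuated copies plus independent noise, enough to make axis selection
  testable without pretending to biomechanics.
- **Posture** enters only through broadband noise SD — lying 0.05,
  sitting 0.10, standing 0.30 in packet-amplitude units. No quantitative
  per-posture SNR is available to match, so these values are chosen once
  to reproduce the qualitative ordering (standing degrades accuracy),
  not any particular error magnitude.
- **Determinism**: all randomness derives from one integer seed through
  independent spawned streams (traits, phases, mechanical noise,
  reference noise), so identical (protocol, seed) reproduces every sample
  bit for bit regardless of call order.

What the generator does *not* model — SCG fiducial morphology (MC/AO/AC/MO
peaks), motion artifacts, sensor drift, respiratory sinus arrhythmia,
cardiac amplitude changes during breath-holds, inter-axis cross-talk
physics — bounds what passing tests show: they validate the estimation
pipeline under its stated spectral assumptions, not performance on real
recordings of ambulatory subjects.

## Numerical and design choices

- **Window counts**: T − L + 1 windows per T-second segment (96 at
  L = 25 s, 116 at L = 5 s per 120 s posture), with mechanical and
  reference streams sharing window centres exactly; on CSV ingest,
  near-integer sampling rates are snapped to the integer they encode so
  sample counts stay consistent across streams.
- **Degenerate inputs**: all-zero signals are rejected by `normalize`,
  produce zero PSDs in `welch_psd`, and flagged-invalid rate series in
  `extract_rate_series`; windows longer than a segment are skipped with a
  warning rather than erroring the whole run.
- **Test problem sizes**: the cohort fixtures use 5 subjects × 120 s
  sitting segments for error bounds and 3 subjects × 3 postures for the
  end-to-end determinism replica — large enough that every pooled group
  holds hundreds of window pairs, small enough to keep the suite quick.
- **Smoothing vs. responsiveness**: with argmax peak-picking, a step
  change in HR flips the estimate abruptly once the window majority
  covers the new rate (the switch is a symmetric "majority vote" at the
  window centre), so step-transition width is not a useful smoothing
  metric. The smoothing that longer windows actually buy shows up as
  reduced window-to-window fluctuation, and that is what the tests
  assert: mean |Δ estimate| between consecutive windows decreases
  monotonically from 5 s to 25 s to 55 s for both vitals.

## Known limitations

- In-band argmax performs no harmonic disambiguation; it is safe here
  because the envelope's fundamental dominates, but real SCG envelopes
  with strong second harmonics could flip to double the rate.
- Windows partially overlapping a breath-hold are kept (only fully
  breath-held windows fail the amplitude gate); their estimates derive
  from a truncated oscillation and carry extra error that is genuinely
  part of the protocol.
- The LOA are descriptive for overlapping-window data, as noted above.
- Error magnitudes on the synthetic cohort reflect the generator's noise
  model and should be read as validation of the machinery, not as
  predicted clinical accuracy.
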