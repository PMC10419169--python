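# Methods

`swdscope` analyzes spike-wave discharges (SWDs) — the EEG hallmark of
absence seizures — in rodent cortical recordings, and ships a synthetic-EEG
generator so every estimator can be validated by parameter recovery against
known ground truth rather than against expert annotation. This note explains
the models, the parameters that matter, and the choices made where the
underlying procedures are conventionally described only qualitatively.

## Synthetic EEG model

### Background

Resting EEG is modeled as first-order autoregressive noise, `x[t] =
0.95·x[t−1] + ε[t]`, mean-removed and rescaled to an exact target RMS
(default 50 µV). The AR(1) pole gives the falling ("1/f-like") spectrum
characteristic of cortical background without claiming any biophysics. A
zero RMS produces a silent trace, which is useful for degenerate-input
tests.

### Discharge waveform

Each spike-wave cycle of period `T` is a piecewise sum of shaped pulses laid
out over the cycle, mirroring the classical morphology labels (positive
transient early, spike, positive transient late, wave):

| component | shape | position (fraction of `T`) | amplitude |
|---|---|---|---|
| PT early | Gaussian bump | 0.06 ± 0.02 | +0.08·A |
| spike | Gaussian, σ = 6 ms (fixed in seconds) | 0.14 | −A |
| PT late | Gaussian bump | 0.22 ± 0.02 | +0.07·A |
| wave, negative lobe | half-sine | 0.30–0.62 | −0.40·A |
| wave, rebound | half-sine | 0.66–0.94 | calibrated |

`A` is the configured spike amplitude (default 900 µV, the scale of
vehicle-condition discharges; atypical discharges use ~3000 µV). The spike
width is fixed in seconds so spikes stay sharp even in slow cycles. After
rendering, the whole segment is rescaled so that the spike-peak deviation
**from the event median** equals `A` exactly — the same baseline the
morphology estimator uses, which makes amplitude recovery well defined.

The cycle rate settles linearly from `fundamental_start_hz` (default
9.5 Hz) to `fundamental_steady_hz` (default 7.5 Hz) over the first second.
This reproduces the decreasing time-frequency ridge seen in wavelet
spectrograms of real discharges without asserting its exact law. Because
the cycle waveform is strongly non-sinusoidal, its Welch spectrum carries
power at the fundamental and its harmonics — the package's spectral tests
verify peaks at 7.5, 15 and 22.5 Hz for a steady train.

### Asymmetry: definition and calibration

The asymmetry index is the share of the negative-polarity component of a
discharge in its total deflection, in percent:

    AI = 100 · A⁻ / (A⁻ + A⁺),

with `A⁻`/`A⁺` the integrated unsigned areas below/above a polarity
baseline. **The baseline is the event median, not the event mean.** Signed
areas about the sample mean cancel identically for any signal, so a
mean-referenced area index would equal 50% for every event; the median
preserves the intended invariants (a pure sinusoid scores 50, flipping
polarity maps `x → 100 − x`, the index is amplitude-scale invariant) while
remaining robust to slow drift and non-degenerate for asymmetric trains.

The generator imposes a target asymmetry exactly by solving for the rebound
amplitude with a 1-D root find (Brent's method) against the package's own
estimator on the clean segment. Targets roughly in [0.4, 0.95] are
attainable with the default component geometry; outside that range the
solver raises rather than silently clamping. Ground-truth annotations store
the *measured* asymmetry of the rendered segment (exact to the calibration
tolerance, 0.01 percentage points).

### Variants

* **mature** — spike and wave in every cycle.
* **immature** — exactly 40% of cycles lose their sharp spike and only 50%
  keep a wave (random subsets). The fractions operationalize a qualitative
  description ("fewer sharp spikes, irregular presence of a wave") and are
  package conventions, not measured quantities.
* **fused** — mature sub-trains of 3–6 s separated by 0.3 s pauses,
  annotated as a single long event; with long durations this reproduces the
  ~100 s merged discharges seen under seizure-aggravating treatment.
* **atypical** — a three-part, ~3000 µV discharge: spikes-only onset
  (quarter of the duration), a 2.5 Hz inverted-polarity middle (half), and
  a 0.8 Hz terminal part. Atypical discharges are built with a fixed
  near-symmetric rebound ("poorly expressed asymmetry") and skip the
  asymmetry calibration.

### Session assembly

Within an event interval the discharge waveform *replaces* the background
rather than adding to it: a discharge dominates the trace, and replacement
keeps every ground-truth parameter exact inside the event. Event onsets are
drawn uniformly over the feasible set by the spacings construction: the
slack remaining after subtracting event durations and mandatory gaps
(`min_gap`, default 2 s, also enforced at the session edges) is split by
sorted uniform draws. This samples the same distribution a rejection
sampler would target but cannot fail; genuinely infeasible requests raise
`PackingError` up front. All randomness derives from a single seed through
`numpy` seed sequences, so identical configs give bit-identical sessions.

Default study conditions: 300 s sessions at 400 Hz with 10 discharges of
2–8 s. The sampling rate is a package choice (the recording hardware's rate
is not part of the analysis definition): 400 Hz resolves the 6 ms spikes
comfortably while keeping a session at 120k samples. The 300 s length keeps
discharge occupancy near 15–20%, inside the robustness envelope of the
baseline estimator (below).

## Detection

The criterion — trains lasting ≥ 1 s with amplitude at least two-fold the
baseline EEG — is operationalized as:

1. **Envelope**: rectified trace smoothed with a 50 ms moving average. The
   window bridges intra-cycle zero crossings so a 7–8 Hz train forms one
   suprathreshold interval, but keeps edges within tens of milliseconds.
2. **Baseline**: the median over non-overlapping 1 s windows of the
   window-wise envelope peak. "Baseline EEG amplitude" has no standard
   quantitative definition; the median window-peak is used because events
   occupying a minority of the recording shift only the upper tail of the
   window-peak distribution. Measured on the default conditions, adding one
   900 µV discharge covering 5% of a session moves the estimate by well
   under 10%. The estimator degrades once events occupy roughly a third of
   the recording — dense recordings need a longer session or an external
   baseline. A flat recording yields a zero baseline flagged degenerate
   (and no detections).
3. **Thresholding**: maximal intervals with envelope above
   `threshold_factor × baseline` (default 2), gaps up to `merge_gap`
   (default 0.5 s) closed, intervals shorter than `min_duration` (1 s)
   discarded. The 0.5 s merge keeps single discharges whole across wave
   troughs while leaving genuinely separate discharges (≥ 2 s apart by
   construction) distinct.

Detected events use seconds from recording start and half-open
`[onset, offset)` intervals everywhere. Against ground truth, matching is
greedy one-to-one by interval overlap; precision = matched/detected,
recall = matched/true. Under the default conditions (20 seeded sessions,
10 events each, spike peaks 18× the background RMS) the detector attains
precision = recall = 1.0 with onset errors ~5 ms and offset errors ~60 ms
(the final low-amplitude rebound falls below threshold slightly before the
true cycle end).

## Morphology

* **Spike picking**: the event is split into a slow wave (60 ms moving
  average) and a sharp residual; spikes are peaks of the rectified residual
  exceeding 2× the wave scale (median absolute wave amplitude), at least
  60 ms apart — below one 8 Hz cycle, above a spike width, so PT shoulders
  are not double-counted. Each peak is snapped to the raw extremum within
  ±10 ms so the amplitude is read at the actual spike tip. Amplitude is the
  unsigned deviation from the event median. A pure sinusoid has no sharp
  residual and yields zero spikes.
* **Mean amplitude** is the arithmetic mean over all spikes of the event
  (empty spike lists are an error at this level; the aggregate
  `analyze_event` reports the mean as absent instead).
* **Maturity**: immature iff the spike rate falls below 0.75× the nominal
  cycle rate (7.5 Hz) **or** a wave is detected in fewer than 70% of
  inter-spike intervals. Wave presence uses a lightly smoothed (20 ms)
  trace with 40 ms margins around the spikes, requiring a dip below 25% of
  the mean spike amplitude; heavier smoothing would wash out the ~40 ms
  wave lobe. All thresholds are configurable; the defaults classify
  generated mature/immature events with ≥ 90% accuracy (100% on the seeded
  suite).

## Spectra

Welch PSDs use Hann windows of fixed 2 s length with 7/8 overlap, one-sided
density scaling (µV²/Hz) and per-window mean removal; the bin spacing is
exactly `1/window_length` = 0.5 Hz. Segments shorter than one window raise
an error rather than being zero-padded. The default analysis band is
0–25 Hz. Averaging is pointwise over identical grids with segment counts
summed. Integrated PSD tracks signal variance within 10% (Monte-Carlo
checked).

Morlet spectrograms use the PyWavelets complex Morlet (`cmor1.5-1.0`:
bandwidth 1.5, center frequency 1.0 — about six oscillations under the
envelope at each analysis frequency) on a 0.25 Hz grid over 1–25 Hz, with
scales `f_c · f_s / f`. The per-time argmax ridge is exposed for
diagnostics; it is flat for steady tones, decreases monotonically for a
10→7 Hz chirp, and settles nowhere on white noise.

Background (interictal) segments for spectral comparison are 8–10 s
stretches at least 2 s away from every event boundary, packed for maximal
coverage: the fewest equal segments that cover a free interval with sizes
in [8, 10] s, falling back to 10 s blocks when full coverage is impossible
(a 60 s event-free minute yields six 10 s segments).

## Group statistics

Per-frequency group comparison uses the two-sided Mann–Whitney U test at
every bin of the common grid, Bonferroni-adjusted with factor
`n_frequencies × n_comparisons`. With the 0.5 Hz grid's 52 analyzed
frequencies and a 4-stage pairwise design's 6 comparisons the factor is
312. `n_comparisons` is a required input: it encodes the experimental
design and is never inferred from the data. Adjusted p-values are
`min(1, factor · p)`; under a global null (identical gamma-noise groups,
n = 25/25, 52 bins, factor 312, 1000 replicates) the measured family-wise
error is below 1%, comfortably under the nominal 5%.

The Mann–Whitney implementation delegates to `scipy.stats`: the exact null
distribution for total N ≤ 20 without ties, the tie-corrected
continuity-corrected normal approximation otherwise. Tests verify the
exact branch against full enumeration of group splits for N ≤ 14.
Kruskal–Wallis and one-way ANOVA likewise wrap scipy; ANOVA is verified
against direct sums-of-squares computation to 10⁻¹⁰ relative error, and a
zero within-group variance raises a degenerate-data error instead of an
infinite F. Multi-group stepdown post-hoc procedures (Newman–Keuls) are
out of scope; pairwise tests with explicit Bonferroni factors are provided
instead, because two-group designs make stepdown ordering redundant and
its tie-breaking rules are not reconstructible from qualitative
descriptions.

Percent-of-control is `100 · drug_mean / vehicle_mean` rounded half-up to
one decimal — the rounding that reproduces published forced-swim
percentages from their printed group means. Monoamine turnover is the
metabolite/parent concentration ratio per sample, with group summaries as
the mean of per-sample ratios (which is why a printed group ratio need not
equal the ratio of printed group means).

## Synthetic data: what passing tests do and do not show

The generator reproduces the *features the estimators key on*: amplitude
ratios, durations, gap structure, cycle rates, spectral harmonics and area
asymmetry. It does not reproduce artifacts (movement, electrode pops),
non-stationary background (sleep spindles, theta), inter-animal
variability, or any biophysics of the thalamocortical loop. Passing the
recovery suites therefore shows the estimators are *correct
implementations of their definitions* and robust at realistic SNR — not
that they match a human expert on real recordings with artifacts.

## Numerical choices and problem sizes

* Calibration root-find tolerance 10⁻⁴ in rebound scale (≈ 0.01 points of
  asymmetry).
* EDF export quantizes to 16 bits over a symmetric ±`physical_max` range
  (`physical_max` = the ceiled absolute signal maximum), giving a step of
  `physical_max / 32767` ≈ 0.03 µV at 1000 µV; one-second data records,
  last record zero-padded.
* The test and acceptance suites use 20 sessions × 300 s for detection,
  6 × 10 seeded sessions for the asymmetry grid, 30 s trains for harmonic
  structure, and 1000 Monte-Carlo replicates for family-wise error — sizes
  chosen so the full suite completes in about a minute on one CPU while
  keeping Monte-Carlo noise well inside the asserted margins.

## Known limitations

* The baseline estimator assumes discharges occupy ≲ 20–30% of the
  recording (see above).
* Atypical discharges, with their < 1 Hz terminal cycles, can split into
  multiple detected events under the default 0.5 s merge gap; detection
  quality targets are defined for mature-type discharges.
* The exact Mann–Whitney branch requires tie-free data; ties switch to the
  asymptotic approximation regardless of sample size.
* The "sensitive"/"insensitive" responder subgrouping seen in treatment
  studies has no stated quantitative criterion; the package takes any such
  partition as user input rather than inventing one.
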