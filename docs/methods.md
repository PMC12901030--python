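# Methods

`attnrhythm` reconstructs where and how strongly covert spatial
attention is deployed among three peripheral stimuli from multichannel
sensor recordings, detects discrete attentional events, quantifies
their rhythmicity, and relates them to oculomotor behaviour.  Every
stage is paired with a synthetic-session generator that plants known
dynamics, so the pipeline is validated end to end by parameter
recovery rather than by inspection.

## Inverted encoding model

Sensor data are modelled as a weighted sum of three angular information
channels plus noise, `X = W C + N`.  Channel *k* has a half-wave
rectified sinusoidal tuning curve

    f(θ, μ_k) = |cos^α(0.5 (θ − μ_k) π / 180)|,   α = 5,

with preferred angles μ = 0°, 120°, 240° (0° up, counter-clockwise
positive, so 90° points left).  On localizer epochs — exactly one
position stimulated per trial — both `X` (averaged over the training
window) and the design `C` are known, and the weights are estimated per
channel by the marginal least-squares estimator

    w_k = X c_kᵀ (c_k c_kᵀ)⁻¹.

This is deliberately the per-channel (marginal) regression, not the
joint multichannel solution; the joint pseudoinverse
`W = X Cᵀ (C Cᵀ)⁻¹` is available behind `fit_weights(..., joint=True)`
for comparison, since with correlated design columns the two differ.

Because neighbouring sensors are not independent, each `w_k` is
pre-whitened with the channel's residual covariance `E_k` (estimated
from `ε_k = X − w_k c_k`):

    g_k = E_k⁻¹ w_k (w_kᵀ E_k⁻¹ w_k)⁻¹,

which enforces `g_kᵀ w_k = 1` exactly.  `E_k` is regularized by
shrinkage toward its diagonal with the analytic squared-loss-optimal
intensity (the standard ratio of the summed sampling variance of the
off-diagonal entries to their summed squared magnitude, clipped to
[0, 1]).  This diagonal-target shrinkage is implemented in the package
because the widely available Ledoit–Wolf routine shrinks toward a
scaled identity instead.  Decision epochs are decoded per sample as
`C = Gᵀ X`, with no temporal smoothing.

The training window is chosen by leave-one-block-out cross-validation
over candidate windows; the held-out score is the decoded response of
the true channel minus the mean of the off-channels (the underlying
study does not print its score formula; this difference score is the
package's documented substitute).  Ties break toward the earlier
window.  Localizer trials with a detected (micro)saccade in the first
200 ms, and flicker-task trials, are excluded from training.

## Attentional vector

The three decoded channel responses are summed as planar vectors along
their target directions.  Vector length indexes attention strength;
the angle indexes the attended locus; the maximum angular similarity
(MAS) is the largest cosine between the angle and the three targets
(minimum 0.5, attained exactly midway between two targets).  Channel
responses enter signed — a negative response pulls the vector away from
its target; no rectification is applied because the decoding model
makes no positivity guarantee, and the readout should not hide that
(a `rectify` flag exists for sensitivity analysis).  Angles are
reported as NaN when the vector length is below 1e−12.

## Spectral analysis of attention strength

Band-limited fluctuations of the vector length are computed with a
Butterworth/Hilbert filterbank: 4th-order band-passes at quarter-octave
centers 2^1.5 … 2^6.5 Hz (2.83–90.5 Hz), passband = center × 2^±0.5,
applied forward–backward (zero phase).  Zero-phase filtering is chosen
so that event-aligned analyses carry no group delay; the effective
order doubles.  The amplitude envelope is the magnitude of the analytic
signal; two cycles of the center frequency are trimmed from each trial
edge and propagate as missing values, never as zeros.  Baseline
normalization divides each frequency by its trial-average amplitude in
the 0.5 s before stimulus onset and expresses the ratio in dB; since
these are amplitude (not power) ratios, the convention is 20·log10
(configurable).

Sensor-level time–frequency decomposition uses Morlet wavelets with
bandwidth f/σ_f = 5.83 and the kernel truncated at ±σ_t, scaled so an
in-band unit tone yields a unit envelope.

Correct-vs-error comparisons match trial counts per stratum (unordered
contrast combination × framing): correct trials are subsampled 100
times to the per-stratum error counts, averaged, and compared as
(correct − error)/correct × 100.  Strata with no error trials, or where
errors outnumber correct trials, are dropped and recorded.

## Attentional events

An attentional event is a sample at which the readout is both selective
and strong: MAS above its 90th percentile over all stimulus-on samples
of the whole dataset, and vector length above its 90th percentile
within the trial (the asymmetry — dataset-wide vs within-trial — is
deliberate and follows the method being reimplemented).  The onset is
the first sample at which the conjunction becomes true (rising edge),
or at which the nearest-target locus changes while it remains true;
onsets within 0.025 s of the previous accepted onset are discarded.
Exact MAS ties between two targets resolve toward the previously
attended locus, which is conservative against spurious switches.
Events are labelled stay/switch by comparison with the previous event's
locus within the trial; first-in-trial events carry no sequence label.

Inter-event intervals (IEIs) are collected within trials at per-sample
resolution over 0.025–0.5 s; intervals longer than 0.5 s exist and are
counted in the normalizing denominator but fall outside the displayed
range.  The null model randomizes, at every timepoint independently,
which trials hold an event (a permutation of each column of the
trial × time event matrix), preserving the task-locked event-rate
profile and per-timepoint counts exactly while destroying within-trial
temporal structure; 1000 shuffles is the default.

Modes: the observed-minus-null histogram is z-scored per bin against
the shuffle null, bins not significant one-sided at α = 0.01 are set to
zero, the truncated difference is smoothed twice with a 0.01 s boxcar
(edges padded with the first/last value), and local maxima are
extracted.  Two numerical safeguards are applied, both consequences of
running the procedure on a single session where the reference method
aggregates over participants: (i) a mode must have topographic
prominence of at least 10% of the histogram maximum, because the
per-bin test admits ~α isolated noise bins whose shoulders otherwise
masquerade as modes; (ii) mode latencies are refined by parabolic
interpolation around the peak so the first-to-second-mode *cycle
length* does not carry two full bins of quantization jitter.  The
cycle length is the latency from the first to the second mode.

Second-order sequences classify each interval by the (previous label,
current label) pair; pairs whose earlier event is first-in-trial are
excluded.  Under a phase-resetting rhythm the four classes collapse
onto the first-order histograms; under a free-running rhythm,
repetition classes (stay-after-stay, switch-after-switch) sit at full
cycles while alternations sit half a cycle off — the pipeline
distinguishes the regimes from event statistics alone.

The threshold sweep evaluates all 144 combinations of the percentile
lists {50, 55, …, 95, 97.5, 99} for MAS and length.  Modulation
intensity per cell: log10 of the interval probabilities (zero bins
floored to the smallest observed positive probability), linear detrend,
two passes of a 0.025 s (10-sample) boxcar, local maxima under the same
10%-prominence rule, then the SD of the smoothed detrended values
between the first and second maxima; missing when fewer than two
maxima exist.

Choice regression: for each outcome (H, M, L as chosen-vs-not), a
binomial logit of choice on the six per-trial event counts
({stay, switch} × {H, M, L locus value}).  Constant predictors are
dropped with a warning; on separation or non-convergence a ridge
(L2)-penalized fit is used and flagged, with standard errors reported
as missing.

## Peri-event dynamics

Strength traces are averaged from −0.2 to +0.2 s around event onsets
per label; events whose window leaves the trial are dropped.  The
averaged trace is z-scored over its pooled pre-event (−0.2…−0.03 s)
and post-event (0.03…0.2 s) samples, excluding the ±0.03 s zone whose
by-definition extreme values would skew the normalization.  Peri-event
fluctuation frequencies are the inverse of the latency between the two
detrended/0.025 s-boxcar-smoothed peaks closest to the event, computed
separately pre and post; with fewer than two peaks the frequency is
missing.  Note the boxcar itself nulls frequencies near 40 Hz (its
first zero), bounding what this estimator can recover.  Switch/stay
strength ratios are means over −0.15…−0.05 s (pre) and 0.05…0.15 s
(post) of the raw (un-normalized) event-triggered averages.

## Oculomotor analysis

Gaze velocity is the per-sample Euclidean norm of the first difference
of (x, y) times the sampling rate (a per-axis-maximum alternative sits
behind a flag, the printed rule being ambiguous), smoothed with a
causal one-sided Gaussian kernel of 0.02 s total width (σ = 0.01 s,
truncated at 3σ).  The causal form is a deliberate choice: a symmetric
kernel leaks the velocity spike of a step backwards in time, so the
first suprathreshold sample precedes the actual gaze shift by several
samples; with causal smoothing the first crossing is the step sample
itself.  A saccade is recorded when smoothed velocity exceeds 6× the
within-trial median, with a 0.025 s refractory between onsets.  The
displacement from 0.01 s before to 0.03 s after onset classifies
microsaccades (< 1°); this measurement window is the package's own
definition, the source method giving only the 1° criterion.  Saccade
rate is the cross-trial onset probability per sample times the
sampling rate.

Coupling analyses: event-triggered saccade rates (±0.3 s) per label
minus the trial-shuffle null (events shuffled, labels recomputed after
each shuffle); the proportion of events with at least one saccade in
the 0.3 s before onset; saccade-triggered attention strength
(−0.4…0.8 s) z-scored on the 0.4 s before saccade onset; and IEI
histograms split by whether any saccade onset falls strictly inside
the interval.  Pupil traces are mapped so the pooled 5th/95th
percentiles go to 0/1 (values outside may exceed [0, 1]) and
differentiated by adjacent-frame subtraction.  Blink handling is out
of scope for synthetic gaze.

## Statistics

FDR control is Benjamini–Hochberg step-up (the reference method never
names its FDR variant; BH is the default reading).  Paired t tests are
classical, one- or two-sided; identical inputs return statistic 0, and
constant non-zero differences raise rather than report an infinite
statistic.

## The synthetic-data generator

The generator defines the study conditions the tests and acceptance
checks run under.

**Task design.**  Framing (2) × ordered assignment of 3-of-5 contrast
levels to the three locations (60) × orientation condition (3 identical
+ 6 all-different = 9) = 1080 unique decision trials; localizer blocks
are 90 single-stimulus presentations (3 positions × 3 orientations ×
10 repetitions, one repetition per combination flicker-flagged).

**Forward model.**  Random unit-norm sensor patterns per channel
(default 24 sensors in the analysis drivers) and a random SPD noise
covariance with unit mean diagonal; noise is zero-mean Gaussian,
correlated over sensors through the Cholesky factor and white in time,
scaled by 1/snr.  No 1/f component is added by default: the source
data's sensor-noise spectrum is not characterized, so the generator
exposes covariance structure as configuration rather than asserting a
spectrum.

**Latent attention process.**  A locus (0°/120°/240°) attended at each
moment, with an oscillation of frequency `osc_freq` (default 11 Hz) and
depth `osc_depth` (default 0.5).  Under the phase-locked policy,
refocusing (stay) events occur at oscillation peaks and reorienting
(switch) events at troughs.  With `reset_on_switch=True` (default, the
"reset" regime) the oscillation restarts at every event, so the next
switch candidate is half a cycle and the next stay candidate a full
cycle after the previous event, regardless of history; skipped
opportunities add whole cycles with geometric probability
(`p_event = 0.8` at the first opportunity, ≈ 8.8 events/s).  With
`reset_on_switch=False` (the "follow" regime) events lock to the
absolute peaks and troughs of a free-running oscillation.  The switch
fraction defaults to 0.37.  A "uniform" policy plants homogeneous
Poisson events with random loci for null calibration.  All planted
event trains respect the detector's 0.025 s minimum spacing.

**Sensor drive.**  The attended channel receives
`baseline + 0.5·gain·(1 + osc_depth·cos φ(t))`; unattended channels sit
at `baseline` (a common-mode term that cancels in the vector readout).
From each planted event onset, a 12.5 ms pulse raises the attended
channel to `baseline + 0.5·gain + pulse`, with the pulse amplitude
lognormal around `gain` (σ = 0.2) and the oscillatory part pinned to
its mean for the pulse duration.  Two properties motivate this shape
over a bare continuous oscillation.  First, threshold crossings of a
smooth oscillation lead its peak by a phase-dependent lag, so planted
event times could never be recovered to the sample; a pulse with a
sharp onset can be.  Second, percentile thresholds are degenerate on
near-two-valued signals (rank among numerical ties is noise), and if
pulse height followed the oscillation phase, the within-trial length
threshold would systematically miss trough (switch) pulses and bias
the stay/switch labels; a continuous, phase-independent amplitude
spread makes threshold misses label-blind.  The pre-stimulus period
(1.5 s) carries noise only.

**What the generator does not emulate.**  Real sensor noise is neither
white in time nor stationary; real attentional events have no
square-pulse signature; eye, cardiac and muscle artifacts, head
movement, and volume-conduction structure beyond a static covariance
are absent; the localizer response is a boxcar at a fixed latency
rather than an evoked waveform.  Passing recovery tests therefore
demonstrates the correctness of the analysis logic under the stated
model, not performance on real recordings.

**Gaze.**  Fixational drift is low-pass-filtered Gaussian noise
(5 Hz bandwidth, SD 0.05° by default — a realistic drift amplitude and
timescale; generated with padding so no filter transient leaks into
the trial), saccades are instantaneous steps (0.3–0.8° by default) at
Poisson background times (1.5 Hz) plus, under coupling, a step Δ s
(default 0.15) before a fraction p of switch events; minimum spacing
0.025 s; the pupil is a slow (0.5 Hz) smooth drift.

**Choices.**  The reported choice is the highest-value alternative
with probability 0.45, the most-sampled alternative with probability
0.35, and uniform otherwise — above-chance accuracy (so correct trials
outnumber errors within strata, as required by the stratified
comparison) while event counts retain decision information.

## Problem sizes

Validation runs use sizes chosen to make the statistics decisive at
desk scale: 24 sensors; localizer sessions of 2–18 blocks (180–1620
trials); decision sessions of 20–150 trials for unit tests and 500
trials (snr 1) for the full rhythm-recovery check; 100–300 trials of
event trains for histogram calibration with 100–300 shuffles in tests
(the library default remains 1000 shuffles, used by the analysis
drivers); gaze sessions of 100 trials.  With these sizes the planted
11 Hz rhythm is recovered to one quarter-octave in the strength
spectrum and the stay-IEI cycle length to one sample of 1/11 s.

## Known limitations

* Mode detection on a single session needs the prominence floor
  described above; with across-participant aggregation (also
  implemented via `stats.paired_t` over per-participant histograms) the
  floor is unnecessary.
* The peri-event frequency estimator cannot see frequencies near the
  boxcar null (~40 Hz) and needs two interior peaks per 0.17 s
  interval, bounding it below ~12 Hz from the other side.
* The generator's pulse amplitudes are label-independent by design, so
  the switch/stay strength-ratio analysis measures ≈ 1 on default
  synthetic sessions; the machinery is exercised by planting explicit
  deficits in tests.
* Decoding quality at snr = 1 limits single-event recovery (detections
  are enriched at planted onsets but individual onsets are
  noise-limited); aggregate statistics (spectra, IEI modes) are the
  reliable readouts at that noise level, matching how the method is
  meant to be used.
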