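# Methods

This note documents the models behind `socksig`, the parameters that matter,
what the synthetic generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Signals and conventions

All channels are uniformly sampled single time series (`SignalRecord`):
conductance in μS, PPG in arbitrary units, acceleration in g, temperature in
°C, or raw ADC counts.  Time is in seconds, sample indexing is 0-based, and
intervals are half-open `[start, end)`.  Files are UTF-8 tab-separated text
with a `#`-prefixed JSON header (`rate_hz`, `start_time_s`, per-channel
name/units); floats are written at full precision so round-trips are
lossless.  Printed-value comparisons round half away from zero at the
printed precision (computed decimal-exactly from the shortest float repr,
so 32.355 → 32.36).

## Sensor calibration

The accelerometer transfer is the affine map
`ACC = 2·(ADC − ADC_min)/(ADC_max − ADC_min) − 1` g with the bench-measured
counts `ADC_min = 541`, `ADC_max = 965` as defaults.  The temperature sensor
follows its datasheet constants — 100 mV/°C scale and 0.5 V offset:
`T = (ADC·Vcc/2^n − 0.5)·100` °C with `n = 12` bits.  `Vcc` defaults to
3.3 V, the typical supply of the acquisition hardware; it is configurable
because the value is hardware-specific.  The EDA sensor's counts→μS transfer
is deliberately *not* built in: vendor constants vary, so the pipeline takes
conductance either pre-converted or through a user-supplied affine transfer.
Inverse (encoding) transfers round to nearest and clamp to `[0, 2^n − 1]`,
so a round-trip is exact to within half a quantization step.

Electrode bench arithmetic: per-segment mean/sample-sd/min/max, the overall
mean as the mean of per-segment means, the spread as overall max − min, and
the spread as a percentage of the mean.  The equivalent conductance (mS) and
the percentage are quoted against the mean rounded at printed (2 dp)
precision, matching how bench reports chain their printed values; the
unrounded mean is retained alongside.

## Two-device synchronization

The two acquisition devices are electrically decoupled and share only an
optical trigger: one records the digital drive of an LED, the other the
analog response of a light sensor.  Alignment binarizes both channels at
half-range and takes the lag maximizing their normalized cross-correlation;
the lagging device's records are shifted onto the common clock and both sets
trimmed to the overlap.  A secondary correlation peak within 1% of the
maximum and more than 100 ms away raises an ambiguity warning (regular pulse
trains can alias).  With ≥2 irregularly spaced pulses the planted offset is
recovered to the sample.

## Synthetic data

The generator's defaults are the study conditions the pipeline targets:
300 s recordings at 1 kHz.

**Dual-site EDA.**  Each site is
`tonic level + slow drift + Σ a_k·B(t − t_k) + N(0, σ)` clipped to
`[0, ceiling]`, with values below a configurable sensor floor set to 0 and
every zero run recorded as a saturation interval.  `B` is the Bateman kernel
`e^(−t/τ_d) − e^(−t/τ_r)` normalized to unit peak, τ_r = 0.7 s, τ_d = 2.0 s
(standard SCR shape constants).  Event times follow a homogeneous Poisson
process with a 1 s refractory period, 6 events/min by default.  A fraction
`p_shared` (default 0.7) of hand events re-occur at the foot after a lag
drawn from N(0.41 s, 0.70 s) — hand leading on average, as expected from the
slower foot response; the remaining foot activity is an independent Poisson
stream at the complementary rate.  Hand tonic defaults to 5 μS (typical
palmar level), foot tonic to 1 μS (the medial arch runs far lower, which is
what makes foot saturation common); the sensor ceiling defaults to 25 μS.
The drift is a random walk sampled on a 20 s knot grid, interpolated and
rescaled to a total sd (default 0.3 μS): tonic level must wander slowly, and
a naive white-noise walk at the sample rate carries second-scale power that
masquerades as small SCRs.  Saturation is exposed both as floor-clipping and
as an all-zero channel (`all_zero_foot`), because a fully null foot record
is equally consistent with low conductance below the floor and with an
open-circuit contact; the generator does not assert which is physiologic.

**PPG.**  Beats are laid down with inter-beat intervals `60/N(HR, σ_HR)`
truncated positive; each beat contributes a systolic Gaussian lobe
(σ = 80 ms) plus a delayed (350 ms), smaller (45%) diastolic lobe (σ =
120 ms), producing the systolic peak / dicrotic notch / diastolic peak
morphology of a reflective sensor; the lobe widths are chosen narrow enough
that the notch actually exists as a local minimum.  Sinusoidal baseline
wander (0.25 Hz, respiratory) and white noise are added.  Ground truth
records the systolic apex times.

**Ancillary channels.**  Near-still triaxial acceleration (Gaussian jitter
about a gravity-aligned rest vector) and a slowly drifting skin temperature
clipped to 29–34 °C.  These exist so association screens have realistic
regressors; motion artifacts, gait and thermoregulatory sweating dynamics
are out of scope.

All generators draw from per-channel substreams spawned deterministically
from one top-level seed, so identical seeds give bit-identical output.

*What passing tests show:* the statistics (consensus, lag, R_EDA, detection
metrics, HR error) are recovered correctly when their generating assumptions
hold.  The generator does not emulate motion artifacts, electrode drift,
pathology-specific dynamics, or inter-subject waveform variability, so green
tests certify the algorithms, not field performance on real feet.

## EDA pipeline

**Filtering** is zero-phase (forward–backward second-order-sections
Butterworth) so SCR onset and peak times are not shifted — an offline
pipeline can afford acausality, and event timing is the quantity of
interest downstream.  The 750 ms moving-average window rounds to the nearest
odd sample count and uses edge-replicated padding to preserve length.

**Decomposition** solves the sparse-driver convex program: minimize
`0.5‖Bℓ + Cd + K q − y‖² + α·Σq + 0.5γ‖ℓ‖²` subject to `q ≥ 0`, where `K`
is convolution with the unit-peak Bateman kernel, `B` a clamped cubic
B-spline basis with 10 s knots, `C` a linear trend.  Because `q ≥ 0` turns
the L1 penalty into a linear term, the problem is a smooth bound-constrained
convex quadratic; it is solved with L-BFGS-B using FFT convolution/
correlation for the kernel operator and its adjoint, at a decimated solver
rate (default 25 Hz; sudomotor dynamics live well below 1 Hz, and the
analysis drivers use 8 Hz for 300 s records).  Components are linearly
interpolated back to the input rate and the residual is *defined* as
`filtered − tonic − phasic`, so the reconstruction identity holds to
machine precision.  α = 8e-4, kernel taus and knot spacing follow the
published values of the convex decomposition this implements; γ defaults to
1e-3 rather than the published 1e-2 because that value presumes a
standardized input — on raw microsiemens, γ = 1e-2 makes a sustained driver
cheaper than the spline for slow sub-μS drifts, leaking tonic variation
into the phasic channel (standardizing inside the solver was rejected: a
z-scored pure drift always has O(1) amplitude, making the leak worse).
Failure to converge raises a `DecompositionError` carrying the solver
message.

**SCR detection** marks onsets at upward zero-crossings of the first
derivative smoothed over 250 ms, takes the next derivative sign change
(refined to the local signal maximum) as the peak, keeps events with
amplitude ≥ 0.05 μS — the low end of the conventional 0.05–0.1 μS response
threshold, favoring sensitivity at the low-conductance foot — and enforces a
1 s inter-onset refractory.  Half-recovery time is the first post-peak
crossing of onset + amplitude/2, NaN if never reached.  Detection can run on
the filtered signal or on the phasic component; the filtered signal is the
default entry point, but slow-drift-heavy records over-call there, and the
phasic route is exposed for exactly that case.

**Measurability** is the count-based ratio `R_EDA = #(S > 0)/len(S)`
("measurable" read strictly: ties at exactly 0 count as unmeasurable), and
`total_measurable_duration = R_EDA × duration` so ratio and duration agree
exactly (0.75 of 300 s ⇔ 225 s).  The reported intervals are the maximal
positive runs merged across gaps shorter than 100 ms; they are descriptive
and are *not* used to compute the ratio, since merging would inflate it.

## Concordance statistics

**Peak matching** pairs foot (test) to hand (reference) peaks within ±2 s,
each test peak used at most once, by a max-cardinality, minimum-total-|lag|
assignment (Hungarian algorithm with a large out-of-window cost and a tiny
earlier-reference tie-break, so equidistant test peaks attach to the earlier
reference).  An optimal assignment was chosen over nearest-first greedy
because greedy provably under-matches (e.g. ref {0, 1}, test {−1.5, 0.1}:
greedy finds one pair, the optimum two) and exclusivity plus maximal pairing
is the intent of the window-shortening/no-double-counting conventions in
earlier dual-site work.  That stricter historical rule — a reference whose
window still holds ≥2 unassigned test peaks scores no pair — is available as
`rule="strict"`.  Consensus = pairs / reference peaks.

**Lags** are test − reference times of matched pairs (positive ⇒ hand
leads); mean and sample sd, flagged undefined with no pairs.  **Windowed
correlations** cut both phasic signals at [−2.0, +2.2] s around each matched
reference peak (the window that holds a full SCR waveform) and report
Pearson r on the raw phasic values; windows clipped by a record edge are
dropped, not zero-padded, since padding manufactures correlation.  **Extra
events** counts test events with no reference within ±2 s.  The
**association screen** routes by declared candidate type — continuous →
Pearson, ordinal (age range) → Spearman, binary group → ANOVA when
Shapiro–Wilk (α = 0.05) accepts normality in each group, else
Mann–Whitney U — and applies no multiplicity correction, mirroring
screening practice; interpret its p-values accordingly.

## PPG pipeline

Band-pass filtering is zero-phase fourth-order Butterworth; the default
[1, 8] Hz band is the conventional pulse band.  Note that at heart rates
near 50 BPM the pulse fundamental (0.83 Hz) falls below a 1 Hz corner and
the filter rings, producing mid-beat artifacts — the reason cutoff tuning
exists as a first-class operation.

Peak detection squares the zero-clipped signal and compares a 111 ms
(peak-scale) to a 667 ms (beat-scale) moving average plus an offset
`β·mean(squared signal)`; blocks at least one peak-window wide yield one
peak each (block maximum), with a 300 ms refractory.  The window widths are
the published constants of the two-moving-average scheme; β defaults to 0.2
rather than the published 0.02 because a pulse with a pronounced diastolic
lobe (squared amplitude up to ~20% of systolic) defeats the beat-scale
average alone, and the published value presumes waveforms without a
separable diastolic peak.  Since the offset scales with the signal's mean
square, detection is invariant to amplitude scaling.  Peaks within half a
beat-scale window (334 ms) of either record edge are suppressed: the moving
averages run on edge-padded samples there and produce warm-up blocks.

Scoring matches detections to labels within ±100 ms (≈10% of a beat at
60 BPM; how true positives are adjudicated against manual labels is
otherwise a free choice) using the same optimal exclusive assignment as
peak matching.  Accuracy is TP/(TP+FP+FN) — the unique definition consistent
with jointly reported accuracy/PPV/sensitivity triples.  The grid search
evaluates filter → detect → score over inclusive-endpoint linear cutoff
grids and breaks accuracy ties toward the lowest upper cutoff, then the
lowest lower cutoff (the least aggressive band on the plateau).
Instantaneous HR is 60/IBI assigned at the closing peak; HR error
interpolates both series onto a uniform 1 s grid over their overlap (the
HR series exists only at peak instants, so a common grid is required;
1 s is fine-grained relative to HR dynamics).  Bias is mean(true − pred),
so spurious extra peaks (overestimated HR) give negative bias.

## Problem sizes in the shipped analyses and tests

The analysis drivers run the full study conditions: 300 s at 1 kHz,
19 EDA + 15 PPG subjects, with the decomposition solved at 8 Hz.  The test
suite exercises the same code on smaller instances chosen for statistical
sufficiency rather than scale: event-level properties use 300 s records at
8 Hz (event statistics do not need kilohertz sampling), filter-response and
sync checks run at 1 kHz where sample-level precision is the point, and the
PPG end-to-end sweep uses 60 s records at 500 Hz — at 100 Hz, timing
quantization alone contributes ~2 BPM at 120 BPM, which would test the
sample clock rather than the detector.  The 50–120 BPM sweep uses a 0.5 Hz
lower cutoff so the band covers the lowest fundamental (see above).

## Known limitations

- The decomposition is exact only at the solver rate; between decimation
  points the phasic component is linearly interpolated.
- Derivative-based SCR detection on the *filtered* signal over-calls on
  records with strong tonic drift; use the phasic entry point there.
- The consensus statistic is inflated by chance co-occurrence when both
  sites are event-dense (a ±2 s window is generous at 6 events/min), and
  diluted by saturation episodes that hide foot events.
- The association screen performs no multiple-testing correction.
- Synthetic PPG carries no motion artifact, so detection accuracies on it
  bound real ankle performance from above.
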