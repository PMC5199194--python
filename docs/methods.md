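# Methods

This note documents the analysis model, the synthetic-data generator, the
tunable parameters and the numerical choices, in the package's own terms.

## Analysis pipeline

### Stimulus protocol

Drifting sinusoidal gratings at 12 directions, 30° apart, each presented
for 1.5 s at a temporal frequency of 2 cycles/s (three grating cycles);
spatial frequency 0.02 cycles/degree (metadata only); traces sampled at
10 kHz. The protocol object enforces three invariants: the directions
tile 360°, the cycle count times the cycle period equals the stimulus
duration, and the cycle-averaging window spans exactly one cycle.

### Trace preprocessing

*Current clamp (Vm, mV).* Spikes are detected where the first difference
of the raw trace, scaled to mV/ms, crosses a positive threshold
(`dvdt_threshold_mv_per_ms`, default 10 — a typical value for cortical
spikes at 10 kHz; the threshold is an experimenter-set quantity, so it is
a configuration parameter). Detections within a 2 ms refractory window of
a previous one are suppressed. The subthreshold Vm is the raw trace put
through a 6 ms running median (window forced to an odd sample count);
spike removal is applied **per sweep, before trial averaging**, because
spikes occur at different times across trials and a median filter on the
trial average would not remove them.

*Voltage clamp (EPSC, pA; inward currents negative).* Each condition's
trial-averaged trace is smoothed with a 40 ms running mean. The mean
filter is linear, so smoothing before or after trial averaging is
equivalent; averaging first is cheaper.

Both filters use reflect padding so the output length equals the input
length and there is no startup bias. They are idempotent on constants and
commute with additive offsets (property-tested).

*Cycle averaging.* For each stimulus condition the window from 50 to
550 ms after each of the three cycle onsets is extracted and averaged.
If the third cycle's peak-to-peak amplitude is below
`adaptation_ratio_threshold` (default 0.5) times the mean of the first
two cycles' amplitudes, the cell is taken to adapt in the third cycle and
only cycles 1–2 are averaged; the flag is surfaced per condition in the
QC output. Peak-to-peak amplitude is used as the per-cycle response
measure because it needs no baseline and is sign-convention agnostic
(depolarizations and inward currents alike). The threshold itself is a
stand-in for an unquantified judgment call and is configurable.

*Baselines.* The blank (gray-screen) sweeps of the matching LED state are
preprocessed like stimulus sweeps, averaged, and the mean and SD of the
averaged trace over a window of one stimulus duration starting at the
nominal stimulus onset give the baseline. Vm analysis uses LED-off blanks
only; EPSC baselines are computed separately for LED-on and LED-off
because the holding current differs between the two states.

*Response magnitude.* The baseline mean is subtracted from the
cycle-averaged trace; the response magnitude for a direction is the peak
depolarization (current clamp) or the peak inward current reported as a
positive number (voltage clamp).

### Orientation statistics

For a tuning curve R(θ) over the 12 drift directions the orientation
vector is `Σ R(θ)e^{2iθ} / Σ R(θ)` (θ in radians). Negative
baseline-subtracted magnitudes are clipped to zero before the sum — the
statistic assumes non-negative weights — and the clipped fraction is
reported per cell. The modulus is the gOSI; the preferred orientation is
half the phase, minus 90°, wrapped into [−90°, 90°) (half-open so each
orientation has a unique representative; a boundary tie maps to −90°).
The −90° shift converts the drift-direction peak into the grating
orientation. A resultant with modulus below 1e−12, or an all-zero clipped
curve, leaves pref_O undefined; such cells are excluded listwise from
difference and correlation statistics and counted in the QC report.

ΔO between two preferences is the absolute difference reduced along the
180° cycle into [0°, 90°]. It is a metric on the orientation circle
(symmetry and the triangle inequality are brute-force tested on a grid).
If either preference is undefined, the ΔO is undefined.

### Decomposition

Total (LED-off) and thalamic (LED-on) cycle-averaged traces are each
baseline-subtracted with their own LED-matched baseline; the cortical
trace is their point-by-point difference, and its peak inward value gives
the cortical magnitude. When the adaptation rule selects different cycle
counts for the LED-off and LED-on traces of one direction, both are
recomputed with the smaller count so the subtraction operates on
commensurate windows. The scale factor is the mean of the thalamic tuning
curve divided by the mean of the total curve (NaN, flagged, if the total
mean is not positive); the ocular-dominance ratio is the contralateral
curve mean over the ipsilateral curve mean, computed for total and for
thalamic input.

Cortical magnitudes can come out negative at some directions (noise);
they are clipped by the orientation-vector rule and the clipped fraction
is reported rather than silently absorbed. Linear subtraction ignores
possible nonlinear thalamo-cortical interactions; that caveat is inherent
to the method.

### Cohort statistics

Metrics are summarized as mean ± SEM (sample SD/√n; SEM is NaN for
n = 1). The battery comprises: two-sample two-sided Kolmogorov–Smirnov
tests between age groups on the inter-ocular ΔO of total and thalamic
EPSCs; one-sample K-S of each ΔO sample against Uniform(0, 90), the null
of unrelated preferences; paired t-tests between total and thalamic ΔO
and between the contralateral and ipsilateral thalamic-cortical
differences within each cohort; and Pearson correlation of thalamic vs
total ΔO per cohort. K-S p-values are asymptotic (empirical type-I error
at n = 25 against the uniform null: 0.034 at α = 0.05, within a
reasonable calibration band). No multiple-testing correction is applied.
All tests are two-sided.

## Synthetic-data generator

Each simulated cell receives, per eye e, a thalamic and a cortical
excitatory component with amplitudes

    T_e(θ) = A_e · s_e · tune(θ; pref_thal_e, κ)
    C_e(θ) = A_e · (1 − s_e) · tune(θ; pref_cort_e, κ)

where `tune` is a peak-normalized von-Mises-style bump on the 180°
orientation cycle, `(exp(κ(cos 2Δ − 1)) + b)/(1 + b)` with concentration
κ = 2 and baseline offset b = 0.1 (these give component gOSI ≈ 0.5,
moderately selective layer-4-like tuning, and keep all magnitudes
positive so no clipping occurs in clean data). s_e is the eye's scale
factor; A_contra is log-normal (median 100 pA, log-SD 0.3) and
A_ipsi = A_contra / ci_ratio with ci_ratio = 2.0, so the configured
ocular-dominance ratio is exact by construction.

A sweep's evoked waveform is the amplitude times a half-rectified 2 Hz
sinusoid over the three grating cycles, riding on a holding baseline
(−40 pA LED-off, −120 pA LED-on, standing in for the tonic holding-current
shift under photoactivation; −60 mV rest in current clamp) plus white
Gaussian noise. Thalamic and cortical components share the response
phase, so the peak of the sum equals the sum of the peaks and the linear
decomposition is exact at zero noise (an optional phase-jitter parameter
breaks this for robustness experiments). LED-on sweeps contain the
thalamic component only; blank sweeps are baseline plus noise; two trials
per condition and two blanks per LED state by default (trial counts in
such experiments are not standardized; two is a minimal realistic
choice). Current-clamp cells map summed input to depolarization at
0.15 mV/pA and inject a stereotyped 1.5 ms spike waveform at 50 Hz while
the noiseless Vm exceeds a threshold (−48 mV default), recording the
injection times; this exercises spike detection and removal without a
conductance model.

### Preference draws and preset calibration

The contralateral thalamic preference is uniform on [−90°, 90°). The
ipsilateral thalamic preference, and each eye's cortical preference, are
the reference preference plus zero-mean normal jitter, wrapped. The
jitter scale σ is calibrated so that the **analytic mean of the wrapped
absolute difference** (computed by quadrature and inverted with a root
finder) equals the cohort preset mean. That analytic mean is monotone in
σ and saturates at 45° — the uniform limit of unrelated orientations — so
a preset mean at or above 45° cannot be realized by jitter of any scale;
it is implemented as an independent uniform draw instead. This applies to
the young ipsilateral thalamic-cortical preset (49.0°): in the young
cohort the ipsilateral cortical wiring is modeled as fully random, which
is also how that cohort is interpreted scientifically. Its analytic mean
is 45°.

Cohort presets (means in degrees; scale factors dimensionless):

| preset | ΔO thalamic | thal-cort contra | thal-cort ipsi | s_contra | s_ipsi | n (VC) | n (CC) |
|--------|------------:|-----------------:|---------------:|---------:|-------:|-------:|-------:|
| adult  | 19.6        | 17.0             | 22.4           | 0.32     | 0.32   | 15     | 14     |
| young  | 30.9        | 35.8             | 49.0 (→45)     | 0.43     | 0.52   | 26     | 25     |

The inter-ocular ΔO of the *total* input and the Vm tuning are emergent:
the total preference is the vector-sum preference of the summed
components, so it interpolates between the thalamic and cortical
preferences with weights set by the scale factor.

Default white-noise SDs (15 pA voltage clamp, 2 mV current clamp per
10 kHz sample) keep the demo in a clean, high-SNR regime; the helper
`noise_sd_for_magnitude_snr` computes the white-noise SD giving a target
per-direction magnitude SNR, defined as the median-amplitude cell's mean
per-direction contralateral total magnitude divided by the magnitude
estimator's theoretical noise SD, `noise_sd/√(W · n_trials · n_cycles)`
with W the smoothing window in samples. Because the ipsilateral eye is
half as strong, its conditions sit at roughly half that SNR — a real
property of ocular-dominance recordings worth keeping in mind when
interpreting noisy-recovery results: at a typical-condition SNR of 5 the
ipsilateral preference errors dominate, and since ΔO is a folded
statistic, preference jitter biases recovered ΔO means upward.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: labeled
sweeps, 2 Hz modulated responses, additive thalamic/cortical components,
LED-state baselines, blanks, spikes, cohort-level preference scatter. It
does **not** model conductances, inhibition, adaptation dynamics (the
adaptation rule is exercised by dedicated fixtures, not by default
cohorts), correlated membrane noise (the noise is white; a per-sweep
phase-jitter option covers timing variability), eye-movement or state
fluctuations, or
nonlinear thalamo-cortical interactions. Passing tests therefore show the
pipeline is correct under its own assumptions, not that those assumptions
hold for any particular real recording.

## Numerical choices and degenerate inputs

* Filter windows are converted to samples by rounding; the median window
  is forced odd. Traces shorter than one window are errors.
* Windows for cycle extraction are placed by rounding
  `(onset + k·period + 0.05 s) · fs`; a trace not covering the last
  window is an error, as are non-finite samples.
* A resultant modulus below 1e−12 counts as untuned (floating-point sums
  of symmetric curves do not cancel exactly).
* Paired t with all-zero differences returns t = 0 with NaN p (flagged);
  Pearson with a zero-variance input raises.
* An empty test battery (all cells untuned) is returned, with QC counts,
  rather than raised.
* Dataset files store raw unfiltered traces at full precision
  (`%.17g`, parsed with round-trip float precision) so preprocessing is
  re-runnable and write→read is the identity.
* All randomness flows from explicit integer seeds; per-cell streams are
  derived from `(seed, cell_index)`, and the demo derives independent
  cohort seeds from the master seed, all below 2³¹.

## Problem sizes

The default test suite and the demo use the standard cohort sizes
(26/15 voltage-clamp and 25/14 current-clamp cells) for the acceptance
checks and scaled-down cohorts (2–12 cells) for unit and pipeline tests;
noisy-recovery checks use 10 replicates of the adult voltage-clamp cohort
and the qualitative cohort checks 20 replicates of the young cohort.
These sizes are the package's chosen balance between statistical
resolution and a test suite that runs in a few minutes.

## Known limitations

* The adaptation criterion and the dV/dt spike threshold are explicit,
  configurable stand-ins for experimenter judgment.
* Linear subtraction inherits the nonlinear-interaction caveat above.
* The uniform fallback for preset difference means ≥ 45° makes those
  presets reproduce the *random* limit rather than the nominal number.
* Asymptotic K-S p-values are slightly conservative at n ≈ 15–25.
* The recovered inter-ocular difference of *total* excitation is an
  emergent quantity; cohort means for it scatter more across seeds than
  the directly calibrated thalamic presets.
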