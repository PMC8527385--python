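# Methods

This note documents the models, conventions and numerical choices behind
`somnoval`, in the order data flows through the pipeline. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic nights

The package validates a device-agreement pipeline whose original inputs
(ambulatory PSG with 256 Hz ECG, tracker JSON exports) cannot be
redistributed. The `synthio` module therefore generates complete nights
with known ground truth, and the test suite treats those truths as the
reference the pipeline must recover.

**Sleep process.** PSG hypnograms are simulated from a first-order Markov
chain over {W, N1, N2, N3, REM} at the 20 s epoch length. The default
transition matrix ships as a config fixture
(`somnoval/data/default_psg_model.yaml`); its stay probabilities
correspond to mean bout lengths of roughly 2 min (W), 1.5 min (N1),
5 min (N2), 4.5 min (N3) and 5.5 min (REM), which give plausible adult
architecture when started from wake. A first-order chain has geometric
run lengths and no ultradian cycle structure; consequently the package
deliberately excludes variables that need a cycle definition (for
instance "REM in the first cycle").

**Tracker staging.** The tracker truth is the dominant PSG stage per 30 s
epoch mapped through wake=W, light=N1+N2, deep=N3, rem=REM, then
perturbed by a 4×4 confusion matrix. Misclassification persists over
segments of geometric mean length 5 epochs (redrawn whenever the true
stage changes) rather than flipping epochs independently: real staging
errors come in stretches, and independent flips would fragment rem/deep
runs so badly that the minimum-run smoothing below would remove those
stages entirely. Per-epoch marginal error rates are those of the matrix
either way, and an identity matrix reproduces the truth exactly. Finally,
rem and deep runs shorter than 9 epochs (4.5 min) are absorbed into their
neighbours, reproducing the duration discontinuity observable in the
emulated device's output. The default confusion matrix was chosen to
echo the qualitative pattern reported for this device class — light sleep
least reliable, deep often absorbed into light, wake leaking into rem —
and is a study condition, not a fitted quantity.

**Clocks.** The tracker clock leads the PSG clock by a constant per-night
offset drawn uniformly from 1.9–7.5 min (the observed range in the
cohort this pipeline was designed around), quantised to 1 ms — the
resolution of the vendor timestamp format, which keeps file round trips
exact. Within-night drift is out of scope.

**Heart rate and ECG.** A piecewise-linear HR curve follows stage
baselines (W 70, N1 62, N2 58, N3 55, REM 65 bpm) plus a slow sinusoid
(amplitude 2 bpm, period 5 min) and smoothed knot noise; beats integrate
that rate with 1% lognormal IBI jitter, with optional beat
deletion/insertion to emulate artifact gaps and ectopy. The ECG is a sum
of Gaussian templates: a narrow R bump (SD 12 ms) at each beat and a
broad T bump (SD 60 ms, default lag 280 ms), plus white noise. This is
not physiological morphology (no P wave, no QT dynamics); it is the
minimal construction exhibiting the sharp-versus-slow tangent contrast
the T-wave screen exploits, which is exactly what the screen's tests
need.

**Tracker HR sampling.** Sample intervals are drawn from the 5/10/15 s
menu with weights 0.5/0.4/0.1; each value is the integer-rounded mean of
the true curve over the preceding interval. The menu bounds the
per-minute count to 4–12 by construction, and the weights give a long-run
average near 7.5 samples/min, the rate reported for this device class.

**Vendor dialect.** `write_fitbit_json` emits the two-dialect JSON
structure: a "stages" sleep log of 30 s run records with a separate
short-wake list (isolated single-epoch wake runs are written as 20 s
short-wake records, the main data continuing the surrounding stage), or a
1-min "classic" log for nights under three hours. "Restless" is emitted
as a configurable classic label without any physiological claim, since
its meaning is undocumented.

## Beat detection and the T-wave screen

Detection runs band-pass (1–30 Hz Butterworth, zero-phase) → derivative →
squaring → 150 ms moving-window integration → adaptive signal/noise
thresholding, then localises peaks on the filtered signal and adds an
amplitude search-back (local maxima above 35% of the median candidate
amplitude). The wide passband and search-back are deliberate: the
detector is sensitivity-first and will flag prominent T waves as
candidates, delegating discrimination to the curvature screen. Polarity
is corrected by the sign of the mean signal value at the candidates
(ties leave the signal unchanged), with re-detection on a flipped trace,
and each candidate is realigned to the signal maximum within ±200 ms
(ties to the smallest index; windows clipped at the edges).

**QAVSD₆₀ convention.** The statistic is the 0.6 quantile (linear
interpolation) of the absolute fs²-scaled central second difference over
samples within ±28 ms of the realigned peak, apex included, windows
clipped at edges and scored on what remains. Two numerical choices:

* The signal is Gaussian-smoothed (σ = 8 ms) before differencing. White
  measurement noise otherwise dominates the second difference of slow
  T waves and would erase the R/T contrast; smoothing with a unit-mass
  kernel leaves the second difference of any quadratic trend exactly
  unchanged, so the statistic's calibration on smooth structure is
  unaffected.
* Values are reported in units of 4096 mV/s². In these units the
  conventional hard limits 35/256 ≈ 0.137 and 120/256 ≈ 0.469 bracket the
  valley between T-wave and R-peak curvature for millivolt-scale ECG at
  256 Hz; a 1 mV R wave of 12 ms SD scores ≈ 0.45 and an 0.8 mV T wave
  ≈ 0.08.

**Cutoff.** The per-subject cutoff is the first strict local minimum of a
Gaussian KDE (Silverman bandwidth, 512-point grid over [0, max]) inside
the hard limits, falling back to 35/256 when no interior minimum exists
(degenerate or unimodal samples). The valley is required to be
bandwidth-robust: a test checks the cutoff moves by < 0.1 units under
±50% bandwidth. Peaks closer than 360 ms to their kept predecessor are
dropped iff their QAVSD₆₀ is below the cutoff, scanning left to right
with re-evaluation, so runs of close T detections collapse onto the true
beat while genuine premature beats (sharp, high-curvature) survive.
Fewer than 10 peaks fall back to the fixed cutoff rather than a density.

## Clock alignment

Each HR value summarises an interval (the preceding 5–15 s for the
tracker, one IBI for the PSG side), so values are assigned to interval
midpoints before interpolation; assigning them to interval ends, as the
raw records do, would build a systematic half-interval lag (~5 s) into
the estimate. Both series are linearly interpolated onto 0.2 s grids
spanning their sample range (no extrapolation; points inside gaps longer
than 5 min are marked invalid). For every lag within ±30 min the Pearson
correlation over jointly valid points is computed exactly via FFT sliding
sums; lags with under 10 min of overlap, or under 50% of the shorter
series' valid span, are excluded, and ties resolve to the smallest |lag|.
The search bound of 30 min is safely wide for the 1.9–7.5 min offsets the
generator draws. Sub-step (parabolic) refinement is out of scope; the
acceptance study measures recovery within 1 s on 100 nights, which the
grid resolution plus midpoint assignment achieves with margin.

## Sleep variables

Epochs are half-open `[t, t + epoch_s)`. S_on is the start of the first
criterion epoch (N1 or N2 for PSG; first non-wake for tracker series,
which cannot distinguish N1 from N2), S_off the end of the last non-wake
epoch. WASO counts wake strictly inside [S_on, S_off]. Two TST
conventions are provided because the underlying definition is ambiguous
in the literature this mirrors: convention A (default) counts sleep-stage
time inside [S_on, S_off], so TST_A + WASO = S_off − S_on holds as an
exact identity; convention B is the sleep period S_off − S_on itself.
REM latency is the start of the first REM epoch at or after S_on, minus
S_on, and is missing when no such epoch exists.

Trimming for HR₁₀/HRvar₁₀ drops ⌊n·0.10⌋ order statistics per tail
(a "total" mode halving the fraction across tails is available, since
"10%-trimmed" does not pin the convention down); the variance uses
denominator n_kept − 1 and is missing for a single survivor. HRvar₁₀ is a
variance and carries bpm² even where the emulated study's tables print
bpm. Each minute's stage is the PSG stage with the largest overlap (ties
to the earlier-starting stage); minutes lacking samples on either device
are excluded and logged. The overall HR window is S_on − 30 min to S_off
(`hr_window="figure_caption"` extends it to S_off + 30 min — the source
material states both variants, so both are config options);
stage-stratified statistics use S_on to S_off.

## Agreement statistics

Differences are PSG − tracker throughout: positive bias = tracker
underestimates. Per-night Bland–Altman uses bias ± 1.96·SD with the
classical approximate LoA confidence intervals (SE(LoA) = SD·√(3/n),
t quantile) and a two-tailed one-sample t test of zero bias (missing for
zero-variance differences). The x-axis convention (PSG value for sleep
variables, device mean for HR) is metadata used by the plotting helper.

**Mixed-model LoA.** Per-minute differences are modelled as
d_ij = β₀ + b_i + e_ij with subject intercepts b_i ~ N(0, σ²_b) and AR(1)
within-subject residuals (parameters σ_w, φ). The likelihood is evaluated
in closed form: the AR(1) inverse is tridiagonal and the intercept a
rank-one update, so each evaluation is O(n) (Woodbury identity), the mean
is profiled out by GLS, and Nelder–Mead optimises (log σ_w, log σ_b,
atanh φ). REML is the default — with a profiled mean, plain ML biases
σ_b downward and the bias CI undercovers — and matches the default of the
standard mixed-model tooling for this analysis; `method="ML"` is
available and is cross-checked against an independent R `nlme::lme`
(corAR1) fit to ~1e-3 in one test. LoA use the total SD
√(σ²_b + σ²_w): an agreement interval must describe a new minute of a new
subject, so both components belong in it. The bias CI uses a t quantile
with n_subjects − 1 degrees of freedom, the effective unit for the mean
under a subject intercept. Minutes within a subject are treated as
consecutive for the AR(1) index; a single subject fixes σ_b = 0
(unidentifiable); a constant difference vector returns the degenerate
exact answer without optimisation.

**Epoch matching.** Each 20 s PSG epoch takes the tracker stage with the
largest overlap if it exceeds half the epoch (>10 s); an exact 10 s/10 s
split between two different tracker stages goes to the earlier-starting
one; epochs with no dominating stage (outside tracker coverage or only
half covered) are excluded and counted. One-vs-rest confusion counts
define sensitivity TP/P and specificity TN/N with P, N the *PSG*
positives/negatives, accuracy, PPV, NPV (undefined ratios are NaN) and
MCC with the standard four-marginal denominator, 0 by convention when a
marginal is empty; the denominator is computed as an exact integer
product before a single square root so the result is bit-identical to a
brute-force tally. Cohort EBE tables are pooled across nights
(micro-average) with a per-night macro-average alongside, since the
emulated analysis does not state which it used. The REM early/late split
partitions epochs at S_on + 120 min per night (window-based; an
episode-based reading exists but is not implemented).

## Pipeline and reproducibility

A cohort run parses each night, aligns clocks, derives adjusted and
unadjusted summaries, minute statistics and EBE pairs, and assembles the
report; nights failing a stage are skipped with machine-readable codes
(`classic_datatype`, `parse_error`, `derivation_failed`), and only an
all-night failure aborts the run. Classic-dialect nights enter run-length
distributions only. All tabular outputs are CSV with fixed float
formatting, so reruns with the same config and seed are byte-identical.
Every ambiguity above (onset criterion, TST convention, trim mode, HR
window, x-axis mode, border adjustment) is an explicit `RunConfig` key.

**Problem sizes.** The simulation studies in `somnoval.benchmarks` use
eight-hour nights (1440 PSG epochs) for clock-offset recovery (100
nights), four-hour nights for file round trips (100 nights), 50 ECG
records of 200 beats (T/R amplitude ratio 0.8, noise SD 5% of R) for the
T-wave screen, 100 replicates of 50 subjects × 400 minutes (bias 0.9,
σ_b 1.5, σ_w 3.0, φ 0.5) for mixed-model recovery, and ten-night cohorts
for end-to-end effect propagation. The no-noise propagation cohorts
additionally quantise stage changes to 60 s blocks (the common multiple
of the 20 s and 30 s grids) and enter sleep through N1: dominant-stage
resampling between mismatched grids is only invertible on a common
block grid, and the PSG N1-onset and tracker first-sleep onset only
denote the same instant when N1 comes first — without those two
constraints the residual disagreement is a property of the grids and
definitions, not of the pipeline.

## What passing tests do and do not show

The generators emulate record structure, grids, clocks, sampling rates,
rounding and the staging-error geometry of real data; they do not emulate
real ECG morphology, EEG-based scoring ambiguity, movement artifacts, or
the vendor's actual staging algorithm. Passing tests therefore establish
that the pipeline's arithmetic, conventions and estimators are correct
and that known effects propagate undistorted end to end — not that any
particular device achieves the simulated agreement levels on real nights.
The cohort-level empirical values of the study this design mirrors are
not reproduced here, since its raw recordings are not available.
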