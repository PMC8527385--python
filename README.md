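# somnoval

Validation of wrist multisensor sleep trackers against polysomnography
(PSG), as a tested, reusable Python pipeline.

Consumer wrist trackers estimate sleep stages and heart rate from
accelerometry and photoplethysmography. Before such a device can be used
in clinical or research settings its output has to be compared, night by
night and epoch by epoch, with the reference standard: visually scored
PSG. That comparison is harder than it sounds — the two instruments do
not share a clock (misalignments of 1.9–7.5 minutes per night are
typical), the PSG electrocardiogram needs artifact-robust R-peak
detection before a heart-rate series exists, the tracker reports sleep in
two incompatible record dialects on a different epoch grid than the PSG,
and repeated per-minute heart-rate differences are strongly serially
correlated, which invalidates ordinary limits of agreement.

`somnoval` implements the full chain for this kind of study:

* **ECG beat detection** (`somnoval.ecgbeats`) — an energy-based QRS
  detector with polarity correction and apex realignment, followed by a
  T-wave screen: the 60% quantile of the absolute second derivative in a
  ±28 ms window around each peak (QAVSD₆₀) separates sharp R apexes from
  slow T waves; whenever two detections fall within 360 ms the later one
  is dropped iff its QAVSD₆₀ lies below a per-subject cutoff placed at the
  first local minimum of the QAVSD₆₀ density inside fixed hard limits
  (35/256–120/256 in reported units, fallback 35/256). HR = 60/IBI.
* **Clock alignment** (`somnoval.clockalign`) — both HR series are
  linearly interpolated, resampled at 0.2 s, and the lag maximising the
  Pearson cross-correlation over jointly valid points is removed from all
  tracker timestamps.
* **Vendor records** (`somnoval.fitbit_records`) — parses the tracker's
  JSON dialect ("stages": 30 s wake/light/deep/rem runs plus a separate
  short-wake list; "classic": 1-min asleep/restless/awake), merges the
  short-wake set into the hypnogram (an epoch overlapped ≥ 15 s by a wake
  record becomes wake), and trims bordering wake epochs that the vendor
  algorithm sometimes places around a sleep episode.
* **Sleep variables** (`somnoval.sleepvars`) — onset S_on (first N1 or
  first N2 epoch; first non-wake for the tracker), offset S_off, TST,
  WASO, REM latency and stage durations; run-length decompositions; and
  per-minute 10%-trimmed HR mean (HR₁₀) and variance (HRvar₁₀) per device.
* **Agreement statistics** (`somnoval.agreement`) — Bland–Altman bias and
  limits of agreement b ± 1.96·SD for per-night variables (differences
  oriented PSG − tracker); for repeated per-minute HR differences an
  intercept-only linear mixed model with a random intercept per subject
  and AR(1) residuals, fitted by REML, with LoA = b ± 1.96·√(σ²_between +
  σ²_within); and epoch-by-epoch (EBE) sensitivity, specificity, accuracy,
  MCC, PPV and NPV after matching each 20 s PSG epoch with the dominating
  (>50%) tracker stage under the equivalence wake=W, light=N1+N2, deep=N3,
  rem=REM.
* **Synthetic nights** (`somnoval.synthio`) — the raw recordings of such
  studies are rarely shareable, so a first-class generator produces whole
  nights (ECG, PSG hypnograms, vendor-dialect JSON, intraday HR) with
  known ground truth; every claim the pipeline makes is tested against
  that truth.
* **Orchestration** (`somnoval.pipeline`, `somnoval` CLI) — cohort
  directories in, per-night and cohort CSV tables out, deterministic for
  a fixed configuration and seed.

## Worked example

`examples/02_detect_beats.py` builds a 200-beat ECG whose T waves are 80%
of the R amplitude and runs detection with and without the curvature
screen:

```
true beats                  : 200
candidates without screen   : 400  (F1 = 0.667)
beats after T-wave screen   : 200  (F1 = 1.000)
QAVSD cutoff                : 0.245 (density_minimum), hard limits 0.137-0.469
```

Every T wave initially doubles as a beat candidate (F1 = 0.667); the
per-subject density-valley cutoff (0.245, inside the hard limits) removes
exactly the 200 T waves and restores perfect detection.

`examples/05_cohort_agreement.py` simulates a five-night cohort with the
default imperfect staging model and runs the whole pipeline:

```
Bland-Altman (PSG minus tracker, border-adjusted):
variable     bias  loa_lower  loa_upper  n
    s_on     0.83      -0.94       2.59  5
     tst    27.03       1.84      52.22  5
    waso   -27.00     -50.33      -3.67  5
    reml   -70.83    -198.09      56.42  5
...
Epoch-by-epoch agreement (pooled across nights):
stage  sensitivity  specificity  accuracy    mcc
 wake        0.586        0.862     0.830  0.364
light        0.740        0.488     0.629  0.236
 deep        0.347        0.960     0.853  0.401
  rem        0.286        0.960     0.858  0.330
```

Negative biases mean the tracker overestimates (here WASO and REM
latency), and specificity exceeds sensitivity for every stage — the
characteristic consumer-wearable pattern the default generator encodes.
The remaining examples cover night simulation, clock alignment and
sleep-variable derivation.

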