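"""Synthetic night generator.

The study data this toolkit targets -- single-channel ECG at 256 Hz, PSG
hypnograms in 20 s epochs, and tracker sleep/heart-rate records in the
vendor's JSON dialect -- are not publicly deposited.  This module generates
complete synthetic nights with known ground truth so that every downstream
stage (beat detection, clock alignment, sleep-variable derivation,
agreement statistics) can be exercised and tested end to end.

Every generator is bit-reproducible for a fixed seed.  The defaults encode
the observed study conditions: 20 s PSG epochs, 30 s tracker epochs, a
constant per-night clock offset in the observed 1.9-7.5 min range, 4-12
integer-rounded heart-rate samples per minute drawn at 5/10/15 s intervals,
and tracker rem/deep runs never shorter than 4.5 min (the "nonbiological
discontinuity" of the vendor's staging output).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import (
    CLASSIC_STAGES,
    PSG_STAGES,
    PSG_TO_TRACKER,
    TRACKER_STAGES,
    Hypnogram,
    HRSeries,
    SampledSignal,
)

# Observed per-night clock misalignment range between tracker and PSG
# clocks, in seconds (1.9 to 7.5 minutes).
OFFSET_RANGE_S = (114.0, 450.0)

#: Default HR sampling interval menu of the tracker, seconds, and the
#: probability of each interval.  The weights reproduce the observed
#: long-run average of about 7.5 HR samples per minute.
DEFAULT_INTERVAL_MENU = (5.0, 10.0, 15.0)
DEFAULT_INTERVAL_WEIGHTS = (0.5, 0.4, 0.1)

#: Tracker rem/deep runs shorter than this many 30 s epochs do not occur in
#: vendor output (4.5 min discontinuity); the generator reproduces that.
DEFAULT_MIN_RUN_EPOCHS = 9

# Gaussian ECG template widths (seconds).  The narrow R and broad T bump
# reproduce the sharp-versus-slow tangent contrast that the curvature-based
# T-wave screen exploits.
R_TEMPLATE_SD = 0.012
T_TEMPLATE_SD = 0.060

#: Baseline heart rate per PSG stage, bpm.  REM and wake run higher than
#: consolidated NREM sleep, giving the clock-alignment cross-correlation a
#: stage-structured signal to lock onto.
STAGE_HR_BPM = {"W": 70.0, "N1": 62.0, "N2": 58.0, "N3": 55.0, "REM": 65.0}

# Default tracker-vs-truth stage misclassification (rows: true stage,
# columns: observed stage, order wake/light/deep/rem).  Chosen to echo the
# qualitative pattern of consumer staging output: light sleep is the least
# reliable call, deep is often absorbed into light, wake leaks into rem.
DEFAULT_CONFUSION = np.array(
    [
        [0.60, 0.30, 0.02, 0.08],
        [0.10, 0.62, 0.13, 0.15],
        [0.01, 0.35, 0.60, 0.04],
        [0.08, 0.30, 0.02, 0.60],
    ]
)


# ---------------------------------------------------------------------------
# Stage-transition model


@dataclass
class StageTransitionModel:
    """First-order Markov model over sleep stages at fixed epoch length."""

    states: tuple
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        k = len(self.states)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix shape does not match states")
        if np.any(self.transition_matrix < 0) or np.any(self.initial_distribution < 0):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each transition-matrix row must sum to 1")
        if not np.isclose(self.initial_distribution.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")

    @classmethod
    def from_dict(cls, spec: dict) -> "StageTransitionModel":
        states = tuple(spec["states"])
        tm = np.array(
            [[spec["transition_matrix"][s].get(t, 0.0) for t in states] for s in states],
            dtype=float,
        )
        init = np.array([spec.get("initial_distribution", {}).get(s, 0.0) for s in states])
        return cls(states, tm, init)


def default_psg_model() -> StageTransitionModel:
    """Plausible adult sleep-architecture model shipped as a config fixture."""
    text = importlib.resources.files("somnoval.data").joinpath("default_psg_model.yaml").read_text()
    return StageTransitionModel.from_dict(yaml.safe_load(text))


def gen_hypnogram(model: StageTransitionModel, n_epochs: int, epoch_s: float, seed: int,
                  start: float = 0.0) -> Hypnogram:
    """Simulate a fixed-epoch hypnogram from a stage-transition model."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(model.states)
    labels = np.empty(n_epochs, dtype=object)
    state = rng.choice(k, p=model.initial_distribution)
    labels[0] = model.states[state]
    # Draw all uniforms at once; inverse-CDF per step keeps the loop cheap.
    cum = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random(n_epochs - 1)
    for i in range(1, n_epochs):
        state = int(np.searchsorted(cum[state], u[i - 1], side="right"))
        state = min(state, k - 1)
        labels[i] = model.states[state]
    return Hypnogram(start=start, epoch_s=float(epoch_s), labels=labels)


# ---------------------------------------------------------------------------
# Tracker hypnogram from PSG truth


def _dominant_label(psg: Hypnogram, t0: float, t1: float):
    """Stage covering the largest part of [t0, t1); ties to the earlier
    epoch.  Returns None if the window has no overlap with the series."""
    overlap: dict = {}
    order: dict = {}
    for i, lab in enumerate(psg.labels):
        e0 = psg.start + i * psg.epoch_s
        e1 = e0 + psg.epoch_s
        ov = min(t1, e1) - max(t0, e0)
        if ov > 0:
            if lab not in overlap:
                order[lab] = e0
            overlap[lab] = overlap.get(lab, 0.0) + ov
    if not overlap:
        return None
    best = max(overlap.values())
    winners = [lab for lab, ov in overlap.items() if np.isclose(ov, best, atol=1e-9)]
    return min(winners, key=lambda lab: order[lab])


def _runs(labels: np.ndarray):
    """Maximal runs as (start_index, length, label) triples."""
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((i, j - i, labels[i]))
        i = j
    return runs

def _smooth_min_runs(labels: np.ndarray, min_run: int, stages=("rem", "deep")) -> np.ndarray:
    """Absorb runs of the given stages shorter than ``min_run`` epochs into
    the neighbouring run (previous if any, else next)."""
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        for start, length, lab in _runs(labels):
            if lab in stages and length < min_run:
                repl = labels[start - 1] if start > 0 else labels[start + length]
                labels[start:start + length] = repl
                changed = True
                break
    return labels


def gen_fitbit_from_psg(psg: Hypnogram, confusion: np.ndarray = None,
                        clock_offset: float = 0.0,
                        min_run_epochs: int = DEFAULT_MIN_RUN_EPOCHS,
                        seed: int = 0,
                        error_run_epochs: int = 5) -> Hypnogram:
    """Derive a 30 s tracker hypnogram from PSG truth.

    The PSG stages are mapped W->wake, N1/N2->light, N3->deep, REM->rem,
    resampled to the tracker's 30 s grid (dominant stage per epoch),
    perturbed by the ``confusion`` matrix, and smoothed so that no rem or
    deep run is shorter than ``min_run_epochs``.  The returned series
    carries tracker clock timestamps: recorded time = physical (PSG-clock)
    time + ``clock_offset``.

    Staging errors of real trackers come in contiguous stretches, not as
    independent epoch flips, so the confusion draw persists over segments
    of geometric mean length ``error_run_epochs`` (redrawn whenever the
    true stage changes; set to 1 for independent per-epoch noise).  The
    per-epoch marginal misclassification rates are those of ``confusion``
    either way, and an identity matrix reproduces the truth exactly.
    """
    if len(psg) == 0:
        raise ValueError("empty PSG hypnogram")
    if not np.isfinite(clock_offset):
        raise ValueError("clock offset must be finite")
    if min_run_epochs < 1:
        raise ValueError("min_run_epochs must be >= 1")
    if confusion is None:
        confusion = np.eye(len(TRACKER_STAGES))
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (4, 4) or not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("confusion must be 4x4 with rows summing to 1 (wake/light/deep/rem)")

    n_fb = int(psg.duration // 30.0)
    if n_fb < 1:
        raise ValueError("PSG night shorter than one tracker epoch")
    if error_run_epochs < 1:
        raise ValueError("error_run_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(TRACKER_STAGES)}
    labels = np.empty(n_fb, dtype=object)
    cum = np.cumsum(confusion, axis=1)
    u = rng.random(n_fb)
    redraw = rng.random(n_fb) < 1.0 / error_run_epochs
    prev_true = None
    current = None
    for k in range(n_fb):
        t0 = psg.start + 30.0 * k
        true = PSG_TO_TRACKER[_dominant_label(psg, t0, t0 + 30.0)]
        if current is None or true != prev_true or redraw[k]:
            obs = int(np.searchsorted(cum[idx[true]], u[k], side="right"))
            current = TRACKER_STAGES[min(obs, 3)]
        labels[k] = current
        prev_true = true
    labels = _smooth_min_runs(labels, min_run_epochs)
    return Hypnogram(start=psg.start + clock_offset, epoch_s=30.0, labels=labels)


# ---------------------------------------------------------------------------
# ECG synthesis


def gen_ecg(beat_times, fs: float, r_amp: float = 1.0, t_amp: float = 0.3,
            t_lag_ms: float = 280.0, noise_sd: float = 0.0, polarity: int = 1,
            seed: int = 0, start_time: float = 0.0, pad_s: float = 1.0) -> SampledSignal:
    """Synthesise a single-channel ECG (mV) as R plus T Gaussian bumps.

    Each beat contributes a narrow R bump (SD 12 ms) at the beat time and a
    broader T bump (SD 60 ms) lagged by ``t_lag_ms``, on top of white
    measurement noise; the whole trace is multiplied by ``polarity``.
    This deliberately minimal morphology provides exactly the failure mode
    the curvature screen targets: prominent slow T waves close enough to the
    R peak to masquerade as beats.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if polarity not in (1, -1):
        raise ValueError("polarity must be +1 or -1")
    t_lag = t_lag_ms / 1000.0
    if t_lag < 3.0 * (R_TEMPLATE_SD + T_TEMPLATE_SD):
        raise ValueError(
            f"t_lag_ms={t_lag_ms} too small: R and T templates overlap "
            f"(need >= {3000.0 * (R_TEMPLATE_SD + T_TEMPLATE_SD):.0f} ms)")
    if len(beat_times) >= 2:
        min_ibi = float(np.min(np.diff(beat_times)))
        if t_lag >= min_ibi:
            raise ValueError("t_lag_ms must be smaller than the minimum inter-beat interval")
    if len(beat_times) and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat times must be strictly increasing")

    dur = (beat_times[-1] - start_time + t_lag + pad_s) if len(beat_times) else pad_s
    n = int(np.ceil(dur * fs))
    t = start_time + np.arange(n) / fs
    x = np.zeros(n)
    for amp, sd, lag in ((r_amp, R_TEMPLATE_SD, 0.0), (t_amp, T_TEMPLATE_SD, t_lag)):
        if amp == 0:
            continue
        for bt in beat_times:
            c = bt + lag
            i0 = max(int((c - 5 * sd - start_time) * fs), 0)
            i1 = min(int((c + 5 * sd - start_time) * fs) + 2, n)
            x[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - c) / sd) ** 2)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return SampledSignal(values=polarity * x, fs=fs, start_time=start_time, units="mV")


# ---------------------------------------------------------------------------
# Heart-rate curve and tracker HR sampling


@dataclass
class HRCurve:
    """Piecewise-linear heart-rate curve (bpm over clock seconds).

    Values are held constant beyond the first/last knot.  ``mean`` computes
    the exact time average over an interval (piecewise-quadratic
    antiderivative), which the tracker sampler integer-rounds.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("curve needs >= 2 strictly increasing knots")
        # Cumulative exact integral at the knots.
        seg = 0.5 * (self.values[1:] + self.values[:-1]) * np.diff(self.times)
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        return np.interp(t, self.times, self.values)

    def _integral_to(self, t: float) -> float:
        """Exact integral of the curve from the first knot to ``t``."""
        if t <= self.times[0]:
            return float(self.values[0] * (t - self.times[0]))
        if t >= self.times[-1]:
            return float(self._cum[-1] + self.values[-1] * (t - self.times[-1]))
        k = int(np.searchsorted(self.times, t, side="right") - 1)
        dt = t - self.times[k]
        slope = (self.values[k + 1] - self.values[k]) / (self.times[k + 1] - self.times[k])
        return float(self._cum[k] + self.values[k] * dt + 0.5 * slope * dt * dt)

    def mean(self, t0: float, t1: float) -> float:
        if t1 <= t0:
            raise ValueError("interval must have positive length")
        return (self._integral_to(t1) - self._integral_to(t0)) / (t1 - t0)


def hr_curve_from_hypnogram(psg: Hypnogram, seed: int = 0,
                            stage_hr: dict = None,
                            wobble_amp: float = 2.0,
                            wobble_period_s: float = 300.0,
                            noise_sd: float = 1.0,
                            knot_step_s: float = 30.0) -> HRCurve:
    """Ground-truth HR curve driven by the PSG stages.

    Stage baselines (:data:`STAGE_HR_BPM`) plus a slow sinusoidal wobble
    and smoothed knot noise; knots every ``knot_step_s`` seconds.
    """
    stage_hr = dict(STAGE_HR_BPM if stage_hr is None else stage_hr)
    rng = np.random.default_rng(seed)
    times = np.arange(psg.start, psg.end + knot_step_s / 2, knot_step_s)
    base = np.empty(len(times))
    for i, t in enumerate(times):
        k = min(int((t - psg.start) // psg.epoch_s), len(psg) - 1)
        base[i] = stage_hr[psg.labels[k]]
    phase = rng.uniform(0, 2 * np.pi)
    wobble = wobble_amp * np.sin(2 * np.pi * (times - psg.start) / wobble_period_s + phase)
    rough = rng.normal(0.0, noise_sd, len(times))
    # 5-knot moving average keeps the noise slow compared with the sampler.
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(rough, kernel, mode="same")
    return HRCurve(times=times, values=base + wobble + smooth)


def beats_from_hr_curve(curve: HRCurve, t0: float = None, t1: float = None,
                        ibi_jitter: float = 0.01, seed: int = 0,
                        delete_rate: float = 0.0, insert_rate: float = 0.0) -> np.ndarray:
    """Beat times whose local rate follows the HR curve.

    ``ibi_jitter`` is the fractional SD of multiplicative inter-beat
    variability.  ``delete_rate``/``insert_rate`` emulate artifact-masked and
    ectopic beats: deletions drop a beat (creating a gap, as manual artifact
    marking does), insertions add a premature beat halfway to the next one.
    """
    rng = np.random.default_rng(seed)
    t0 = curve.start if t0 is None else t0
    t1 = curve.end if t1 is None else t1
    beats = []
    t = t0
    while t < t1:
        ibi = 60.0 / max(curve(t), 20.0)
        if ibi_jitter > 0:
            ibi *= np.exp(rng.normal(0.0, ibi_jitter))
        t += ibi
        if t < t1:
            beats.append(t)
    beats = np.asarray(beats)
    if delete_rate > 0 and len(beats):
        beats = beats[rng.random(len(beats)) >= delete_rate]
    if insert_rate > 0 and len(beats) > 1:
        extra = []
        for i in np.nonzero(rng.random(len(beats) - 1) < insert_rate)[0]:
            extra.append(beats[i] + 0.5 * (beats[i + 1] - beats[i]))
        beats = np.sort(np.concatenate([beats, extra]))
    return beats


def gen_fitbit_hr(true_hr_curve: HRCurve, night_span, interval_menu=DEFAULT_INTERVAL_MENU,
                  interval_weights=DEFAULT_INTERVAL_WEIGHTS, seed: int = 0) -> HRSeries:
    """Tracker-style intraday HR samples over ``night_span = (t0, t1)``.

    Sample times advance by intervals drawn from the menu with the given
    weights; each reported value is the integer-rounded mean of the true
    curve over the preceding interval.  With the default 5/10/15 s menu
    this yields 4-12 samples per clock minute by construction and a
    long-run average near the observed 7.5 per minute.
    """
    t0, t1 = night_span
    if t1 <= t0:
        raise ValueError("empty night span")
    menu = np.asarray(interval_menu, dtype=float)
    weights = None if interval_weights is None else np.asarray(interval_weights, dtype=float)
    rng = np.random.default_rng(seed)
    times, values = [], []
    t = float(t0)
    while True:
        dt = float(rng.choice(menu, p=weights))
        t += dt
        if t > t1:
            break
        times.append(t)
        values.append(round(true_hr_curve.mean(t - dt, t)))
    return HRSeries(np.asarray(times), np.asarray(values, dtype=float), device="fitbit")


# ---------------------------------------------------------------------------
# Whole-night truth


@dataclass
class NightTruth:
    """Ground truth for one synthetic night.

    ``true_beat_times`` and ``psg_hypnogram`` are on the PSG clock;
    ``fitbit_hypnogram`` and ``fitbit_hr`` carry tracker-clock timestamps
    (tracker time = PSG time + ``clock_offset``).
    """

    subject_id: str
    true_beat_times: np.ndarray
    true_hr_curve: HRCurve
    psg_hypnogram: Hypnogram
    fitbit_hypnogram: Hypnogram
    clock_offset: float
    rng_seed: int
    fitbit_hr: HRSeries = None
    force_classic: bool = False

    def __post_init__(self) -> None:
        self.true_beat_times = np.asarray(self.true_beat_times, dtype=float)
        if len(self.true_beat_times) > 1 and np.any(np.diff(self.true_beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if not np.isfinite(self.clock_offset):
            raise ValueError("clock offset must be finite")
        bad = set(self.psg_hypnogram.labels) - set(PSG_STAGES)
        if bad:
            raise ValueError(f"PSG labels outside alphabet: {bad}")
        bad = set(self.fitbit_hypnogram.labels) - set(TRACKER_STAGES)
        if bad:
            raise ValueError(f"tracker labels outside alphabet: {bad}")


def gen_night(subject_id: str, seed: int, n_psg_epochs: int = 1440,
              model: StageTransitionModel = None,
              confusion: np.ndarray = None,
              clock_offset: float = None,
              min_run_epochs: int = DEFAULT_MIN_RUN_EPOCHS,
              start: float = 0.0,
              ibi_jitter: float = 0.01,
              beat_delete_rate: float = 0.0,
              beat_insert_rate: float = 0.0,
              force_classic: bool = False,
              stage_block_s: float = None) -> NightTruth:
    """Simulate one complete night (default eight hours of 20 s PSG epochs).

    ``confusion`` defaults to :data:`DEFAULT_CONFUSION`; pass the identity
    to obtain a tracker that stages perfectly.  ``clock_offset`` defaults to
    a draw from the observed 1.9-7.5 min misalignment range.

    ``stage_block_s`` (for instance 60, the common multiple of the 20 s and
    30 s grids) quantises PSG stage changes to that block length.  Dominant-
    stage resampling between mismatched grids is then exactly invertible,
    which no-noise end-to-end checks use to separate pipeline errors from
    irreducible grid-resampling disagreement.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=6)]
    model = default_psg_model() if model is None else model
    confusion = DEFAULT_CONFUSION if confusion is None else confusion
    if clock_offset is None:
        # Vendor timestamps carry millisecond resolution; quantising the
        # offset keeps file round trips exact.
        clock_offset = round(float(rng.uniform(*OFFSET_RANGE_S)), 3)
    if stage_block_s is None:
        psg = gen_hypnogram(model, n_psg_epochs, 20.0, seed=sub[0], start=start)
    else:
        if stage_block_s != 60.0:
            raise ValueError("stage_block_s must be 60 (common multiple of the 20/30 s grids)")
        blocks = gen_hypnogram(model, max(n_psg_epochs // 3, 1), 60.0, seed=sub[0], start=start)
        psg = Hypnogram(start=start, epoch_s=20.0, labels=np.repeat(blocks.labels, 3))
    fb = gen_fitbit_from_psg(psg, confusion=confusion, clock_offset=clock_offset,
                             min_run_epochs=min_run_epochs, seed=sub[1])
    curve = hr_curve_from_hypnogram(psg, seed=sub[2])
    beats = beats_from_hr_curve(curve, ibi_jitter=ibi_jitter, seed=sub[3],
                                delete_rate=beat_delete_rate, insert_rate=beat_insert_rate)
    shifted_curve = HRCurve(curve.times + clock_offset, curve.values)
    fb_hr = gen_fitbit_hr(shifted_curve, (fb.start, fb.end), seed=sub[4])
    return NightTruth(subject_id=subject_id, true_beat_times=beats, true_hr_curve=curve,
                      psg_hypnogram=psg, fitbit_hypnogram=fb, clock_offset=clock_offset,
                      rng_seed=seed, fitbit_hr=fb_hr, force_classic=force_classic)


# ---------------------------------------------------------------------------
# Vendor-dialect JSON writer

_EPOCH_FMT = "%Y-%m-%dT%H:%M:%S.%f"


def _iso(seconds: float) -> str:
    import datetime as _dt

    base = _dt.datetime(1970, 1, 1)
    t = base + _dt.timedelta(seconds=float(seconds))
    return t.strftime(_EPOCH_FMT)[:-3]  # millisecond precision


def iso_to_seconds(stamp: str) -> float:
    import datetime as _dt

    base = _dt.datetime(1970, 1, 1)
    return (_dt.datetime.strptime(stamp, _EPOCH_FMT) - base).total_seconds()


def _classic_from_stages(fb: Hypnogram, restless_prob: float, seed: int) -> Hypnogram:
    """Collapse the 30 s stages series to the 1-min classic alphabet.

    Wake minutes become "awake" (or "restless" with the given probability;
    the restless label has no claimed physiological meaning), everything
    else "asleep".  Minute label = dominant 30 s label, ties to the earlier
    epoch.
    """
    rng = np.random.default_rng(seed)
    n_min = len(fb) // 2
    labels = np.empty(n_min, dtype=object)
    for m in range(n_min):
        a, b = fb.labels[2 * m], fb.labels[2 * m + 1]
        lab = a  # dominant with tie -> earlier reduces to the first epoch
        if a != b and b == "wake" and a != "wake":
            lab = a
        if lab == "wake":
            labels[m] = "restless" if rng.random() < restless_prob else "awake"
        else:
            labels[m] = "asleep"
    return Hypnogram(start=fb.start, epoch_s=60.0, labels=labels)


def write_fitbit_json(truth: NightTruth, path, restless_prob: float = 0.2) -> None:
    """Emit one night in the vendor's JSON dialect.

    For a "stages" night the sleep log contains 30 s "levels" run records;
    isolated single-epoch wake runs are emitted as a separate short-wake
    record list (20 s records) with the main data continuing the
    neighbouring sleep stage -- re-merging the two sets reproduces the truth
    series exactly.  Nights shorter than three hours (or flagged) are
    written in the 1-min "classic" dialect only.  Intraday HR samples are
    appended under "heart".
    """
    import json

    fb = truth.fitbit_hypnogram
    classic = truth.force_classic or fb.duration < 3 * 3600.0
    log = {
        "logId": abs(hash(truth.subject_id)) % 10**12,
        "dateTime": _iso(fb.start),
        "startTime": _iso(fb.start),
        "endTime": _iso(fb.end),
    }
    if classic:
        series = _classic_from_stages(fb, restless_prob, truth.rng_seed)
        data = [
            {"dateTime": _iso(series.start + s * 60.0), "level": lab, "seconds": int(n * 60)}
            for s, n, lab in _runs(series.labels)
        ]
        log.update({"type": "classic", "levels": {"data": data, "shortData": []}})
    else:
        labels = fb.labels.copy()
        short = []
        runs = _runs(labels)
        for start, length, lab in runs:
            interior = 0 < start and start + length < len(labels)
            if lab == "wake" and length == 1 and interior:
                t0 = fb.start + 30.0 * start
                short.append({"dateTime": _iso(t0 + 5.0), "level": "wake", "seconds": 20})
                labels[start] = labels[start - 1]
        data = [
            {"dateTime": _iso(fb.start + 30.0 * s), "level": lab, "seconds": int(n * 30)}
            for s, n, lab in _runs(labels)
        ]
        log.update({"type": "stages", "levels": {"data": data, "shortData": short}})
    heart = []
    if truth.fitbit_hr is not None:
        heart = [
            {"dateTime": _iso(t), "value": int(v)}
            for t, v in zip(truth.fitbit_hr.times, truth.fitbit_hr.values)
        ]
    payload = {"sleep": [log], "heart": heart}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
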