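"""Simulation studies quantifying the pipeline's accuracy on synthetic
nights with known ground truth.

Each routine regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns summary metrics.  They are exercised by the test
suite and by ``scripts/acceptance.py``; problem sizes default to the
study conditions the generators encode (eight-hour nights, clock offsets
in the observed 1.9-7.5 min range, 200-beat ECG records with prominent
T waves, fifty-subject heart-rate panels).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clockalign, sleepvars, synthio
from .agreement import ConfusionCounts, confusion, ebe_metrics, mixed_loa
from .core import BeatSeries, Hypnogram, TRACKER_STAGES
from .ecgbeats import HARD_LIMITS, derive_cutoff, detect_beats
from .fitbit_records import FitbitNight, parse_night
from .pipeline import NightInput, RunConfig, run
from .synthio import gen_ecg, gen_night, write_fitbit_json


# ---------------------------------------------------------------------------
# Independent oracles


def ebe_counting_oracle(pairs: pd.DataFrame, target_stage: str, stage_map: dict = None):
    """Exhaustive per-epoch tally and direct formula evaluation,
    independent of the vectorised implementation."""
    from .core import PSG_TO_TRACKER

    stage_map = PSG_TO_TRACKER if stage_map is None else stage_map
    tp = fp = tn = fn = 0
    for psg_lab, fb_lab in zip(pairs["psg"], pairs["fitbit"]):
        p = stage_map[psg_lab] == target_stage
        f = fb_lab == target_stage
        if p and f:
            tp += 1
        elif p and not f:
            fn += 1
        elif f:
            fp += 1
        else:
            tn += 1

    import math

    def div(a, b):
        return a / b if b > 0 else float("nan")

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": div(tp, tp + fn), "specificity": div(tn, tn + fp),
        "accuracy": div(tp + tn, tp + fp + tn + fn), "mcc": mcc,
        "ppv": div(tp, tp + fp), "npv": div(tn, tn + fn),
    }


_METRICS = ("sensitivity", "specificity", "accuracy", "mcc", "ppv", "npv")


def _f1(detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.05) -> float:
    """F1 of detected beat times against truth with greedy matching."""
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    for t in detected:
        if len(truth) == 0:
            break
        j = int(np.argmin(np.abs(truth - t)))
        if abs(truth[j] - t) <= tol_s and not used[j]:
            used[j] = True
            tp += 1
    fp = len(detected) - tp
    fn = len(truth) - tp
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")


# ---------------------------------------------------------------------------
# Studies


def ebe_oracle_study(n_cases: int = 1000, max_epochs: int = 500, seed: int = 0) -> dict:
    """Agreement between ebe_metrics and the counting oracle on random
    paired label sequences."""
    rng = np.random.default_rng(seed)
    from .core import PSG_STAGES

    n_exact = 0
    worst = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(1, max_epochs + 1))
        pairs = pd.DataFrame({
            "psg": rng.choice(PSG_STAGES, size=n),
            "fitbit": rng.choice(TRACKER_STAGES, size=n),
            "epoch_start": 20.0 * np.arange(n),
        })
        stage = str(rng.choice(TRACKER_STAGES))
        c = confusion(pairs, stage)
        m = ebe_metrics(c)
        o = ebe_counting_oracle(pairs, stage)
        counts_ok = (c.tp, c.fp, c.tn, c.fn) == (o["tp"], o["fp"], o["tn"], o["fn"])
        diffs = []
        for k in _METRICS:
            a, b = getattr(m, k), o[k]
            if np.isnan(a) and np.isnan(b):
                continue
            diffs.append(abs(a - b))
        if counts_ok and (not diffs or max(diffs) == 0.0):
            n_exact += 1
        if diffs:
            worst = max(worst, max(diffs))
    return {"n_cases": n_cases, "n_exact": n_exact, "max_abs_diff": worst}


def worked_ebe_example() -> dict:
    """The fixed confusion-count example (tp=40, fn=60, fp=10, tn=90)."""
    m = ebe_metrics(ConfusionCounts(tp=40, fp=10, tn=90, fn=60, target_stage="rem"))
    return {k: getattr(m, k) for k in _METRICS}


def clock_shift_study(n_nights: int = 100, n_psg_epochs: int = 1440, seed: int = 0) -> dict:
    """Recovery of injected clock offsets from decimated, integer-rounded
    tracker HR versus beat-wise PSG HR."""
    rng = np.random.default_rng(seed)
    errors, corrs = [], []
    for i in range(n_nights):
        night = gen_night(f"shift{i:03d}", seed=int(rng.integers(0, 2**31 - 1)),
                          n_psg_epochs=n_psg_epochs)
        beats = BeatSeries(night.true_beat_times, np.arange(len(night.true_beat_times)))
        a = clockalign.interp_resample(clockalign.beats_to_hr_series(beats))
        b = clockalign.interp_resample(clockalign.center_tracker_hr(night.fitbit_hr))
        est = clockalign.estimate_shift(a, b)
        errors.append(abs(est.lag - night.clock_offset))
        corrs.append(est.peak_correlation)
    errors = np.asarray(errors)
    return {"n_nights": n_nights,
            "n_within_1s": int(np.sum(errors <= 1.0)),
            "max_abs_error_s": float(errors.max()),
            "min_peak_corr": float(np.min(corrs))}


def twave_rejection_study(n_records: int = 50, n_beats: int = 200, seed: int = 0,
                          r_amp: float = 1.0, t_over_r: float = 0.8,
                          noise_over_r: float = 0.05) -> dict:
    """Beat-detection F1 with and without the curvature screen on ECGs
    with prominent T waves."""
    rng = np.random.default_rng(seed)
    f1_with, f1_without, in_limits = [], [], 0
    n_improved = 0
    for i in range(n_records):
        beats = np.cumsum(rng.uniform(0.75, 1.05, n_beats)) + 1.0
        sig = gen_ecg(beats, fs=256.0, r_amp=r_amp, t_amp=t_over_r * r_amp,
                      noise_sd=noise_over_r * r_amp, seed=int(rng.integers(0, 2**31 - 1)))
        with_ = detect_beats(sig)
        without = detect_beats(sig, apply_t_rejection=False)
        a, b = _f1(with_.peak_times, beats), _f1(without.peak_times, beats)
        f1_with.append(a)
        f1_without.append(b)
        if a > b:
            n_improved += 1
        cut = derive_cutoff(without.qavsd_values)
        if cut.source == "density_minimum" and HARD_LIMITS[0] < cut.value < HARD_LIMITS[1]:
            in_limits += 1
    return {"n_records": n_records,
            "min_f1_with_rejection": float(np.min(f1_with)),
            "mean_f1_with_rejection": float(np.mean(f1_with)),
            "mean_f1_without_rejection": float(np.mean(f1_without)),
            "n_strictly_improved": n_improved,
            "frac_cutoff_in_limits": in_limits / n_records}


def simulate_ar1_panel(n_subjects: int, n_minutes: int, bias: float, sd_between: float,
                       sd_within: float, phi: float, rng) -> list:
    """Per-subject difference vectors from the random-intercept + AR(1)
    model (stationary innovations)."""
    groups = []
    for _ in range(n_subjects):
        b = rng.normal(0.0, sd_between)
        e = np.empty(n_minutes)
        e[0] = rng.normal(0.0, sd_within)
        innov = rng.normal(0.0, sd_within * np.sqrt(1.0 - phi * phi), n_minutes - 1)
        for t in range(1, n_minutes):
            e[t] = phi * e[t - 1] + innov[t - 1]
        groups.append(bias + b + e)
    return groups


def mixed_loa_recovery_study(n_replicates: int = 100, n_subjects: int = 50,
                             n_minutes: int = 400, bias: float = 0.9,
                             sd_between: float = 1.5, sd_within: float = 3.0,
                             phi: float = 0.5, seed: int = 0) -> dict:
    """Monte-Carlo recovery of the mixed-model parameters."""
    rng = np.random.default_rng(seed)
    covered = 0
    rel = {"sd_between": [], "sd_within": [], "phi": []}
    for _ in range(n_replicates):
        groups = simulate_ar1_panel(n_subjects, n_minutes, bias, sd_between,
                                    sd_within, phi, rng)
        fit = mixed_loa(groups)
        lo, hi = fit.bias_ci(0.95)
        if lo <= bias <= hi:
            covered += 1
        rel["sd_between"].append(abs(fit.sd_between - sd_between) / sd_between)
        rel["sd_within"].append(abs(fit.sd_within - sd_within) / sd_within)
        rel["phi"].append(abs(fit.phi - phi) / phi)
    return {"n_replicates": n_replicates,
            "bias_ci_coverage": covered,
            "median_rel_err_sd_between": float(np.median(rel["sd_between"])),
            "median_rel_err_sd_within": float(np.median(rel["sd_within"])),
            "median_rel_err_phi": float(np.median(rel["phi"]))}


def bland_altman_closed_form_check() -> dict:
    """Fixed difference vectors against hand-derived bias/SD/LoA."""
    from .agreement import bland_altman

    worst = 0.0
    # d = {-1, +1}: bias 0, SD sqrt(2), LoA -/+ 1.96 sqrt(2)
    ba = bland_altman([(-1.0, 0.0), (1.0, 0.0)])
    s2 = np.sqrt(2.0)
    worst = max(worst, abs(ba.bias), abs(ba.sd - s2),
                abs(ba.loa_lower + 1.96 * s2), abs(ba.loa_upper - 1.96 * s2))
    # d = {5, 5, 5}: bias 5, LoA collapse to the bias, p undefined
    ba2 = bland_altman([(5.0, 0.0)] * 3)
    worst = max(worst, abs(ba2.bias - 5.0), abs(ba2.loa_lower - 5.0),
                abs(ba2.loa_upper - 5.0), 0.0 if np.isnan(ba2.p_value) else 1.0)
    # d = 1..8: bias 4.5, SD of 1..8
    d = np.arange(1.0, 9.0)
    ba3 = bland_altman([(v, 0.0) for v in d])
    sd = float(np.std(d, ddof=1))
    worst = max(worst, abs(ba3.bias - 4.5), abs(ba3.loa_upper - (4.5 + 1.96 * sd)))
    return {"max_abs_error": worst}


def sleep_variable_checks(n_random: int = 1000, seed: int = 0) -> dict:
    """The worked seven-epoch hypnogram plus conservation identities on
    random PSG hypnograms."""
    h = Hypnogram(0.0, 20.0, np.array(["W", "N1", "N2", "N2", "W", "REM", "W"], dtype=object))
    s = sleepvars.summarize(h, "N1_on")
    worked = {
        "s_on_s": s.s_on, "s_off_s": s.s_off, "waso_s": s.waso * 60.0,
        "reml_s": s.reml * 60.0, "rem_d_s": s.rem_d * 60.0, "light_d_s": s.light_d * 60.0,
    }
    sB = sleepvars.summarize(h, "N1_on", tst_convention="B")
    worked["tst_convB_s"] = sB.tst * 60.0

    rng = np.random.default_rng(seed)
    from .core import PSG_STAGES

    worst = 0.0
    n_checked = 0
    for _ in range(n_random):
        n = int(rng.integers(2, 120))
        labels = rng.choice(PSG_STAGES, size=n)
        hyp = Hypnogram(0.0, 20.0, labels.astype(object))
        if "N1" not in labels:
            continue
        a = sleepvars.summarize(hyp, "N1_on", tst_convention="A")
        span = (a.s_off - a.s_on) / 60.0
        worst = max(worst, abs(a.tst + a.waso - span))
        worst = max(worst, abs(a.light_d + a.deep_d + a.rem_d - a.tst))
        n_checked += 1
    return {"worked": worked, "n_random_checked": n_checked,
            "max_abs_conservation_error_min": worst}


def roundtrip_study(n_nights: int = 100, n_psg_epochs: int = 720, seed: int = 0,
                    tmp_dir=None) -> dict:
    """Vendor-file round trip: write then parse, compare stage series and
    HR samples."""
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(seed)
    n_exact = 0
    with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
        path = Path(td) / "night.json"
        for i in range(n_nights):
            truth = gen_night(f"rt{i:03d}", seed=int(rng.integers(0, 2**31 - 1)),
                              n_psg_epochs=n_psg_epochs)
            write_fitbit_json(truth, path)
            parsed = parse_night(path)
            merged = parsed.hypnogram()
            ok = (
                parsed.datatype == "stages"
                and len(merged) == len(truth.fitbit_hypnogram)
                and all(a == b for a, b in zip(merged.labels, truth.fitbit_hypnogram.labels))
                and abs(merged.start - truth.fitbit_hypnogram.start) < 5e-4
                and len(parsed.hr_series) == len(truth.fitbit_hr)
                and np.array_equal(parsed.hr_series.values, truth.fitbit_hr.values)
                and np.allclose(parsed.hr_series.times, truth.fitbit_hr.times, atol=5e-4)
            )
            n_exact += bool(ok)
    return {"n_nights": n_nights, "n_exact": n_exact}


def _nights_from_truths(truths) -> list:
    nights = []
    for t in truths:
        fb = FitbitNight(datatype="stages", stage_series=t.fitbit_hypnogram,
                         short_wake=[], hr_series=t.fitbit_hr)
        beats = BeatSeries(t.true_beat_times, np.arange(len(t.true_beat_times)))
        nights.append(NightInput(subject_id=t.subject_id, psg_hypnogram=t.psg_hypnogram,
                                 fitbit=fb, psg_beats=beats))
    return nights


def inflate_tracker_waso(truth, extra_min: float = 30.0):
    """Flip interior tracker sleep epochs to wake, adding exactly
    ``extra_min`` of WASO without moving onset or offset."""
    fb = truth.fitbit_hypnogram
    labels = fb.labels.copy()
    sleep_idx = [i for i, lab in enumerate(labels) if lab != "wake"]
    first, last = sleep_idx[0], sleep_idx[-1]
    eligible = [i for i in sleep_idx if first < i < last]
    need = int(round(extra_min * 60.0 / fb.epoch_s))
    if len(eligible) < need:
        raise ValueError("night too short to inject the requested WASO")
    step = len(eligible) / need
    chosen = [eligible[int(k * step)] for k in range(need)]
    labels[chosen] = "wake"
    truth.fitbit_hypnogram = Hypnogram(fb.start, fb.epoch_s, labels)
    return truth


def _n1_entry_model():
    """Default sleep-architecture model constrained to enter sleep through
    N1 from wake.

    In the no-noise cohorts the PSG N1-onset criterion and the tracker's
    first-non-wake onset must denote the same instant; a night whose first
    sleep epoch is N2 would make the two onset definitions differ (and
    hence every onset-anchored variable) even with a perfect tracker.
    """
    m = synthio.default_psg_model()
    tm = m.transition_matrix.copy()
    w = tm[0].copy()
    tm[0] = 0.0
    tm[0, 0] = w[0]
    tm[0, 1] = w[1:].sum()
    return synthio.StageTransitionModel(m.states, tm, m.initial_distribution)


def effect_propagation_study(n_nights: int = 10, n_psg_epochs: int = 720,
                             seed: int = 0) -> dict:
    """End-to-end propagation of known effects through the full pipeline.

    Cohort A: identity confusion, zero offsets, block-aligned stage
    changes, sleep entered through N1 -- every EBE metric must be 1 and
    every sleep-variable bias 0 (clock variables up to the sub-step
    alignment residual).  Cohort B: the same nights with 30 min of tracker
    WASO injected -- the WASO bias must be -30 min (PSG minus tracker).
    """
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_nights)]
    kwargs = dict(n_psg_epochs=n_psg_epochs, confusion=np.eye(4), min_run_epochs=1,
                  clock_offset=0.0, stage_block_s=60.0, model=_n1_entry_model())
    truths_a = [gen_night(f"ident{i:02d}", seed=s, **kwargs) for i, s in enumerate(seeds)]
    rep_a = run(RunConfig(), nights=_nights_from_truths(truths_a))
    ba = rep_a.sleep_ba[rep_a.sleep_ba.adjusted]
    max_bias = float(ba["bias"].abs().max())
    pooled = rep_a.ebe[(rep_a.ebe.averaging == "pooled") & (rep_a.ebe.window == "all")]
    metric_cols = list(_METRICS)
    min_metric = float(pooled[metric_cols].min().min())

    truths_b = [inflate_tracker_waso(gen_night(f"waso{i:02d}", seed=s, **kwargs))
                for i, s in enumerate(seeds)]
    rep_b = run(RunConfig(), nights=_nights_from_truths(truths_b))
    ba_b = rep_b.sleep_ba[rep_b.sleep_ba.adjusted]
    waso_bias = float(ba_b.loc[ba_b.variable == "waso", "bias"].iloc[0])
    return {"n_nights": n_nights,
            "identity_max_abs_bias_min": max_bias,
            "identity_min_ebe_metric": min_metric,
            "injected_waso_bias_min": waso_bias}
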