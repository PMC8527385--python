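"""End-to-end orchestration over a cohort of nights.

A cohort is a directory with one sub-directory per night containing

* ``fitbit.json``     -- vendor-dialect sleep + intraday HR file,
* ``psg_hypnogram.tsv`` -- PSG stage sequence (20 s epochs),
* ``psg_beats.csv``   -- detected or ground-truth R-peak series, or
* ``ecg.csv``         -- raw ECG (time_s, value) from which beats are
  detected when no beat series is present.

:func:`run` parses every night, estimates and applies the tracker-PSG
clock shift, derives sleep variables under the configured onset criterion
(adjusted and unadjusted for bordering wake), computes per-minute trimmed
HR statistics and epoch-by-epoch pairs, and assembles the cohort
agreement report.  Nights that fail a stage are skipped with a logged,
machine-readable reason; the run fails only if every night fails.
Given a fixed configuration and seed the outputs are byte-identical
across reruns.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clockalign, sleepvars, synthio
from .agreement import AgreementReport, NightData, cohort_report, map_epochs
from .core import BeatSeries, Hypnogram
from .ecgbeats import detect_beats, read_ecg_csv
from .fitbit_records import FitbitNight, parse_night, trim_bordering_wake

logger = logging.getLogger(__name__)

#: Machine-readable night-exclusion codes.
EXCLUDE_CLASSIC = "classic_datatype"
EXCLUDE_PARSE = "parse_error"
EXCLUDE_ALIGN = "alignment_failed"
EXCLUDE_DERIVE = "derivation_failed"


@dataclass
class RunConfig:
    """Configuration of a cohort run; every analysis choice that the
    underlying study leaves ambiguous is an explicit key here."""

    onset_criterion: str = "N1_on"        # or "N2_on"
    border_adjust: bool = True
    tst_convention: str = "A"             # A: sleep time; B: S_off - S_on
    trim_per_tail: float = 0.10
    trim_mode: str = "per_tail"           # or "total"
    max_lag_min: float = 30.0
    step_s: float = 0.2
    hr_window: str = "methods_text"       # or "figure_caption"
    x_axis_mode: str = "psg_value"
    rem_threshold_min: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.trim_per_tail < 0.4):
            raise ValueError("trim_per_tail must be in [0, 0.4)")
        if self.max_lag_min <= 0:
            raise ValueError("max_lag_min must be positive")
        if self.onset_criterion not in sleepvars.ONSET_CRITERIA:
            raise ValueError(f"unknown onset criterion {self.onset_criterion!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class NightInput:
    """One night's raw inputs (in memory or on disk)."""

    subject_id: str
    psg_hypnogram: Hypnogram
    fitbit: FitbitNight
    psg_beats: BeatSeries = None

    @classmethod
    def from_dir(cls, night_dir) -> "NightInput":
        night_dir = Path(night_dir)
        psg_h = Hypnogram.from_tsv(night_dir / "psg_hypnogram.tsv")
        fitbit = parse_night(night_dir / "fitbit.json")
        beats = None
        if (night_dir / "psg_beats.csv").exists():
            beats = BeatSeries.from_csv(night_dir / "psg_beats.csv")
        elif (night_dir / "ecg.csv").exists():
            beats = detect_beats(read_ecg_csv(night_dir / "ecg.csv"))
        else:
            raise FileNotFoundError(f"{night_dir}: neither psg_beats.csv nor ecg.csv present")
        return cls(subject_id=night_dir.name, psg_hypnogram=psg_h, fitbit=fitbit,
                   psg_beats=beats)


def process_night(inp: NightInput, config: RunConfig) -> NightData:
    """Run the full per-night chain: align, merge, trim, derive, pair."""
    fitbit = inp.fitbit
    if fitbit.datatype == "classic":
        # Classic nights carry no stages/short-wake structure; they enter
        # only the run-length distributions.
        raise _NightExcluded(EXCLUDE_CLASSIC, run_lengths={
            "fitbit_classic": sleepvars.run_lengths(fitbit.stage_series)})

    psg_hr = clockalign.beats_to_hr_series(inp.psg_beats)
    fb_hr = clockalign.center_tracker_hr(fitbit.hr_series)
    a = clockalign.interp_resample(psg_hr, step_s=config.step_s)
    b = clockalign.interp_resample(fb_hr, step_s=config.step_s)
    shift = clockalign.estimate_shift(a, b, max_lag_s=config.max_lag_min * 60.0)
    aligned = clockalign.apply_shift(fitbit, shift)

    merged = aligned.hypnogram()
    trimmed, _adj = trim_bordering_wake(merged)

    crit = config.onset_criterion
    summaries = {}
    psg_summary = sleepvars.summarize(inp.psg_hypnogram, crit, config.tst_convention)
    for adj in (True, False):
        summaries[("psg", crit, adj)] = psg_summary
        summaries[("fitbit", crit, adj)] = sleepvars.summarize(
            trimmed if adj else merged, crit, config.tst_convention)

    ms = sleepvars.minute_hr_stats(
        inp.psg_beats, aligned.hr_series, inp.psg_hypnogram, criterion=crit,
        window="overall", hr_window_mode=config.hr_window,
        trim_per_tail=config.trim_per_tail, trim_mode=config.trim_mode)
    s_on = sleepvars.sleep_onset(inp.psg_hypnogram, crit)
    s_off = sleepvars.sleep_offset(inp.psg_hypnogram)
    if len(ms):
        ms["in_stage_window"] = (ms["minute_start"] >= s_on) & (ms["minute_start"] < s_off)

    pairs = map_epochs(inp.psg_hypnogram, merged)
    s_on_n1 = sleepvars.sleep_onset(inp.psg_hypnogram, "N1_on")
    runs = {"psg": sleepvars.run_lengths(inp.psg_hypnogram),
            "fitbit": sleepvars.run_lengths(merged)}
    return NightData(subject_id=inp.subject_id, summaries=summaries, minute_stats=ms,
                     ebe_pairs=pairs, s_on_n1=s_on_n1, run_lengths=runs,
                     shift_lag=shift.lag, shift_corr=shift.peak_correlation)


class _NightExcluded(Exception):
    def __init__(self, code: str, run_lengths: dict = None):
        super().__init__(code)
        self.code = code
        self.run_lengths = run_lengths or {}


def run(config: RunConfig, nights=None, cohort_dir=None, out_dir=None) -> AgreementReport:
    """Execute a cohort run.

    ``nights`` is a list of :class:`NightInput`; alternatively
    ``cohort_dir`` names a directory of night sub-directories.  When
    ``out_dir`` is given, per-night and cohort tables are written as CSV.
    """
    if nights is None:
        if cohort_dir is None:
            raise ValueError("provide nights or cohort_dir")
        night_dirs = sorted(p for p in Path(cohort_dir).iterdir() if p.is_dir())
        nights = []
        for nd in night_dirs:
            try:
                nights.append(NightInput.from_dir(nd))
            except (ValueError, FileNotFoundError) as exc:
                logger.warning("night %s excluded (%s): %s", nd.name, EXCLUDE_PARSE, exc)
    if not nights:
        raise ValueError("no parsable nights")

    processed, extra_runs = [], []
    for inp in nights:
        try:
            processed.append(process_night(inp, config))
        except _NightExcluded as exc:
            logger.info("night %s excluded (%s)", inp.subject_id, exc.code)
            for device, runs in exc.run_lengths.items():
                extra_runs.append((inp.subject_id, device, runs))
        except (ValueError, RuntimeError) as exc:
            logger.warning("night %s excluded (%s): %s", inp.subject_id, EXCLUDE_DERIVE, exc)
    if not processed:
        raise RuntimeError("all nights failed")

    report = cohort_report(processed, criteria=(config.onset_criterion,),
                           adjusted=(True, False) if config.border_adjust else (False,),
                           rem_threshold_min=config.rem_threshold_min)
    if extra_runs:
        rows = [{"subject": s, "device": dev, "stage": st, "duration_min": dur}
                for s, dev, runs in extra_runs for st, dur in runs]
        report.run_lengths = pd.concat([report.run_lengths, pd.DataFrame(rows)],
                                       ignore_index=True)
    if out_dir is not None:
        _write_report(report, processed, config, out_dir)
    return report


def _write_report(report: AgreementReport, processed, config: RunConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    fmt = "%.6f"
    report.sleep_ba.to_csv(out / "sleep_bland_altman.csv", index=False, float_format=fmt)
    report.hr_loa.to_csv(out / "hr_mixed_loa.csv", index=False, float_format=fmt)
    report.ebe.to_csv(out / "ebe_metrics.csv", index=False, float_format=fmt)
    report.run_lengths.to_csv(out / "run_lengths.csv", index=False, float_format=fmt)
    report.shifts.to_csv(out / "shifts.csv", index=False, float_format=fmt)
    rows = []
    for nd in processed:
        for (device, crit, adj), s in nd.summaries.items():
            row = {"subject": nd.subject_id, "device": device, "adjusted": adj}
            row.update(s.as_dict())
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "night_summaries.csv", index=False, float_format=fmt)
    ms_frames = []
    for nd in processed:
        if len(nd.minute_stats):
            m = nd.minute_stats.copy()
            m.insert(0, "subject", nd.subject_id)
            ms_frames.append(m)
    if ms_frames:
        pd.concat(ms_frames, ignore_index=True).to_csv(
            out / "minute_hr_stats.csv", index=False, float_format=fmt)


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(out_dir, n_nights: int, seed: int, with_ecg: bool = False,
                    **night_kwargs) -> list:
    """Write a synthetic cohort directory and return the night truths.

    Each night gets ``fitbit.json``, ``psg_hypnogram.tsv``,
    ``psg_beats.csv`` (ground-truth beat times) and, when ``with_ecg``,
    ``ecg.csv``; ``truth.yaml`` records the injected clock offset.
    Additional keyword arguments are forwarded to
    :func:`somnoval.synthio.gen_night`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truths = []
    for i in range(n_nights):
        sid = f"night{i:03d}"
        night_dir = out / sid
        night_dir.mkdir(exist_ok=True)
        truth = synthio.gen_night(sid, seed=int(rng.integers(0, 2**31 - 1)), **night_kwargs)
        synthio.write_fitbit_json(truth, night_dir / "fitbit.json")
        truth.psg_hypnogram.to_tsv(night_dir / "psg_hypnogram.tsv")
        beats = BeatSeries(truth.true_beat_times,
                           np.arange(len(truth.true_beat_times)))
        beats.to_csv(night_dir / "psg_beats.csv")
        if with_ecg:
            ecg = synthio.gen_ecg(truth.true_beat_times, fs=256.0, t_amp=0.3,
                                  noise_sd=0.05, seed=truth.rng_seed)
            with open(night_dir / "ecg.csv", "w") as fh:
                fh.write("time_s,value\n")
                t = ecg.times()
                for ti, vi in zip(t, ecg.values):
                    fh.write(f"{ti:.6f},{vi:.5f}\n")
        with open(night_dir / "truth.yaml", "w") as fh:
            yaml.safe_dump({"subject_id": sid, "clock_offset_s": float(truth.clock_offset),
                            "rng_seed": int(truth.rng_seed)}, fh)
        truths.append(truth)
    return truths
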