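"""Per-night sleep variables, run-length distributions and per-minute
trimmed heart-rate statistics.

Sleep variables depend on an explicit onset criterion: S_on is the start
of the first N1 epoch (criterion ``N1_on``) or first N2 epoch (``N2_on``)
for PSG series, and the first non-wake epoch for tracker series (the
tracker does not distinguish N1 from N2).  S_off is the end of the last
non-wake epoch.  Two total-sleep-time conventions are supported:
convention A counts actual sleep-stage time inside [S_on, S_off] (so
TST_A + WASO = S_off - S_on exactly), convention B takes the sleep period
S_off - S_on itself.

Heart-rate summaries use the 10%-trimmed mean (HR_10) and 10%-trimmed
variance (HRvar_10) of the values inside each clock minute, computed for
both devices, with the minute's sleep stage taken as the PSG stage
covering more than half of the minute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BeatSeries, Hypnogram, HRSeries, is_wake
from .ecgbeats import ibi_to_bpm

logger = logging.getLogger(__name__)

ONSET_CRITERIA = ("N1_on", "N2_on")
_CRITERION_STAGE = {"N1_on": "N1", "N2_on": "N2"}
_REM_LABELS = frozenset({"REM", "rem"})
_LIGHT_LABELS = frozenset({"N1", "N2", "light"})
_DEEP_LABELS = frozenset({"N3", "deep"})


@dataclass
class SleepSummary:
    """Per-night sleep variables under a stated onset criterion.

    Clock times in seconds; durations in minutes.  ``reml`` is NaN when no
    REM occurs after onset.
    """

    criterion: str
    s_on: float
    s_off: float
    tst: float
    waso: float
    reml: float
    rem_d: float
    light_d: float
    deep_d: float
    tst_convention: str = "A"

    def as_dict(self) -> dict:
        return {
            "criterion": self.criterion, "s_on": self.s_on, "s_off": self.s_off,
            "tst": self.tst, "waso": self.waso, "reml": self.reml,
            "rem_d": self.rem_d, "light_d": self.light_d, "deep_d": self.deep_d,
            "tst_convention": self.tst_convention,
        }


def _is_tracker(h: Hypnogram) -> bool:
    """A series is treated as PSG iff it uses any PSG stage label."""
    from .core import PSG_STAGES

    return not (set(h.labels.tolist()) & set(PSG_STAGES))


def sleep_onset(h: Hypnogram, criterion: str = "N1_on"):
    """Clock time of sleep onset, or NaN (with a warning) if the criterion
    stage never occurs.

    PSG series: start of the first epoch labelled with the criterion stage.
    Tracker series: start of the first non-wake epoch (criterion ignored
    beyond validation).
    """
    if criterion not in ONSET_CRITERIA:
        raise ValueError(f"criterion must be one of {ONSET_CRITERIA}")
    if _is_tracker(h):
        hits = [i for i, lab in enumerate(h.labels) if not is_wake(lab)]
    else:
        stage = _CRITERION_STAGE[criterion]
        hits = [i for i, lab in enumerate(h.labels) if lab == stage]
    if not hits:
        logger.warning("onset criterion stage absent; S_on undefined")
        return float("nan")
    return h.start + hits[0] * h.epoch_s


def sleep_offset(h: Hypnogram):
    """End time of the last non-wake epoch, NaN if the night has no sleep."""
    hits = [i for i, lab in enumerate(h.labels) if not is_wake(lab)]
    if not hits:
        logger.warning("no sleep epochs; S_off undefined")
        return float("nan")
    return h.start + (hits[-1] + 1) * h.epoch_s


def summarize(h: Hypnogram, criterion: str = "N1_on", tst_convention: str = "A") -> SleepSummary:
    """Derive all per-night sleep variables.

    WASO is wake time strictly inside [S_on, S_off]; REML is the latency
    from S_on to the first REM epoch at or after S_on.  Stage durations
    (rem_d, light_d, deep_d) count epochs inside [S_on, S_off]; for PSG
    alphabets light_d covers N1+N2 and deep_d covers N3, mirroring the
    tracker's light/deep stages.
    """
    if tst_convention not in ("A", "B"):
        raise ValueError("tst_convention must be 'A' or 'B'")
    s_on = sleep_onset(h, criterion)
    if not np.isfinite(s_on):
        raise ValueError("sleep onset undefined: criterion stage absent")
    s_off = sleep_offset(h)
    starts = h.epoch_starts()
    inside = (starts >= s_on) & (starts < s_off)
    labs = h.labels[inside]
    ep_min = h.epoch_s / 60.0
    waso = sum(ep_min for lab in labs if is_wake(lab))
    span_min = (s_off - s_on) / 60.0
    tst = span_min - waso if tst_convention == "A" else span_min
    rem_idx = [i for i, lab in enumerate(h.labels)
               if lab in _REM_LABELS and starts[i] >= s_on]
    reml = (starts[rem_idx[0]] - s_on) / 60.0 if rem_idx else float("nan")
    rem_d = sum(ep_min for lab in labs if lab in _REM_LABELS)
    light_d = sum(ep_min for lab in labs if lab in _LIGHT_LABELS)
    deep_d = sum(ep_min for lab in labs if lab in _DEEP_LABELS)
    return SleepSummary(criterion=criterion, s_on=float(s_on), s_off=float(s_off),
                        tst=tst, waso=waso, reml=reml, rem_d=rem_d,
                        light_d=light_d, deep_d=deep_d, tst_convention=tst_convention)


def run_lengths(h: Hypnogram):
    """Maximal-run decomposition as (stage, duration in minutes) tuples.

    A run is a block of consecutive epochs sharing one stage, terminated by
    any other stage regardless of the interruption's length.  Durations sum
    to the night duration exactly.
    """
    out = []
    i, n = 0, len(h.labels)
    while i < n:
        j = i
        while j < n and h.labels[j] == h.labels[i]:
            j += 1
        out.append((h.labels[i], (j - i) * h.epoch_s / 60.0))
        i = j
    return out


# ---------------------------------------------------------------------------
# Trimmed statistics


def _trim(values: np.ndarray, trim_per_tail: float, mode: str) -> np.ndarray:
    if not 0 <= trim_per_tail < 0.5:
        raise ValueError("trim fraction must be in [0, 0.5)")
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("need at least one value")
    if mode == "per_tail":
        k = int(np.floor(len(v) * trim_per_tail))
    elif mode == "total":
        k = int(np.floor(len(v) * trim_per_tail / 2.0))
    else:
        raise ValueError("mode must be 'per_tail' or 'total'")
    return v[k:len(v) - k]


def trimmed_mean(values, trim_per_tail: float = 0.10, mode: str = "per_tail") -> float:
    """Mean after dropping ``floor(n*trim)`` order statistics from each tail
    (mode "total" splits the fraction across the tails)."""
    return float(np.mean(_trim(values, trim_per_tail, mode)))


def trimmed_var(values, trim_per_tail: float = 0.10, mode: str = "per_tail") -> float:
    """Sample variance (denominator n_kept - 1) of the trimmed values; NaN
    when a single value survives trimming."""
    kept = _trim(values, trim_per_tail, mode)
    if len(kept) < 2:
        return float("nan")
    return float(np.var(kept, ddof=1))


# ---------------------------------------------------------------------------
# Per-minute heart-rate statistics


def dominant_stage(h: Hypnogram, t0: float, t1: float):
    """Stage with the largest overlap with [t0, t1); ties go to the
    earlier-starting stage; None when the window has no overlap at all."""
    overlap, first = {}, {}
    for i, lab in enumerate(h.labels):
        e0 = h.start + i * h.epoch_s
        e1 = e0 + h.epoch_s
        ov = min(t1, e1) - max(t0, e0)
        if ov > 0:
            overlap[lab] = overlap.get(lab, 0.0) + ov
            first.setdefault(lab, e0)
    if not overlap:
        return None
    best = max(overlap.values())
    winners = sorted((lab for lab, ov in overlap.items()
                      if np.isclose(ov, best, atol=1e-9)), key=lambda lab: first[lab])
    return winners[0]


def minute_hr_stats(psg_beats: BeatSeries, fitbit_hr: HRSeries, psg_h: Hypnogram,
                    criterion: str = "N1_on", window: str = "by_stage",
                    hr_window_mode: str = "methods_text",
                    trim_per_tail: float = 0.10, trim_mode: str = "per_tail") -> pd.DataFrame:
    """Per-minute trimmed HR statistics for both devices.

    ``window="overall"`` spans S_on - 30 min to S_off (mode
    "figure_caption" extends to S_off + 30 min); ``window="by_stage"``
    spans S_on to S_off.  PSG values in a minute are 60/IBI for the
    intervals closing in that minute; tracker values are the samples in the
    minute.  Minutes with no sample on either device are excluded and
    logged.  Returns a DataFrame with one row per retained minute.
    """
    s_on = sleep_onset(psg_h, criterion)
    s_off = sleep_offset(psg_h)
    if not (np.isfinite(s_on) and np.isfinite(s_off)):
        raise ValueError("onset/offset undefined for this night")
    if window == "overall":
        t0 = s_on - 30.0 * 60.0
        t1 = s_off + (30.0 * 60.0 if hr_window_mode == "figure_caption" else 0.0)
    elif window == "by_stage":
        t0, t1 = s_on, s_off
    else:
        raise ValueError("window must be 'overall' or 'by_stage'")

    psg_hr_times = psg_beats.peak_times[1:]
    psg_hr_vals = ibi_to_bpm(psg_beats.ibis)
    rows, n_excluded = [], 0
    n_min = int((t1 - t0) // 60.0)
    for m in range(n_min):
        m0, m1 = t0 + 60.0 * m, t0 + 60.0 * (m + 1)
        pv = psg_hr_vals[(psg_hr_times >= m0) & (psg_hr_times < m1)]
        fv = fitbit_hr.values[(fitbit_hr.times >= m0) & (fitbit_hr.times < m1)]
        if len(pv) == 0 or len(fv) == 0:
            n_excluded += 1
            continue
        rows.append({
            "minute_start": m0,
            "stage": dominant_stage(psg_h, m0, m1),
            "psg_hr10": trimmed_mean(pv, trim_per_tail, trim_mode),
            "psg_hrvar10": trimmed_var(pv, trim_per_tail, trim_mode),
            "fitbit_hr10": trimmed_mean(fv, trim_per_tail, trim_mode),
            "fitbit_hrvar10": trimmed_var(fv, trim_per_tail, trim_mode),
            "n_psg": len(pv),
            "n_fitbit": len(fv),
        })
    if n_excluded:
        logger.info("minute_hr_stats: excluded %d minutes with no samples on one device",
                    n_excluded)
    return pd.DataFrame(rows)
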