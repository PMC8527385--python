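"""Parsing and reconstruction of tracker sleep and heart-rate records.

The vendor emits one JSON file per collection date with two sleep-record
dialects.  "Stages" nights carry 30 s run records over wake/light/deep/rem
plus a *separate* list of short (<30 s) wake records; wakefulness after
sleep onset can only be reconstructed by merging the two sets.  "Classic"
nights (sleep episodes under three hours, low battery, poor skin contact)
carry 1-min asleep/restless/awake records only.  Intraday heart rate is a
flat list of integer-bpm samples at irregular 2-15 s intervals.

This module parses the dialect, merges the stages and short-wake sets into
a single 30 s hypnogram, and applies the bordering-wake adjustment: the
vendor's staging sometimes brackets a sleep episode with wake epochs, which
would corrupt onset/offset-derived variables, so maximal leading and
trailing wake runs are removed and the implied corrections to onset,
offset, total sleep time and WASO reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import CLASSIC_STAGES, TRACKER_STAGES, Hypnogram, HRSeries, is_wake
from .synthio import iso_to_seconds


@dataclass
class WakeRecord:
    """One short-wake record: a wake episode shorter than a tracker epoch."""

    start: float
    seconds: float


@dataclass
class FitbitNight:
    """Parsed tracker night.

    ``stage_series`` is the sleep-set hypnogram as recorded (30 s epochs
    for the stages dialect, 60 s for classic); ``short_wake`` holds the
    separate sub-30 s wake records of a stages night.  Use
    :func:`merge_sleep_and_wake` (or :meth:`hypnogram`) to obtain the
    reconstructed series.
    """

    datatype: str
    stage_series: Hypnogram
    short_wake: list
    hr_series: HRSeries
    raw_records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.datatype not in ("classic", "stages"):
            raise ValueError(f"unknown datatype {self.datatype!r}")
        alphabet = set(TRACKER_STAGES) if self.datatype == "stages" else set(CLASSIC_STAGES)
        bad = set(self.stage_series.labels) - alphabet
        if bad:
            raise ValueError(f"stage labels outside the {self.datatype} alphabet: {bad}")

    def hypnogram(self) -> Hypnogram:
        """Stage series with the short-wake set merged in (stages dialect);
        classic nights return the series unchanged."""
        if self.datatype == "classic":
            return self.stage_series
        return merge_sleep_and_wake(self.stage_series, self.short_wake)

    def shifted(self, delta_s: float) -> "FitbitNight":
        """Copy with all tracker timestamps translated by ``delta_s``."""
        return FitbitNight(
            self.datatype,
            self.stage_series.shifted(delta_s),
            [WakeRecord(w.start + delta_s, w.seconds) for w in self.short_wake],
            self.hr_series.shifted(delta_s),
            self.raw_records,
        )


@dataclass
class BorderAdjustment:
    """Deltas implied by removing bordering wake from a tracker night.

    Onset moves later by the leading wake removed, offset earlier by the
    trailing wake removed; total sleep time and WASO shrink accordingly.
    """

    leading_wake_s: float
    trailing_wake_s: float

    @property
    def delta_s_on(self) -> float:
        return +self.leading_wake_s

    @property
    def delta_s_off(self) -> float:
        return -self.trailing_wake_s

    @property
    def delta_tst(self) -> float:
        return -(self.leading_wake_s + self.trailing_wake_s)

    @property
    def delta_waso(self) -> float:
        # Bordering wake lies outside [S_on, S_off] once trimmed, so it
        # never counted toward WASO; the adjustment leaves WASO unchanged.
        return 0.0


# ---------------------------------------------------------------------------
# Parsing


def _parse_levels(level_records, epoch_s: float, alphabet, what: str) -> Hypnogram:
    recs = []
    for rec in level_records:
        try:
            start = iso_to_seconds(rec["dateTime"])
            level = rec["level"]
            seconds = float(rec["seconds"])
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed {what} record {rec!r}") from exc
        if level not in alphabet:
            raise ValueError(f"malformed {what} record {rec!r}: unknown level {level!r}")
        if seconds <= 0 or seconds % epoch_s:
            raise ValueError(
                f"malformed {what} record {rec!r}: seconds not a positive multiple of {epoch_s:g}")
        recs.append((start, seconds, level))
    recs.sort(key=lambda r: r[0])
    for (s0, d0, _), (s1, _, _) in zip(recs, recs[1:]):
        if s1 < s0 + d0 - 1e-9:
            raise ValueError(f"overlapping level records at t={s1:.1f}s")
        if s1 > s0 + d0 + 1e-9:
            raise ValueError(f"gap between level records at t={s0 + d0:.1f}s")
    labels = []
    for start, seconds, level in recs:
        labels.extend([level] * int(round(seconds / epoch_s)))
    return Hypnogram(start=recs[0][0], epoch_s=epoch_s, labels=np.array(labels, dtype=object))


def parse_night(path) -> FitbitNight:
    """Parse one vendor JSON file into a :class:`FitbitNight`.

    The datatype is taken from the sleep log's ``type`` field when present
    and otherwise detected from the record granularity (30 s multiples with
    four-stage levels versus 1-min three-level records).
    """
    with open(path) as fh:
        payload = json.load(fh)
    sleep_logs = payload.get("sleep", [])
    if len(sleep_logs) != 1:
        raise ValueError(f"expected exactly one sleep log, found {len(sleep_logs)}")
    log = sleep_logs[0]
    levels = log.get("levels", {})
    data = levels.get("data", [])
    if not data:
        raise ValueError("sleep log contains no level records")

    datatype = log.get("type")
    if datatype is None:
        seen = {rec.get("level") for rec in data}
        datatype = "classic" if seen & set(CLASSIC_STAGES) else "stages"
    if datatype == "stages":
        series = _parse_levels(data, 30.0, set(TRACKER_STAGES), "stages")
        short = []
        for rec in levels.get("shortData", []):
            try:
                start = iso_to_seconds(rec["dateTime"])
                seconds = float(rec["seconds"])
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"malformed short-wake record {rec!r}") from exc
            if rec.get("level") != "wake":
                raise ValueError(f"malformed short-wake record {rec!r}: level must be 'wake'")
            if not (0 < seconds < 30):
                raise ValueError(f"malformed short-wake record {rec!r}: must be <30 s")
            short.append(WakeRecord(start, seconds))
        short.sort(key=lambda w: w.start)
    else:
        series = _parse_levels(data, 60.0, set(CLASSIC_STAGES), "classic")
        short = []

    hr_records = payload.get("heart", [])
    times, values = [], []
    for rec in hr_records:
        try:
            times.append(iso_to_seconds(rec["dateTime"]))
            values.append(float(rec["value"]))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed heart-rate record {rec!r}") from exc
    hr = HRSeries(np.asarray(times), np.asarray(values), device="fitbit")
    return FitbitNight(datatype=datatype, stage_series=series, short_wake=short,
                       hr_series=hr, raw_records=[log])


# ---------------------------------------------------------------------------
# Merging and border adjustment


def merge_sleep_and_wake(stage_series: Hypnogram, short_wake,
                         overlap_threshold_s: float = 15.0) -> Hypnogram:
    """Merge the stages sleep set with the short-wake record set.

    Any 30 s epoch overlapped by a single short-wake record for at least
    ``overlap_threshold_s`` (half an epoch by default) is relabelled wake;
    a record straddling an epoch boundary 10 s + 10 s therefore relabels
    neither epoch.
    all other epochs keep their sleep-set label.  Wake records outside the
    sleep-log span are clipped with a warning.  No epochs are created or
    destroyed, so total labelled time is conserved.
    """
    import warnings

    labels = stage_series.labels.copy()
    n = len(labels)
    overlap = np.zeros(n)
    for rec in short_wake:
        w0, w1 = rec.start, rec.start + rec.seconds
        if w1 <= stage_series.start or w0 >= stage_series.end:
            warnings.warn(f"short-wake record at t={rec.start:.1f}s outside the sleep log span; clipped")
            continue
        k0 = max(int((w0 - stage_series.start) // stage_series.epoch_s), 0)
        k1 = min(int(np.ceil((w1 - stage_series.start) / stage_series.epoch_s)), n)
        for k in range(k0, k1):
            e0 = stage_series.start + k * stage_series.epoch_s
            ov = max(0.0, min(w1, e0 + stage_series.epoch_s) - max(w0, e0))
            overlap[k] = max(overlap[k], ov)
    labels[overlap >= overlap_threshold_s] = "wake"
    return Hypnogram(stage_series.start, stage_series.epoch_s, labels)


def trim_bordering_wake(series: Hypnogram):
    """Remove maximal leading and trailing wake runs.

    Returns the trimmed hypnogram and the :class:`BorderAdjustment`
    reporting how onset/offset-derived variables move.  A series with no
    sleep at all has no sleep episode to delimit and raises.
    """
    n = len(series)
    lead = 0
    while lead < n and is_wake(series.labels[lead]):
        lead += 1
    if lead == n:
        raise ValueError("all-wake series: no sleep episode to trim to")
    trail = 0
    while is_wake(series.labels[n - 1 - trail]):
        trail += 1
    trimmed = Hypnogram(series.start + lead * series.epoch_s, series.epoch_s,
                        series.labels[lead:n - trail].copy())
    adj = BorderAdjustment(leading_wake_s=lead * series.epoch_s,
                           trailing_wake_s=trail * series.epoch_s)
    return trimmed, adj


def count_hr_per_minute(hr: HRSeries, span=None) -> np.ndarray:
    """Number of HR samples in each clock minute of ``span = (t0, t1)``.

    Minutes are half-open ``[t0 + 60k, t0 + 60(k+1))``; the span defaults
    to the sample range and must cover at least one full minute.
    """
    if span is None:
        if len(hr) == 0:
            raise ValueError("empty series and no span given")
        span = (hr.times[0], hr.times[-1])
    t0, t1 = span
    n_min = int((t1 - t0) // 60.0)
    if n_min < 1:
        raise ValueError("span must cover at least one minute")
    counts = np.zeros(n_min, dtype=int)
    for t in hr.times:
        k = int((t - t0) // 60.0)
        if 0 <= k < n_min:
            counts[k] += 1
    return counts
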