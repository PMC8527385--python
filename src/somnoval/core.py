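"""Core containers shared across the validation pipeline.

The pipeline compares two nocturnal recordings of the same night: a
polysomnogram (PSG; the reference standard, staged visually in fixed
20-second epochs with stages W/N1/N2/N3/REM) and a wrist multisensor
tracker whose "stages" record dialect reports wake/light/deep/rem in
30-second epochs plus intraday heart-rate samples at irregular 2-15 s
intervals.  All timestamps are carried as seconds since an arbitrary
absolute epoch; stage epochs are half-open intervals ``[t, t + epoch_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Stage alphabets.  "W"/"wake"/"awake" denote wakefulness in the PSG,
# tracker-stages and tracker-classic dialects respectively; "restless" is a
# classic-dialect label of unknown physiological meaning and is carried
# through without semantic claims.
PSG_STAGES = ("W", "N1", "N2", "N3", "REM")
TRACKER_STAGES = ("wake", "light", "deep", "rem")
CLASSIC_STAGES = ("awake", "restless", "asleep")
WAKE_LABELS = frozenset({"W", "wake", "awake"})

#: PSG -> tracker stage equivalence used throughout (light captures N1+N2,
#: deep captures N3).
PSG_TO_TRACKER = {"W": "wake", "N1": "light", "N2": "light", "N3": "deep", "REM": "rem"}

VALID_EPOCH_LENGTHS = (20.0, 30.0, 60.0)


def is_wake(label: str) -> bool:
    return label in WAKE_LABELS


@dataclass
class Hypnogram:
    """Fixed-epoch sequence of sleep-stage labels.

    Parameters
    ----------
    start : float
        Clock time of the first epoch, seconds since the absolute epoch.
    epoch_s : float
        Epoch length in seconds; 20 for PSG, 30 for tracker "stages",
        60 for tracker "classic".
    labels : sequence of str
        One stage label per epoch.
    """

    start: float
    epoch_s: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if float(self.epoch_s) not in VALID_EPOCH_LENGTHS:
            raise ValueError(f"epoch_s must be one of {VALID_EPOCH_LENGTHS}, got {self.epoch_s}")
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def end(self) -> float:
        """Clock time one past the final epoch."""
        return self.start + self.epoch_s * len(self.labels)

    @property
    def duration(self) -> float:
        return self.epoch_s * len(self.labels)

    def epoch_starts(self) -> np.ndarray:
        return self.start + self.epoch_s * np.arange(len(self.labels))

    def shifted(self, delta_s: float) -> "Hypnogram":
        """Copy with every timestamp translated by ``delta_s`` seconds."""
        return Hypnogram(self.start + delta_s, self.epoch_s, self.labels.copy())

    def to_tsv(self, path) -> None:
        """Write as two-column TSV (epoch_start_s, stage)."""
        starts = self.epoch_starts()
        with open(path, "w") as fh:
            fh.write("epoch_start_s\tstage\n")
            for t, lab in zip(starts, self.labels):
                fh.write(f"{t:.3f}\t{lab}\n")

    @classmethod
    def from_tsv(cls, path) -> "Hypnogram":
        starts, labels = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("epoch_start_s"):
                raise ValueError(f"unrecognised hypnogram TSV header: {header!r}")
            for line in fh:
                if not line.strip():
                    continue
                t, lab = line.rstrip("\n").split("\t")
                starts.append(float(t))
                labels.append(lab)
        if len(starts) < 1:
            raise ValueError("empty hypnogram file")
        if len(starts) > 1:
            steps = np.diff(starts)
            epoch_s = float(steps[0])
            if not np.allclose(steps, epoch_s, atol=1e-6):
                raise ValueError("hypnogram TSV epochs are not equally spaced")
        else:
            epoch_s = 30.0
        return cls(start=float(starts[0]), epoch_s=round(epoch_s, 6), labels=np.array(labels, dtype=object))


@dataclass
class HRSeries:
    """Irregularly timestamped heart-rate samples for one device.

    The tracker reports integer bpm at 2-15 s intervals; the PSG side is
    derived from inter-beat intervals and is real-valued.
    """

    times: np.ndarray
    values: np.ndarray
    device: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("HR sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def shifted(self, delta_s: float) -> "HRSeries":
        return HRSeries(self.times + delta_s, self.values.copy(), self.device)


@dataclass
class SampledSignal:
    """Uniformly sampled single-channel signal (the ECG trace).

    ``values`` are in the declared ``units`` (mV by default), sampled at
    ``fs`` Hz starting at clock time ``start_time`` seconds.
    """

    values: np.ndarray
    fs: float
    start_time: float = 0.0
    units: str = "mV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.fs

    def index_to_time(self, idx) -> np.ndarray:
        return self.start_time + np.asarray(idx) / self.fs


@dataclass
class BeatSeries:
    """Detected R peaks with inter-beat intervals and per-peak curvature.

    ``qavsd_values`` holds the 60% quantile of the absolute second
    derivative around each (realigned) peak, the statistic used to
    discriminate sharp R apexes from slower T waves.
    """

    peak_times: np.ndarray
    peak_indices: np.ndarray
    qavsd_values: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.qavsd_values is None:
            self.qavsd_values = np.full(len(self.peak_times), np.nan)
        self.qavsd_values = np.asarray(self.qavsd_values, dtype=float)
        if len(self.peak_times) > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals in seconds (length ``n_peaks - 1``)."""
        return np.diff(self.peak_times)

    def to_csv(self, path) -> None:
        """Write as CSV (peak_time_s, ibi_s, qavsd); ibi_s is the interval
        *ending* at the peak (empty for the first peak)."""
        with open(path, "w") as fh:
            fh.write("peak_time_s,ibi_s,qavsd\n")
            for i, (t, q) in enumerate(zip(self.peak_times, self.qavsd_values)):
                ibi = "" if i == 0 else f"{self.peak_times[i] - self.peak_times[i - 1]:.6f}"
                fh.write(f"{t:.6f},{ibi},{q:.6f}\n")

    @classmethod
    def from_csv(cls, path) -> "BeatSeries":
        times, qs = [], []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                t, _ibi, q = line.rstrip("\n").split(",")
                times.append(float(t))
                qs.append(float(q) if q else np.nan)
        times = np.asarray(times)
        return cls(times, np.full(len(times), -1, dtype=int), np.asarray(qs))
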