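"""Data-driven clock alignment between PSG-derived and tracker heart rate.

The two recording systems do not share a clock; per-night misalignments of
1.9-7.5 minutes were observed in the cohort this toolkit targets.  Both
heart-rate series are linearly interpolated, resampled on a common 0.2 s
grid, and the lag maximising their Pearson cross-correlation is taken as
the tracker-minus-PSG clock offset, which is then subtracted from every
tracker timestamp.

Correlations are computed over jointly valid grid points only: grid points
outside a series' sample range, or inside gaps longer than five minutes
(artifact-masked ECG segments), are flagged invalid so they cannot bias
the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core import BeatSeries, HRSeries
from .ecgbeats import ibi_to_bpm

DEFAULT_STEP_S = 0.2
DEFAULT_MAX_LAG_S = 30.0 * 60.0  # observed offsets are <= 7.5 min; 30 min is safely wide
MAX_GAP_S = 5.0 * 60.0


@dataclass
class RegularSeries:
    """Regularly resampled series with a validity mask."""

    start: float
    step: float
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must have equal length")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("valid samples must be finite")


@dataclass
class ShiftEstimate:
    """Estimated clock lag (tracker minus PSG, seconds) and its peak
    cross-correlation."""

    lag: float
    peak_correlation: float
    search_range: float

    def __post_init__(self) -> None:
        if abs(self.lag) > self.search_range + 1e-9:
            raise ValueError("lag outside the search range")


def beats_to_hr_series(beats: BeatSeries, device: str = "psg",
                       at: str = "midpoint") -> HRSeries:
    """Beat-wise heart rate: 60/IBI per inter-beat interval.

    Each value summarises one interval, so by default it is assigned to the
    interval midpoint (``at="end"`` assigns it to the closing beat
    instead).  Midpoint assignment keeps the series free of the half-
    interval reporting delay that would otherwise bias lag estimates.
    """
    if len(beats) < 2:
        raise ValueError("need at least 2 beats for an HR series")
    if at == "midpoint":
        times = 0.5 * (beats.peak_times[1:] + beats.peak_times[:-1])
    elif at == "end":
        times = beats.peak_times[1:]
    else:
        raise ValueError("at must be 'midpoint' or 'end'")
    return HRSeries(times, ibi_to_bpm(beats.ibis), device=device)


def center_tracker_hr(hr: HRSeries) -> HRSeries:
    """Re-assign tracker HR samples to the midpoint of their measurement
    interval.

    The tracker reports the average over the preceding 5-15 s interval at
    the interval's end; shifting each sample back by half the gap to its
    predecessor removes the resulting half-interval reporting delay (the
    first sample, whose interval is unknown, is dropped).
    """
    if len(hr) < 2:
        raise ValueError("need at least 2 samples")
    gaps = np.diff(hr.times)
    return HRSeries(hr.times[1:] - 0.5 * gaps, hr.values[1:].copy(), device=hr.device)


def interp_resample(hr: HRSeries, step_s: float = DEFAULT_STEP_S,
                    max_gap_s: float = MAX_GAP_S) -> RegularSeries:
    """Linear interpolation onto a regular grid spanning [first, last] sample.

    No extrapolation: the grid starts at the first sample.  Gaps between
    samples are interpolated regardless of length, but grid points falling
    inside gaps longer than ``max_gap_s`` are marked invalid.
    """
    if len(hr) < 2:
        raise ValueError("need at least 2 samples to interpolate")
    t0, t1 = hr.times[0], hr.times[-1]
    n = int(np.floor((t1 - t0) / step_s)) + 1
    grid = t0 + step_s * np.arange(n)
    values = np.interp(grid, hr.times, hr.values)
    valid = np.ones(n, dtype=bool)
    gaps = np.diff(hr.times)
    for j in np.nonzero(gaps > max_gap_s)[0]:
        a, b = hr.times[j], hr.times[j + 1]
        valid[(grid > a) & (grid < b)] = False
    return RegularSeries(start=float(t0), step=step_s, values=values, valid_mask=valid)


def _masked_corr_by_lag(a: RegularSeries, b: RegularSeries):
    """Pearson correlation of jointly valid points for every integer lag.

    Lag ``k`` compares ``a[i]`` with ``b[i - k - base]`` where ``base``
    accounts for the difference in grid start times; positive physical lag
    means b's content occurs later on the common clock.  All five sliding
    sums are obtained with FFT cross-correlations, so the per-lag Pearson
    coefficients are exact up to floating-point error.
    """
    ma = a.valid_mask.astype(float)
    mb = b.valid_mask.astype(float)
    xa = np.where(a.valid_mask, a.values, 0.0)
    xb = np.where(b.valid_mask, b.values, 0.0)

    def corr(u, v):
        # c[k] = sum_i u[i] * v[i - k], k = -(len(v)-1) .. len(u)-1
        return fftconvolve(u, v[::-1], mode="full")

    n_ab = corr(ma, mb)
    s_a = corr(xa, mb)
    s_b = corr(ma, xb)
    s_ab = corr(xa, xb)
    s_aa = corr(xa * xa, mb)
    s_bb = corr(ma, xb * xb)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_ab - s_a * s_b / n_ab
        var_a = s_aa - s_a * s_a / n_ab
        var_b = s_bb - s_b * s_b / n_ab
        r = cov / np.sqrt(var_a * var_b)
    # Index k in the full correlation corresponds to shifting b by
    # (k - (len(b) - 1)) grid steps relative to a.
    shifts = np.arange(len(n_ab)) - (len(mb) - 1)
    return shifts, r, n_ab


def estimate_shift(a: RegularSeries, b: RegularSeries,
                   max_lag_s: float = DEFAULT_MAX_LAG_S,
                   min_overlap_s: float = 600.0,
                   min_overlap_frac: float = 0.5) -> ShiftEstimate:
    """Lag of ``b`` relative to ``a`` maximising the Pearson correlation.

    Lags are multiples of the grid step within +/-``max_lag_s``; the
    returned lag is the clock offset of b's source relative to a's (for
    tracker-vs-PSG input: tracker minus PSG).  Lags with joint overlap
    below ``min_overlap_s`` or below ``min_overlap_frac`` of the shorter
    series' valid span are excluded; ties resolve to the smallest |lag|.
    """
    if abs(a.step - b.step) > 1e-12:
        raise ValueError("series must share the same grid step")
    step = a.step
    shifts, r, n_ab = _masked_corr_by_lag(a, b)
    # Physical lag of b's clock relative to a's: a grid shift of k steps
    # matches a[i] with b[i-k], i.e. content delayed by -k steps plus the
    # difference in grid start times.
    lags = (b.start - a.start) - shifts * step
    min_pts = max(int(np.ceil(min_overlap_s / step)),
                  int(min_overlap_frac * min(a.valid_mask.sum(), b.valid_mask.sum())))
    ok = (np.abs(lags) <= max_lag_s + 1e-9) & (n_ab >= min_pts) & np.isfinite(r)
    if not np.any(ok):
        raise ValueError("insufficient valid overlap within the lag search range")
    cand = np.nonzero(ok)[0]
    best_r = np.max(r[cand])
    ties = cand[r[cand] >= best_r - 1e-12]
    best = ties[np.argmin(np.abs(lags[ties]))]
    return ShiftEstimate(lag=float(lags[best]), peak_correlation=float(r[best]),
                         search_range=float(max_lag_s))


def apply_shift(night, shift: ShiftEstimate):
    """Translate all tracker timestamps by -lag, aligning them to the PSG
    clock.  Accepts any object with a ``shifted(delta_s)`` method
    (FitbitNight, Hypnogram, HRSeries)."""
    return night.shifted(-shift.lag)
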