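"""Estimate the tracker-minus-PSG clock offset of one night.

Both heart-rate series are linearly interpolated, resampled at 0.2 s and
cross-correlated; the lag with maximal Pearson correlation is the
estimated clock offset.
"""

import numpy as np

from somnoval.clockalign import (
    apply_shift,
    beats_to_hr_series,
    center_tracker_hr,
    estimate_shift,
    interp_resample,
)
from somnoval.core import BeatSeries
from somnoval.synthio import gen_night

night = gen_night("demo", seed=7, n_psg_epochs=1440)

beats = BeatSeries(night.true_beat_times, np.arange(len(night.true_beat_times)))
psg = interp_resample(beats_to_hr_series(beats))
tracker = interp_resample(center_tracker_hr(night.fitbit_hr))

est = estimate_shift(psg, tracker)
aligned = apply_shift(night.fitbit_hr, est)

print(f"injected offset : {night.clock_offset:8.2f} s")
print(f"estimated lag   : {est.lag:8.2f} s  (peak correlation {est.peak_correlation:.3f})")
print(f"recovery error  : {est.lag - night.clock_offset:+8.3f} s")
print(f"aligned HR span : {aligned.times[0]:.1f} .. {aligned.times[-1]:.1f} s (PSG clock)")
# Offsets drawn from the observed 1.9-7.5 min range are recovered to a
# fraction of a second despite 4-12 integer-rounded samples per minute.
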