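"""Derive per-night sleep variables from PSG and tracker hypnograms.

Variables depend on the sleep-onset criterion (first N1 versus first N2
epoch) and, for the tracker, on the bordering-wake adjustment.
"""

from somnoval.fitbit_records import trim_bordering_wake
from somnoval.sleepvars import run_lengths, summarize
from somnoval.synthio import gen_night

night = gen_night("demo", seed=11, n_psg_epochs=1440)

psg = summarize(night.psg_hypnogram, criterion="N1_on")
trimmed, adj = trim_bordering_wake(night.fitbit_hypnogram)
tracker = summarize(trimmed, criterion="N1_on")

print(f"{'variable':10s} {'PSG':>10s} {'tracker':>10s}")
for var in ("tst", "waso", "reml", "rem_d", "light_d", "deep_d"):
    print(f"{var:10s} {getattr(psg, var):10.1f} {getattr(tracker, var):10.1f}")
print(f"(minutes; tracker trimmed of {adj.leading_wake_s:g}s leading / "
      f"{adj.trailing_wake_s:g}s trailing border wake)")

runs = run_lengths(night.fitbit_hypnogram)
rem_runs = [d for s, d in runs if s == "rem"]
print(f"tracker rem runs: n={len(rem_runs)}, shortest={min(rem_runs):.1f} min"
      if rem_runs else "tracker rem runs: none")
# The shortest tracker rem run is >= 4.5 min: the generator reproduces
# the duration discontinuity seen in the vendor's staging output.
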