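# Default per-20-s-epoch stage-transition model for synthetic PSG nights.
#
# Stay probabilities correspond to mean uninterrupted bout lengths of roughly
# 2 min (W), 1.5 min (N1), 5 min (N2), 4.5 min (N3) and 5.5 min (REM), which
# produce a plausible adult sleep architecture (short N1 bouts, consolidated
# N2/N3, REM latency of the order of an hour) when started from wake.
states: [W, N1, N2, N3, REM]
initial_distribution:
  W: 1.0
transition_matrix:
  W:   {W: 0.850, N1: 0.120, N2: 0.020, N3: 0.003, REM: 0.007}
  N1:  {W: 0.060, N1: 0.780, N2: 0.140, N3: 0.005, REM: 0.015}
  N2:  {W: 0.015, N1: 0.015, N2: 0.935, N3: 0.025, REM: 0.010}
  N3:  {W: 0.010, N1: 0.005, N2: 0.045, N3: 0.930, REM: 0.010}
  REM: {W: 0.020, N1: 0.020, N2: 0.015, N3: 0.005, REM: 0.940}
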