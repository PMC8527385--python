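"""Beat-detection pipeline: candidate detection, polarity, realignment,
curvature statistic, cutoff derivation and T-wave rejection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnoval.core import BeatSeries, SampledSignal
from somnoval.ecgbeats import (
    FALLBACK_CUTOFF,
    HARD_LIMITS,
    QAVSD_UNIT_MV_S2,
    TWaveCutoff,
    correct_polarity,
    derive_cutoff,
    detect_beats,
    ibi_to_bpm,
    pan_tompkins,
    qavsd,
    read_ecg_csv,
    realign_peak,
    reject_t_waves,
)
from somnoval.synthio import gen_ecg


def regular_beats(n=60, ibi=1.0, t0=1.0):
    return t0 + ibi * np.arange(n)


class TestPanTompkins:
    def test_flat_signal_yields_no_peaks(self):
        sig = SampledSignal(np.zeros(2560), fs=256.0)
        assert len(pan_tompkins(sig)) == 0

    def test_clean_ecg_without_t_waves_has_perfect_recall_precision(self):
        beats = regular_beats()
        sig = gen_ecg(beats, 256.0, t_amp=0.0, noise_sd=0.0)
        idx = pan_tompkins(sig)
        times = sig.index_to_time(idx)
        assert len(times) == len(beats)
        assert np.all(np.abs(times - beats) < 0.05)

    def test_beat_times_invariant_to_resampling(self):
        beats = regular_beats(40)
        t256 = detect_beats(gen_ecg(beats, 256.0, t_amp=0.0, noise_sd=0.0)).peak_times
        t512 = detect_beats(gen_ecg(beats, 512.0, t_amp=0.0, noise_sd=0.0)).peak_times
        assert len(t256) == len(t512)
        assert np.all(np.abs(t256 - t512) <= 1.0 / 256.0 + 1e-9)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            pan_tompkins(SampledSignal(np.zeros(100), fs=256.0))


class TestCorrectPolarity:
    def test_negative_mean_flips_signal(self):
        sig = SampledSignal(np.array([-0.8, -0.9, 0.1] * 200), fs=256.0)
        out = correct_polarity(sig, [0, 1, 3, 4])
        assert np.array_equal(out.values, -sig.values)

    def test_positive_mean_returns_identical_signal(self):
        sig = SampledSignal(np.array([0.9, 0.8, -0.1] * 200), fs=256.0)
        assert correct_polarity(sig, [0, 1]) is sig

    def test_zero_mean_tie_leaves_signal_unchanged(self):
        sig = SampledSignal(np.array([1.0, -1.0] * 300), fs=256.0)
        assert correct_polarity(sig, [0, 1]) is sig

    def test_no_candidates_warns_and_returns_signal(self):
        sig = SampledSignal(np.zeros(600), fs=256.0)
        with pytest.warns(UserWarning):
            assert correct_polarity(sig, []) is sig


class TestRealignPeak:
    def test_candidate_at_local_max_unchanged(self):
        sig = gen_ecg(np.array([1.0]), 256.0, t_amp=0.0, noise_sd=0.0)
        apex = int(np.argmax(sig.values))
        assert realign_peak(sig, apex) == apex

    def test_offset_candidate_moves_to_argmax_oracle(self):
        sig = gen_ecg(np.array([1.0]), 256.0, t_amp=0.0, noise_sd=0.0)
        apex = int(np.argmax(sig.values))
        cand = apex - 10
        h = int(round(256 * 0.2))
        oracle = cand - h + int(np.argmax(sig.values[cand - h:cand + h + 1]))
        got = realign_peak(sig, cand)
        assert got == oracle == apex

    def test_edge_candidate_uses_truncated_window(self):
        values = np.linspace(1.0, 0.0, 600)  # maximum at index 0
        sig = SampledSignal(values, fs=256.0)
        assert realign_peak(sig, 3) == 0


class TestQavsd:
    def test_constant_signal_has_zero_curvature(self):
        sig = SampledSignal(np.full(1000, 3.3), fs=256.0)
        assert qavsd(sig, 500) == 0.0

    def test_quadratic_signal_gives_exact_second_derivative(self):
        # x(t) = a t^2 sampled at fs: fs^2-scaled second difference is 2a
        # exactly, and unit-mass smoothing preserves it on the interior.
        fs, a = 256.0, 5.0
        t = np.arange(4096) / fs
        sig = SampledSignal(a * t * t, fs=fs)
        expected = 2 * a / QAVSD_UNIT_MV_S2
        for idx in (600, 2048, 3000):
            assert qavsd(sig, idx) == pytest.approx(expected, rel=1e-9)

    def test_r_apexes_score_above_t_apexes(self):
        beats = regular_beats(100, 0.9)
        sig = gen_ecg(beats, 256.0, r_amp=1.0, t_amp=0.8, noise_sd=0.05, seed=1)
        r_idx = np.round(beats * 256).astype(int)
        t_idx = np.round((beats + 0.28) * 256).astype(int)
        r_q = np.median([qavsd(sig, i) for i in r_idx])
        t_q = np.median([qavsd(sig, i) for i in t_idx])
        assert r_q > 3 * t_q

    def test_window_smaller_than_three_samples_rejected(self):
        sig = SampledSignal(np.zeros(100), fs=256.0)
        with pytest.raises(ValueError):
            qavsd(sig, 0, half_window_ms=1.0)


class TestDeriveCutoff:
    def test_two_cluster_sample_puts_cutoff_near_the_valley(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(0.06, 0.01, 200)
        hi = rng.normal(0.42, 0.03, 200)
        values = np.concatenate([lo, hi])
        cut = derive_cutoff(values)
        assert cut.source == "density_minimum"
        assert HARD_LIMITS[0] < cut.value < HARD_LIMITS[1]
        assert lo.max() < cut.value < hi.min()

    def test_cutoff_robust_to_bandwidth_halving_and_doubling(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0.06, 0.01, 300), rng.normal(0.42, 0.03, 300)])
        cuts = [derive_cutoff(values, bw_scale=s).value for s in (0.5, 1.0, 1.5)]
        assert max(cuts) - min(cuts) < 0.1

    def test_degenerate_point_mass_falls_back(self):
        cut = derive_cutoff(np.full(50, 0.8))
        assert cut.source == "fallback" and cut.value == FALLBACK_CUTOFF

    def test_insufficient_values_rejected(self):
        with pytest.raises(ValueError):
            derive_cutoff(np.array([0.1] * 9))
        with pytest.raises(ValueError):
            derive_cutoff(np.array([]))

    def test_cutoff_invariant_enforced(self):
        with pytest.raises(ValueError):
            TWaveCutoff(value=0.9, source="density_minimum")


class TestRejectTWaves:
    def cutoff(self):
        return TWaveCutoff(FALLBACK_CUTOFF, "fallback")

    def test_widely_spaced_peaks_untouched(self):
        peaks = BeatSeries(np.array([1.0, 1.8, 2.6]), np.arange(3),
                           np.array([0.01, 0.01, 0.01]))
        out = reject_t_waves(peaks, self.cutoff())
        assert np.array_equal(out.peak_times, peaks.peak_times)

    def test_low_curvature_follower_within_refractory_is_dropped(self):
        peaks = BeatSeries(np.array([1.0, 1.3, 2.0, 2.3]), np.arange(4),
                           np.array([0.5, 0.01, 0.5, 0.01]))
        out = reject_t_waves(peaks, self.cutoff())
        assert np.allclose(out.peak_times, [1.0, 2.0])
        assert np.all(out.ibis > 0)

    def test_sharp_premature_beat_is_retained(self):
        peaks = BeatSeries(np.array([1.0, 1.3]), np.arange(2), np.array([0.5, 0.5]))
        out = reject_t_waves(peaks, self.cutoff())
        assert len(out) == 2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.05, 2.0), min_size=1, max_size=30),
           st.lists(st.floats(0.0, 1.0), min_size=30, max_size=30))
    def test_never_removes_isolated_peaks(self, gaps, qs):
        times = 1.0 + np.cumsum(np.asarray(gaps))
        qv = np.asarray(qs[: len(times)])
        peaks = BeatSeries(times, np.arange(len(times)), qv)
        out = reject_t_waves(peaks, self.cutoff())
        kept = set(np.round(out.peak_times, 9))
        for i, t in enumerate(times):
            neighbours = [abs(t - u) for j, u in enumerate(times) if j != i]
            if not neighbours or min(neighbours) >= 0.36:
                assert round(t, 9) in kept


class TestDetectBeats:
    def test_flat_signal_returns_empty_series(self):
        sig = SampledSignal(np.zeros(256 * 20), fs=256.0)
        assert len(detect_beats(sig)) == 0

    def test_tall_t_waves_are_rejected_and_screen_improves_f1(self):
        rng = np.random.default_rng(3)
        beats = np.cumsum(rng.uniform(0.75, 1.05, 200)) + 1.0
        sig = gen_ecg(beats, 256.0, r_amp=1.0, t_amp=0.8, noise_sd=0.05, seed=3)
        full = detect_beats(sig)
        raw = detect_beats(sig, apply_t_rejection=False)
        assert len(full) == len(beats)
        assert np.all(np.abs(full.peak_times - beats) < 0.05)
        assert len(raw) > len(full)

    def test_inverted_polarity_gives_identical_beat_times(self):
        beats = regular_beats(30)
        pos = gen_ecg(beats, 256.0, t_amp=0.3, noise_sd=0.02, seed=5, polarity=1)
        neg = gen_ecg(beats, 256.0, t_amp=0.3, noise_sd=0.02, seed=5, polarity=-1)
        assert np.array_equal(detect_beats(pos).peak_times, detect_beats(neg).peak_times)

    def test_additive_constant_does_not_change_beat_times(self):
        beats = regular_beats(30)
        sig = gen_ecg(beats, 256.0, t_amp=0.3, noise_sd=0.02, seed=6)
        shifted = SampledSignal(sig.values + 2.5, sig.fs, sig.start_time, sig.units)
        assert np.array_equal(detect_beats(sig).peak_times,
                              detect_beats(shifted).peak_times)

    def test_noise_free_detection_hits_truth_within_one_sample(self):
        beats = regular_beats(40)
        sig = gen_ecg(beats, 256.0, t_amp=0.0, noise_sd=0.0)
        out = detect_beats(sig)
        assert len(out) == len(beats)
        assert np.all(np.abs(out.peak_times - beats) <= 1.0 / 256.0 + 1e-9)

    def test_output_ibis_consistent_with_peak_times(self, small_night):
        beats = small_night.true_beat_times[:120]
        sig = gen_ecg(beats, 256.0, t_amp=0.3, noise_sd=0.03, seed=8)
        out = detect_beats(sig)
        assert np.all(out.ibis > 0)
        assert np.allclose(out.ibis, np.diff(out.peak_times))


class TestIbiToBpm:
    @pytest.mark.parametrize("ibi,bpm", [(1.0, 60.0), (0.5, 120.0), (0.8, 75.0)])
    def test_definition(self, ibi, bpm):
        assert ibi_to_bpm(ibi) == pytest.approx(bpm)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ibi_to_bpm(0.0)


class TestIo:
    def test_csv_round_trip(self, tmp_path):
        sig = gen_ecg(regular_beats(12), 256.0, t_amp=0.0, noise_sd=0.0)
        path = tmp_path / "ecg.csv"
        with open(path, "w") as fh:
            fh.write("time_s,value\n")
            for t, v in zip(sig.times(), sig.values):
                fh.write(f"{t:.8f},{v:.8f}\n")
        back = read_ecg_csv(path)
        assert back.fs == pytest.approx(256.0, rel=1e-4)
        assert np.allclose(back.values, sig.values, atol=1e-7)
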