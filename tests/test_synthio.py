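"""Generator contracts: determinism, stationary behaviour, run-length
laws, ECG construction, tracker HR sampling and vendor-file output."""

import json

import numpy as np
import pytest
from scipy import stats

from somnoval.core import Hypnogram, TRACKER_STAGES
from somnoval.synthio import (
    DEFAULT_CONFUSION,
    HRCurve,
    StageTransitionModel,
    default_psg_model,
    gen_ecg,
    gen_fitbit_from_psg,
    gen_fitbit_hr,
    gen_hypnogram,
    gen_night,
    write_fitbit_json,
)


def two_state_model(p_stay=0.5):
    return StageTransitionModel(("W", "N2"),
                                [[p_stay, 1 - p_stay], [1 - p_stay, p_stay]],
                                [0.5, 0.5])


class TestGenHypnogram:
    def test_absorbing_chain_stays_in_initial_stage(self):
        model = StageTransitionModel(("W", "N2"), np.eye(2), [1.0, 0.0])
        h = gen_hypnogram(model, 50, 20.0, seed=0)
        assert all(lab == "W" for lab in h.labels)

    def test_fixed_seed_is_bit_reproducible(self):
        model = default_psg_model()
        h1 = gen_hypnogram(model, 200, 20.0, seed=123)
        h2 = gen_hypnogram(model, 200, 20.0, seed=123)
        assert list(h1.labels) == list(h2.labels)

    def test_uniform_two_state_stationary_frequency(self):
        # Empirical W frequency within 3 binomial SEs of one half.
        n = 100_000
        h = gen_hypnogram(two_state_model(0.5), n, 20.0, seed=7)
        freq = np.mean(h.labels == "W")
        se = 0.5 / np.sqrt(n)
        assert abs(freq - 0.5) < 3 * se

    def test_run_lengths_follow_geometric_law(self):
        # Two-state chain: run length ~ Geometric(1 - p_stay).
        p_stay = 0.8
        h = gen_hypnogram(two_state_model(p_stay), 100_000, 20.0, seed=11)
        runs = []
        i = 0
        labels = h.labels
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            runs.append(j - i)
            i = j
        runs = np.asarray(runs)
        kmax = 20
        observed = np.array([np.sum(runs == k) for k in range(1, kmax)]
                            + [np.sum(runs >= kmax)])
        p = 1 - p_stay
        probs = np.array([p * p_stay ** (k - 1) for k in range(1, kmax)])
        probs = np.append(probs, 1 - probs.sum())
        chi2 = stats.chisquare(observed, probs * len(runs))
        assert chi2.pvalue > 0.001

    def test_invalid_transition_matrix_rejected(self):
        with pytest.raises(ValueError):
            StageTransitionModel(("W", "N2"), [[0.9, 0.2], [0.5, 0.5]], [1.0, 0.0])

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            gen_hypnogram(default_psg_model(), 0, 20.0, seed=0)


class TestGenFitbitFromPsg:
    def test_identity_confusion_zero_offset_maps_stages_exactly(self):
        # Block-aligned PSG: every 30 s tracker epoch sits inside one run.
        labels = np.repeat(["W", "N1", "N2", "N3", "REM", "N2"], 3).astype(object)
        psg = Hypnogram(0.0, 20.0, labels)
        fb = gen_fitbit_from_psg(psg, np.eye(4), 0.0, min_run_epochs=1, seed=0)
        expected = [s for s in ["wake", "light", "light", "deep", "rem", "light"]
                    for _ in range(2)]
        assert list(fb.labels) == expected
        assert fb.start == 0.0

    def test_offset_translates_every_boundary(self):
        psg = gen_hypnogram(default_psg_model(), 120, 20.0, seed=3)
        fb0 = gen_fitbit_from_psg(psg, np.eye(4), 0.0, 1, seed=0)
        fb300 = gen_fitbit_from_psg(psg, np.eye(4), 300.0, 1, seed=0)
        assert list(fb0.labels) == list(fb300.labels)
        assert fb300.start - fb0.start == 300.0

    def test_min_run_smoothing_forbids_short_rem_and_deep_runs(self):
        psg = gen_hypnogram(default_psg_model(), 1440, 20.0, seed=5)
        fb = gen_fitbit_from_psg(psg, DEFAULT_CONFUSION, 0.0, min_run_epochs=9, seed=6)
        i = 0
        labels = fb.labels
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            if labels[i] in ("rem", "deep"):
                assert j - i >= 9
            i = j

    def test_empty_psg_rejected(self):
        with pytest.raises(ValueError):
            gen_fitbit_from_psg(Hypnogram(0.0, 20.0, np.array([], dtype=object)),
                                np.eye(4), 0.0, 1, 0)


class TestGenEcg:
    def test_noise_free_r_only_peaks_at_beat_samples(self):
        beats = np.array([1.0, 2.0, 3.0])
        sig = gen_ecg(beats, fs=256.0, r_amp=1.0, t_amp=0.0, noise_sd=0.0)
        for bt in beats:
            k = int(round(bt * 256.0))
            lo, hi = k - 128, k + 128
            assert np.argmax(sig.values[lo:hi]) + lo == k

    def test_negative_polarity_is_exact_negation(self):
        beats = np.arange(1.0, 6.0)
        pos = gen_ecg(beats, 256.0, noise_sd=0.05, seed=4, polarity=1)
        neg = gen_ecg(beats, 256.0, noise_sd=0.05, seed=4, polarity=-1)
        assert np.array_equal(neg.values, -pos.values)

    def test_tall_t_waves_fool_a_naive_local_maximum_detector(self):
        # Simple thresholded local-maximum scan with 360 ms spacing finds
        # more peaks than beats when T waves are prominent.
        from scipy.signal import find_peaks

        beats = np.cumsum(np.full(50, 0.9)) + 0.5
        sig = gen_ecg(beats, 256.0, r_amp=1.0, t_amp=0.8, t_lag_ms=280.0, noise_sd=0.0)
        peaks, _ = find_peaks(sig.values, height=0.3)
        assert len(peaks) == 2 * len(beats)

    def test_overlapping_templates_rejected(self):
        with pytest.raises(ValueError):
            gen_ecg(np.array([1.0, 2.0]), 256.0, t_lag_ms=100.0)


class TestGenFitbitHr:
    def test_constant_curve_yields_exact_value(self):
        curve = HRCurve([0.0, 3600.0], [60.0, 60.0])
        hr = gen_fitbit_hr(curve, (0.0, 3600.0), seed=0)
        assert np.all(hr.values == 60.0)

    def test_sampling_rate_always_4_to_12_per_minute(self):
        curve = HRCurve([0.0, 7200.0], [55.0, 70.0])
        hr = gen_fitbit_hr(curve, (0.0, 7200.0), seed=1)
        from somnoval.fitbit_records import count_hr_per_minute

        counts = count_hr_per_minute(hr, span=(60.0, 7140.0))
        assert counts.min() >= 4 and counts.max() <= 12
        assert 6.0 <= counts.mean() <= 9.0

    def test_linear_ramp_sample_equals_interval_midpoint(self):
        curve = HRCurve([0.0, 1000.0], [50.0, 90.0])  # slope 0.04 bpm/s
        hr = gen_fitbit_hr(curve, (0.0, 1000.0), seed=2)
        gaps = np.diff(np.concatenate([[0.0], hr.times]))
        mids = curve(hr.times - gaps / 2.0)
        assert np.all(np.abs(hr.values - mids) <= 0.5 + 1e-9)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            gen_fitbit_hr(HRCurve([0.0, 10.0], [60.0, 60.0]), (5.0, 5.0))


class TestVendorJson:
    def test_round_trip_reproduces_stage_series(self, small_night, tmp_path):
        from somnoval.fitbit_records import parse_night

        path = tmp_path / "night.json"
        write_fitbit_json(small_night, path)
        parsed = parse_night(path)
        merged = parsed.hypnogram()
        assert parsed.datatype == "stages"
        assert list(merged.labels) == list(small_night.fitbit_hypnogram.labels)
        assert np.array_equal(parsed.hr_series.values, small_night.fitbit_hr.values)

    def test_short_night_written_as_classic_only(self, tmp_path):
        truth = gen_night("short", seed=77, n_psg_epochs=360)  # 2 h < 3 h
        path = tmp_path / "short.json"
        write_fitbit_json(truth, path)
        payload = json.loads(path.read_text())
        assert payload["sleep"][0]["type"] == "classic"
        levels = {rec["level"] for rec in payload["sleep"][0]["levels"]["data"]}
        assert levels <= {"asleep", "restless", "awake"}

    def test_singleton_interior_wake_goes_to_short_data(self, tmp_path):
        labels = np.array(["light"] * 100 + ["wake"] + ["light"] * 379, dtype=object)
        truth = gen_night("sw", seed=9, n_psg_epochs=720)
        truth.fitbit_hypnogram = Hypnogram(truth.fitbit_hypnogram.start, 30.0, labels)
        path = tmp_path / "sw.json"
        write_fitbit_json(truth, path)
        payload = json.loads(path.read_text())
        short = payload["sleep"][0]["levels"]["shortData"]
        assert len(short) == 1 and short[0]["seconds"] == 20
        data_levels = [rec["level"] for rec in payload["sleep"][0]["levels"]["data"]]
        assert "wake" not in data_levels
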