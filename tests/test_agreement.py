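"""Agreement statistics: Bland-Altman closed forms, mixed-model LoA
(including the R nlme cross-check), epoch mapping and EBE metrics."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somnoval.agreement import (
    ConfusionCounts,
    bland_altman,
    cohort_report,
    confusion,
    ebe_metrics,
    map_epochs,
    mixed_loa,
    rem_window_split,
)
from somnoval.benchmarks import ebe_counting_oracle, simulate_ar1_panel
from somnoval.core import Hypnogram, PSG_STAGES, TRACKER_STAGES


def pairs_df(psg_labels, fb_labels):
    n = len(psg_labels)
    return pd.DataFrame({"psg": psg_labels, "fitbit": fb_labels,
                         "epoch_start": 20.0 * np.arange(n)})


def metrics_equal(m1, m2):
    for k in ("sensitivity", "specificity", "accuracy", "mcc", "ppv", "npv"):
        a, b = getattr(m1, k), getattr(m2, k)
        if not ((np.isnan(a) and np.isnan(b)) or a == b):
            return False
    return True


class TestBlandAltman:
    def test_identical_pairs_collapse_to_zero(self):
        ba = bland_altman([(5.0, 5.0), (7.0, 7.0), (9.0, 9.0)])
        assert ba.bias == 0.0
        assert ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_plus_minus_one_closed_form(self):
        ba = bland_altman([(-1.0, 0.0), (1.0, 0.0)])
        s2 = np.sqrt(2.0)
        assert ba.bias == pytest.approx(0.0, abs=1e-12)
        assert ba.sd == pytest.approx(s2, abs=1e-12)
        assert ba.loa_lower == pytest.approx(-1.96 * s2, abs=1e-12)
        assert ba.loa_upper == pytest.approx(1.96 * s2, abs=1e-12)

    def test_constant_differences_have_missing_p(self):
        ba = bland_altman([(5.0, 0.0)] * 3)
        assert ba.bias == 5.0
        assert ba.loa_lower == ba.loa_upper == 5.0
        assert np.isnan(ba.p_value)

    def test_loa_ci_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        d = rng.normal(1.0, 2.0, 400)
        small = bland_altman([(v, 0.0) for v in d[:20]])
        large = bland_altman([(v, 0.0) for v in d])
        w_small = small.loa_upper_ci[1] - small.loa_upper_ci[0]
        w_large = large.loa_upper_ci[1] - large.loa_upper_ci[0]
        assert w_large < w_small

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 0.0)])


class TestMixedLoA:
    def test_zero_noise_recovers_bias_exactly(self):
        groups = [np.full(50, 0.9), np.full(80, 0.9)]
        fit = mixed_loa(groups)
        assert fit.bias == 0.9
        assert fit.sd_between == 0.0 and fit.sd_within == 0.0

    def test_single_subject_reduces_to_subject_mean(self):
        rng = np.random.default_rng(1)
        y = 0.5 + rng.normal(0, 1.0, 300)
        fit = mixed_loa([y])
        assert fit.sd_between == 0.0
        assert fit.bias == pytest.approx(np.mean(y), abs=0.05)

    def test_one_minute_per_subject_matches_bland_altman_bias(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.7, 1.5, 40)
        fit = mixed_loa([np.array([v]) for v in d])
        ba = bland_altman([(v, 0.0) for v in d])
        assert fit.bias == pytest.approx(ba.bias, abs=1e-8)

    def test_parameter_recovery_on_one_large_panel(self):
        rng = np.random.default_rng(3)
        groups = simulate_ar1_panel(50, 400, bias=0.9, sd_between=1.5,
                                    sd_within=3.0, phi=0.5, rng=rng)
        fit = mixed_loa(groups)
        assert fit.sd_within == pytest.approx(3.0, rel=0.1)
        assert fit.phi == pytest.approx(0.5, rel=0.15)
        assert fit.sd_between == pytest.approx(1.5, rel=0.3)
        assert abs(fit.bias - 0.9) < 3.0 * fit.se_bias
        total = np.sqrt(fit.sd_between**2 + fit.sd_within**2)
        assert fit.loa_upper - fit.loa_lower == pytest.approx(2 * 1.96 * total, rel=1e-9)

    def test_agrees_with_r_nlme_oracle(self, tmp_path):
        # Independent fit of the same model with nlme::lme + corAR1.
        rng = np.random.default_rng(4)
        groups = simulate_ar1_panel(6, 40, bias=0.5, sd_between=1.0,
                                    sd_within=2.0, phi=0.4, rng=rng)
        fit = mixed_loa(groups, method="ML")
        rows = [{"subject": i, "minute_index": j, "d": float(v)}
                for i, arr in enumerate(groups) for j, v in enumerate(arr)]
        csv = tmp_path / "panel.csv"
        pd.DataFrame(rows).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            d <- read.csv("{csv}")
            suppressMessages(library(nlme))
            m <- lme(d ~ 1, random = ~1 | subject,
                     correlation = corAR1(form = ~minute_index | subject),
                     data = d, method = "ML")
            vc <- VarCorr(m)
            cat(fixef(m)[1], as.numeric(vc[1, 2]), m$sigma,
                coef(m$modelStruct$corStruct, unconstrained = FALSE), sep = ",")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        r_bias, r_sb, r_sw, r_phi = map(float, out.stdout.strip().split(","))
        assert fit.bias == pytest.approx(r_bias, abs=1e-4)
        assert fit.sd_between == pytest.approx(r_sb, abs=1e-3)
        assert fit.sd_within == pytest.approx(r_sw, abs=1e-3)
        assert fit.phi == pytest.approx(r_phi, abs=1e-3)


class TestMapEpochs:
    def fb(self, labels, start=0.0):
        return Hypnogram(start, 30.0, np.array(labels, dtype=object))

    def psg(self, labels, start=0.0):
        return Hypnogram(start, 20.0, np.array(labels, dtype=object))

    def test_contained_epoch_takes_the_covering_stage(self):
        pairs = map_epochs(self.psg(["N2"]), self.fb(["light", "rem"]))
        assert list(pairs["fitbit"]) == ["light"]

    def test_exact_tie_takes_earlier_tracker_stage(self):
        # PSG epoch [20, 40) splits 10/10 between light [0,30) and rem [30,60).
        pairs = map_epochs(self.psg(["W", "N2"]), self.fb(["light", "rem"]))
        assert list(pairs["fitbit"])[1] == "light"

    def test_dominant_overlap_wins(self):
        # PSG epoch [40, 60) overlaps rem [30, 60) for 20 s.
        pairs = map_epochs(self.psg(["W", "W", "N2"]), self.fb(["light", "rem"]))
        assert list(pairs["fitbit"])[2] == "rem"

    def test_uncovered_epochs_excluded_and_counted(self):
        pairs = map_epochs(self.psg(["N2"] * 6), self.fb(["light"]))
        assert len(pairs) <= 2
        assert pairs.attrs["n_excluded"] == 6 - len(pairs)

    def test_output_no_longer_than_psg(self, clean_night):
        pairs = map_epochs(clean_night.psg_hypnogram, clean_night.fitbit_hypnogram)
        n_psg = len(clean_night.psg_hypnogram)
        assert len(pairs) + pairs.attrs["n_excluded"] == n_psg


class TestConfusionAndMetrics:
    def test_perfect_agreement_has_no_errors(self):
        pairs = pairs_df(["REM"] * 10, ["rem"] * 10)
        c = confusion(pairs, "rem")
        assert c.fp == 0 and c.fn == 0 and c.tp == 10

    def test_total_disagreement_on_target(self):
        pairs = pairs_df(["REM"] * 5 + ["N2"] * 5, ["light"] * 5 + ["rem"] * 5)
        c = confusion(pairs, "rem")
        assert c.tp == 0 and c.fn == 5 and c.fp == 5 and c.tn == 0

    def test_counts_match_brute_force_tally_on_random_fixture(self):
        rng = np.random.default_rng(5)
        pairs = pairs_df(rng.choice(PSG_STAGES, 200), rng.choice(TRACKER_STAGES, 200))
        for stage in TRACKER_STAGES:
            c = confusion(pairs, stage)
            o = ebe_counting_oracle(pairs, stage)
            assert (c.tp, c.fp, c.tn, c.fn) == (o["tp"], o["fp"], o["tn"], o["fn"])

    def test_worked_metric_example(self):
        m = ebe_metrics(ConfusionCounts(tp=40, fp=10, tn=90, fn=60, target_stage="rem"))
        assert m.sensitivity == pytest.approx(0.40)
        assert m.specificity == pytest.approx(0.90)
        assert m.accuracy == pytest.approx(0.65)
        assert m.ppv == pytest.approx(0.80)
        assert m.npv == pytest.approx(0.60)
        assert m.mcc == pytest.approx(3000.0 / np.sqrt(50 * 100 * 100 * 150))

    def test_perfect_and_inverted_classifiers(self):
        perfect = ebe_metrics(ConfusionCounts(50, 0, 50, 0, "rem"))
        assert perfect.mcc == 1.0 and perfect.accuracy == 1.0
        inverted = ebe_metrics(ConfusionCounts(0, 50, 0, 50, "rem"))
        assert inverted.mcc == -1.0 and inverted.sensitivity == 0.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(1, 500), st.integers(0, 2**31 - 1))
    def test_metrics_equal_counting_oracle_on_random_grids(self, n, seed):
        rng = np.random.default_rng(seed)
        pairs = pairs_df(rng.choice(PSG_STAGES, n), rng.choice(TRACKER_STAGES, n))
        stage = str(rng.choice(TRACKER_STAGES))
        m = ebe_metrics(confusion(pairs, stage))
        o = ebe_counting_oracle(pairs, stage)
        for k in ("sensitivity", "specificity", "accuracy", "mcc", "ppv", "npv"):
            a, b = getattr(m, k), o[k]
            assert (np.isnan(a) and np.isnan(b)) or a == b

    def test_pooled_accuracy_is_permutation_invariant(self):
        rng = np.random.default_rng(6)
        pairs = pairs_df(rng.choice(PSG_STAGES, 100), rng.choice(TRACKER_STAGES, 100))
        shuffled = pairs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        for stage in TRACKER_STAGES:
            assert metrics_equal(ebe_metrics(confusion(pairs, stage)),
                                 ebe_metrics(confusion(shuffled, stage)))


class TestRemWindowSplit:
    def test_all_rem_before_threshold_leaves_late_sensitivity_missing(self):
        psg = ["REM"] * 10 + ["N2"] * 10
        fb = ["rem"] * 10 + ["light"] * 10
        pairs = pairs_df(psg, fb)  # epochs end at 400 s, threshold far later
        early, late = rem_window_split(pairs, s_on=0.0, threshold_min=120.0)
        assert early.sensitivity == 1.0
        assert np.isnan(late.sensitivity)

    def test_identical_windows_give_equal_metrics(self):
        rng = np.random.default_rng(7)
        block_psg = rng.choice(PSG_STAGES, 60)
        block_fb = rng.choice(TRACKER_STAGES, 60)
        pairs = pairs_df(np.concatenate([block_psg, block_psg]),
                         np.concatenate([block_fb, block_fb]))
        # First copy ends at 1200 s; split there.
        early, late = rem_window_split(pairs, s_on=0.0, threshold_min=20.0)
        assert metrics_equal(early, late)


class TestCohortReport:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_report([])
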