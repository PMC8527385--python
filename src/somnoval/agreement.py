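"""Agreement statistics: Bland-Altman, mixed-model limits of agreement,
and epoch-by-epoch (EBE) comparison across mismatched epoch grids.

Differences are oriented PSG minus tracker throughout, so a positive bias
means the tracker underestimates.  Per-night sleep variables use ordinary
Bland-Altman limits of agreement (bias +/- 1.96 SD of the differences).
Per-minute heart-rate differences are repeated measures with strong serial
correlation, so their bias and LoA come from an intercept-only linear
mixed model with a random intercept per subject and AR(1) within-subject
residuals, fitted by maximum likelihood; the LoA use the total SD
sqrt(sd_between^2 + sd_within^2).

EBE comparison matches each 20 s PSG epoch with the dominating tracker
stage (>50% of the interval, exact ties to the earlier-starting tracker
stage) and computes one-vs-rest sensitivity, specificity, accuracy,
Matthews correlation, PPV and NPV under the stage equivalence wake=W,
light=N1+N2, deep=N3, rem=REM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import PSG_TO_TRACKER, TRACKER_STAGES, Hypnogram

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass
class BAStats:
    """Bland-Altman summary of paired values (differences = PSG - tracker)."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple
    loa_upper_ci: tuple
    p_value: float
    n: int
    x_axis_mode: str = "psg_value"


def bland_altman(pairs, x_axis_mode: str = "psg_value") -> BAStats:
    """Classical Bland-Altman statistics for per-night paired values.

    ``pairs`` is a sequence of (psg_value, tracker_value).  LoA are
    bias +/- 1.96 SD with approximate 95% CIs (SE(LoA) = SD * sqrt(3/n));
    the p value is a two-tailed one-sample t test of zero bias, reported
    as NaN when the differences have zero variance.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2): (psg, tracker) per night")
    if len(arr) < 2:
        raise ValueError("need at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    n = len(d)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    tq = stats.t.ppf(0.975, n - 1)
    se_loa = sd * np.sqrt(3.0 / n)
    if sd > 0:
        import warnings as _warnings

        with _warnings.catch_warnings():
            # Near-identical differences trip scipy's precision-loss
            # warning; the p value is still the right degenerate answer.
            _warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        p = float("nan")
    return BAStats(bias=bias, sd=sd, loa_lower=loa_lo, loa_upper=loa_hi,
                   loa_lower_ci=(loa_lo - tq * se_loa, loa_lo + tq * se_loa),
                   loa_upper_ci=(loa_hi - tq * se_loa, loa_hi + tq * se_loa),
                   p_value=p, n=n, x_axis_mode=x_axis_mode)


# ---------------------------------------------------------------------------
# Mixed-model limits of agreement


@dataclass
class MixedLoA:
    """Intercept-only mixed model for repeated per-minute differences."""

    bias: float
    sd_between: float
    sd_within: float
    phi: float
    loa_lower: float
    loa_upper: float
    p_value: float
    se_bias: float
    n_subjects: int
    n_obs: int
    converged: bool = True
    method: str = "REML"

    def bias_ci(self, level: float = 0.95) -> tuple:
        """Confidence interval for the bias using a t quantile with
        subject-level degrees of freedom (the random intercept makes the
        subject, not the minute, the effective unit for the mean)."""
        df = max(self.n_subjects - 1, 1)
        q = stats.t.ppf(0.5 + level / 2.0, df)
        return (self.bias - q * self.se_bias, self.bias + q * self.se_bias)


def _subject_arrays(minute_diffs) -> list:
    """Normalise input to a list of per-subject difference vectors ordered
    by minute index."""
    if isinstance(minute_diffs, pd.DataFrame):
        df = minute_diffs.sort_values(["subject", "minute_index"])
        return [g["d"].to_numpy(dtype=float) for _, g in df.groupby("subject", sort=True)]
    return [np.asarray(v, dtype=float) for v in minute_diffs]


def _nll_terms(groups, mu, sd_b, sd_w, phi):
    """Profile pieces of the Gaussian log-likelihood.

    Covariance per subject: sd_b^2 * J + sd_w^2 * R(phi) with R the AR(1)
    correlation matrix.  The AR(1) inverse is tridiagonal and the random
    intercept is a rank-one update, so everything is closed form and O(n).
    Returns (nll, sum_wy, sum_w) where mu_hat = sum_wy / sum_w is the GLS
    mean and 1/sum_w its variance.
    """
    s2w = sd_w * sd_w
    s2b = sd_b * sd_b
    om2 = 1.0 - phi * phi
    nll = 0.0
    sum_wy = 0.0
    sum_w = 0.0
    for y in groups:
        n = len(y)
        r = y - mu
        if n == 1:
            c = 1.0 / s2w
            uy = y[0] / s2w
            ur = r[0] / s2w
            quad_a = r[0] * r[0] / s2w
            logdet_a = 2.0 * np.log(sd_w)
        else:
            inner_r = r[1:-1]
            c = (2.0 / (1.0 + phi) + (n - 2) * (1.0 - phi) / (1.0 + phi)) / s2w
            uy = (y[0] + y[-1] + (1.0 - phi) * np.sum(y[1:-1])) / (s2w * (1.0 + phi))
            ur = (r[0] + r[-1] + (1.0 - phi) * np.sum(inner_r)) / (s2w * (1.0 + phi))
            quad_a = (r[0] ** 2 + r[-1] ** 2 + (1.0 + phi * phi) * np.sum(inner_r**2)
                      - 2.0 * phi * np.sum(r[:-1] * r[1:])) / (s2w * om2)
            logdet_a = 2.0 * n * np.log(sd_w) + (n - 1) * np.log(om2)
        shrink = 1.0 + s2b * c
        logdet = logdet_a + np.log(shrink)
        quad = quad_a - s2b / shrink * ur * ur
        nll += 0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
        sum_wy += uy / shrink
        sum_w += c / shrink
    return nll, sum_wy, sum_w


def mixed_loa(minute_diffs, max_iter: int = 200, method: str = "REML") -> MixedLoA:
    """Fit the intercept-only random-intercept + AR(1) model and derive
    limits of agreement.

    ``minute_diffs`` is a DataFrame with columns (subject, minute_index, d)
    or a list of per-subject difference vectors.  Variance parameters are
    estimated by restricted maximum likelihood by default (``method="ML"``
    for plain maximum likelihood); REML removes the downward bias of the
    between-subject SD that plain ML incurs with a profiled mean.  Bias is
    the fixed intercept (GLS mean at the fitted variance parameters), its
    test a Wald z test; LoA = bias +/- 1.96 * sqrt(sd_between^2 +
    sd_within^2).  With a single subject the between-subject SD is not
    identifiable and is fixed at zero.  Raises on non-convergence with
    optimizer diagnostics.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    groups = _subject_arrays(minute_diffs)
    if len(groups) == 0 or any(len(g) == 0 for g in groups):
        raise ValueError("empty input")
    all_d = np.concatenate(groups)
    n_obs = len(all_d)
    n_sub = len(groups)
    if np.ptp(all_d) == 0:
        b = float(all_d[0])
        return MixedLoA(bias=b, sd_between=0.0, sd_within=0.0, phi=0.0,
                        loa_lower=b, loa_upper=b, p_value=float("nan"),
                        se_bias=0.0, n_subjects=n_sub, n_obs=n_obs)

    scale = float(np.std(all_d))
    means = np.array([np.mean(g) for g in groups])
    within = [np.var(g) for g in groups if len(g) > 1]
    sw0 = float(np.sqrt(np.mean(within))) if within else scale
    if not np.isfinite(sw0) or sw0 <= 0:
        sw0 = scale
    sb0 = float(np.std(means)) or 0.1 * scale
    # Pooled lag-1 autocorrelation of within-subject residuals.
    num = den = 0.0
    for g in groups:
        if len(g) > 2:
            e = g - np.mean(g)
            num += np.sum(e[:-1] * e[1:])
            den += np.sum(e * e)
    phi0 = float(np.clip(num / den if den > 0 else 0.0, -0.9, 0.9))
    single = n_sub == 1

    def unpack(x):
        sd_w = np.exp(x[0])
        sd_b = 0.0 if single else np.exp(x[1])
        phi = np.tanh(x[2])
        return sd_b, sd_w, phi

    def objective(x):
        sd_b, sd_w, phi = unpack(x)
        # Profile the mean: GLS mean given the variance parameters.
        _, swy, sw = _nll_terms(groups, 0.0, sd_b, sd_w, phi)
        mu = swy / sw
        nll, _, _ = _nll_terms(groups, mu, sd_b, sd_w, phi)
        if method == "REML":
            # Restricted likelihood: penalise by the information about the
            # profiled mean, 0.5 * log |X' V^-1 X| with X = 1.
            nll += 0.5 * np.log(sw)
        return nll

    x0 = np.array([np.log(max(sw0, 1e-8 * scale)),
                   np.log(max(sb0, 1e-8 * scale)),
                   np.arctanh(np.clip(phi0, -0.99, 0.99))])
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"maxiter": max_iter * 10, "xatol": 1e-7, "fatol": 1e-9})
    if not res.success:
        raise RuntimeError(f"mixed model did not converge: {res.message} "
                           f"(nit={res.nit}, final nll={res.fun:.6g})")
    sd_b, sd_w, phi = unpack(res.x)
    _, swy, sw = _nll_terms(groups, 0.0, sd_b, sd_w, phi)
    mu = swy / sw
    se = float(1.0 / np.sqrt(sw))
    sd_tot = float(np.sqrt(sd_b**2 + sd_w**2))
    z = mu / se if se > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MixedLoA(bias=float(mu), sd_between=float(sd_b), sd_within=float(sd_w),
                    phi=float(phi), loa_lower=float(mu - 1.96 * sd_tot),
                    loa_upper=float(mu + 1.96 * sd_tot), p_value=p, se_bias=se,
                    n_subjects=n_sub, n_obs=n_obs, converged=bool(res.success),
                    method=method)


# ---------------------------------------------------------------------------
# Epoch-by-epoch comparison


def map_epochs(psg: Hypnogram, fb: Hypnogram) -> pd.DataFrame:
    """Pair each 20 s PSG epoch with the dominating tracker stage.

    Both series must already be on the same clock (apply the estimated
    shift first).  For each PSG epoch the tracker stage with the largest
    overlap wins if it covers more than half the epoch (>10 s); an exact
    10 s / 10 s split between two different tracker stages goes to the
    earlier-starting one.  PSG epochs without such a dominating stage
    (outside tracker coverage, or only half covered) are excluded; the
    count of exclusions is in ``df.attrs["n_excluded"]``.

    Returns a DataFrame with columns psg, fitbit, epoch_start.
    """
    if fb.epoch_s < psg.epoch_s:
        raise ValueError("expected tracker epochs at least as long as PSG epochs")
    rows = []
    n_excluded = 0
    half = psg.epoch_s / 2.0
    for i, plab in enumerate(psg.labels):
        t0 = psg.start + i * psg.epoch_s
        t1 = t0 + psg.epoch_s
        # Tracker epochs overlapping [t0, t1)
        k0 = int(np.floor((t0 - fb.start) / fb.epoch_s))
        k1 = int(np.ceil((t1 - fb.start) / fb.epoch_s))
        overlap, first = {}, {}
        for k in range(max(k0, 0), min(k1, len(fb))):
            e0 = fb.start + k * fb.epoch_s
            ov = min(t1, e0 + fb.epoch_s) - max(t0, e0)
            if ov > 0:
                lab = fb.labels[k]
                overlap[lab] = overlap.get(lab, 0.0) + ov
                first.setdefault(lab, e0)
        winner = None
        if overlap:
            best = max(overlap.values())
            winners = sorted((lab for lab, ov in overlap.items()
                              if np.isclose(ov, best, atol=1e-9)),
                             key=lambda lab: first[lab])
            if best > half + 1e-9:
                winner = winners[0]
            elif np.isclose(best, half, atol=1e-9) and len(winners) >= 2:
                winner = winners[0]
        if winner is None:
            n_excluded += 1
        else:
            rows.append({"psg": plab, "fitbit": winner, "epoch_start": t0})
    df = pd.DataFrame(rows, columns=["psg", "fitbit", "epoch_start"])
    df.attrs["n_excluded"] = n_excluded
    return df


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a target tracker stage."""

    tp: int
    fp: int
    tn: int
    fn: int
    target_stage: str

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pairs: pd.DataFrame, target_stage: str,
              stage_map: dict = None) -> ConfusionCounts:
    """One-vs-rest confusion counts from matched epoch pairs.

    ``target_stage`` is a tracker stage (wake/light/deep/rem); PSG labels
    are mapped through ``stage_map`` (default wake=W, light=N1+N2,
    deep=N3, rem=REM).  Positives P = PSG epochs of the target stage
    (tp + fn); negatives N = the rest (tn + fp).
    """
    stage_map = PSG_TO_TRACKER if stage_map is None else stage_map
    if target_stage not in TRACKER_STAGES:
        raise ValueError(f"target_stage must be one of {TRACKER_STAGES}")
    psg_pos = np.array([stage_map[lab] == target_stage for lab in pairs["psg"]], dtype=bool)
    fb_pos = np.array([lab == target_stage for lab in pairs["fitbit"]], dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(psg_pos & fb_pos)),
        fp=int(np.sum(~psg_pos & fb_pos)),
        tn=int(np.sum(~psg_pos & ~fb_pos)),
        fn=int(np.sum(psg_pos & ~fb_pos)),
        target_stage=target_stage,
    )


@dataclass
class EBEMetrics:
    """Epoch-by-epoch agreement metrics; undefined ratios are NaN, except
    MCC which is 0 by convention when a confusion-matrix marginal is empty."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    ppv: float
    npv: float


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def ebe_metrics(c: ConfusionCounts) -> EBEMetrics:
    """Six agreement metrics from one-vs-rest confusion counts.

    Sensitivity = TP/P and specificity = TN/N with P, N the PSG positives
    and negatives; accuracy = (TP+TN)/(P+N); PPV = TP/(TP+FP);
    NPV = TN/(TN+FN); MCC = (TP*TN - FP*FN) / sqrt of the product of all
    four marginals.
    """
    import math

    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    # Exact integer product before the single square root.
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return EBEMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        mcc=float(mcc),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def rem_window_split(pairs: pd.DataFrame, s_on: float,
                     threshold_min: float = 120.0, stage_map: dict = None):
    """REM agreement split at ``s_on + threshold_min`` minutes.

    Epochs starting before the threshold form the early window, the rest
    the late window; each is scored one-vs-rest for the rem stage.
    Returns (early_metrics, late_metrics).
    """
    cut = s_on + threshold_min * 60.0
    early = pairs[pairs["epoch_start"] < cut]
    late = pairs[pairs["epoch_start"] >= cut]
    return (ebe_metrics(confusion(early, "rem", stage_map)),
            ebe_metrics(confusion(late, "rem", stage_map)))


# ---------------------------------------------------------------------------
# Cohort report


@dataclass
class NightData:
    """Processed single-night inputs to the cohort report."""

    subject_id: str
    summaries: dict                # (device, criterion, adjusted) -> SleepSummary
    minute_stats: pd.DataFrame     # output of sleepvars.minute_hr_stats per window
    ebe_pairs: pd.DataFrame        # output of map_epochs (aligned)
    s_on_n1: float                 # PSG N1 onset (clock s) for the REM split
    run_lengths: dict = field(default_factory=dict)  # device -> [(stage, min)]
    shift_lag: float = float("nan")
    shift_corr: float = float("nan")


@dataclass
class AgreementReport:
    """Cohort-level agreement tables."""

    sleep_ba: pd.DataFrame
    hr_loa: pd.DataFrame
    ebe: pd.DataFrame
    run_lengths: pd.DataFrame
    shifts: pd.DataFrame
    n_nights: int

SLEEP_VARIABLES = ("s_on", "s_off", "tst", "waso", "reml", "rem_d", "light_d", "deep_d")


def cohort_report(nights, criteria=("N1_on",), adjusted=(True,),
                  rem_threshold_min: float = 120.0) -> AgreementReport:
    """Assemble cohort agreement tables from per-night data.

    Bland-Altman statistics per sleep variable (per onset criterion and
    border-adjustment setting; clock variables s_on/s_off are compared in
    minutes), mixed-model LoA for per-minute HR_10 and HRvar_10 overall
    and per PSG stage, pooled (micro-average) EBE metrics per stage with a
    per-night macro-average alongside, the REM early/late split, run-length
    distributions and per-night clock shifts.
    """
    if len(nights) < 1:
        raise ValueError("need at least one night")

    ba_rows = []
    for criterion in criteria:
        for adj in adjusted:
            for var in SLEEP_VARIABLES:
                pairs = []
                for nd in nights:
                    p = nd.summaries.get(("psg", criterion, adj))
                    f = nd.summaries.get(("fitbit", criterion, adj))
                    if p is None or f is None:
                        continue
                    pv, fv = getattr(p, var), getattr(f, var)
                    if var in ("s_on", "s_off"):
                        pv, fv = pv / 60.0, fv / 60.0
                    if np.isfinite(pv) and np.isfinite(fv):
                        pairs.append((pv, fv))
                if len(pairs) >= 2:
                    ba = bland_altman(pairs, x_axis_mode="psg_value")
                    ba_rows.append({"criterion": criterion, "adjusted": adj, "variable": var,
                                    "bias": ba.bias, "loa_lower": ba.loa_lower,
                                    "loa_upper": ba.loa_upper, "p_value": ba.p_value,
                                    "n": ba.n})
    sleep_ba = pd.DataFrame(ba_rows)

    # Mixed-model LoA for HR_10 / HRvar_10, overall and per PSG stage.
    loa_rows = []
    frames = []
    for nd in nights:
        ms = nd.minute_stats
        if ms is None or len(ms) == 0:
            continue
        ms = ms.copy()
        ms["subject"] = nd.subject_id
        frames.append(ms)
    if frames:
        allms = pd.concat(frames, ignore_index=True)
        allms["minute_index"] = (allms["minute_start"] // 60.0).astype(int)
        for measure, pcol, fcol in (("hr10", "psg_hr10", "fitbit_hr10"),
                                    ("hrvar10", "psg_hrvar10", "fitbit_hrvar10")):
            allms[f"d_{measure}"] = allms[pcol] - allms[fcol]
            # Stage-stratified statistics are restricted to the onset-to-
            # offset window when the pipeline marked it; the overall window
            # additionally covers the half hour before onset.
            if "in_stage_window" in allms.columns:
                stage_base = allms[allms["in_stage_window"]]
            else:
                stage_base = allms
            scopes = [("overall", allms)] + [
                (str(st), g) for st, g in stage_base.groupby("stage") if st is not None]
            for scope, g in scopes:
                g = g.dropna(subset=[f"d_{measure}"])
                if g["subject"].nunique() < 1 or len(g) < 3:
                    continue
                df = g.rename(columns={f"d_{measure}": "d"})[["subject", "minute_index", "d"]]
                try:
                    fit = mixed_loa(df)
                except RuntimeError as exc:
                    logger.warning("mixed LoA failed for %s/%s: %s", measure, scope, exc)
                    continue
                loa_rows.append({"measure": measure, "scope": scope, "bias": fit.bias,
                                 "sd_between": fit.sd_between, "sd_within": fit.sd_within,
                                 "phi": fit.phi, "loa_lower": fit.loa_lower,
                                 "loa_upper": fit.loa_upper, "p_value": fit.p_value,
                                 "n_subjects": fit.n_subjects, "n_obs": fit.n_obs})
    hr_loa = pd.DataFrame(loa_rows)

    # EBE: pooled micro-average and per-night macro-average.
    ebe_rows = []
    pooled = pd.concat([nd.ebe_pairs for nd in nights if len(nd.ebe_pairs)],
                       ignore_index=True) if any(len(nd.ebe_pairs) for nd in nights) else pd.DataFrame()
    metric_names = ("sensitivity", "specificity", "accuracy", "mcc", "ppv", "npv")
    for stage in TRACKER_STAGES:
        if len(pooled):
            m = ebe_metrics(confusion(pooled, stage))
            row = {"stage": stage, "window": "all", "averaging": "pooled"}
            row.update({k: getattr(m, k) for k in metric_names})
            ebe_rows.append(row)
        per_night = []
        for nd in nights:
            if len(nd.ebe_pairs):
                per_night.append(ebe_metrics(confusion(nd.ebe_pairs, stage)))
        if per_night:
            row = {"stage": stage, "window": "all", "averaging": "macro"}
            for k in metric_names:
                vals = [getattr(m, k) for m in per_night]
                vals = [v for v in vals if not np.isnan(v)]
                row[k] = float(np.mean(vals)) if vals else float("nan")
            ebe_rows.append(row)
    # REM early/late split, pooled across nights relative to each night's onset.
    early_frames, late_frames = [], []
    for nd in nights:
        if len(nd.ebe_pairs) and np.isfinite(nd.s_on_n1):
            cut = nd.s_on_n1 + rem_threshold_min * 60.0
            early_frames.append(nd.ebe_pairs[nd.ebe_pairs["epoch_start"] < cut])
            late_frames.append(nd.ebe_pairs[nd.ebe_pairs["epoch_start"] >= cut])
    for name, frames_ in (("rem_lt_threshold", early_frames), ("rem_ge_threshold", late_frames)):
        if frames_:
            sub = pd.concat(frames_, ignore_index=True)
            if len(sub):
                m = ebe_metrics(confusion(sub, "rem"))
                row = {"stage": "rem", "window": name, "averaging": "pooled"}
                row.update({k: getattr(m, k) for k in metric_names})
                ebe_rows.append(row)
    ebe = pd.DataFrame(ebe_rows)

    rl_rows = []
    for nd in nights:
        for device, runs in nd.run_lengths.items():
            for stage, dur in runs:
                rl_rows.append({"subject": nd.subject_id, "device": device,
                                "stage": stage, "duration_min": dur})
    run_lengths_df = pd.DataFrame(rl_rows)

    shifts = pd.DataFrame([{"subject": nd.subject_id, "lag_s": nd.shift_lag,
                            "peak_corr": nd.shift_corr} for nd in nights])
    return AgreementReport(sleep_ba=sleep_ba, hr_loa=hr_loa, ebe=ebe,
                           run_lengths=run_lengths_df, shifts=shifts,
                           n_nights=len(nights))


# ---------------------------------------------------------------------------
# Plotting (optional, Bland-Altman panels)


def plot_bland_altman(pairs, ba: BAStats = None, ax=None, xlabel: str = "",
                      ylabel: str = "PSG - tracker"):
    """Bland-Altman panel: differences against the PSG value or the device
    mean depending on ``ba.x_axis_mode``, with bias and LoA lines."""
    import matplotlib.pyplot as plt

    arr = np.asarray(pairs, dtype=float)
    ba = bland_altman(arr) if ba is None else ba
    x = arr[:, 0] if ba.x_axis_mode == "psg_value" else arr.mean(axis=1)
    d = arr[:, 0] - arr[:, 1]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, d, s=14, alpha=0.7)
    for y, style in ((ba.bias, "--"), (ba.loa_lower, ":"), (ba.loa_upper, ":")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel(xlabel or ("PSG value" if ba.x_axis_mode == "psg_value" else "device mean"))
    ax.set_ylabel(ylabel)
    return ax
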