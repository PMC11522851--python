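"""Diagnostic statistics: AMS classification, subgroup comparison, ROC and
method agreement.

AMS classification follows the Lake Louise convention: a morning is
positive when the total score is >= 3 *and* the headache item scores >= 1.
Participant-nights with total >= 3 but headache = 0 fall outside both
printed definitions and are classified negative under this conjunctive
rule, with a flag so they can be audited.

Group comparisons use the Mann-Whitney U-test with the Hodges-Lehmann
median-difference estimate (median of all pairwise differences) and a 95%
confidence interval from inversion of the rank test.  ROC analysis reports
the AUC (oriented so AUC >= 0.5), a Hanley-McNeil confidence interval and
the Youden-optimal operating point in both conventions: the standard index
sensitivity + specificity - 1, and the reported sum sensitivity +
specificity, which some field tables print.  Bland-Altman agreement reports
bias, 95% limits of agreement and the regression of differences on
averages (slope, x-intercept, r^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .config import StatsConfig
from .errors import (
    DegenerateGroupingError,
    InputDomainError,
    InsufficientDataError,
)
from .session import LLSRecord, MORNING, peak_lls


@dataclass(frozen=True)
class AMSStatus:
    participant_id: str
    day_label: str
    is_positive: bool
    #: total >= 3 without headache: outside both printed definitions,
    #: classified negative but flagged for audit.
    rule_gap: bool = False


@dataclass
class GroupComparison:
    metric: str
    median_pos: float
    iqr_pos: tuple[float, float]
    median_neg: float
    iqr_neg: tuple[float, float]
    hl_median_difference: float
    ci95: tuple[float, float]
    p_value: float
    n_pos: int = 0
    n_neg: int = 0


@dataclass
class RocResult:
    metric: str
    auc: float
    auc_ci95: tuple[float, float]
    p_value: float
    cutoff_value: float
    cutoff_direction: str  # "below" | "above"
    sensitivity: float
    specificity: float
    youden_reported: float  # sensitivity + specificity (printed convention)
    youden_standard: float  # sensitivity + specificity - 1


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa95: tuple[float, float]
    slope: float | None
    slope_ci: tuple[float, float] | None
    x_intercept: float | None
    x_intercept_ci: tuple[float, float] | None
    r_squared: float | None
    n_pairs: int = 0


# ---------------------------------------------------------------------------
# classification and outliers
# ---------------------------------------------------------------------------

def classify_ams(record: LLSRecord) -> AMSStatus:
    """Classify a morning Lake Louise record as AMS-positive or -negative."""
    if record.time_of_day != MORNING:
        raise InputDomainError("AMS status is derived from morning records only")
    positive = record.total_score >= 3 and record.headache_score >= 1
    return AMSStatus(
        participant_id=record.participant_id,
        day_label=record.day_label,
        is_positive=positive,
        rule_gap=(record.total_score >= 3 and record.headache_score == 0),
    )


def remove_outliers(values, k: float = 3.0) -> tuple[np.ndarray, list[float]]:
    """Single-pass +-k*SD outlier removal (mean/SD from all input values).

    Returns the retained values and a log of removed ones.  With zero SD
    nothing is removable and the input is returned unchanged.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size < 3:
        raise InputDomainError("outlier removal needs at least 3 values")
    sd = vals.std(ddof=1)
    if sd == 0:
        return vals, []
    keep = np.abs(vals - vals.mean()) <= k * sd
    return vals[keep], vals[~keep].tolist()


# ---------------------------------------------------------------------------
# Mann-Whitney / Hodges-Lehmann
# ---------------------------------------------------------------------------

def hodges_lehmann(pos, neg) -> float:
    """Median of all pairwise differences (positive minus negative)."""
    diffs = np.subtract.outer(np.asarray(pos, float), np.asarray(neg, float))
    return float(np.median(diffs))


def compare_groups(pos, neg, metric: str = "") -> GroupComparison:
    """Mann-Whitney comparison of a feature between AMS+ and AMS- nights.

    The effect size is the Hodges-Lehmann estimate (positive minus
    negative) with a 95% CI from inversion of the rank test (normal
    approximation to the critical U order statistic).
    """
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateGroupingError(f"{metric or 'comparison'}: a group is empty")
    diffs = np.sort(np.subtract.outer(pos, neg), axis=None)
    m, n = pos.size, neg.size
    hl = float(np.median(diffs))
    N = m * n
    z = sps.norm.ppf(0.975)
    k = int(np.floor(N / 2.0 - z * np.sqrt(m * n * (m + n + 1) / 12.0)))
    k = min(max(k, 0), (N - 1) // 2)
    ci = (float(diffs[k]), float(diffs[N - 1 - k]))
    if np.all(pos == pos[0]) and np.all(neg == neg[0]) and pos[0] == neg[0]:
        p = 1.0  # all observations identical: no evidence either way
    else:
        p = float(sps.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    q_pos = np.percentile(pos, [25, 50, 75])
    q_neg = np.percentile(neg, [25, 50, 75])
    return GroupComparison(
        metric=metric,
        median_pos=float(q_pos[1]),
        iqr_pos=(float(q_pos[0]), float(q_pos[2])),
        median_neg=float(q_neg[1]),
        iqr_neg=(float(q_neg[0]), float(q_neg[2])),
        hl_median_difference=hl,
        ci95=ci,
        p_value=p,
        n_pos=m,
        n_neg=n,
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def youden_indices(sensitivity: float, specificity: float) -> tuple[float, float]:
    """Both Youden conventions: (reported = sens + spec, standard = sens + spec - 1)."""
    return sensitivity + specificity, sensitivity + specificity - 1.0


def auc_mann_whitney(pos, neg) -> float:
    """AUC as the rank statistic U/(n1*n2); ties count one half."""
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u) / (pos.size * neg.size)


def _hanley_mcneil_ci(auc: float, n1: int, n2: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_youden(pos, neg, metric: str = "", cfg: StatsConfig | None = None) -> RocResult:
    """ROC analysis with the Youden-optimal cutoff.

    The orientation ("below"/"above") is chosen so the AUC is at least 0.5:
    for saturation-like metrics low values indicate illness and the cutoff
    direction is "below".  Cutoffs are midpoints between consecutive
    distinct scores; ties in the Youden index are broken toward higher
    sensitivity, then toward the cutoff closest to the pooled median (the
    less extreme operating point).
    """
    cfg = cfg or StatsConfig()
    cfg.validate()
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateGroupingError(f"{metric or 'roc'}: both classes must be present")
    if np.unique(np.concatenate([pos, neg])).size < 2:
        raise DegenerateGroupingError("ROC needs at least 2 distinct score values")

    auc_raw = auc_mann_whitney(pos, neg)
    direction = "above" if auc_raw >= 0.5 else "below"
    auc = auc_raw if auc_raw >= 0.5 else 1.0 - auc_raw

    uniq = np.unique(np.concatenate([pos, neg]))
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    if direction == "above":
        sens = (pos[:, None] > cuts[None, :]).mean(axis=0)
        spec = (neg[:, None] <= cuts[None, :]).mean(axis=0)
    else:
        sens = (pos[:, None] < cuts[None, :]).mean(axis=0)
        spec = (neg[:, None] >= cuts[None, :]).mean(axis=0)
    j = sens + spec
    pooled_median = float(np.median(np.concatenate([pos, neg])))
    # lexicographic choice: max Youden, then max sensitivity, then the
    # cutoff nearest the pooled median.
    order = np.lexsort((np.abs(cuts - pooled_median), -sens, -j))
    best = order[0]

    p = float(sps.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    yr, ys = youden_indices(float(sens[best]), float(spec[best]))
    return RocResult(
        metric=metric,
        auc=auc,
        auc_ci95=_hanley_mcneil_ci(auc, pos.size, neg.size),
        p_value=p,
        cutoff_value=float(cuts[best]),
        cutoff_direction=direction,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden_reported=yr,
        youden_standard=ys,
    )


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------

def bland_altman(reference, test) -> BlandAltmanResult:
    """Bland-Altman agreement between a reference and a test measure.

    Differences are reference minus test; bias is their mean and the 95%
    limits of agreement are bias +- 1.96 SD.  An ordinary least-squares fit
    of differences on pairwise averages gives the slope, the x-intercept
    (the average value at which the fitted difference is zero) and r^2,
    with 95% CIs from the regression (delta method for the x-intercept).
    """
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.size != tst.size:
        raise InputDomainError("reference and test must be paired")
    if ref.size < 3:
        raise InsufficientDataError("Bland-Altman needs at least 3 pairs")
    diffs = ref - tst
    avgs = (ref + tst) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)

    if np.var(avgs) == 0:
        return BlandAltmanResult(bias, sd, loa, None, None, None, None, None, ref.size)
    if np.var(diffs) == 0:
        # constant offset: flat difference line, no explainable variance
        return BlandAltmanResult(bias, sd, loa, 0.0, (0.0, 0.0), None, None, 0.0, ref.size)

    X = sm.add_constant(avgs)
    fit = sm.OLS(diffs, X).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    ci = fit.conf_int(alpha=0.05)
    slope_ci = (float(ci[1][0]), float(ci[1][1]))
    if slope == 0:
        x_int, x_int_ci = None, None
    else:
        x_int = -intercept / slope
        cov = fit.cov_params()
        var_a, var_b = float(cov[0][0]), float(cov[1][1])
        cov_ab = float(cov[0][1])
        var_xi = (var_a + x_int**2 * var_b + 2 * x_int * cov_ab) / slope**2
        t = sps.t.ppf(0.975, df=ref.size - 2)
        half = t * np.sqrt(max(var_xi, 0.0))
        x_int_ci = (x_int - half, x_int + half)
    return BlandAltmanResult(
        bias, sd, loa, slope, slope_ci, x_int, x_int_ci, float(fit.rsquared), ref.size
    )


# ---------------------------------------------------------------------------
# exploratory correlations
# ---------------------------------------------------------------------------

def exploratory_correlations(
    features: pd.DataFrame,
    lls_records: Sequence[LLSRecord],
    feature_cols: Sequence[str],
    night_labels: Sequence[str],
) -> pd.DataFrame:
    """Pearson correlations of per-night features against each participant's
    peak morning LLS total.

    ``features`` must carry one row per participant-night with
    ``participant_id`` and ``night_label`` columns.  Cells with fewer than 3
    paired observations are marked not assessable (NaN r/p with the pair
    count recorded).
    """
    peaks: dict[str, int] = {}
    for pid in features["participant_id"].unique():
        try:
            peaks[pid] = peak_lls(lls_records, pid)[1]
        except Exception:
            continue
    rows = []
    for night in night_labels:
        sub = features[features["night_label"] == night]
        for col in feature_cols:
            pairs = [
                (float(v), peaks[p])
                for p, v in zip(sub["participant_id"], sub[col])
                if p in peaks and pd.notna(v)
            ]
            if len(pairs) < 3:
                rows.append({"night_label": night, "feature": col, "n": len(pairs),
                             "r": np.nan, "p_value": np.nan})
                continue
            x, y = np.array([a for a, _ in pairs]), np.array([b for _, b in pairs])
            if np.var(x) == 0 or np.var(y) == 0:
                rows.append({"night_label": night, "feature": col, "n": len(pairs),
                             "r": np.nan, "p_value": np.nan})
                continue
            r, p = sps.pearsonr(x, y)
            rows.append({"night_label": night, "feature": col, "n": len(pairs),
                         "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
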