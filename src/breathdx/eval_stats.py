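"""Evaluation statistics for diagnostic classifiers.

Point metrics (AUC, sensitivity, specificity, accuracy, F1) with Wilson
score 95% intervals on the proportion-type metrics and a DeLong normal
interval on the AUC; paired-model comparisons by the DeLong test on
correlated AUCs and McNemar's test on discordant correctness; the
any-marker-positive serum tumour-marker panel rule; and paired pre/post
surgery monitoring of predicted risk.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, ttest_rel, wilcoxon
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

from .tables import SERUM_MARKERS

__all__ = ["roc_auc", "wilson_ci", "PerfReport", "performance_report",
           "delong_test", "mcnemar_test", "serum_panel_classify",
           "prepost_comparison"]


def roc_auc(scores, labels) -> float:
    """Probability a positive outscores a negative, ties counting 1/2.

    Computed via mid-ranks, which is exactly the pairwise definition.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(scores)
    u = r[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def wilson_ci(k: int, n: int, level: float = 0.95,
              method: str = "wilson") -> tuple[float, float]:
    """Binomial proportion interval (Wilson score by default).

    ``method="beta"`` gives the Clopper-Pearson exact interval instead.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=method)
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


# ---------------------------------------------------------------------------
# DeLong machinery

def _placements(scores, pos):
    """Per-positive (V10) and per-negative (V01) placement values."""
    s_pos, s_neg = scores[pos], scores[~pos]
    v10 = np.array([np.mean((x > s_neg) + 0.5 * (x == s_neg)) for x in s_pos])
    v01 = np.array([np.mean((s_pos > x) + 0.5 * (s_pos == x)) for x in s_neg])
    return v10, v01


def _delong_auc_variance(scores, pos) -> tuple[float, float]:
    v10, v01 = _placements(np.asarray(scores, dtype=float), pos)
    auc = float(v10.mean())
    n1, n0 = v10.size, v01.size
    var = 0.0
    if n1 > 1:
        var += float(np.var(v10, ddof=1)) / n1
    if n0 > 1:
        var += float(np.var(v01, ddof=1)) / n0
    return auc, var


def delong_test(scores_a, scores_b, labels):
    """DeLong test for two correlated AUCs on the same samples.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value on the
    paired AUC difference using the placement-value covariance.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != pos.shape[0]:
        raise ValueError("paired score vectors must share the label vector")
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("DeLong needs at least two samples per class")

    va10, va01 = _placements(scores_a, pos)
    vb10, vb01 = _placements(scores_b, pos)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0)
    delta = auc_a - auc_b
    if var <= 0:
        if abs(delta) < 1e-12:
            return auc_a, auc_b, 0.0, 1.0
        raise ValueError("degenerate pairing: zero variance with nonzero AUC difference")
    z = delta / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return auc_a, auc_b, float(z), p


def mcnemar_test(correct_a, correct_b) -> tuple[int, int, float]:
    """McNemar's paired test on per-sample correctness indicators.

    ``b`` counts samples only model A got right, ``c`` those only model B
    got right.  Exact two-sided binomial p when ``b + c <= 25``, else the
    continuity-corrected chi-square approximation.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("paired indicator vectors must have equal length")
    b = int((a & ~bb).sum())
    c = int((~a & bb).sum())
    if b + c == 0:
        return b, c, 1.0
    exact = (b + c) <= 25
    table = [[0, b], [c, 0]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return b, c, float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# performance reporting

@dataclass
class PerfReport:
    """Confusion-derived metrics with 95% intervals for one (sub)group."""

    subgroup: str
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None
    auc_ci: tuple[float, float] | None
    sensitivity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None
    accuracy: float
    accuracy_ci: tuple[float, float]
    f1: float | None
    f1_ci: tuple[float, float] | None

    def to_dict(self) -> dict:
        return asdict(self)


def performance_report(scores, labels, threshold: float,
                       subgroup_mask=None, subgroup: str = "all",
                       level: float = 0.95) -> PerfReport:
    """Confusion counts and intervalled metrics at ``score >= threshold``.

    Wilson intervals are attached to sensitivity (k=TP over positives),
    specificity (k=TN over negatives), accuracy and F1 (on the F1 ratio
    2TP / (2TP+FP+FN)); the AUC interval is the DeLong normal interval.
    Single-class subgroups get accuracy/sensitivity-style counts only.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    if subgroup_mask is not None:
        m = np.asarray(subgroup_mask, dtype=bool)
        scores, pos = scores[m], pos[m]
    n = scores.size
    if n == 0:
        raise ValueError("empty subgroup")
    pred = scores >= threshold
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    tn = int((~pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    n1, n0 = tp + fn, tn + fp

    acc = (tp + tn) / n
    acc_ci = wilson_ci(tp + tn, n, level)
    sens = sens_ci = spec = spec_ci = f1 = f1_ci = auc = auc_ci = None
    if n1 > 0:
        sens = tp / n1
        sens_ci = wilson_ci(tp, n1, level)
        f1_den = 2 * tp + fp + fn
        if f1_den > 0:
            f1 = 2 * tp / f1_den
            f1_ci = wilson_ci(2 * tp, f1_den, level)
    if n0 > 0:
        spec = tn / n0
        spec_ci = wilson_ci(tn, n0, level)
    if n1 > 0 and n0 > 0:
        auc, var = _delong_auc_variance(scores, pos)
        z = norm.ppf(0.5 + level / 2)
        hw = z * np.sqrt(var)
        auc_ci = (float(np.clip(auc - hw, 0, 1)), float(np.clip(auc + hw, 0, 1)))

    return PerfReport(subgroup=subgroup, n=n, tp=tp, fp=fp, tn=tn, fn=fn,
                      auc=auc, auc_ci=auc_ci, sensitivity=sens,
                      sensitivity_ci=sens_ci, specificity=spec,
                      specificity_ci=spec_ci, accuracy=acc, accuracy_ci=acc_ci,
                      f1=f1, f1_ci=f1_ci)


# ---------------------------------------------------------------------------
# serum tumour-marker panel

def serum_panel_classify(sheet: pd.DataFrame) -> pd.DataFrame:
    """Any-positive serum-marker panel rule.

    A marker is positive iff its value is strictly above the upper limit of
    its clinical normal range; the panel is positive iff any available
    marker is.  Samples with every marker missing are flagged ``excluded``
    (panel verdict undefined, not negative).  Returns a frame indexed by
    sample id with per-marker booleans, ``panel_positive`` and ``excluded``.
    """
    out = pd.DataFrame(index=pd.Index(sheet["sample_id"], name="sample_id"))
    avail = pd.DataFrame(index=out.index)
    for m, upper in SERUM_MARKERS.items():
        vals = pd.to_numeric(sheet[m], errors="coerce").to_numpy()
        out[f"{m}_positive"] = vals > upper
        avail[m] = ~np.isnan(vals)
    any_avail = avail.any(axis=1)
    out["panel_positive"] = out[[f"{m}_positive" for m in SERUM_MARKERS]].any(axis=1)
    out.loc[~any_avail, "panel_positive"] = False
    out["excluded"] = ~any_avail
    return out


def prepost_comparison(scores_pre, scores_post, alternative_test: bool = False):
    """Paired pre- vs post-operative comparison of predicted risk.

    Returns ``(mean_drop, statistic, p, n_pairs)`` where ``mean_drop`` is the
    mean of (post - pre).  Default is the two-sided paired t-test on the
    per-pair differences; ``alternative_test=True`` uses the Wilcoxon
    signed-rank test instead (predicted probabilities are bounded, so the
    t assumption is approximate).
    """
    pre = np.asarray(scores_pre, dtype=float)
    post = np.asarray(scores_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post score vectors must pair one-to-one")
    n = pre.size
    if n < 2:
        raise ValueError("need at least two pre/post pairs")
    diff = post - pre
    mean_drop = float(diff.mean())
    if alternative_test:
        if np.all(diff == 0):
            return mean_drop, 0.0, 1.0, n
        stat, p = wilcoxon(diff)
        return mean_drop, float(stat), float(p), n
    if np.all(diff == diff[0]):
        if diff[0] == 0:
            return mean_drop, 0.0, 1.0, n
        return mean_drop, float(np.sign(diff[0]) * np.inf), 0.0, n
    t, p = ttest_rel(post, pre)
    return mean_drop, float(t), float(p), n
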