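"""Dual-criteria differential-VOC screening.

Each compound is assessed two ways on the training samples:

* a two-sided Wilcoxon rank-sum test between malignant and benign groups
  (exact enumeration for small tie-free groups, tie-corrected normal
  approximation with continuity correction otherwise);
* the variable-importance-in-projection (VIP) score of an OPLS-DA model —
  a one-predictive-component PLS on class labels after removal of
  ``n_orthogonal`` components of y-orthogonal variation.

Compounds with p < 0.05 *and* VIP > 1 (both strict) become candidate
biomarkers, unless they appear on a user-supplied exclusion list of drug
metabolites / contaminants.  The univariate ROC-AUC of each compound is
reported alongside for downstream ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .eval_stats import roc_auc

__all__ = ["P_THRESHOLD", "VIP_THRESHOLD", "OplsModel", "rank_sum_test",
           "fit_oplsda", "vip_scores", "screen"]

P_THRESHOLD = 0.05
VIP_THRESHOLD = 1.0


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when ``min(|x|, |y|) <= 8`` and there
    are no ties; otherwise the normal approximation with tie-corrected
    variance and continuity correction.  Identical constant groups give
    p = 1 (no evidence) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method,
                              use_continuity=True).pvalue)


@dataclass
class OplsModel:
    """Single-response O-PLS model with one predictive component."""

    weights: np.ndarray            # unit predictive weight vector w
    loadings: np.ndarray           # predictive loading p
    scores: np.ndarray             # predictive score t (per sample)
    y_loading: float               # q, regression of centered y on t
    ortho_weights: np.ndarray      # (n_orthogonal, p)
    ortho_loadings: np.ndarray
    ortho_scores: np.ndarray       # (n_orthogonal, n)
    explained_y_variance: float    # fraction of centered-y SS explained by t
    x_mean: np.ndarray
    y_mean: float
    n_predictive: int = 1

    @property
    def n_orthogonal(self) -> int:
        return self.ortho_weights.shape[0]


def fit_oplsda(X, y, n_orthogonal: int = 1) -> OplsModel:
    """Fit OPLS-DA by NIPALS orthogonal signal correction.

    ``y`` is a binary label vector, encoded +/-1 and centered internally;
    ``X`` columns are centered internally.  Each orthogonal component is the
    part of the current predictive loading orthogonal to the weight vector;
    its score is deflated from X and the predictive weight refit.  With
    ``n_orthogonal=0`` the model is exactly one-component PLS-DA.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes are inconsistent")
    levels = np.unique(y)
    if levels.size != 2:
        raise ValueError("y must take exactly two values")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    if n_orthogonal >= min(X.shape):
        raise ValueError("more components than the rank of X can support")

    yv = np.where(y == levels[1], 1.0, -1.0)
    y_mean = float(yv.mean())
    yc = yv - y_mean
    x_mean = X.mean(axis=0)
    Xc = X - x_mean

    def _weight(mat):
        w = mat.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("X carries no covariance with y")
        return w / nw

    w = _weight(Xc)
    ow, ol, os_ = [], [], []
    for _ in range(n_orthogonal):
        t = Xc @ w
        p_load = Xc.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            raise ValueError("no orthogonal variation left to extract")
        w_o /= n_wo
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        ow.append(w_o)
        ol.append(p_o)
        os_.append(t_o)
        w = _weight(Xc)

    t = Xc @ w
    p_load = Xc.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    ss_y = float(yc @ yc)
    explained = float(q * q * (t @ t) / ss_y) if ss_y > 0 else 0.0

    p = X.shape[1]
    return OplsModel(
        weights=w, loadings=p_load, scores=t, y_loading=q,
        ortho_weights=np.array(ow).reshape(len(ow), p),
        ortho_loadings=np.array(ol).reshape(len(ol), p),
        ortho_scores=np.array(os_).reshape(len(os_), X.shape[0]),
        explained_y_variance=explained, x_mean=x_mean, y_mean=y_mean,
    )


def vip_scores(model: OplsModel) -> np.ndarray:
    """VIP over the predictive component(s).

    For a single predictive component this is ``sqrt(p) * |w_j| / ||w||``,
    so the scores satisfy the normalization ``sum(VIP^2) = p``.
    """
    w = model.weights
    p = w.shape[0]
    return np.sqrt(p) * np.abs(w) / np.linalg.norm(w)


def screen(X: pd.DataFrame, y, exclusion_list=(), n_orthogonal: int = 1,
           p_threshold: float = P_THRESHOLD,
           vip_threshold: float = VIP_THRESHOLD) -> pd.DataFrame:
    """Per-compound screening table on training data.

    ``X`` is a normalized samples x compounds frame, ``y`` the per-sample
    class labels (malignant treated as the positive group by string match,
    otherwise the second sorted level).  Returns one row per compound with
    columns ``p_value, vip, auc, candidate, excluded``.
    """
    y = np.asarray(y)
    levels = np.unique(y)
    if levels.size != 2 or min((y == l).sum() for l in levels) == 0:
        raise ValueError("screening needs two non-empty classes")
    pos_level = "malignant" if "malignant" in levels else levels[1]
    pos = y == pos_level

    model = fit_oplsda(X.to_numpy(dtype=float), pos.astype(int), n_orthogonal)
    vip = vip_scores(model)

    excl = set(map(str, exclusion_list))
    rows = []
    for j, cid in enumerate(X.columns):
        col = X.iloc[:, j].to_numpy(dtype=float)
        pval = rank_sum_test(col[pos], col[~pos])
        auc = roc_auc(col, pos)
        excluded = str(cid) in excl
        cand = (pval < p_threshold) and (vip[j] > vip_threshold) and not excluded
        rows.append((cid, pval, vip[j], auc, cand, excluded))
    return pd.DataFrame(rows, columns=["compound_id", "p_value", "vip", "auc",
                                       "candidate", "excluded"]
                        ).set_index("compound_id")
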