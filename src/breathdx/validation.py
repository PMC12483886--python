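"""Synthetic validation experiments for the pipeline.

Self-contained experiments that quantify, on generated cohorts with known
ground truth, how well each stage behaves: type-I error calibration of the
tests, agreement of closed-form statistics with brute-force oracles,
recovery of planted biomarkers by the dual screening criterion, and the
end-to-end pattern (panel size, held-out AUC vs the design ceiling, paired
pre/post monitoring).  Every experiment takes an explicit seed and is fully
deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import modeling, qc, screening
from .eval_stats import delong_test, mcnemar_test, roc_auc
from .modeling import youden_threshold
from .pipeline import PipelineConfig, prepost_by_group
from .synth import SyntheticConfig, generate_cohort

__all__ = ["ranksum_type1_error", "delong_type1_error",
           "roc_auc_oracle_max_dev", "youden_oracle_max_dev",
           "mcnemar_enum_max_dev", "delong_bootstrap_diff",
           "screening_recovery", "screening_null_rate", "end_to_end"]


# ---------------------------------------------------------------------------
# type-I error calibration

def ranksum_type1_error(n_reps: int = 500, n1: int = 30, n2: int = 30,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical rejection rate of the rank-sum test under its null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        p = screening.rank_sum_test(rng.normal(0, 1, n1), rng.normal(0, 1, n2))
        hits += p < alpha
    return hits / n_reps


def delong_type1_error(n_reps: int = 500, n: int = 60, rho: float = 0.6,
                       alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the DeLong test for two equally useless, correlated
    score vectors (labels independent of both)."""
    rng = np.random.default_rng(seed)
    labels = np.r_[np.ones(n // 2, bool), np.zeros(n - n // 2, bool)]
    hits = 0
    for _ in range(n_reps):
        u = rng.normal(0, 1, n)
        a = u
        b = rho * u + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
        _, _, _, p = delong_test(a, b, labels)
        hits += p < alpha
    return hits / n_reps


# ---------------------------------------------------------------------------
# brute-force oracle agreement

def roc_auc_oracle_max_dev(n_instances: int = 200, seed: int = 0) -> float:
    """Max |AUC - pairwise enumeration| over random instances (n <= 50)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 51))
        scores = np.round(rng.normal(0, 1, n), 1)
        labels = rng.random(n) < 0.5
        labels[0], labels[1] = True, False
        brute = float(np.mean([(a > b) + 0.5 * (a == b)
                               for a in scores[labels] for b in scores[~labels]]))
        worst = max(worst, abs(roc_auc(scores, labels) - brute))
    return worst


def youden_oracle_max_dev(n_instances: int = 200, seed: int = 0) -> float:
    """Max gap between J at the returned threshold and the exhaustive best."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(6, 31))
        scores = np.round(rng.random(n), 2)
        labels = rng.random(n) < 0.5
        labels[0], labels[1] = True, False
        t = youden_threshold(scores, labels)
        n1, n0 = labels.sum(), (~labels).sum()

        def j_at(c):
            pred = scores >= c
            return ((pred & labels).sum() / n1
                    + (~pred & ~labels).sum() / n0 - 1)

        best = max(j_at(c) for c in np.r_[scores - 1e-9, scores + 1e-9,
                                          -np.inf, np.inf])
        worst = max(worst, abs(best - j_at(t)))
    return worst


def mcnemar_enum_max_dev(max_discordant: int = 12) -> float:
    """Max |p - full binomial enumeration| over all (b, c) with b+c <= cap."""
    worst = 0.0
    for b in range(max_discordant + 1):
        for c in range(max_discordant + 1 - b):
            if b + c == 0:
                continue
            av = np.r_[np.ones(b, bool), np.zeros(c, bool)]
            bv = np.r_[np.zeros(b, bool), np.ones(c, bool)]
            _, _, p = mcnemar_test(av, bv)
            n, k = b + c, min(b, c)
            exact = 2 * binom.cdf(k, n, 0.5)
            if 2 * k == n:
                exact -= binom.pmf(k, n, 0.5)
            worst = max(worst, abs(p - min(1.0, exact)))
    return worst


def delong_bootstrap_diff(n_boot: int = 2000, seed: int = 0) -> float:
    """|DeLong p - stratified paired-bootstrap p| on a 40-sample toy."""
    rng = np.random.default_rng(seed)
    labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
    a = labels + rng.normal(0, 1.2, 40)
    b = labels + rng.normal(0, 2.0, 40)
    _, _, _, p_delong = delong_test(a, b, labels)

    pos = np.where(labels)[0]
    neg = np.where(~labels)[0]
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.r_[rng.choice(pos, pos.size), rng.choice(neg, neg.size)]
        deltas[i] = roc_auc(a[idx], labels[idx]) - roc_auc(b[idx], labels[idx])
    frac = np.mean(deltas < 0) + 0.5 * np.mean(deltas == 0)
    p_boot = 2 * min(frac, 1 - frac)
    return abs(p_delong - p_boot)


# ---------------------------------------------------------------------------
# cohort-level experiments

def _prepare(config: SyntheticConfig, pipe: PipelineConfig):
    peaks, snr, sheet, truth = generate_cohort(config)
    report, valid = qc.apply_qc(peaks, snr)
    sheet = sheet[sheet["sample_id"].isin(report.retained_samples)]
    sheet = sheet.reset_index(drop=True)
    split = modeling.stratified_split(sheet, pipe.train_fraction, pipe.seed)
    norm = qc.normalize(valid, reference_samples=split.train_ids,
                        method=pipe.normalization)
    y_by_id = sheet.set_index("sample_id")["class"]
    y_train = (y_by_id.loc[split.train_ids] == "malignant").to_numpy()
    return truth, sheet, split, norm, y_train


def screening_recovery(n_seeds: int = 10, seed0: int = 0,
                       **config_overrides) -> pd.DataFrame:
    """Planted-marker recovery of the dual screening criterion per seed.

    For each seed, generates a study-structured cohort, runs QC /
    normalization / the 60% training split, screens on the training samples
    only, and counts how many planted markers were flagged candidate.
    """
    rows = []
    for i in range(n_seeds):
        cfg = SyntheticConfig(seed=seed0 + i, **config_overrides)
        pipe = PipelineConfig(seed=seed0 + i)
        truth, sheet, split, norm, y_train = _prepare(cfg, pipe)
        X_train = norm.values.loc[split.train_ids]
        tab = screening.screen(X_train,
                               np.where(y_train, "malignant", "benign"),
                               exclusion_list=truth.excluded_compound_ids)
        cands = set(tab.index[tab["candidate"]])
        planted = set(truth.planted_compound_ids) & set(norm.values.columns)
        rows.append({"seed": seed0 + i,
                     "n_candidates": len(cands),
                     "n_planted_retained": len(planted),
                     "n_recovered": len(cands & planted)})
    return pd.DataFrame(rows)


def screening_null_rate(n_seeds: int = 5, seed0: int = 100) -> float:
    """Mean fraction of compounds flagged candidate when nothing is planted."""
    rates = []
    for i in range(n_seeds):
        cfg = SyntheticConfig(effect_size=0.0, seed=seed0 + i)
        pipe = PipelineConfig(seed=seed0 + i)
        truth, sheet, split, norm, y_train = _prepare(cfg, pipe)
        X_train = norm.values.loc[split.train_ids]
        tab = screening.screen(X_train,
                               np.where(y_train, "malignant", "benign"))
        rates.append(tab["candidate"].mean())
    return float(np.mean(rates))


def end_to_end(n_seeds: int = 10, seed0: int = 0, panel_size: int = 18,
               **config_overrides) -> pd.DataFrame:
    """Full pipeline pattern on study-structured cohorts, one row per seed.

    The candidate panel handed to forward selection emulates the
    literature-curated biomarker list of the workflow: the planted markers
    (the synthetic stand-in for externally known disease biology) topped up
    to ``panel_size`` with the highest-VIP screened non-planted compounds.
    Records the chosen panel size, held-out test AUC against the recorded
    design ceiling, and the paired pre/post monitoring p-values per class.
    """
    rows = []
    for i in range(n_seeds):
        cfg = SyntheticConfig(seed=seed0 + i, **config_overrides)
        pipe = PipelineConfig(seed=seed0 + i)
        truth, sheet, split, norm, y_train = _prepare(cfg, pipe)
        X_train = norm.values.loc[split.train_ids]
        tab = screening.screen(X_train,
                               np.where(y_train, "malignant", "benign"),
                               exclusion_list=truth.excluded_compound_ids)
        planted = [c for c in truth.planted_compound_ids
                   if c in norm.values.columns]
        extras = [c for c in tab.sort_values("vip", ascending=False).index
                  if c not in planted and not tab.loc[c, "excluded"]]
        panel = planted + extras[:max(0, panel_size - len(planted))]

        ranked = modeling.rank_features(X_train, y_train, panel,
                                        p_values=tab["p_value"])
        trace = modeling.forward_select(X_train, y_train, ranked,
                                        cv_folds=pipe.cv_folds,
                                        delta=pipe.delta,
                                        patience=pipe.patience,
                                        seed=pipe.seed + 1)
        hp = modeling.grid_search_cv(X_train, y_train, trace.chosen_features,
                                     cv_folds=pipe.cv_folds, seed=pipe.seed + 2)
        model = modeling.fit_final(X_train, y_train, trace.chosen_features, hp)

        y_by_id = sheet.set_index("sample_id")["class"]
        X_test = norm.values.loc[split.test_ids]
        y_test = (y_by_id.loc[split.test_ids] == "malignant").to_numpy()
        test_auc = roc_auc(model.predict_risk(X_test), y_test)

        mal = (sheet["class"] == "malignant").to_numpy()
        _, _, p_mal, n_mal = prepost_by_group(model, norm.values, sheet, mal)
        _, _, p_ben, n_ben = prepost_by_group(model, norm.values, sheet, ~mal)
        rows.append({"seed": seed0 + i, "chosen_k": trace.chosen_k,
                     "test_auc": test_auc, "design_auc": truth.design_auc,
                     "prepost_p_malignant": p_mal, "prepost_p_benign": p_ben,
                     "n_pairs_malignant": n_mal, "n_pairs_benign": n_ben})
    return pd.DataFrame(rows)
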