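"""Split arithmetic, ranking, forward selection, tuning, Youden threshold."""

import numpy as np
import pandas as pd
import pytest

from breathdx import (fit_final, forward_select, grid_search_cv, rank_features,
                      roc_auc, stratified_split, youden_threshold)
from breathdx.modeling import DEFAULT_HYPERPARAMS


def _sheet(n_mal, n_ben, timepoint="preop"):
    n = n_mal + n_ben
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "class": ["malignant"] * n_mal + ["benign"] * n_ben,
        "subtype": ["LC"] * n_mal + ["benign_nodule"] * n_ben,
        "stage": ["I"] * n_mal + ["unknown"] * n_ben,
        "timepoint": [timepoint] * n,
        "pair_id": [""] * n,
        "ca125": [np.nan] * n, "progrp": [np.nan] * n,
        "cea": [np.nan] * n, "cyfra211": [np.nan] * n,
    })


class TestStratifiedSplit:
    def test_study_arithmetic(self):
        """132 pre-op samples at 60% give a 79-sample discovery set."""
        split = stratified_split(_sheet(97, 35), 0.6, seed=0)
        assert len(split.train_ids) == 79
        assert len(split.test_ids) == 53

    def test_exact_stratification(self):
        split = stratified_split(_sheet(5, 5), 0.6, seed=1)
        labels = dict(zip(_sheet(5, 5)["sample_id"], _sheet(5, 5)["class"]))
        train_mal = sum(labels[s] == "malignant" for s in split.train_ids)
        assert len(split.train_ids) == 6 and train_mal == 3

    def test_partition_disjoint_exhaustive(self):
        sheet = _sheet(30, 12)
        split = stratified_split(sheet, 0.6, seed=5)
        assert not set(split.train_ids) & set(split.test_ids)
        assert set(split.train_ids) | set(split.test_ids) == set(sheet["sample_id"])

    def test_deterministic_under_seed(self):
        a = stratified_split(_sheet(40, 15), 0.6, seed=9)
        b = stratified_split(_sheet(40, 15), 0.6, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_postop_ineligible(self):
        sheet = pd.concat([_sheet(10, 10), _sheet(4, 4, "postop")],
                          ignore_index=True)
        sheet["sample_id"] = [f"s{i}" for i in range(len(sheet))]
        split = stratified_split(sheet, 0.6, seed=0)
        post = set(sheet.loc[sheet["timepoint"] == "postop", "sample_id"])
        assert not post & (set(split.train_ids) | set(split.test_ids))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_sheet(10, 1), 0.6, seed=0)


class TestRankFeatures:
    def test_perfect_separator_first(self, rng):
        y = np.repeat([True, False], 10)
        X = pd.DataFrame(rng.normal(0, 1, (20, 5)),
                         columns=list("abcde"))
        X["e"] = np.where(y, 1.0, -1.0)
        assert rank_features(X, y, list("abcde"))[0] == "e"

    def test_tie_break_by_p_then_id(self):
        y = np.array([True, True, False, False])
        X = pd.DataFrame({"b": [4.0, 3, 2, 1], "a": [4.0, 3, 2, 1],
                          "c": [4.0, 3, 2, 1]})
        p = pd.Series({"a": 0.5, "b": 0.1, "c": 0.5})
        assert rank_features(X, y, ["a", "b", "c"], p) == ["b", "a", "c"]

    def test_matches_pairwise_oracle(self, rng):
        y = rng.random(12) < 0.5
        y[:2], y[-2:] = True, False
        X = pd.DataFrame(rng.normal(0, 1, (12, 6)),
                         columns=[f"f{j}" for j in range(6)])
        ranked = rank_features(X, y, X.columns)
        def brute(col):
            pos, neg = col[y], col[~y]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            a = wins / (len(pos) * len(neg))
            return max(a, 1 - a)
        scores = [brute(X[c].to_numpy()) for c in ranked]
        assert scores == sorted(scores, reverse=True)


class TestForwardSelect:
    def test_single_informative_feature_found(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.repeat([True, False], [30, 30])
            X = pd.DataFrame(rng.normal(0, 1, (60, 51)),
                             columns=[f"f{j}" for j in range(51)])
            X["f0"] = np.where(y, 2.5, 0.0) + rng.normal(0, 1, 60)
            ranked = rank_features(X, y, X.columns)
            trace = forward_select(X, y, ranked, seed=seed, cv_repeats=3)
            if trace.chosen_k <= 3 and "f0" in trace.chosen_features:
                hits += 1
        assert hits >= 8

    def test_trace_has_no_gaps_and_argmax_contract(self, rng):
        y = np.repeat([True, False], [20, 20])
        X = pd.DataFrame(rng.normal(0, 1, (40, 8)),
                         columns=[f"f{j}" for j in range(8)])
        X["f0"] += np.where(y, 1.5, 0.0)
        trace = forward_select(X, y, list(X.columns), seed=0, cv_repeats=2)
        assert len(trace.cv_auc) >= trace.chosen_k
        assert trace.chosen_k == int(np.argmax(trace.cv_auc)) + 1

    def test_fold_reduction_warns(self):
        rng = np.random.default_rng(0)
        y = np.repeat([True, False], [12, 3])
        X = pd.DataFrame(rng.normal(0, 1, (15, 3)), columns=list("abc"))
        with pytest.warns(UserWarning):
            trace = forward_select(X, y, list("abc"), cv_folds=5, seed=0,
                                   cv_repeats=1)
        assert trace.folds == 3


class TestGridSearch:
    def _toy(self, seed=0, sep=False):
        rng = np.random.default_rng(seed)
        y = np.repeat([True, False], [25, 25])
        X = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("abc"))
        X["a"] += np.where(y, 8.0 if sep else 1.0, 0.0)
        return X, y

    def test_singleton_grid_returned(self):
        X, y = self._toy()
        hp = grid_search_cv(X, y, list("abc"), grid=[DEFAULT_HYPERPARAMS])
        assert hp == DEFAULT_HYPERPARAMS

    def test_separable_tie_breaks_to_first(self):
        X, y = self._toy(sep=True)
        grid = [{"penalty": "l2", "C": c, "class_weight": None,
                 "max_iter": 1000} for c in (10.0, 1.0)]
        assert grid_search_cv(X, y, list("abc"), grid=grid)["C"] == 10.0

    def test_matches_exhaustive_reevaluation(self):
        from breathdx.modeling import _cv_auc
        X, y = self._toy(seed=4)
        grid = [{"penalty": p, "C": c, "class_weight": None, "max_iter": 1000}
                for p in ("l1", "l2") for c in (0.1, 1.0)]
        best = grid_search_cv(X, y, list("abc"), grid=grid, seed=3)
        scores = [_cv_auc(X[list("abc")].to_numpy(), y.astype(int), hp, 5, 3)
                  for hp in grid]
        assert best == grid[int(np.argmax(scores))]


class TestFitFinal:
    def test_separable_single_feature(self):
        y = np.repeat([True, False], [10, 10])
        X = pd.DataFrame({"a": np.where(y, 5.0, -5.0)})
        model = fit_final(X, y, ["a"])
        risk = model.predict_risk(X)
        assert roc_auc(risk, y) == 1.0
        assert (risk[y] > risk[~y].max()).all()

    def test_matches_irls_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (40, 3))
        beta = np.array([1.0, -0.5, 0.2])
        y = rng.random(40) < 1 / (1 + np.exp(-(X @ beta + 0.3)))
        df = pd.DataFrame(X, columns=list("abc"))
        model = fit_final(df, y, list("abc"),
                          {"penalty": "l2", "C": 1.0, "class_weight": None,
                           "max_iter": 1000})
        # Newton/IRLS on the penalized log-likelihood, intercept unpenalized
        Xd = np.c_[X, np.ones(40)]
        w = np.zeros(4)
        lam = np.array([1.0, 1.0, 1.0, 0.0])
        for _ in range(100):
            mu = 1 / (1 + np.exp(-(Xd @ w)))
            g = Xd.T @ (y - mu) - lam * w
            H = (Xd * (mu * (1 - mu))[:, None]).T @ Xd + np.diag(lam)
            step = np.linalg.solve(H, g)
            w += step
            if np.max(np.abs(step)) < 1e-13:
                break
        np.testing.assert_allclose(np.r_[model.coef, model.intercept], w,
                                   atol=1e-6)

    def test_label_flip_negates_coefficients(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(0, 1, (30, 2)), columns=list("ab"))
        y = rng.random(30) < 0.5
        y[:3], y[-3:] = True, False
        a = fit_final(X, y, list("ab"))
        b = fit_final(X, ~y, list("ab"))
        np.testing.assert_allclose(a.coef, -np.asarray(b.coef), atol=1e-6)
        assert a.intercept == pytest.approx(-b.intercept, abs=1e-6)

    def test_json_round_trip(self, tmp_path):
        y = np.repeat([True, False], [10, 10])
        X = pd.DataFrame({"a": np.where(y, 2.0, 0.0), "b": np.zeros(20)})
        model = fit_final(X, y, ["a", "b"])
        model.to_json(tmp_path / "m.json")
        back = type(model).from_json(tmp_path / "m.json")
        assert back == model


class TestYouden:
    def test_separable_midpoint(self):
        t = youden_threshold([0.8, 0.7, 0.5, 0.2], [1, 1, 0, 0])
        assert t == pytest.approx(0.6)

    def test_degenerate_all_equal_warns(self):
        with pytest.warns(UserWarning):
            t = youden_threshold([0.5, 0.5, 0.5], [1, 0, 1])
        assert not np.isfinite(t)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.random(n), 2)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            t = youden_threshold(scores, labels)
            n1, n0 = labels.sum(), (~labels).sum()
            def j_at(c):
                pred = scores >= c
                return ((pred & labels).sum() / n1
                        + (~pred & ~labels).sum() / n0 - 1)
            best = max(j_at(c) for c in np.r_[scores - 1e-9, scores + 1e-9,
                                              -np.inf, np.inf])
            assert j_at(t) == pytest.approx(best, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.2], [1, 1])
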