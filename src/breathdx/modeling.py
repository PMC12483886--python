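"""Model development: split, feature ranking/selection, tuning, thresholding.

The training path mirrors a standard small-cohort biomarker workflow:

* stratified 60/40 discovery/testing split (largest-remainder per-class
  allocation so ``|train| = floor(0.6 n)`` exactly);
* candidate features ranked by univariate training ROC-AUC (direction
  symmetric: ``max(a, 1-a)``);
* progressive forward selection under 5-fold stratified cross-validation,
  adding one feature at a time and stopping once mean out-of-fold AUC stops
  improving;
* exhaustive grid search over logistic-regression hyperparameters
  (penalty, strength, class weights, iteration cap) by mean stratified-CV
  AUC;
* final regularized logistic fit with a Youden-index decision threshold
  taken from the training predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .eval_stats import roc_auc

__all__ = ["SplitSpec", "SelectionTrace", "FittedClassifier", "DEFAULT_GRID",
           "SELECTION_HYPERPARAMS",
           "stratified_split", "rank_features", "forward_select",
           "grid_search_cv", "fit_final", "youden_threshold"]

#: Default hyperparameter grid: penalty, inverse regularization strength C,
#: class weights, and iteration cap, searched in this order.
DEFAULT_GRID = [
    {"penalty": pen, "C": c, "class_weight": cw, "max_iter": mi}
    for pen in ("l1", "l2")
    for c in (0.01, 0.1, 1.0, 10.0)
    for cw in (None, "balanced")
    for mi in (100, 1000)
]

DEFAULT_HYPERPARAMS = {"penalty": "l2", "C": 1.0, "class_weight": None,
                       "max_iter": 1000}

#: Hyperparameters used while *scoring* candidate feature subsets during
#: forward selection (before the grid search tunes the final model).  A
#: moderately strong ridge keeps fold fits stable when the subset size
#: approaches the per-fold sample count.
SELECTION_HYPERPARAMS = {"penalty": "l2", "C": 0.1, "class_weight": None,
                         "max_iter": 1000}


def _make_lr(hp: dict) -> LogisticRegression:
    # penalty expressed via l1_ratio (0 = ridge, 1 = lasso) for sklearn >= 1.8;
    # lbfgs for ridge (intercept unpenalized), liblinear for lasso
    if hp["penalty"] == "l1":
        return LogisticRegression(solver="liblinear", l1_ratio=1.0, C=hp["C"],
                                  class_weight=hp["class_weight"],
                                  max_iter=hp["max_iter"], random_state=0)
    return LogisticRegression(solver="lbfgs", l1_ratio=0.0, C=hp["C"],
                              class_weight=hp["class_weight"],
                              max_iter=hp["max_iter"], tol=1e-8)


def _fit_quiet(clf: LogisticRegression, X, y) -> LogisticRegression:
    # the iteration cap is a searched hyperparameter; hitting it is an
    # admissible model, not a user error
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        return clf.fit(X, y)


@dataclass
class SplitSpec:
    train_fraction: float
    seed: int
    train_ids: list[str]
    test_ids: list[str]


def stratified_split(sheet: pd.DataFrame, train_fraction: float = 0.6,
                     seed: int = 0) -> SplitSpec:
    """Class-stratified random split of the pre-operative samples.

    Only ``timepoint == "preop"`` samples are eligible (post-operative
    samples are reserved for monitoring).  The overall training size is
    ``floor(train_fraction * n)``; per-class allocations are rounded by
    largest remainder so the total is hit exactly while class proportions
    stay within one sample of the stratified ideal.
    """
    pre = sheet[sheet["timepoint"] == "preop"]
    n = len(pre)
    counts = pre["class"].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need at least two pre-op samples per class")
    n_train = int(np.floor(train_fraction * n))

    quotas = {c: train_fraction * k for c, k in counts.items()}
    alloc = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = n_train - sum(alloc.values())
    # distribute the shortfall by largest fractional remainder (ties by class name)
    order = sorted(quotas, key=lambda c: (-(quotas[c] - alloc[c]), c))
    for c in order[:short]:
        alloc[c] += 1

    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for c in sorted(counts.index):
        ids = pre.loc[pre["class"] == c, "sample_id"].to_numpy()
        perm = rng.permutation(len(ids))
        train_ids += list(ids[perm[: alloc[c]]])
        test_ids += list(ids[perm[alloc[c]:]])
    return SplitSpec(train_fraction=train_fraction, seed=seed,
                     train_ids=train_ids, test_ids=test_ids)


def rank_features(X_train: pd.DataFrame, y_train, candidates,
                  p_values: pd.Series | None = None) -> list[str]:
    """Order candidate features by descending univariate training AUC.

    AUC direction is folded (``max(a, 1-a)``); ties break by smaller
    rank-sum p-value (when provided), then by feature id.
    """
    y = np.asarray(y_train, dtype=bool)
    keyed = []
    for cid in candidates:
        a = roc_auc(X_train[cid].to_numpy(dtype=float), y)
        a = max(a, 1 - a)
        pv = float(p_values[cid]) if p_values is not None else 1.0
        keyed.append((-a, pv, str(cid), cid))
    return [k[3] for k in sorted(keyed)]


@dataclass
class SelectionTrace:
    """Mean cross-validated AUC after each feature addition."""

    ranked: list[str]
    cv_auc: list[float]          # one entry per step actually evaluated
    chosen_k: int
    delta: float
    patience: int
    folds: int
    seed: int
    warnings: list[str] = field(default_factory=list)

    @property
    def chosen_features(self) -> list[str]:
        return self.ranked[: self.chosen_k]


def _cv_auc(X: np.ndarray, y: np.ndarray, hp: dict, folds: int, seed: int,
            repeats: int = 1) -> float:
    """Mean out-of-fold AUC of a logistic model under repeated stratified CV."""
    aucs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(X, y):
            clf = _make_lr(hp)
            _fit_quiet(clf, X[tr], y[tr])
            s = clf.predict_proba(X[te])[:, 1]
            aucs.append(roc_auc(s, y[te]))
    return float(np.mean(aucs))


def forward_select(X_train: pd.DataFrame, y_train, ranked: list[str],
                   cv_folds: int = 5, delta: float = 0.005, patience: int = 2,
                   seed: int = 0, cv_repeats: int = 10,
                   hyperparams: dict | None = None) -> SelectionTrace:
    """Progressive forward selection along a ranked feature list.

    At step k the logistic model is trained on the top-k features within
    each stratified CV fold and the mean out-of-fold AUC recorded;
    ``cv_repeats`` re-randomized fold assignments are averaged so the trace
    is not dominated by fold noise at these sample sizes.  The walk stops
    after ``patience`` consecutive steps whose improvement over the running
    best is <= ``delta``; the chosen size is the argmax of the recorded
    trace (smallest k on ties).
    """
    if not ranked:
        raise ValueError("ranked feature list is empty")
    y = np.asarray(y_train, dtype=bool).astype(int)
    hp = dict(SELECTION_HYPERPARAMS if hyperparams is None else hyperparams)
    msgs: list[str] = []
    min_stratum = int(min(np.bincount(y)))
    folds = cv_folds
    if min_stratum < folds:
        folds = max(2, min_stratum)
        msgs.append(f"reduced CV folds from {cv_folds} to {folds}")
        warnings.warn(msgs[-1], stacklevel=2)

    trace: list[float] = []
    best = -np.inf
    stall = 0
    for k in range(1, len(ranked) + 1):
        Xk = X_train[ranked[:k]].to_numpy(dtype=float)
        score = _cv_auc(Xk, y, hp, folds, seed, repeats=cv_repeats)
        trace.append(score)
        if score > best + delta:
            best = max(best, score)
            stall = 0
        else:
            best = max(best, score)
            stall += 1
            if stall >= patience:
                break

    chosen_k = int(np.argmax(trace)) + 1
    return SelectionTrace(ranked=ranked, cv_auc=trace, chosen_k=chosen_k,
                          delta=delta, patience=patience, folds=folds,
                          seed=seed, warnings=msgs)


def grid_search_cv(X_train: pd.DataFrame, y_train, features: list[str],
                   grid: list[dict] | None = None, cv_folds: int = 5,
                   seed: int = 0) -> dict:
    """Exhaustive grid search by mean stratified-CV AUC.

    Every cell uses the same seeded fold assignment; ties break toward the
    earlier grid entry.
    """
    grid = DEFAULT_GRID if grid is None else grid
    if not grid:
        raise ValueError("empty hyperparameter grid")
    y = np.asarray(y_train, dtype=bool).astype(int)
    X = X_train[list(features)].to_numpy(dtype=float)
    folds = min(cv_folds, int(min(np.bincount(y))))
    best_hp, best_score = None, -np.inf
    for hp in grid:
        score = _cv_auc(X, y, hp, folds, seed)
        if score > best_score:
            best_hp, best_score = hp, score
    return dict(best_hp)


@dataclass
class FittedClassifier:
    """Regularized logistic model plus its Youden decision threshold.

    Prediction is the inverse logit of the linear score over the stored
    feature columns; ``score >= threshold`` calls a sample malignant.
    """

    features: list[str]
    coef: list[float]
    intercept: float
    hyperparams: dict
    threshold: float

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        z = X[self.features].to_numpy(dtype=float) @ np.asarray(self.coef) \
            + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict_label(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_risk(X) >= self.threshold

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedClassifier":
        return cls(**json.loads(Path(path).read_text()))


def youden_threshold(scores, labels) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct sorted scores
    plus -inf/+inf sentinels; the rule is ``score >= threshold`` = positive.
    Ties break toward higher specificity, then the lower threshold.  If
    every score is equal, J = 0 everywhere and the +inf sentinel is
    returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    if pos.all() or not pos.any():
        raise ValueError("both labels must be present")
    distinct = np.unique(scores)
    cands = [-np.inf, np.inf]
    cands += list((distinct[:-1] + distinct[1:]) / 2)
    n1, n0 = pos.sum(), (~pos).sum()

    best = None
    for t in cands:
        pred = scores >= t
        sens = (pred & pos).sum() / n1
        spec = (~pred & ~pos).sum() / n0
        key = (sens + spec - 1, spec, -t)
        if best is None or key > best[0]:
            best = (key, t)
    if distinct.size == 1:
        warnings.warn("all scores equal; Youden threshold degenerate",
                      stacklevel=2)
    return float(best[1])


def fit_final(X_train: pd.DataFrame, y_train, features: list[str],
              hyperparams: dict | None = None) -> FittedClassifier:
    """Fit the final logistic model and attach its training Youden threshold."""
    hp = dict(DEFAULT_HYPERPARAMS if hyperparams is None else hyperparams)
    y = np.asarray(y_train, dtype=bool).astype(int)
    X = X_train[list(features)].to_numpy(dtype=float)
    clf = _make_lr(hp)
    _fit_quiet(clf, X, y)
    model = FittedClassifier(features=list(features),
                             coef=[float(c) for c in clf.coef_[0]],
                             intercept=float(clf.intercept_[0]),
                             hyperparams=hp, threshold=0.5)
    risk = model.predict_risk(X_train)
    model.threshold = youden_threshold(risk, y.astype(bool))
    return model
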