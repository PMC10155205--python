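"""Cross-validated ensemble models for HIA classification and regression.

The AutoML-style setup is emulated with a fixed, transparent roster of
scikit-learn base learners evaluated by 10-fold out-of-fold (OOF)
prediction, followed by greedy forward selection with replacement on the
OOF predictions (log loss for classification, RMSE for regression) to build
a weighted committee. Every source of randomness fans out from one master
seed, so runs are exactly reproducible.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .metrics import log_loss, rmse

MAX_GREEDY_ROUNDS = 25


@contextmanager
def _quiet_fit():
    """MLP members may hit their iteration cap on small folds; that is an
    accepted part of the fixed-budget roster, not a run failure."""
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@dataclass(frozen=True)
class CrossValConfig:
    """K-fold setup; stratification keeps class balance per fold."""

    k: int = 10
    seed: int = 0
    stratified: bool = True

    def validate(self, n_samples: int):
        if not (2 <= self.k <= n_samples):
            raise ValueError(
                f"folds must satisfy 2 <= k <= n_samples, got k={self.k}, "
                f"n={n_samples}"
            )


@dataclass
class OutOfFoldPredictions:
    """Per-sample held-out predictions plus the fold map that produced them."""

    values: np.ndarray  # probability of class 1, or predicted HIA percent
    fold_id: np.ndarray
    train_index_sets: list[np.ndarray]  # per fold, the indices trained on


@dataclass
class EnsembleModel:
    """Weighted committee of fitted base learners for one task."""

    task: str  # "classification" | "regression"
    member_names: list[str]
    members: list  # fitted estimators, aligned with member_names
    weights: np.ndarray  # non-negative, sum to 1

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if len(self.members) == 0:
            raise ValueError("ensemble needs at least one member")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        self.weights = w


def _seed_for(master_seed: int, *tags: str) -> int:
    """Stable derived seed below 2^31 for a named random stream."""
    h = np.uint64(master_seed)
    for tag in tags:
        for ch in tag:
            h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**63 - 1))
    return int(h % (2**31 - 1))


def classifier_roster(seed: int) -> dict[str, object]:
    """Default candidate classifiers, spanning the usual tabular-QSPR families."""
    s = lambda tag: _seed_for(seed, "clf", tag)
    return {
        "baseline": DummyClassifier(strategy="prior"),
        "logistic": make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0, max_iter=5000, random_state=s("lr")),
        ),
        "random_forest": RandomForestClassifier(
            n_estimators=300, random_state=s("rf"), n_jobs=1
        ),
        "extra_trees": ExtraTreesClassifier(
            n_estimators=300, random_state=s("et"), n_jobs=1
        ),
        "gradient_boosting": HistGradientBoostingClassifier(
            max_iter=150, random_state=s("gb")
        ),
        "mlp": make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(64,), max_iter=600, random_state=s("mlp")
            ),
        ),
    }


def regressor_roster(seed: int) -> dict[str, object]:
    s = lambda tag: _seed_for(seed, "reg", tag)
    return {
        "baseline": DummyRegressor(strategy="mean"),
        "ridge": make_pipeline(StandardScaler(), Ridge(alpha=1.0)),
        "random_forest": RandomForestRegressor(
            n_estimators=300, random_state=s("rf"), n_jobs=1
        ),
        "extra_trees": ExtraTreesRegressor(
            n_estimators=300, random_state=s("et"), n_jobs=1
        ),
        "gradient_boosting": HistGradientBoostingRegressor(
            max_iter=150, random_state=s("gb")
        ),
        "mlp": make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=(64,), max_iter=800, random_state=s("mlp")
            ),
        ),
    }


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _fold_iter(y: np.ndarray, cv: CrossValConfig, task: str):
    if task == "classification" and cv.stratified:
        counts = np.bincount(y.astype(int))
        if counts.min() < cv.k:
            raise ValueError(
                f"stratified {cv.k}-fold CV impossible: rarest class has "
                f"{counts.min()} samples; use fewer folds"
            )
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
        return splitter.split(np.zeros_like(y), y)
    splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    return splitter.split(np.zeros_like(y))


def cross_val_predict(
    learner, X, y, cv: CrossValConfig, task: str
) -> OutOfFoldPredictions:
    """Out-of-fold predictions: each sample scored by the model whose
    training folds exclude it. Regression outputs are clipped to [0, 100]."""
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=float)
    cv.validate(len(ya))
    values = np.full(len(ya), np.nan)
    fold_id = np.full(len(ya), -1, dtype=int)
    train_sets: list[np.ndarray] = []
    for f, (train_idx, test_idx) in enumerate(_fold_iter(ya, cv, task)):
        est = clone(learner)
        with _quiet_fit():
            est.fit(Xa[train_idx], ya[train_idx])
        if task == "classification":
            proba = est.predict_proba(Xa[test_idx])
            classes = list(est.classes_)
            pos = proba[:, classes.index(1)] if 1 in classes else np.zeros(len(test_idx))
            values[test_idx] = pos
        else:
            values[test_idx] = np.clip(est.predict(Xa[test_idx]), 0.0, 100.0)
        fold_id[test_idx] = f
        train_sets.append(train_idx)
    assert not np.isnan(values).any()
    return OutOfFoldPredictions(values=values, fold_id=fold_id, train_index_sets=train_sets)


def greedy_ensemble_weights(
    oof_by_name: dict[str, np.ndarray],
    y: np.ndarray,
    criterion,
    max_rounds: int = MAX_GREEDY_ROUNDS,
) -> dict[str, float]:
    """Greedy forward selection with replacement minimising ``criterion``.

    Starts from the single best candidate and repeatedly adds (possibly
    re-adds) the candidate whose inclusion in the running average lowers the
    OOF criterion most, stopping when no addition improves it. Weights are
    selection counts normalised to 1; the result is never worse than the
    best single candidate.
    """
    names = sorted(oof_by_name)
    counts: dict[str, int] = {}
    current_sum = np.zeros_like(next(iter(oof_by_name.values())))
    current_score = np.inf
    total = 0
    for _ in range(max_rounds):
        best_name, best_score = None, current_score
        for name in names:
            cand = (current_sum + oof_by_name[name]) / (total + 1)
            score = criterion(y, cand)
            if score < best_score - 1e-12:
                best_name, best_score = name, score
        if best_name is None:
            break
        counts[best_name] = counts.get(best_name, 0) + 1
        current_sum += oof_by_name[best_name]
        total += 1
        current_score = best_score
    return {name: c / total for name, c in counts.items()}


def _train_ensemble(
    X, y, cv: CrossValConfig, candidates: dict[str, object], task: str, criterion
) -> tuple[EnsembleModel, OutOfFoldPredictions]:
    if not candidates:
        raise ValueError("empty candidate roster")
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=float)
    oof_by_name: dict[str, np.ndarray] = {}
    fold_info: OutOfFoldPredictions | None = None
    for name in sorted(candidates):
        oof = cross_val_predict(candidates[name], Xa, ya, cv, task)
        oof_by_name[name] = oof.values
        fold_info = oof  # identical fold map across candidates (same cv seed)
    weights = greedy_ensemble_weights(oof_by_name, ya, criterion)
    member_names = sorted(weights)
    members = []
    for name in member_names:
        est = clone(candidates[name])
        with _quiet_fit():
            est.fit(Xa, ya)
        members.append(est)
    w = np.array([weights[n] for n in member_names])
    blended = np.zeros_like(ya, dtype=float)
    for name, wt in zip(member_names, w):
        blended += wt * oof_by_name[name]
    model = EnsembleModel(task=task, member_names=member_names, members=members, weights=w)
    oof_out = OutOfFoldPredictions(
        values=blended,
        fold_id=fold_info.fold_id,
        train_index_sets=fold_info.train_index_sets,
    )
    return model, oof_out


def train_classifier_ensemble(
    X, y, cv: CrossValConfig, candidates: dict[str, object] | None = None
) -> tuple[EnsembleModel, OutOfFoldPredictions]:
    """Greedy OOF-log-loss ensemble over the classifier roster."""
    ya = np.asarray(y)
    if len(np.unique(ya)) < 2:
        raise ValueError("classification needs both classes present")
    if candidates is None:
        candidates = classifier_roster(cv.seed)
    return _train_ensemble(X, ya, cv, candidates, "classification", log_loss)


def train_regressor_ensemble(
    X, y, cv: CrossValConfig, candidates: dict[str, object] | None = None
) -> tuple[EnsembleModel, OutOfFoldPredictions]:
    """Greedy OOF-RMSE ensemble over the regressor roster; predictions in [0, 100]."""
    if candidates is None:
        candidates = regressor_roster(cv.seed)
    ya = np.asarray(y, dtype=float)
    if len(ya) < cv.k:
        raise ValueError("need at least k samples")
    return _train_ensemble(X, ya, cv, candidates, "regression", rmse)


def predict_proba(model: EnsembleModel, X) -> np.ndarray:
    """Weighted-average class-1 probability of the committee."""
    if model.task != "classification":
        raise ValueError("predict_proba requires a classification ensemble")
    Xa = _as_array(X)
    out = np.zeros(Xa.shape[0])
    for est, w in zip(model.members, model.weights):
        proba = est.predict_proba(Xa)
        classes = list(est.classes_)
        pos = proba[:, classes.index(1)] if 1 in classes else np.zeros(Xa.shape[0])
        out += w * pos
    return np.clip(out, 0.0, 1.0)


def predict_value(model: EnsembleModel, X) -> np.ndarray:
    """Weighted-average HIA prediction of the committee, clipped to [0, 100]."""
    if model.task != "regression":
        raise ValueError("predict_value requires a regression ensemble")
    Xa = _as_array(X)
    out = np.zeros(Xa.shape[0])
    for est, w in zip(model.members, model.weights):
        out += w * est.predict(Xa)
    return np.clip(out, 0.0, 100.0)
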