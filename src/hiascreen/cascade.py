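"""Two-stage screening cascade for highly permeable compounds.

Stage 1 applies the classification ensemble at a raised probability cutoff,
accepting only high-confidence positives. Stage 2 passes the remaining
molecules to the regression ensemble and accepts those with predicted HIA at
or above a raised cutoff (default 90%, above the 85% class boundary, to keep
stage-2 acceptances reliable). Everything else is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .modeling import EnsembleModel, predict_proba, predict_value

DEFAULT_REG_CUTOFF = 90.0


@dataclass(frozen=True)
class CascadeModel:
    classifier: EnsembleModel
    clf_cutoff: float
    regressor: EnsembleModel
    reg_cutoff: float = DEFAULT_REG_CUTOFF

    def __post_init__(self):
        if not (0.0 < self.clf_cutoff < 1.0):
            raise ValueError(f"clf_cutoff must lie in (0, 1), got {self.clf_cutoff}")
        if not (0.0 < self.reg_cutoff <= 100.0):
            raise ValueError(f"reg_cutoff must lie in (0, 100], got {self.reg_cutoff}")
        if self.classifier.task != "classification":
            raise ValueError("stage-1 model must be a classification ensemble")
        if self.regressor.task != "regression":
            raise ValueError("stage-2 model must be a regression ensemble")


def build_cascade(
    classifier: EnsembleModel,
    clf_cutoff: float,
    regressor: EnsembleModel,
    reg_cutoff: float = DEFAULT_REG_CUTOFF,
) -> CascadeModel:
    return CascadeModel(
        classifier=classifier,
        clf_cutoff=clf_cutoff,
        regressor=regressor,
        reg_cutoff=reg_cutoff,
    )


@dataclass(frozen=True)
class ScreeningDecision:
    """Per-molecule cascade outcome; exactly one stage applies."""

    molecule_id: str
    stage: str  # "classifier" | "regressor" | "rejected"
    probability: float
    predicted_hia: float | None  # absent if decided at stage 1
    selected: bool


@dataclass(frozen=True)
class ScreenReport:
    n_selected: int
    n_true_positive: int
    n_false_positive: int
    recovered_fraction: float


def screen(
    cascade: CascadeModel,
    X,
    ids: Sequence[str] | None = None,
    score_all: bool = False,
) -> list[ScreeningDecision]:
    """Run the cascade on preprocessed descriptors ``X`` (input order kept).

    Stage 1 selects molecules with class-1 probability >= ``clf_cutoff``;
    only the remainder is scored by the regressor (unless ``score_all`` is
    set for diagnostics), and selected when predicted HIA >= ``reg_cutoff``.
    """
    n = X.shape[0]
    if ids is None:
        ids = list(getattr(X, "index", range(n)))
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValueError("ids and X must be aligned")

    proba = predict_proba(cascade.classifier, X)
    stage1 = proba >= cascade.clf_cutoff

    hia = np.full(n, np.nan)
    need_reg = np.ones(n, dtype=bool) if score_all else ~stage1
    if need_reg.any():
        Xa = X[need_reg] if isinstance(X, np.ndarray) else X.loc[need_reg]
        hia[need_reg] = predict_value(cascade.regressor, Xa)

    decisions = []
    for i in range(n):
        if stage1[i]:
            decisions.append(
                ScreeningDecision(
                    molecule_id=ids[i],
                    stage="classifier",
                    probability=float(proba[i]),
                    predicted_hia=float(hia[i]) if score_all else None,
                    selected=True,
                )
            )
        elif hia[i] >= cascade.reg_cutoff:
            decisions.append(
                ScreeningDecision(
                    molecule_id=ids[i],
                    stage="regressor",
                    probability=float(proba[i]),
                    predicted_hia=float(hia[i]),
                    selected=True,
                )
            )
        else:
            decisions.append(
                ScreeningDecision(
                    molecule_id=ids[i],
                    stage="rejected",
                    probability=float(proba[i]),
                    predicted_hia=float(hia[i]),
                    selected=False,
                )
            )
    return decisions


def evaluate_screen(
    decisions: Sequence[ScreeningDecision], true_labels: Sequence[int]
) -> ScreenReport:
    """Selection quality against known permeability classes.

    ``recovered_fraction`` is the share of all truly highly permeable
    molecules that the cascade selected.
    """
    if len(decisions) != len(true_labels):
        raise ValueError("every decision needs a true label")
    y = np.asarray(true_labels, dtype=int)
    sel = np.array([d.selected for d in decisions], dtype=bool)
    n_tp = int((sel & (y == 1)).sum())
    n_fp = int((sel & (y == 0)).sum())
    total_pos = int((y == 1).sum())
    recovered = n_tp / total_pos if total_pos > 0 else 0.0
    return ScreenReport(
        n_selected=int(sel.sum()),
        n_true_positive=n_tp,
        n_false_positive=n_fp,
        recovered_fraction=recovered,
    )
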