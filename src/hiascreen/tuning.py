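"""Decision-threshold tuning for a high-precision classifier.

Sweeps the class-1 probability cutoff over a grid, recording precision,
true/false positive counts and the true-positive rate per threshold, and
selects an operating point. The default selection rule returns the smallest
threshold leaving at most ``fp_max`` false positives — the reading of the
"highest precision, fewest false positives, minimum threshold" criterion
that is well-defined when perfect-precision rows exist at higher cutoffs.
The literal maximum-precision reading is available as an alternative rule.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

#: grid used for the packaged reference sweep: the model's default operating
#: point followed by 0.525 .. 0.900 in steps of 0.025
DEFAULT_GRID = (0.5082,) + tuple(np.round(np.arange(0.525, 0.9001, 0.025), 4))

#: pipeline grid: the reference grid extended to 0.975 so tuning still finds
#: a low-false-positive row when the classifier separates classes sharply
PIPELINE_GRID = DEFAULT_GRID + (0.925, 0.95, 0.975)

RULE_MIN_THRESHOLD_FP_MAX = "min_threshold_fp_max"
RULE_MAX_PRECISION = "max_precision_then_min_threshold"


@dataclass(frozen=True)
class SweepRow:
    threshold: float
    precision: float  # NaN when no positives are predicted
    tp: int
    fp: int
    tpr: float


@dataclass(frozen=True)
class SweepTable:
    rows: tuple[SweepRow, ...]
    n_positives: int
    n_negatives: int

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


@dataclass(frozen=True)
class CutoffSelection:
    threshold: float
    rule_id: str
    satisfied_conditions: str


def apply_cutoff(probabilities, threshold: float) -> np.ndarray:
    """Class 1 iff p >= threshold (ties resolve to the positive class)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)


def sweep(oof_probabilities, labels, thresholds: Sequence[float] = DEFAULT_GRID) -> SweepTable:
    """One row per threshold, ordered ascending; rule p >= t -> class 1."""
    thresholds = sorted(thresholds)
    if not thresholds:
        raise ValueError("empty threshold grid")
    p = np.asarray(oof_probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must be aligned")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    rows = []
    for t in thresholds:
        pred = apply_cutoff(p, t)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        prec = tp / (tp + fp) if tp + fp > 0 else math.nan
        tpr = tp / n_pos if n_pos > 0 else math.nan
        rows.append(SweepRow(threshold=float(t), precision=prec, tp=tp, fp=fp, tpr=tpr))
    return SweepTable(rows=tuple(rows), n_positives=n_pos, n_negatives=n_neg)


def select_cutoff(
    table: SweepTable,
    rule: str = RULE_MIN_THRESHOLD_FP_MAX,
    fp_max: int = 1,
) -> CutoffSelection:
    """Choose the operating threshold from a sweep table.

    ``min_threshold_fp_max`` (default): smallest threshold whose false-positive
    count is at most ``fp_max``. ``max_precision_then_min_threshold``: among
    rows of maximal precision, the smallest threshold.
    """
    if len(table) == 0:
        raise ValueError("empty sweep table")
    rows = sorted(table.rows, key=lambda r: r.threshold)
    if rule == RULE_MIN_THRESHOLD_FP_MAX:
        for row in rows:
            if row.fp <= fp_max:
                return CutoffSelection(
                    threshold=row.threshold,
                    rule_id=rule,
                    satisfied_conditions=(
                        f"fp={row.fp} <= fp_max={fp_max} at minimal threshold; "
                        f"precision={row.precision:.3f}"
                    ),
                )
        raise ValueError(f"no sweep row has fp <= {fp_max}")
    if rule == RULE_MAX_PRECISION:
        defined = [r for r in rows if not math.isnan(r.precision)]
        if not defined:
            raise ValueError("no sweep row has defined precision")
        best = max(r.precision for r in defined)
        for row in defined:
            if row.precision == best:
                return CutoffSelection(
                    threshold=row.threshold,
                    rule_id=rule,
                    satisfied_conditions=(
                        f"max precision {best:.3f} at minimal threshold"
                    ),
                )
    raise ValueError(f"unknown selection rule {rule!r}")


# ---------------------------------------------------------------------------
# CSV round-trip and the packaged reference table


def write_sweep_csv(path, table: SweepTable) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["threshold", "precision", "true_positive", "false_positive",
             "true_positive_rate"]
        )
        for row in table.rows:
            writer.writerow([row.threshold, row.precision, row.tp, row.fp, row.tpr])
        writer.writerow([])
        writer.writerow(["n_positives", table.n_positives])
        writer.writerow(["n_negatives", table.n_negatives])


def _rows_from_csv(fh) -> SweepTable:
    reader = csv.reader(fh)
    header = next(reader)
    rows = []
    meta = {}
    for rec in reader:
        if not rec or rec[0] == "":
            continue
        if rec[0] in ("n_positives", "n_negatives"):
            meta[rec[0]] = int(rec[1])
            continue
        rows.append(
            SweepRow(
                threshold=float(rec[0]),
                precision=float(rec[1]),
                tp=int(rec[2]),
                fp=int(rec[3]),
                tpr=float(rec[4]),
            )
        )
    rows.sort(key=lambda r: r.threshold)
    return SweepTable(
        rows=tuple(rows),
        n_positives=meta.get("n_positives", 0),
        n_negatives=meta.get("n_negatives", 0),
    )


def read_sweep_csv(path) -> SweepTable:
    with open(path, newline="", encoding="utf-8") as fh:
        return _rows_from_csv(fh)


def reference_sweep_table() -> SweepTable:
    """The packaged reference cutoff sweep: a 10-fold CV sweep over a
    98-compound training split (67 positives, 31 negatives)."""
    ref = resources.files("hiascreen.data").joinpath("table2.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return _rows_from_csv(fh)
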