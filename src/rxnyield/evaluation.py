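"""Nested cross-validation, chronological splitting, and the metric suite.

Two evaluation regimes:

* **Nested cross-validation** — the labelled corpus is cut into k (default 7)
  near-equal slices and k iterations are run.  In iteration i, slice i is
  the hidden test set, the next slice (i+1 mod k) is the validation slice
  driving early stopping / model selection, and the remaining k−2 slices
  train the model.  Each slice is the test slice exactly once and never
  appears in its own training set.
* **Chronological split** — train strictly before a cutoff date, test on or
  after it, emulating prospective deployment on next year's chemistry.

Metrics: accuracy, ROC AUC, F1 / precision / recall on the positive label,
and the normalized confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score

from .io import ReactionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """Slice assignment and per-iteration (train, validation, test) roles."""

    slice_of: tuple[int, ...]  # record index -> slice id
    k: int

    def slice_indices(self, s: int) -> list[int]:
        return [i for i, x in enumerate(self.slice_of) if x == s]

    def iteration(self, i: int) -> tuple[list[int], list[int], list[int]]:
        """(train, validation, test) record indices for iteration i."""
        test_s = i
        val_s = (i + 1) % self.k
        train = [j for j, s in enumerate(self.slice_of) if s not in (test_s, val_s)]
        return train, self.slice_indices(val_s), self.slice_indices(test_s)

    def iterations(self):
        return [self.iteration(i) for i in range(self.k)]


def nested_cv_split(table: ReactionTable | int, k: int = 7, seed: int = 0) -> SplitPlan:
    """Randomly assign records to k near-equal slices (sizes differ by <= 1).

    ``table`` may be a ReactionTable or simply the number of records.
    Requires k >= 3 so the train/validation/test roles never collide.
    """
    n = table if isinstance(table, int) else len(table)
    if k < 3:
        raise ValueError("k must be at least 3 (train/validation/test roles collide)")
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    slice_of = np.empty(n, dtype=int)
    for s, chunk in enumerate(np.array_split(order, k)):
        slice_of[chunk] = s
    return SplitPlan(tuple(int(x) for x in slice_of), k)


def chronological_split(
    table: ReactionTable, cutoff: _date
) -> tuple[ReactionTable, ReactionTable]:
    """Train on records strictly before ``cutoff``, test on the rest.

    Undated records are excluded (count logged).  An empty side warns but is
    not an error.
    """
    train, test, n_undated = [], [], 0
    for rec in table:
        if rec.date is None:
            n_undated += 1
        elif rec.date < cutoff:
            train.append(rec)
        else:
            test.append(rec)
    if n_undated:
        logger.warning("excluded %d undated records from the chronological split",
                       n_undated)
    if not train or not test:
        logger.warning("chronological split produced an empty side "
                       "(train=%d, test=%d)", len(train), len(test))
    return (ReactionTable(train, table.provenance),
            ReactionTable(test, table.provenance))


@dataclass
class MetricReport:
    """The metric suite on one prediction set.

    ``roc_auc`` is ``None`` when the truth is single-class.  The confusion
    entries are normalized over all predictions (they sum to 1).
    """

    n: int
    accuracy: float
    roc_auc: float | None
    f1: float
    precision: float
    recall: float
    confusion: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "roc_auc": self.roc_auc,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            **{k: v for k, v in self.confusion.items()},
        }


def evaluate(
    predicted_labels: Sequence[int],
    truths: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricReport:
    """Accuracy, ROC AUC, F1/precision/recall on label 1, normalized confusion.

    ROC AUC uses ``scores`` when given (falling back to the hard labels) and
    is reported missing on single-class truth.
    """
    yhat = np.asarray(predicted_labels)
    y = np.asarray(truths)
    if yhat.shape != y.shape:
        raise ValueError("predictions and truths must be aligned")
    if y.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    n = y.size
    acc = float((yhat == y).mean())
    auc = None
    if len(np.unique(y)) > 1:
        s = np.asarray(scores) if scores is not None else yhat
        auc = float(roc_auc_score(y, s))
    f1 = float(f1_score(y, yhat, zero_division=0))
    prec = float(precision_score(y, yhat, zero_division=0))
    rec = float(recall_score(y, yhat, zero_division=0))
    conf = {
        "tp": float(((yhat == 1) & (y == 1)).mean()),
        "fp": float(((yhat == 1) & (y == 0)).mean()),
        "tn": float(((yhat == 0) & (y == 0)).mean()),
        "fn": float(((yhat == 0) & (y == 1)).mean()),
    }
    return MetricReport(n, acc, auc, f1, prec, rec, conf)


def precision_on_selection(truths_of_selected: Sequence[int]) -> float:
    """Observed success rate of a selected (e.g. predicted-positive) set.

    This is precision restricted to the selection: e.g. 25 picks with 2
    failures -> 23/25 = 0.92.
    """
    y = np.asarray(truths_of_selected)
    if y.size == 0:
        raise ValueError("empty selection")
    return float((y == 1).mean())


def summarize_iterations(reports: Sequence[MetricReport]) -> dict:
    """Mean ± sd of each metric across CV iterations (missing values skipped)."""
    out = {}
    for key in ("accuracy", "roc_auc", "f1", "precision", "recall"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if vals:
            out[key] = {"mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
    return out
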