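"""Confidence scoring and per-confidence-bucket performance analysis.

A bounded-regression classifier whose score x lives in [0, 1] carries a free
uncertainty signal: the further x sits from the 0.5 decision boundary, the
more certain the model.  The confidence is ``2·|x − 0.5|`` in [0, 1]; since
a binary classifier's expected accuracy spans 50–100%, the confidence is
also linearly rescaled onto [0.5, 1] (``0.5 + |x − 0.5| = max(x, 1 − x)``),
putting it on the same axis as accuracy.  On that axis a perfectly
calibrated model traces the identity line, and with width-0.05 buckets the
curve starts at the point (0.525, 0.525).

For a softmax classification head the analogous quantity is the maximum
class probability, which for two classes already lies in [0.5, 1].

``calibration_curve`` buckets predictions by scaled confidence and reports
accuracy, precision/recall on the positive label, and ROC AUC per bucket,
plus the bucket's negative-class share — a small absolute number of
misranked negatives in a bucket where negatives are rare can crater the
bucket's ROC AUC while leaving accuracy untouched, so the share is the
diagnostic to read alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


def confidence(x: float | np.ndarray) -> float | np.ndarray:
    """Confidence of a bounded score: 2·|x − 0.5| in [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("scores must lie in [0, 1]")
    out = 2.0 * np.abs(arr - 0.5)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def scaled_confidence(x: float | np.ndarray) -> float | np.ndarray:
    """Confidence linearly rescaled to [0.5, 1]: max(x, 1 − x)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("scores must lie in [0, 1]")
    out = 0.5 + np.abs(arr - 0.5)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def softmax_confidence(probabilities: Sequence[float]) -> float:
    """Maximum class probability of a softmax output.

    For two classes this already lies on the [0.5, 1] scale.  Inputs that do
    not sum to 1 are renormalized with a warning.
    """
    import warnings

    p = np.asarray(probabilities, dtype=float)
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        warnings.warn("probabilities do not sum to 1; renormalizing")
        p = p / total
    return float(p.max())


@dataclass(frozen=True)
class PredictionResult:
    """A bounded score with its derived label and confidence.

    ``label`` is 1 iff score >= 0.5 (the tie at exactly 0.5 is positive).
    """

    score: float
    label: int
    confidence: float
    scaled_confidence: float

    @classmethod
    def from_score(cls, x: float) -> "PredictionResult":
        return cls(
            score=x,
            label=1 if x >= 0.5 else 0,
            confidence=confidence(x),
            scaled_confidence=scaled_confidence(x),
        )


@dataclass(frozen=True)
class CalibrationBin:
    """One scaled-confidence bucket with its performance metrics.

    Metrics that are undefined on the bucket (ROC AUC with a single truth
    class; precision with no positive predictions) are ``None``, never 0.
    """

    low: float
    high: float
    n: int
    n_neg: int
    accuracy: float | None
    precision: float | None
    recall: float | None
    roc_auc: float | None


def bin_edges(bin_width: float = 0.05) -> np.ndarray:
    """Bucket edges partitioning [0.5, 1.0]; the last bucket is closed."""
    n_bins = int(round(0.5 / bin_width))
    return 0.5 + bin_width * np.arange(n_bins + 1)


def calibration_curve(
    predictions: Sequence[PredictionResult],
    truths: Sequence[int],
    bin_width: float = 0.05,
) -> list[CalibrationBin]:
    """Bucket predictions by scaled confidence and score each bucket.

    Buckets are half-open ``[low, high)`` except the last, ``[1−w, 1.0]``.
    Per bucket: accuracy, precision and recall on the positive label, ROC AUC
    over the raw scores, and the negative-truth share ``n_neg``.  Bucket
    counts sum to the total number of predictions.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must be aligned")
    if not predictions:
        return []
    edges = bin_edges(bin_width)
    sc = np.asarray([p.scaled_confidence for p in predictions])
    scores = np.asarray([p.score for p in predictions])
    labels = np.asarray([p.label for p in predictions])
    y = np.asarray(truths)
    # np.digitize with right-open bins; clamp the top edge into the last bin
    idx = np.clip(np.digitize(sc, edges) - 1, 0, len(edges) - 2)

    bins: list[CalibrationBin] = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            bins.append(CalibrationBin(edges[b], edges[b + 1], 0, 0,
                                       None, None, None, None))
            continue
        yb, lb, sb = y[sel], labels[sel], scores[sel]
        acc = float((yb == lb).mean())
        n_pos_pred = int((lb == 1).sum())
        prec = float((yb[lb == 1] == 1).mean()) if n_pos_pred else None
        n_pos_true = int((yb == 1).sum())
        rec = float((lb[yb == 1] == 1).mean()) if n_pos_true else None
        auc = float(roc_auc_score(yb, sb)) if 0 < n_pos_true < n else None
        bins.append(CalibrationBin(edges[b], edges[b + 1], n, int((yb == 0).sum()),
                                   acc, prec, rec, auc))
    return bins


def curve_to_frame(bins: Sequence[CalibrationBin]) -> pd.DataFrame:
    """Tabulate a calibration curve (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "bin_low": b.low,
                "bin_high": b.high,
                "n": b.n,
                "n_neg": b.n_neg,
                "accuracy": b.accuracy,
                "precision": b.precision,
                "recall": b.recall,
                "roc_auc": b.roc_auc,
            }
            for b in bins
        ]
    )
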