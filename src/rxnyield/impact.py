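"""Prevented-negative impact estimation and the combinatorial recommender.

**Impact estimator.**  Deployed as a pre-screen, a reaction-success model
lets a chemist redesign a reaction whenever the model predicts failure.
Each redesign is itself re-screened, and each round is predicted negative
with probability TN + FN (the model's overall negative-prediction rate), so
the process is a short geometric loop.  With a normalized confusion matrix
(TP, FP, TN, FN summing to 1) and n in-silico design/test iterations, the
estimated fraction of negative reactions prevented is

    1 − (1 − TP · Σ_{i=0}^{n} (TN + FN)^i) / (TN + FP)

implemented exactly in this form.

**Recommender.**  An in-silico HTE plate: the Cartesian product of candidate
reagent lists per category (ligand × solvent × base × catalyst), crossed
with every substrate→product pair, is assembled into reaction records,
scored by a fitted model, split into predicted positives and negatives, and
rank-ordered by scaled confidence; picks at or above a confidence cutoff
(default 0.75) are flagged high-confidence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

from .calibration import PredictionResult
from .io import MoleculeEntity, ReactionRecord

logger = logging.getLogger(__name__)

#: Category name -> entity role used when assembling enumerated reactions.
CATEGORY_ROLES = {
    "ligand": "ligand",
    "solvent": "solvent",
    "base": "base",
    "catalyst": "catalyst",
}


@dataclass(frozen=True)
class ConfusionSummary:
    """A confusion matrix normalized over all predictions."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self):
        vals = (self.tp, self.fp, self.tn, self.fn)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("normalized confusion entries must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-6:
            raise ValueError("normalized confusion entries must sum to 1")


def normalized_confusion(
    predicted_labels: Sequence[int], true_labels: Sequence[int]
) -> ConfusionSummary:
    """Confusion counts divided by the total number of predictions."""
    if len(predicted_labels) != len(true_labels):
        raise ValueError("label sequences must be aligned")
    if not predicted_labels:
        raise ValueError("cannot summarize an empty prediction set")
    n = len(true_labels)
    tp = sum(1 for p, t in zip(predicted_labels, true_labels) if p == 1 and t == 1)
    fp = sum(1 for p, t in zip(predicted_labels, true_labels) if p == 1 and t == 0)
    tn = sum(1 for p, t in zip(predicted_labels, true_labels) if p == 0 and t == 0)
    fn = sum(1 for p, t in zip(predicted_labels, true_labels) if p == 0 and t == 1)
    return ConfusionSummary(tp / n, fp / n, tn / n, fn / n)


def prevented_negative_fraction(c: ConfusionSummary, n: int) -> float:
    """Estimated fraction of negative reactions prevented after n redesigns.

    Evaluates ``1 − (1 − TP·Σ_{i=0}^{n}(TN+FN)^i) / (TN+FP)`` literally; n is
    the number of additional in-silico design/test iterations the chemist
    runs before executing a reaction the model still flags negative.

    Raises when TN + FP = 0 (a set with no negative reactions has no
    negatives to prevent; the quantity is undefined).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if c.tn + c.fp == 0:
        raise ValueError("undefined: no negative reactions (TN + FP = 0)")
    geom = sum((c.tn + c.fn) ** i for i in range(n + 1))
    return 1.0 - (1.0 - c.tp * geom) / (c.tn + c.fp)


@dataclass
class ReagentSlate:
    """Candidate reagents per category plus substrate→product pairs."""

    categories: dict[str, list[str]]
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("a slate needs at least one substrate/product pair")
        unknown = set(self.categories) - set(CATEGORY_ROLES)
        if unknown:
            raise ValueError(f"unknown reagent categories: {sorted(unknown)}")


def count_combinations(slate: ReagentSlate) -> int:
    """Size of the enumeration without materializing it.

    The product of the non-empty category sizes times the number of pairs —
    e.g. 5000 building blocks × 1000 conditions enumerate to 5 M candidate
    predictions.
    """
    total = 1
    for cands in slate.categories.values():
        if cands:
            total *= len(cands)
    return total * len(slate.pairs)


def enumerate_reagent_combinations(
    slate: ReagentSlate, validate: bool = True
) -> list[ReactionRecord]:
    """Assemble a reaction record for every reagent combination × pair.

    The substrate is the limiting reactant, candidates carry their category
    roles with no stated molar ratio (equivalents are chosen later at the
    bench), and the desired product is the right side.  Candidates RDKit
    cannot parse are excluded with a warning and the combination count drops
    accordingly.  Empty categories contribute a factor of 1.
    """
    cats = {k: list(v) for k, v in slate.categories.items() if v}
    if validate:
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.error")
        for name in cats:
            kept = []
            for smi in cats[name]:
                if Chem.MolFromSmiles(smi) is None:
                    logger.warning("excluding unparseable %s candidate %r", name, smi)
                else:
                    kept.append(smi)
            cats[name] = kept
        cats = {k: v for k, v in cats.items() if v}

    names = sorted(cats)
    out: list[ReactionRecord] = []
    for substrate, product in slate.pairs:
        for combo in itertools.product(*(cats[n] for n in names)):
            left = [MoleculeEntity(substrate, role="limiting_reactant", molar_ratio=1.0)]
            left += [
                MoleculeEntity(smi, role=CATEGORY_ROLES[name])
                for name, smi in zip(names, combo)
            ]
            right = [MoleculeEntity(product, role="product")]
            out.append(ReactionRecord(tuple(left), tuple(right)))
    return out


@dataclass(frozen=True)
class RecommendationResult:
    """One scored candidate reaction with its rank within its label group."""

    reaction: ReactionRecord
    score: float
    label: int
    scaled_confidence: float
    rank: int
    high_confidence: bool


def rank_candidates(
    reactions: Sequence[ReactionRecord],
    predictions: Sequence[PredictionResult],
    confidence_cutoff: float = 0.75,
) -> tuple[list[RecommendationResult], list[RecommendationResult]]:
    """Split predictions by label and rank each side by scaled confidence.

    Returns (positives, negatives), each sorted by scaled confidence
    descending with a stable tie-break on the reaction string; ranks are
    1-based within each side.  Entries with scaled confidence at or above
    ``confidence_cutoff`` are flagged high-confidence.
    """
    if len(reactions) != len(predictions):
        raise ValueError("reactions and predictions must be aligned")

    def build(side: list[tuple[ReactionRecord, PredictionResult]]):
        side.sort(key=lambda rp: (-rp[1].scaled_confidence, rp[0].reaction_smiles()))
        return [
            RecommendationResult(
                reaction=rec,
                score=pred.score,
                label=pred.label,
                scaled_confidence=pred.scaled_confidence,
                rank=i + 1,
                high_confidence=pred.scaled_confidence >= confidence_cutoff,
            )
            for i, (rec, pred) in enumerate(side)
        ]

    pos = [(r, p) for r, p in zip(reactions, predictions) if p.label == 1]
    neg = [(r, p) for r, p in zip(reactions, predictions) if p.label == 0]
    return build(pos), build(neg)
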