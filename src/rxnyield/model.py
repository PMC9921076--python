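"""Encoder training and inference for binary reaction-success prediction.

The workflow mirrors the two-stage BERT recipe adapted to reactions:

1. **Pretraining** — masked-token modelling on an unlabelled reaction corpus.
   Condition information is unavailable at this stage, so every Equivalent Id
   is nulled and the enriched embedding row for the null id is pinned at
   zero; the table merely reserves its slot in the network.
2. **Fine-tuning** — supervised training on labelled reactions with the
   Equivalent-Id layer active.  The target is binary (yield < 5% fails, the
   rest succeed) but the head is a *bounded regression*: a sigmoid-squashed
   scalar trained with squared error against {0, 1}.  The distance of the
   score from 0.5 then doubles as a calibrated confidence at zero extra
   cost.  A conventional two-way softmax head trained with cross-entropy is
   available for comparison.

Early stopping on a validation slice selects the best epoch; a grid search
over starting learning rate and dropout picks hyperparameters.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .calibration import PredictionResult
from .embedding import (
    EquivalentSchema,
    TokenizedReaction,
    Vocabulary,
    assign_equivalent_ids,
    null_equivalent_ids,
)
from .io import ReactionRecord, ReactionTable

logger = logging.getLogger(__name__)

YIELD_THRESHOLD = 5.0  # percent; below this a reaction counts as failed


def make_labels(yields: Sequence[float]) -> list[int]:
    """Binarize percent yields: < 5% -> 0 (failed), >= 5% -> 1 (succeeded)."""
    labels = []
    for y in yields:
        if y is None or (isinstance(y, float) and math.isnan(y)):
            raise ValueError(
                "missing yield has no label; exclude unlabelled records first"
            )
        if not 0.0 <= y <= 100.0:
            raise ValueError(f"percent yield out of range: {y}")
        labels.append(0 if y < YIELD_THRESHOLD else 1)
    return labels


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``max_sequence_length`` defaults to a desk-scale 128 (a production run
    over industrial ELN reactions would raise it, e.g. to 550, so that long
    reaction SMILES are not capped).  ``head`` selects the bounded-regression
    or the softmax-classification fine-tuning head.
    """

    vocab_size: int = 0
    n_equivalent_ids: int = 12
    max_sequence_length: int = 128
    hidden_size: int = 64
    attention_heads: int = 2
    layers: int = 2
    ffn_size: int | None = None
    dropout: float = 0.1
    learning_rate: float = 1e-3
    head: str = "regression"
    batch_size: int = 64
    mask_fraction: float = 0.15
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.head not in ("regression", "classification"):
            raise ValueError("head must be 'regression' or 'classification'")
        if self.hidden_size % self.attention_heads:
            raise ValueError("hidden_size must be divisible by attention_heads")
        if self.ffn_size is None:
            self.ffn_size = 2 * self.hidden_size


@dataclass
class TrainState:
    epoch: int
    train_loss: float
    validation_metric: float | None
    best_epoch: int


def mask_tokens(
    tr: TokenizedReaction,
    mask_fraction: float,
    seed: int | np.random.Generator,
    vocab: Vocabulary,
) -> tuple[list[str], list[int]]:
    """Apply BERT-style masking to a tokenized reaction.

    ``ceil(mask_fraction * L)`` positions are drawn without replacement; each
    is replaced by ``[MASK]`` (80%), a random ordinary vocabulary token
    (10%), or kept (10%).  Returns the corrupted token list and the sorted
    target positions.  Deterministic for a given seed.
    """
    if not 0.0 < mask_fraction < 1.0:
        raise ValueError("mask_fraction must lie strictly between 0 and 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(tr.tokens)
    n_targets = max(1, math.ceil(mask_fraction * L))
    positions = sorted(rng.choice(L, size=n_targets, replace=False).tolist())
    ordinary = [t for t in vocab.tokens[len_specials():]]
    out = list(tr.tokens)
    for pos in positions:
        u = rng.random()
        if u < 0.8:
            out[pos] = "[MASK]"
        elif u < 0.9 and ordinary:
            out[pos] = ordinary[int(rng.integers(len(ordinary)))]
        # else: keep the original token
    return out, positions


def len_specials() -> int:
    from .embedding import SPECIAL_TOKENS

    return len(SPECIAL_TOKENS)


def _as_tokenized(
    data: Iterable[TokenizedReaction] | Iterable[ReactionRecord] | ReactionTable,
    schema: EquivalentSchema,
) -> list[TokenizedReaction]:
    items = list(data)
    if items and isinstance(items[0], ReactionRecord):
        return [assign_equivalent_ids(r, schema) for r in items]
    return items


def supervised_subset(trs: Sequence[TokenizedReaction]) -> list[TokenizedReaction]:
    """Keep reactions with a yield label; log how many were excluded."""
    kept = [t for t in trs if t.label is not None]
    n_dropped = len(trs) - len(kept)
    if n_dropped:
        logger.warning("excluded %d records without a yield from supervision", n_dropped)
    return kept


class YieldModel:
    """A condition-enriched transformer encoder for reaction success."""

    def __init__(
        self,
        config: ModelConfig,
        vocab: Vocabulary,
        schema: EquivalentSchema | None = None,
    ):
        self.config = config
        self.vocab = vocab
        self.schema = schema or EquivalentSchema()
        if config.vocab_size == 0:
            config.vocab_size = len(vocab)
        if config.vocab_size != len(vocab):
            raise ValueError("config.vocab_size disagrees with the vocabulary")
        if config.n_equivalent_ids < self.schema.n_ids:
            raise ValueError("config reserves fewer equivalent ids than the schema uses")
        self._dtype = np.float32 if config.dtype == "float32" else np.float64
        self.rng = np.random.default_rng(config.seed)
        self.params = nn.init_encoder_params(
            config.vocab_size,
            config.n_equivalent_ids,
            config.max_sequence_length,
            config.hidden_size,
            config.layers,
            config.ffn_size,
            self.rng,
            dtype=self._dtype,
        )
        self.n_truncated = 0
        self._init_heads()

    def _init_heads(self):
        c = self.config
        s = 0.02
        self.params["mlm_w"] = self.rng.normal(0, s, (c.hidden_size, c.vocab_size)).astype(self._dtype)
        self.params["mlm_b"] = np.zeros(c.vocab_size, dtype=self._dtype)
        if c.head == "regression":
            self.params["head_w"] = self.rng.normal(0, s, c.hidden_size).astype(self._dtype)
            self.params["head_b"] = np.zeros(1, dtype=self._dtype)
        else:
            self.params["head_w"] = self.rng.normal(0, s, (c.hidden_size, 2)).astype(self._dtype)
            self.params["head_b"] = np.zeros(2, dtype=self._dtype)

    # ------------------------------------------------------------------ data

    def encode(self, trs: Sequence[TokenizedReaction]):
        """Encode reactions as padded id matrices ([CLS] tokens [SEP] pad...).

        Sequences longer than ``max_sequence_length`` are right-truncated and
        counted in ``self.n_truncated``.
        """
        c = self.config
        budget = c.max_sequence_length - 2
        tok_rows, eq_rows = [], []
        for tr in trs:
            toks = list(tr.tokens)
            eqs = list(tr.equivalent_ids)
            if len(toks) > budget:
                self.n_truncated += 1
                toks, eqs = toks[:budget], eqs[:budget]
            tok_rows.append([self.vocab.cls_id, *self.vocab.encode(toks), self.vocab.sep_id])
            eq_rows.append([0, *eqs, 0])
        T = max(len(r) for r in tok_rows)
        N = len(tok_rows)
        tok_ids = np.full((N, T), self.vocab.pad_id, dtype=np.int64)
        eq_ids = np.zeros((N, T), dtype=np.int64)
        pad_mask = np.zeros((N, T), dtype=bool)
        for i, (tr_row, eq_row) in enumerate(zip(tok_rows, eq_rows)):
            L = len(tr_row)
            tok_ids[i, :L] = tr_row
            eq_ids[i, :L] = eq_row
            pad_mask[i, :L] = True
        return tok_ids, eq_ids, pad_mask

    def _forward(self, tok_ids, eq_ids, pad_mask, train=False, use_enriched=True):
        c = self.config
        return nn.encoder_forward(
            self.params,
            tok_ids,
            eq_ids,
            pad_mask,
            c.layers,
            c.attention_heads,
            dropout=c.dropout if train else 0.0,
            rng=self.rng if train else None,
            use_enriched=use_enriched,
        )

    # ------------------------------------------------------------- pretraining

    def _mask_batch(self, tok_ids, pad_mask, rng):
        """Vectorized 80/10/10 masking over ordinary-token positions."""
        c = self.config
        tok = tok_ids.copy()
        rows, cols, targets = [], [], []
        n_special = len_specials()
        maskable = pad_mask & (tok_ids >= n_special)
        for i in range(tok.shape[0]):
            idx = np.flatnonzero(maskable[i])
            if idx.size == 0:
                continue
            n_t = max(1, math.ceil(c.mask_fraction * idx.size))
            chosen = rng.choice(idx, size=n_t, replace=False)
            for j in chosen:
                rows.append(i)
                cols.append(j)
                targets.append(tok_ids[i, j])
                u = rng.random()
                if u < 0.8:
                    tok[i, j] = self.vocab.mask_id
                elif u < 0.9:
                    tok[i, j] = int(rng.integers(n_special, c.vocab_size))
        return tok, (np.asarray(rows), np.asarray(cols)), np.asarray(targets)

    def _mlm_eval_loss(self, tok_ids, eq_ids, pad_mask, rng):
        masked, pos, targets = self._mask_batch(tok_ids, pad_mask, rng)
        h, _ = self._forward(masked, eq_ids, pad_mask, train=False)
        loss, _, _ = nn.mlm_loss_and_grads(h, self.params, pos, targets)
        return float(loss)

    def pretrain_mlm(
        self,
        corpus,
        epochs: int = 3,
        holdout_fraction: float = 0.1,
    ) -> list[TrainState]:
        """Masked-token pretraining with all Equivalent Ids nulled.

        A held-out slice tracks generalization; the returned history starts
        with the untrained (epoch 0) held-out loss.
        """
        c = self.config
        trs = [null_equivalent_ids(t) for t in _as_tokenized(corpus, self.schema)]
        order = self.rng.permutation(len(trs))
        n_hold = max(1, int(holdout_fraction * len(trs)))
        hold = [trs[i] for i in order[:n_hold]]
        train = [trs[i] for i in order[n_hold:]]

        tok_h, eq_h, mask_h = self.encode(hold)
        tok_t, eq_t, mask_t = self.encode(train)
        opt = nn.Adam(self.params, lr=c.learning_rate)
        history = [TrainState(0, float("nan"),
                              self._mlm_eval_loss(tok_h, eq_h, mask_h,
                                                  np.random.default_rng(c.seed + 1)),
                              0)]
        for epoch in range(1, epochs + 1):
            order = self.rng.permutation(len(train))
            losses = []
            for start in range(0, len(train), c.batch_size):
                idx = order[start:start + c.batch_size]
                T = int(mask_t[idx].sum(axis=1).max())
                tok, eq, pm = tok_t[idx, :T], eq_t[idx, :T], mask_t[idx, :T]
                masked, pos, targets = self._mask_batch(tok, pm, self.rng)
                if len(targets) == 0:
                    continue
                h, cache = self._forward(masked, eq, pm, train=True)
                loss, head_grads, dh = nn.mlm_loss_and_grads(h, self.params, pos, targets)
                grads = nn.encoder_backward(self.params, dh, cache)
                grads.update(head_grads)
                opt.step(self.params, grads)
                losses.append(loss)
            hold_loss = self._mlm_eval_loss(tok_h, eq_h, mask_h,
                                            np.random.default_rng(c.seed + 1))
            history.append(TrainState(epoch, float(np.mean(losses)), hold_loss, 0))
            best = min(range(len(history)), key=lambda i: history[i].validation_metric)
            history[-1].best_epoch = best
        return history

    # -------------------------------------------------------------- finetuning

    def finetune(
        self,
        train_data,
        validation_data=None,
        epochs: int = 10,
        patience: int = 3,
    ) -> list[TrainState]:
        """Supervised fine-tuning with early stopping on validation accuracy.

        The enriched Equivalent-Id layer is active.  With the regression head
        the loss is mean squared error between the bounded score and the
        {0, 1} label; with the classification head, cross-entropy.  The
        parameters of the best validation epoch are restored on exit.
        """
        c = self.config
        train = supervised_subset(_as_tokenized(train_data, self.schema))
        if not train:
            raise ValueError("no labelled records to fine-tune on")
        y_train = np.asarray([t.label for t in train])
        if len(set(y_train.tolist())) == 1:
            logger.warning("single-class training set; proceeding anyway")
        tok_t, eq_t, mask_t = self.encode(train)

        val = None
        if validation_data is not None:
            val = supervised_subset(_as_tokenized(validation_data, self.schema))
        opt = nn.Adam(self.params, lr=c.learning_rate)
        history: list[TrainState] = []
        best_metric, best_epoch, best_params = -np.inf, 0, None
        for epoch in range(1, epochs + 1):
            order = self.rng.permutation(len(train))
            losses = []
            for start in range(0, len(train), c.batch_size):
                idx = order[start:start + c.batch_size]
                T = int(mask_t[idx].sum(axis=1).max())
                tok, eq, pm = tok_t[idx, :T], eq_t[idx, :T], mask_t[idx, :T]
                h, cache = self._forward(tok, eq, pm, train=True)
                pooled, scatter = nn.mean_pool(h, pm)
                if c.head == "regression":
                    loss, head_grads, dpooled = nn.regression_loss_and_grads(
                        pooled, self.params, y_train[idx].astype(self._dtype))
                else:
                    loss, head_grads, dpooled = nn.classification_loss_and_grads(
                        pooled, self.params, y_train[idx])
                grads = nn.encoder_backward(self.params, scatter(dpooled), cache)
                grads.update(head_grads)
                opt.step(self.params, grads)
                losses.append(loss)
            val_metric = None
            if val:
                preds = self.predict(val)
                val_metric = float(np.mean(
                    [p.label == t.label for p, t in zip(preds, val)]))
                if val_metric > best_metric:
                    best_metric, best_epoch = val_metric, epoch
                    best_params = {k: v.copy() for k, v in self.params.items()}
            history.append(TrainState(epoch, float(np.mean(losses)),
                                      val_metric, best_epoch or epoch))
            if val and epoch - best_epoch >= patience:
                break
        if best_params is not None:
            self.params = best_params
        return history

    # --------------------------------------------------------------- inference

    def scores(self, data, batch_size: int | None = None, use_enriched: bool = True) -> np.ndarray:
        """Bounded scores x in [0, 1] (positive-class probability for the
        classification head)."""
        trs = _as_tokenized(data, self.schema)
        bs = batch_size or self.config.batch_size
        out = []
        tok_a, eq_a, mask_a = self.encode(trs)
        for start in range(0, len(trs), bs):
            sl = slice(start, start + bs)
            T = int(mask_a[sl].sum(axis=1).max())
            h, _ = self._forward(tok_a[sl, :T], eq_a[sl, :T], mask_a[sl, :T],
                                 train=False, use_enriched=use_enriched)
            pooled, _ = nn.mean_pool(h, mask_a[sl, :T])
            if self.config.head == "regression":
                out.append(nn.regression_head_forward(pooled, self.params))
            else:
                out.append(nn.classification_head_forward(pooled, self.params)[:, 1])
        return np.concatenate(out) if out else np.empty(0)

    def predict(self, data, batch_size: int | None = None) -> list[PredictionResult]:
        """Score reactions and attach label + confidence.

        The decision threshold is 0.5 with the tie (x exactly 0.5) classed
        positive.
        """
        return [PredictionResult.from_score(float(x)) for x in self.scores(data, batch_size)]

    # ------------------------------------------------------------- persistence

    def save(self, ckpt_dir) -> None:
        d = Path(ckpt_dir)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "params.npz", **self.params)
        (d / "config.json").write_text(json.dumps(asdict(self.config)))
        (d / "schema.json").write_text(self.schema.to_json())
        self.vocab.save(d / "vocab.txt")

    @classmethod
    def load(cls, ckpt_dir) -> "YieldModel":
        d = Path(ckpt_dir)
        config = ModelConfig(**json.loads((d / "config.json").read_text()))
        vocab = Vocabulary.load(d / "vocab.txt")
        schema = EquivalentSchema.from_json((d / "schema.json").read_text())
        model = cls(config, vocab, schema)
        with np.load(d / "params.npz") as npz:
            model.params = {k: npz[k] for k in npz.files}
        return model


@dataclass
class GridPoint:
    learning_rate: float
    dropout: float
    validation_metric: float


def grid_search(
    base_config: ModelConfig,
    vocab: Vocabulary,
    train_data,
    validation_data,
    learning_rates: Sequence[float],
    dropouts: Sequence[float],
    schema: EquivalentSchema | None = None,
    epochs: int = 5,
) -> tuple[ModelConfig, list[GridPoint]]:
    """Exhaustive grid search over starting learning rate and dropout.

    Every grid point is fine-tuned from the same seed and scored on the
    validation slice; ties break toward the smaller learning rate, then the
    smaller dropout.  Returns the winning config and the full grid log.
    """
    if not learning_rates or not dropouts:
        raise ValueError("the hyperparameter grid must be non-empty")
    log: list[GridPoint] = []
    for lr in sorted(learning_rates):
        for dr in sorted(dropouts):
            cfg = copy.deepcopy(base_config)
            cfg.learning_rate, cfg.dropout = lr, dr
            model = YieldModel(cfg, vocab, schema)
            model.finetune(train_data, validation_data, epochs=epochs)
            preds = model.predict(validation_data)
            val = supervised_subset(_as_tokenized(validation_data, model.schema))
            acc = float(np.mean([p.label == t.label for p, t in zip(preds, val)]))
            log.append(GridPoint(lr, dr, acc))
    best = max(log, key=lambda g: (g.validation_metric, -g.learning_rate, -g.dropout))
    cfg = copy.deepcopy(base_config)
    cfg.learning_rate, cfg.dropout = best.learning_rate, best.dropout
    return cfg, log
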