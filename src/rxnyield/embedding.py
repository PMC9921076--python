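"""Condition-enriched token annotation: the Equivalent-Id layer.

Every token of a reaction SMILES is paired with a categorical Equivalent Id
that carries the condition information plain text cannot: the entity's role
(limiting reactant, solvent, product), its binned molar ratio relative to
the limiting reactant, and the structural role of separators.  The id
sequence has exactly the length of the token sequence and is summed into the
encoder's embedding as an extra learned vector per id.

Two design points matter chemically:

* A ``"."`` BETWEEN entities gets the dedicated separator id, while a ``"."``
  INSIDE a salt entity inherits that entity's id — so an ionic pair is one
  continuous block to the model instead of two unrelated molecules.
* Product tokens and the ``>>`` arrow carry constant ids, giving the encoder
  an explicit question/answer (left/right) segmentation.

Id 0 is reserved as the null id: during masked-language-model pretraining,
where condition data is unavailable, all ids are nulled and the null
embedding row is pinned at zero, making the enriched layer a no-op.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

from .io import ReactionRecord, ReactionTable, tokenize_smiles

PAD, UNK, MASK, CLS, SEP = "[PAD]", "[UNK]", "[MASK]", "[CLS]", "[SEP]"
SPECIAL_TOKENS = (PAD, UNK, MASK, CLS, SEP)


@dataclass(frozen=True)
class EquivalentSchema:
    """The categorical id scheme for the enriched embedding.

    Default ids: 0 null, 1 limiting reactant, 2 solvent, 3-8 the six molar
    ratio classes, 9 product, 10 arrow, 11 inter-entity separator.  Default
    ratio thresholds (equivalents vs the limiting reactant) are
    ``[0.5, 1.1, 1.5, 2.5, 5.0]``, chosen to straddle common stoichiometries:
    sub-stoichiometric, ~1 eq, slight excess, moderate excess, large excess,
    solvent-scale excess.  A boundary ratio falls in the upper class
    (half-open bins).
    """

    null_id: int = 0
    limiting_reactant_id: int = 1
    solvent_id: int = 2
    ratio_class_ids: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    product_id: int = 9
    arrow_id: int = 10
    separator_id: int = 11
    ratio_thresholds: tuple[float, ...] = (0.5, 1.1, 1.5, 2.5, 5.0)

    def __post_init__(self):
        object.__setattr__(self, "ratio_class_ids", tuple(self.ratio_class_ids))
        object.__setattr__(self, "ratio_thresholds", tuple(self.ratio_thresholds))
        if self.null_id != 0:
            raise ValueError("the null id is fixed at 0")
        ids = self.all_ids()
        if len(set(ids)) != len(ids):
            raise ValueError("equivalent ids must be distinct")
        if len(self.ratio_class_ids) != len(self.ratio_thresholds) + 1:
            raise ValueError("need exactly one more ratio class than thresholds")
        if any(t <= 0 for t in self.ratio_thresholds):
            raise ValueError("ratio thresholds must be positive")
        if list(self.ratio_thresholds) != sorted(self.ratio_thresholds):
            raise ValueError("ratio thresholds must be ascending")

    def all_ids(self) -> tuple[int, ...]:
        return (
            self.null_id,
            self.limiting_reactant_id,
            self.solvent_id,
            *self.ratio_class_ids,
            self.product_id,
            self.arrow_id,
            self.separator_id,
        )

    @property
    def n_ids(self) -> int:
        return max(self.all_ids()) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "null_id": self.null_id,
                "limiting_reactant_id": self.limiting_reactant_id,
                "solvent_id": self.solvent_id,
                "ratio_class_ids": list(self.ratio_class_ids),
                "product_id": self.product_id,
                "arrow_id": self.arrow_id,
                "separator_id": self.separator_id,
                "ratio_thresholds": list(self.ratio_thresholds),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "EquivalentSchema":
        return cls(**json.loads(s))


def bin_molar_ratio(ratio: float, schema: EquivalentSchema) -> int:
    """Map a molar ratio to its ratio-class id (half-open bins).

    The class index is the number of thresholds at or below the ratio, so a
    ratio equal to a threshold belongs to the upper class.
    """
    if ratio < 0:
        raise ValueError(f"molar ratio must be nonnegative, got {ratio}")
    k = sum(1 for t in schema.ratio_thresholds if t <= ratio)
    return schema.ratio_class_ids[k]


@dataclass(frozen=True)
class TokenizedReaction:
    """A token sequence with its aligned Equivalent-Id sequence."""

    tokens: tuple[str, ...]
    equivalent_ids: tuple[int, ...]
    label: int | None = None
    percent_yield: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "equivalent_ids", tuple(self.equivalent_ids))
        if len(self.tokens) != len(self.equivalent_ids):
            raise ValueError(
                f"token/id length mismatch: {len(self.tokens)} tokens vs "
                f"{len(self.equivalent_ids)} ids"
            )


def _left_entity_id(entity, schema: EquivalentSchema) -> int:
    if entity.role == "limiting_reactant":
        return schema.limiting_reactant_id
    if entity.role == "solvent":
        return schema.solvent_id
    if entity.molar_ratio is None:
        # Missing equivalents on a non-solvent agent: the lowest ratio class
        # doubles as the role-bearing placeholder.
        return schema.ratio_class_ids[0]
    return bin_molar_ratio(entity.molar_ratio, schema)


def assign_equivalent_ids(
    record: ReactionRecord, schema: EquivalentSchema | None = None
) -> TokenizedReaction:
    """Tokenize a reaction and assign one Equivalent Id per token.

    Every token of an entity carries that entity's id — including an
    intra-entity ``"."`` inside a salt.  Inter-entity dots get the separator
    id, every product token the product id, and the arrow its own id.
    """
    if schema is None:
        schema = EquivalentSchema()
    tokens: list[str] = []
    ids: list[int] = []

    def emit_entity(entity, ent_id: int) -> None:
        ent_tokens = tokenize_smiles(entity.smiles)
        tokens.extend(ent_tokens)
        ids.extend([ent_id] * len(ent_tokens))

    for i, ent in enumerate(record.left_entities):
        if i > 0:
            tokens.append(".")
            ids.append(schema.separator_id)
        emit_entity(ent, _left_entity_id(ent, schema))
    tokens.append(">>")
    ids.append(schema.arrow_id)
    for i, ent in enumerate(record.right_entities):
        if i > 0:
            tokens.append(".")
            ids.append(schema.separator_id)
        emit_entity(ent, schema.product_id)

    label = None
    if record.percent_yield is not None:
        label = 0 if record.percent_yield < 5.0 else 1
    return TokenizedReaction(
        tuple(tokens), tuple(ids), label=label, percent_yield=record.percent_yield
    )


def null_equivalent_ids(tr: TokenizedReaction) -> TokenizedReaction:
    """Replace every Equivalent Id with the null id (pretraining mode)."""
    return replace(tr, equivalent_ids=(0,) * len(tr.tokens))


@dataclass
class Vocabulary:
    """Token vocabulary with deterministic frequency-then-lexicographic order."""

    tokens: list[str] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_tokens(cls, ordered: Sequence[str]) -> "Vocabulary":
        v = cls(list(ordered), {t: i for i, t in enumerate(ordered)})
        if len(v.index) != len(v.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        return v

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def encode(self, tokens: Sequence[str]) -> list[int]:
        unk = self.index[UNK]
        return [self.index.get(t, unk) for t in tokens]

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def mask_id(self) -> int:
        return self.index[MASK]

    @property
    def cls_id(self) -> int:
        return self.index[CLS]

    @property
    def sep_id(self) -> int:
        return self.index[SEP]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            return cls.from_tokens([line.rstrip("\n") for line in fh if line.strip()])


def build_vocabulary(corpus: ReactionTable) -> Vocabulary:
    """Build the token vocabulary of a corpus plus the special symbols.

    Ordering is deterministic: specials first, then corpus tokens by
    descending frequency with lexicographic tie-break, so two runs over the
    same corpus write identical vocabulary files.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for rec in corpus:
        counts.update(tokenize_smiles(rec.reaction_smiles()))
    ordered = sorted(counts, key=lambda t: (-counts[t], t))
    return Vocabulary.from_tokens([*SPECIAL_TOKENS, *ordered])
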