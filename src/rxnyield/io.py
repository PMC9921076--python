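"""Reaction records, SMILES tokenization, and delimited-text table IO.

The unit of data is a :class:`ReactionRecord`: an ordered list of left-side
entities (reactants and agents, each with a role and an optional molar ratio
relative to the limiting reactant) and right-side entities (products), plus a
percent yield and a date.  Entities are first-class — a salt such as
``CC(=O)[O-].[Na+]`` is ONE entity whose SMILES contains an intra-entity
``"."``, distinct from the ``"."`` that separates entities in a reaction
SMILES.  Electronic-lab-notebook exports carry this separation natively; the
table format here preserves it through a JSON-encoded ``entities`` column.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import date as _date
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ROLES = (
    "limiting_reactant",
    "reagent",
    "solvent",
    "catalyst",
    "base",
    "ligand",
    "product",
    "unknown",
)

#: Roles allowed on the left (reactant/agent) side of a reaction.
LEFT_ROLES = frozenset(ROLES) - {"product"}


class ReactionFormatError(ValueError):
    """Raised for malformed reaction SMILES or table schemas."""


class TokenizationError(ValueError):
    """Raised when a SMILES string contains an unrecognized character."""

    def __init__(self, smiles: str, offset: int):
        self.smiles = smiles
        self.offset = offset
        super().__init__(
            f"unparseable character {smiles[offset]!r} at offset {offset} "
            f"in {smiles!r}"
        )


# Community-standard SMILES token pattern: bracket atoms, the Br/Cl digraphs,
# %nn ring closures, the reaction arrow, and all single-character organic
# subset / bond / branch symbols.  ">>" must precede ">" so the arrow stays
# one token.
_SMILES_TOKEN = re.compile(
    r"(\[[^\]]+\]|Br|Cl|>>|%\d{2}|"
    r"[BCNOPSFIbcnosp]|"
    r"[\d()=#\-\+\\/:~@\?\*\$\.>])"
)


def tokenize_smiles(s: str) -> list[str]:
    """Split a SMILES (or reaction SMILES) string into atomic tokens.

    Tokenization is lossless: ``"".join(tokenize_smiles(s)) == s``.  Bracket
    atoms (``[Na+]``), two-letter halogens, ``%nn`` ring closures, the
    reaction arrow ``>>``, and ``.`` are each a single token.

    Raises
    ------
    TokenizationError
        Naming the offset of the first character no token can start at.
    """
    if not s:
        raise ValueError("cannot tokenize an empty SMILES string")
    tokens: list[str] = []
    pos = 0
    n = len(s)
    while pos < n:
        m = _SMILES_TOKEN.match(s, pos)
        if m is None:
            raise TokenizationError(s, pos)
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class MoleculeEntity:
    """A molecular entity with its role and molar ratio.

    ``smiles`` may contain an intra-entity ``"."`` (salts / ionic pairs).
    ``molar_ratio`` is the equivalents relative to the limiting reactant;
    ``None`` when unknown (common for solvents).
    """

    smiles: str
    role: str = "unknown"
    molar_ratio: float | None = None

    def __post_init__(self):
        if not self.smiles:
            raise ValueError("entity SMILES must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.molar_ratio is not None and self.molar_ratio < 0:
            raise ValueError("molar_ratio must be nonnegative")


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: left entities >> right entities, yield, date."""

    left_entities: tuple[MoleculeEntity, ...]
    right_entities: tuple[MoleculeEntity, ...]
    percent_yield: float | None = None
    date: _date | None = None

    def __post_init__(self):
        object.__setattr__(self, "left_entities", tuple(self.left_entities))
        object.__setattr__(self, "right_entities", tuple(self.right_entities))
        if not self.left_entities or not self.right_entities:
            raise ValueError("a reaction needs at least one entity on each side")
        n_lim = sum(e.role == "limiting_reactant" for e in self.left_entities)
        if n_lim > 1:
            raise ValueError("at most one limiting reactant per reaction")
        for e in self.right_entities:
            if e.role not in ("product", "unknown"):
                raise ValueError("right-side entities must be products")

    @property
    def limiting_reactant(self) -> MoleculeEntity | None:
        for e in self.left_entities:
            if e.role == "limiting_reactant":
                return e
        return None

    def reaction_smiles(self) -> str:
        left = ".".join(e.smiles for e in self.left_entities)
        right = ".".join(e.smiles for e in self.right_entities)
        return f"{left}>>{right}"


@dataclass
class ReactionTable:
    """A list of reaction records with free-text provenance."""

    records: list[ReactionRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _split_entities(block: str) -> list[str]:
    """Split one side of a reaction SMILES on inter-entity dots.

    Without annotations every top-level ``.`` splits; dots inside bracket
    atoms cannot occur, so a plain split is exact.
    """
    return [p for p in block.split(".") if p]


def parse_reaction(
    rxn: str,
    annotations: Sequence[dict] | None = None,
) -> ReactionRecord:
    """Parse a reaction SMILES into a :class:`ReactionRecord`.

    ``rxn`` uses either the two-part form ``reactants>>products`` or the
    three-part form ``reactants>agents>products``; agents are merged into the
    left side with role ``unknown``.

    ``annotations``, when given, is an ordered list of dicts
    ``{"smiles": ..., "role": ..., "molar_ratio": ...}`` covering first all
    left then all right entities.  Annotated entity boundaries override
    ``"."``-splitting, which is how a salt keeps its internal dot inside one
    entity; the concatenation of annotated SMILES (dot-joined per side) must
    reproduce the reaction string.
    """
    if rxn.count(">>") > 1:
        raise ReactionFormatError(f"multiple reaction arrows in {rxn!r}")
    if ">>" in rxn:
        left_block, right_block = rxn.split(">>")
        agent_block = ""
    else:
        parts = rxn.split(">")
        if len(parts) != 3:
            raise ReactionFormatError(
                f"expected 'left>>right' or 'left>agents>right', got {rxn!r}"
            )
        left_block, agent_block, right_block = parts
    if not left_block or not right_block:
        raise ReactionFormatError(f"empty reaction side in {rxn!r}")

    if annotations is not None:
        entities = [
            MoleculeEntity(
                smiles=a["smiles"],
                role=a.get("role", "unknown"),
                molar_ratio=a.get("molar_ratio"),
            )
            for a in annotations
        ]
        left = [e for e in entities if e.role != "product"]
        right = [e for e in entities if e.role == "product"]
        rebuilt_left = ".".join(e.smiles for e in left)
        merged_left = ".".join(x for x in (left_block, agent_block) if x)
        rebuilt_right = ".".join(e.smiles for e in right)
        if rebuilt_left != merged_left or rebuilt_right != right_block:
            raise ReactionFormatError(
                "entity annotations do not reproduce the reaction SMILES: "
                f"{rebuilt_left}>>{rebuilt_right} != {rxn}"
            )
        return ReactionRecord(tuple(left), tuple(right))

    left = [MoleculeEntity(s) for s in _split_entities(left_block)]
    left += [MoleculeEntity(s) for s in _split_entities(agent_block)]
    right = [MoleculeEntity(s, role="product") for s in _split_entities(right_block)]
    return ReactionRecord(tuple(left), tuple(right))


def canonicalize_and_deduplicate(table: ReactionTable) -> ReactionTable:
    """Canonicalize every entity SMILES (RDKit) and drop duplicate reactions.

    Records containing an entity RDKit cannot parse are dropped with a logged
    warning.  Two records are duplicates when their canonical reaction
    strings are identical; the first occurrence wins.  Idempotent.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")

    def canon(smiles: str) -> str | None:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return None
        return Chem.MolToSmiles(mol)

    out: list[ReactionRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    for rec in table.records:
        new_sides = []
        ok = True
        for side in (rec.left_entities, rec.right_entities):
            new_side = []
            for ent in side:
                c = canon(ent.smiles)
                if c is None:
                    ok = False
                    break
                new_side.append(replace(ent, smiles=c))
            if not ok:
                break
            new_sides.append(tuple(new_side))
        if not ok:
            n_dropped += 1
            logger.warning(
                "dropping record with invalid SMILES: %s", rec.reaction_smiles()
            )
            continue
        new_rec = replace(rec, left_entities=new_sides[0], right_entities=new_sides[1])
        key = new_rec.reaction_smiles()
        if key in seen:
            continue
        seen.add(key)
        out.append(new_rec)
    if n_dropped:
        logger.warning("dropped %d records with invalid SMILES", n_dropped)
    return ReactionTable(out, provenance=table.provenance)


_REQUIRED_COLUMNS = ("reaction_smiles",)


def _entities_json(rec: ReactionRecord) -> str:
    return json.dumps(
        [
            {"smiles": e.smiles, "role": e.role, "molar_ratio": e.molar_ratio}
            for e in (*rec.left_entities, *rec.right_entities)
        ]
    )


def write_reaction_table(table: ReactionTable, path, dialect: str = "csv") -> None:
    """Write a table as delimited text (``csv`` or ``tsv``) with a header.

    Columns: ``reaction_smiles``, ``percent_yield``, ``date`` (ISO-8601),
    ``entities`` (JSON list of ``{smiles, role, molar_ratio}``).
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    rows = [
        {
            "reaction_smiles": rec.reaction_smiles(),
            "percent_yield": rec.percent_yield,
            "date": rec.date.isoformat() if rec.date else None,
            "entities": _entities_json(rec),
        }
        for rec in table.records
    ]
    df = pd.DataFrame(rows, columns=["reaction_smiles", "percent_yield", "date", "entities"])
    df.to_csv(path, sep=sep, index=False)


def read_reaction_table(path, dialect: str = "csv") -> ReactionTable:
    """Read a reaction table written by :func:`write_reaction_table`.

    Only ``reaction_smiles`` is required; yield, date and entities columns
    are optional.  Yields outside [0, 100] are clamped with a warning (ELN
    exports are heterogeneous).  ``read`` after ``write`` reproduces the
    table's semantic content.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, dtype={"reaction_smiles": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ReactionFormatError(f"missing required column(s): {missing}")

    records = []
    for _, row in df.iterrows():
        ann = None
        if "entities" in df.columns and isinstance(row.get("entities"), str):
            ann = json.loads(row["entities"])
        rec = parse_reaction(row["reaction_smiles"], annotations=ann)

        py = row.get("percent_yield") if "percent_yield" in df.columns else None
        if py is not None and pd.notna(py):
            py = float(py)
            if py < 0.0 or py > 100.0:
                logger.warning("clamping out-of-range yield %s into [0, 100]", py)
                py = min(max(py, 0.0), 100.0)
        else:
            py = None

        d = None
        if "date" in df.columns and isinstance(row.get("date"), str):
            d = _date.fromisoformat(row["date"])
        records.append(replace(rec, percent_yield=py, date=d))
    return ReactionTable(records, provenance=str(path))


def read_reagent_lists(path) -> dict[str, list[str]]:
    """Read a reagent-candidate CSV with columns ``category, smiles``."""
    df = pd.read_csv(path)
    missing = [c for c in ("category", "smiles") if c not in df.columns]
    if missing:
        raise ReactionFormatError(f"missing required column(s): {missing}")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["category"], []).append(row["smiles"])
    return out


def write_reagent_lists(categories: dict[str, Iterable[str]], path) -> None:
    rows = [
        {"category": cat, "smiles": s}
        for cat, smileses in categories.items()
        for s in smileses
    ]
    pd.DataFrame(rows, columns=["category", "smiles"]).to_csv(path, index=False)
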