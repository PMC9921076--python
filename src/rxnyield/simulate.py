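"""Synthetic reaction corpora with the statistical structure of ELN data.

The generator emulates the features of industrial reaction records that the
modelling pipeline depends on, without any chemistry engine:

* entity-separated reactions with roles and molar ratios (equivalents);
* salts — entities whose SMILES contains an intra-entity ``"."``;
* a controllable negative/positive class split (default 24% / 76%);
* yields that depend on *conditions*: the success log-odds get a bonus when
  the key reagent is dosed in the beneficial molar-ratio class (a slight
  excess, 1.1–1.5 equivalents) and a bonus per beneficial reagent identity.
  The ratio-class signal is invisible in the SMILES text and reaches a model
  only through the Equivalent-Id channel, which is exactly what makes the
  corpus a test bed for condition enrichment;
* yields spanning the 0–85% range typical of HTE plates, with additive
  replicate noise, binarized at the 5% success threshold downstream;
* dates uniform over a configurable range for chronological splits.

Products are simple template edits of the limiting reactant (an appended
coupling fragment): the encoder consumes text, so corpus realism lies in the
token statistics and the condition/label mechanism, not in mechanism-level
chemistry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable

import numpy as np
from scipy.special import expit

from .embedding import EquivalentSchema, bin_molar_ratio
from .impact import ReagentSlate
from .io import MoleculeEntity, ReactionRecord, ReactionTable

logger = logging.getLogger(__name__)

YIELD_SCALE = 85.0  # top of the simulated HTE yield range, percent

# Index (within the default schema's ratio classes) of the beneficial
# molar-ratio class: 1.1-1.5 equivalents, a slight excess of the key reagent.
BENEFICIAL_RATIO_CLASS = 2

_CORES = ["CCO", "c1ccccc1", "CCN", "c1ccncc1", "CC(C)O", "c1ccc(F)cc1",
          "CC(C)C", "c1ccsc1", "CCOCC", "c1ccc(Cl)cc1"]
_SUBSTITUENTS = ["C", "CC", "CCO", "N", "CO", "CC(C)C", "CN", "CCN"]
_PRODUCT_FRAGMENTS = ["CN", "C(=O)N", "CO", "C(C)N", "CC#N", "C(=O)O"]

# Reagent identity pool; the first three are the beneficial identities.
BENEFICIAL_REAGENTS = ["CCN(CC)CC", "CC(C)P(C(C)C)C(C)C", "CN1CCCC1=O"]
NEUTRAL_REAGENTS = ["CCOC(C)=O", "ClCCl", "CC(C)(C)O", "CN(C)C=O", "CCCCN"]
REAGENT_POOL = BENEFICIAL_REAGENTS + NEUTRAL_REAGENTS

SALT_BASES = ["CC(=O)[O-].[Na+]", "CC(=O)[O-].[K+]", "[K+].[F-]",
              "O=C([O-])O.[Na+]"]
SOLVENTS = ["CCO", "CO", "C1CCOC1", "CC#N", "CS(C)=O"]


@dataclass
class SimulationConfig:
    """Study conditions for corpus generation.

    ``ratio_effect`` is the log-odds bonus when the key (first) reagent sits
    in the beneficial ratio class; ``reagent_effect`` the log-odds bonus per
    beneficial reagent identity.  The intercept is calibrated so the
    realized negative fraction lands within ±3 points of
    ``negative_fraction``.
    """

    n_reactions: int = 1000
    negative_fraction: float = 0.24
    ratio_effect: float = 2.0
    reagent_effect: float = 1.0
    salt_fraction: float = 0.25
    yield_noise_sd: float = 2.0
    date_range: tuple[date, date] = (date(2007, 1, 1), date(2021, 12, 31))
    seed: int = 0

    def __post_init__(self):
        for name in ("negative_fraction", "salt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_reactions <= 0:
            raise ValueError("n_reactions must be positive")


def _sample_ratio(rng: np.random.Generator, class_index: int,
                  schema: EquivalentSchema) -> float:
    """Uniform molar ratio within one ratio class of the schema."""
    t = schema.ratio_thresholds
    lows = [0.05, *t]
    highs = [*t, t[-1] * 1.6]
    return float(rng.uniform(lows[class_index], highs[class_index]))


def _sample_molecule(rng: np.random.Generator) -> str:
    core = _CORES[int(rng.integers(len(_CORES)))]
    sub = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
    return core + sub


def generate_corpus(cfg: SimulationConfig,
                    schema: EquivalentSchema | None = None) -> ReactionTable:
    """Generate a reaction table under the configured label mechanism.

    Each record has one limiting reactant, a product derived from it by an
    appended fragment, 0–3 reagents with equivalents, an optional salt base,
    and an optional solvent.  Success probability is
    ``logistic(b0 + ratio_effect·[key reagent in beneficial class]
    + reagent_effect·(# beneficial reagents))``; the percent yield is
    ``85·p`` plus Gaussian noise, clamped to [0, 100].  Fully reproducible
    from ``cfg.seed``.
    """
    schema = schema or EquivalentSchema()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reactions
    beneficial_id = schema.ratio_class_ids[BENEFICIAL_RATIO_CLASS]
    other_classes = [i for i in range(len(schema.ratio_class_ids))
                     if i != BENEFICIAL_RATIO_CLASS]

    records_wip = []
    z = np.zeros(n)
    for i in range(n):
        substrate = _sample_molecule(rng)
        frag = _PRODUCT_FRAGMENTS[int(rng.integers(len(_PRODUCT_FRAGMENTS)))]
        product = substrate + frag

        n_reagents = int(rng.choice([0, 1, 2, 3], p=[0.1, 0.3, 0.3, 0.3]))
        reagent_idx = rng.choice(len(REAGENT_POOL), size=n_reagents, replace=False)
        reagents = [REAGENT_POOL[j] for j in reagent_idx]

        left = [MoleculeEntity(substrate, role="limiting_reactant", molar_ratio=1.0)]
        n_beneficial = 0
        key_in_beneficial = False
        for j, smi in enumerate(reagents):
            if j == 0:  # the key reagent: its ratio class carries the signal
                if rng.random() < 0.5:
                    cls = BENEFICIAL_RATIO_CLASS
                else:
                    cls = other_classes[int(rng.integers(len(other_classes)))]
                ratio = _sample_ratio(rng, cls, schema)
                key_in_beneficial = (
                    bin_molar_ratio(ratio, schema) == beneficial_id
                )
            else:
                ratio = _sample_ratio(rng, int(rng.integers(len(schema.ratio_class_ids))),
                                      schema)
            left.append(MoleculeEntity(smi, role="reagent", molar_ratio=round(ratio, 3)))
            if smi in BENEFICIAL_REAGENTS:
                n_beneficial += 1
        if rng.random() < cfg.salt_fraction:
            salt = SALT_BASES[int(rng.integers(len(SALT_BASES)))]
            left.append(MoleculeEntity(
                salt, role="base",
                molar_ratio=round(_sample_ratio(
                    rng, int(rng.integers(len(schema.ratio_class_ids))), schema), 3)))
        if rng.random() < 0.8:
            left.append(MoleculeEntity(
                SOLVENTS[int(rng.integers(len(SOLVENTS)))], role="solvent"))

        z[i] = (cfg.ratio_effect * key_in_beneficial
                + cfg.reagent_effect * n_beneficial)
        right = [MoleculeEntity(product, role="product")]
        records_wip.append((left, right))

    noise = rng.normal(0.0, cfg.yield_noise_sd, size=n)
    b0 = _calibrate_intercept(z, noise, cfg.negative_fraction)
    yields = np.clip(YIELD_SCALE * expit(b0 + z) + noise, 0.0, 100.0)

    d0, d1 = cfg.date_range
    span = (d1 - d0).days
    offsets = rng.integers(0, span + 1, size=n)

    records = [
        ReactionRecord(tuple(left), tuple(right),
                       percent_yield=float(round(yields[i], 2)),
                       date=d0 + timedelta(days=int(offsets[i])))
        for i, (left, right) in enumerate(records_wip)
    ]
    return ReactionTable(records, provenance=f"synthetic corpus seed={cfg.seed}")


def _calibrate_intercept(z: np.ndarray, noise: np.ndarray,
                         target_negative_fraction: float,
                         tol: float = 0.03) -> float:
    """Bisect the intercept so the realized negative share hits the target.

    The negative share (yield < 5%) is monotone non-increasing in the
    intercept given fixed covariates and noise, so bisection converges; if
    the target is infeasible under the effect sizes a warning reports the
    achieved value.
    """
    def neg_frac(b0: float) -> float:
        y = np.clip(YIELD_SCALE * expit(b0 + z) + noise, 0.0, 100.0)
        return float((y < 5.0).mean())

    lo, hi = -20.0, 15.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if neg_frac(mid) > target_negative_fraction:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    achieved = neg_frac(b0)
    if abs(achieved - target_negative_fraction) > tol:
        logger.warning(
            "intercept calibration infeasible: target negative fraction %.3f, "
            "achieved %.3f", target_negative_fraction, achieved)
    return b0


def make_recommender_fixture(
    cfg: SimulationConfig,
    category_sizes: tuple[int, int, int, int] = (12, 3, 5, 1),
    n_pairs: int = 40,
) -> tuple[ReagentSlate, Callable[[ReactionRecord], int]]:
    """A reagent slate plus a hidden ground-truth success oracle.

    ``category_sizes`` gives the number of (ligand, solvent, base, catalyst)
    candidates.  The oracle labels any enumerated combination by a
    deterministic rule seeded from ``cfg.seed``: roughly a third of the
    ligands and bases (and one solvent) are beneficial, and success requires
    enough accumulated log-odds.  Both slate and oracle are reproducible
    from the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_lig, n_solv, n_base, n_cat = category_sizes

    # Candidates differ in token identity (substituent atoms), not merely in
    # chain length, so an encoder can tell them apart from the text.
    lig_substituents = ["C", "CC(C)C", "c1ccccc1", "COc1ccccc1", "CN",
                        "FC(F)(F)", "Clc1ccccc1", "CCO", "N#CC", "Cc1ccsc1",
                        "OC", "Cc1ccncc1", "CCN(CC)CC", "Fc1ccccc1"]
    ligands = [s + "P(C)C" for s in lig_substituents[:n_lig]]
    if n_lig > len(lig_substituents):
        ligands += [("C" * k) + "P(CC)CC"
                    for k in range(1, n_lig - len(lig_substituents) + 1)]
    solvent_pool = SOLVENTS + ["CC(C)=O", "ClCCl", "CN(C)C=O", "CCOCC"]
    solvents = [solvent_pool[i % len(solvent_pool)] for i in range(n_solv)]
    base_pool = SALT_BASES + ["CC(C)(C)[O-].[K+]", "[Li+].[OH-]",
                              "O=C([O-])[O-].[Cs+].[Cs+]", "CCN(CC)CC"]
    bases = [base_pool[i % len(base_pool)] for i in range(n_base)]
    metals = ["[Cu+].[I-]", "[Pd]", "[Ni]", "[Cu]", "[Fe]"]
    catalysts = [metals[i % len(metals)] for i in range(n_cat)]

    pairs = []
    for _ in range(n_pairs):
        s = _sample_molecule(rng)
        frag = _PRODUCT_FRAGMENTS[int(rng.integers(len(_PRODUCT_FRAGMENTS)))]
        pairs.append((s, s + frag))

    def pick(cands: list[str], k: int) -> frozenset[str]:
        k = max(1, min(k, len(cands)))
        return frozenset(rng.choice(cands, size=k, replace=False).tolist())

    good_ligands = pick(ligands, max(1, n_lig // 3))
    good_bases = pick(bases, max(1, n_base // 3))
    good_solvents = pick(solvents, 1)

    def oracle(record: ReactionRecord) -> int:
        score = -2.0
        for ent in record.left_entities:
            if ent.role == "ligand" and ent.smiles in good_ligands:
                score += 1.5
            if ent.role == "base" and ent.smiles in good_bases:
                score += 1.0
            if ent.role == "solvent" and ent.smiles in good_solvents:
                score += 0.5
        return int(score >= 0.0)

    slate = ReagentSlate(
        categories={"ligand": ligands, "solvent": solvents,
                    "base": bases, "catalyst": catalysts},
        pairs=pairs,
    )
    return slate, oracle
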