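"""Parse an annotated reaction and inspect its tokens and Equivalent Ids.

The base here is sodium acetate — a salt written with an internal "." — so
the example shows the central disambiguation: the dot INSIDE the salt keeps
the base's ratio-class id, while the dots BETWEEN entities get the dedicated
separator id, and product/arrow tokens carry their constant ids.
"""

import rxnyield as ry

rxn = "CCO.CC(=O)[O-].[Na+].CCN>>CCOC"
record = ry.parse_reaction(
    rxn,
    annotations=[
        {"smiles": "CCO", "role": "limiting_reactant", "molar_ratio": 1.0},
        {"smiles": "CC(=O)[O-].[Na+]", "role": "base", "molar_ratio": 2.0},
        {"smiles": "CCN", "role": "reagent", "molar_ratio": 1.2},
        {"smiles": "CCOC", "role": "product"},
    ],
)
print(f"reaction: {record.reaction_smiles()}")
print(f"left entities: {[e.smiles for e in record.left_entities]}")

tr = ry.assign_equivalent_ids(record)
for token, eq_id in zip(tr.tokens, tr.equivalent_ids):
    print(f"  {token:>6}  id {eq_id}")

# Expected reading: the limiting reactant's tokens carry id 1; the base's
# nine tokens (internal "." included) all carry the ratio class of 2.0
# equivalents (id 6); the inter-entity "." tokens carry the separator id 11;
# ">>" id 10 and every product token id 9.
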