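"""Independent brute-force oracles shared by the test modules."""

from fractions import Fraction


def rank_sum_auc(scores, truths):
    """Pairwise-comparison ROC AUC: P(pos score > neg score), ties half."""
    pos = [s for s, t in zip(scores, truths) if t == 1]
    neg = [s for s, t in zip(scores, truths) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def per_character_id_labeler(record, schema):
    """Independent Equivalent-Id oracle: label every CHARACTER of the
    reaction SMILES by walking the entities, then collapse to per-token ids
    via the token boundaries (asserting each token is id-homogeneous)."""
    import rxnyield as ry
    from rxnyield.embedding import _left_entity_id

    char_ids = []
    for i, ent in enumerate(record.left_entities):
        if i > 0:
            char_ids.append(schema.separator_id)
        char_ids.extend([_left_entity_id(ent, schema)] * len(ent.smiles))
    char_ids.extend([schema.arrow_id] * 2)
    for i, ent in enumerate(record.right_entities):
        if i > 0:
            char_ids.append(schema.separator_id)
        char_ids.extend([schema.product_id] * len(ent.smiles))

    tokens = ry.tokenize_smiles(record.reaction_smiles())
    ids, pos = [], 0
    for t in tokens:
        assert all(c == char_ids[pos] for c in char_ids[pos:pos + len(t)])
        ids.append(char_ids[pos])
        pos += len(t)
    return tokens, ids


def prevented_fraction_exact(tp, fp, tn, fn, n):
    """Exact-rational evaluation of the prevented-negative expression
    1 - (1 - TP * sum_{i=0}^{n} (TN+FN)^i) / (TN+FP)."""
    tp, fp, tn, fn = (Fraction(x).limit_denominator(10**12) for x in (tp, fp, tn, fn))
    geom = sum((tn + fn) ** i for i in range(n + 1))
    return float(1 - (1 - tp * geom) / (tn + fp))
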