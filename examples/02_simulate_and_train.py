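"""Generate a synthetic corpus, fine-tune the enriched encoder, and compare
it against a twin that cannot see the condition channel.

The corpus's success log-odds depend on whether the key reagent is dosed in
the beneficial molar-ratio class (1.1-1.5 equivalents) — information that is
absent from the SMILES text and reaches the model only through the
Equivalent-Id embedding.  The accuracy gap between the enriched model and
its nulled-id twin therefore measures the value of condition enrichment.
Desk-scale settings (1000 reactions, a 1-layer encoder) keep this under a
couple of minutes on a laptop CPU.
"""

import copy

import numpy as np

import rxnyield as ry

table = ry.generate_corpus(ry.SimulationConfig(n_reactions=1000, seed=0))
vocab = ry.build_vocabulary(table)
trs = [ry.assign_equivalent_ids(r) for r in table]
train, val, test = trs[:700], trs[700:850], trs[850:]

config = ry.ModelConfig(max_sequence_length=96, hidden_size=48,
                        attention_heads=2, layers=1, dropout=0.1,
                        learning_rate=3e-3, seed=1)

enriched = ry.YieldModel(copy.deepcopy(config), vocab)
enriched.finetune(train, val, epochs=8)
acc = np.mean([p.label == t.label
               for p, t in zip(enriched.predict(test), test)])

nulled_trs = [ry.null_equivalent_ids(t) for t in trs]
nulled = ry.YieldModel(copy.deepcopy(config), vocab)
nulled.finetune(nulled_trs[:700], nulled_trs[700:850], epochs=8)
acc0 = np.mean([p.label == t.label
                for p, t in zip(nulled.predict(nulled_trs[850:]), test)])

print(f"held-out accuracy, enriched embedding : {acc:.3f}")
print(f"held-out accuracy, nulled embedding   : {acc0:.3f}")
print(f"accuracy gained from condition channel: {acc - acc0:+.3f}")
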