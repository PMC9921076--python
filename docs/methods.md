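# Methods

## Problem and model

`rxnyield` treats reaction success as a binary property of a reaction record:
a reaction whose isolated percent yield is below 5% is a failure (label 0),
everything else a success (label 1). The 5% line reflects the practical
question in medicinal-chemistry synthesis — can enough material be isolated
to test — rather than yield optimization, and it sidesteps the
well-documented hopelessness of regressing exact yields across heterogeneous
electronic-lab-notebook (ELN) data.

The predictor is a BERT-style transformer encoder over tokenized reaction
SMILES whose input embedding is the **sum of three learned tables**:

```
e(t) = E_tok[token_t] + E_pos[t] + E_eq[equivalent_id_t]
```

The third table is the package's distinguishing component. Every token
carries a categorical **Equivalent Id** describing condition information the
plain text cannot: the entity's role (limiting reactant, solvent, product),
the binned molar ratio of a reagent relative to the limiting reactant, and
structural ids for the reaction arrow and inter-entity separators. Two
chemically motivated consequences:

* a salt such as `CC(=O)[O-].[Na+]` is one continuous id block — its
  internal `"."` (an ionic bond) is distinguishable from the `"."` that
  separates entities;
* the left/right (question/answer) segmentation is explicit, through the
  constant product and arrow ids, without a second segment vector.

Id 0 is the **null id** and its embedding row is pinned at exactly zero.
During self-supervised pretraining — masked-token modelling on unlabelled
corpora, where condition data is generally unavailable — all ids are nulled,
which makes the enriched layer a strict no-op while reserving its slot in
the network; fine-tuning then activates it. The pinned row gives an exact
invariant used in the tests: null-id inputs produce bit-identical outputs to
an encoder with no enriched layer.

### Bounded-regression classification and confidence

The fine-tuning head is a *regression bounded to [0, 1]*: a sigmoid-squashed
scalar read off the mean-pooled encoder state, trained with squared error
against the {0, 1} labels and thresholded at 0.5 (the tie at exactly 0.5 is
classed positive — symmetric and exercised by a boundary test). The payoff
of this formulation over plain softmax classification is a free uncertainty
signal: confidence `2·|x − 0.5|`, linearly rescaled to `[0.5, 1]` as
`max(x, 1 − x)` so it shares an axis with accuracy. The scaling and the
decision rule are invariant to the particular squashing function; the
sigmoid is a documented implementation choice, as is mean pooling (it makes
presence-of-an-id-block signals linearly accessible to the head, which
matters at the small scales this package targets). A two-way softmax head
trained with cross-entropy is provided for comparison; its confidence
analogue is the maximum class probability.

Calibration analysis buckets predictions by scaled confidence into width-
0.05 half-open bins over [0.5, 1.0] (last bin closed, so the lowest bin's
midpoint is 0.525 — the origin of a perfectly calibrated curve) and scores
each bucket: accuracy, precision and recall on the positive label, ROC AUC
over the raw scores, and the bucket's negative-truth share. Metrics that are
undefined on a bucket (ROC AUC under single-class truth, precision with no
positive predictions) are reported as missing, never as 0, so they cannot
silently contaminate averages. The negative share is reported because a
bucket where negatives are rare can show a catastrophic ROC AUC from a
handful of misranked negatives while accuracy/precision/recall barely move;
the tests construct exactly this artifact.

## Encoder implementation

The encoder is a compact, dependency-light NumPy implementation with
hand-written backpropagation, verified against central finite differences in
float64 (relative agreement ≲1e-3 at float64, dominated by finite-difference
error on near-zero gradients). Architecture: post-layer-norm blocks
(multi-head self-attention → residual+LN → GELU feed-forward →
residual+LN), learned positional embeddings, padding handled by additive
−1e9 attention bias, Adam with global-norm gradient clipping at 5.0,
Gaussian(0, 0.02) initialization, BERT-style 80/10/10 masking at a 15%
masking rate (`ceil(0.15·L)` targets per sequence, at least one). Desk-scale
defaults: hidden 64, 2 heads, 2 layers, feed-forward 2× hidden, max
sequence length 128 with right-truncation counted (a production run over
industrial ELN data would raise the cap, e.g. to 550, so long reaction
SMILES are not clipped); float32 throughout, float64 available for gradient
checking. All randomness (initialization, shuffling, masking, dropout) flows
from one seeded generator, so identical seeds give identical loss curves and
predictions on one device.

Early stopping during fine-tuning selects the epoch with the best validation
accuracy and restores its parameters; grid search over starting learning
rate × dropout is exhaustive, ties breaking toward the smaller learning
rate, then the smaller dropout.

## Evaluation protocols

* **Nested cross-validation**: 7 near-equal random slices (sizes differ by
  at most 1); iteration i tests on slice i, early-stops on slice (i+1) mod 7
  and trains on the rest, so each slice is tested exactly once by a model
  that never saw it. The rotating validation slice is a design choice (any
  symmetric assignment would do); slicing is random rather than stratified.
* **Chronological split**: train strictly before a cutoff date, test on or
  after, undated records excluded with a logged count — the prospective
  "would this have helped last year" exercise.
* Metric suite: accuracy, ROC AUC (missing under single-class truth), F1 /
  precision / recall on the positive label, and the normalized confusion
  matrix (entries sum to 1). ROC AUC is cross-checked in the tests against a
  brute-force pairwise rank-sum oracle.

## Impact estimator

With a normalized confusion matrix and `n` additional in-silico design/test
iterations, the estimated fraction of negative reactions prevented is

```
1 − (1 − TP · Σ_{i=0}^{n} (TN+FN)^i) / (TN + FP)
```

implemented literally as written: each redesign round is again predicted
negative with probability TN + FN, giving the geometric sum. The expression
is validated against exact rational arithmetic and its closed form at
FP = FN = 0, n = 0. Note that for small `n` the literal expression can go
negative (it is an asymptotic redesign-loop estimate, not a probability);
it is monotone non-decreasing in `n` and saturates as the geometric series
converges. It is undefined when TN + FP = 0 (no negatives to prevent), which
is raised explicitly.

## Recommender

The recommender enumerates the Cartesian product of per-category candidate
lists (ligand / solvent / base / catalyst; empty categories contribute a
factor of 1) crossed with every substrate→product pair, assembling each
combination into a reaction record: substrate as limiting reactant (ratio
1), candidates with their category roles and *no stated molar ratio* — at
recommendation time equivalents are still to be chosen, so candidates fall
into the designated missing-ratio class — and the desired product on the
right. Unparseable candidates are excluded with a warning and the count
recomputed. Scored reactions are split into predicted positives and
negatives, each ranked by scaled confidence descending with a stable
tie-break on the canonical reaction string; entries at or above the
confidence cutoff (default 0.75 on the [0.5, 1] scale) are flagged
high-confidence. `count_combinations` sizes a design space without
materializing it.

## Synthetic corpus generator

The generator produces the data regime the method assumes, not chemistry:

* entity-separated records — one limiting reactant (ratio 1), a product
  formed by appending a small coupling fragment to the substrate (a pure
  string template; the encoder consumes text, so corpus realism lives in
  token statistics and the condition/label mechanism), 0–3 reagents with
  equivalents (P(count) = 0.1/0.3/0.3/0.3), an optional salt base
  (intra-entity `"."`, default share 0.25) and an optional solvent (share
  0.8);
* a hidden logistic success mechanism:
  `p = σ(b0 + ratio_effect·1[key reagent in the beneficial ratio class] +
  reagent_effect·(# beneficial reagent identities))`, with the *beneficial
  ratio class* fixed at 1.1–1.5 equivalents (a slight excess; hit with
  probability 0.5 for the key reagent). Crucially the ratio class is
  invisible in the SMILES text — it reaches a model only through the
  Equivalent-Id channel — while reagent *identity* is visible to any model,
  so the enriched-vs-nulled accuracy gap isolates the condition channel;
* percent yield `85·p` plus Gaussian noise (sd 2 percentage points, the
  replicate-level variation of careful HTE), clamped to [0, 100]; the 0–85%
  span mirrors the yield swings HTE plates show under equivalents changes
  alone. The noise scale matters for the generator's role as a test bed: at
  sd 2 the ratio effect remains recoverable after binarization (the
  majority-vote ceiling of a predictor with the hidden design matrix
  exceeds that of a text-only predictor by ~0.11 accuracy), whereas much
  larger noise would wash the condition signal out of the binary labels
  near the 5% threshold;
* the intercept `b0` is calibrated by bisection so the realized negative
  share lands within ±3 points of the configured 24% (infeasible targets
  warn with the achieved value);
* dates uniform over 2007–2021 by default, for chronological splits;
  everything reproducible from one seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mechanism-level chemistry or any dependence of
success on substrate structure; correlated duplicate/near-duplicate ELN
entries; reporting bias against failed reactions; temperature, time or
concentration effects. A logistic regression on the hidden design matrix
recovers the effect signs and ordering, which is the sanity floor any
encoder should approach.

The recommender fixture mirrors an optimization campaign layout
(12 ligands × 3 solvents × 5 bases × 1 catalyst × 40 pairs = 7200 virtual
reactions by default) with a deterministic seeded oracle in which roughly a
third of ligands and bases (and one solvent) are beneficial.

## Problem sizes and numerical choices

The test suite runs everything at desk scale by choice: corpora of
300–5000 reactions, encoders of 16–48 hidden units and one layer, a few
training epochs. The headline enrichment comparison fine-tunes enriched and
null-id twins (identical seeds and architecture) on three 5000-reaction
corpora, 3500/500/1000 train/validation/test, and compares mean held-out
accuracy; at these conditions the generator's information gap between the
two models is about 0.11 accuracy at the Bayes level, of which the tiny
encoders realize most. Tolerances: exact-arithmetic identities at 1e-12,
oracle equivalences at 1e-10, stochastic checks with explicit slack noted in
each test. Degenerate inputs are defined behaviour: empty calibration input
gives an empty curve, single-class training warns and proceeds, empty
chronological sides warn, unknown tokens map to `[UNK]`.

## Known limitations

* The encoder is deliberately small and CPU-bound; it demonstrates the
  mechanism and is not a drop-in for a GPU-scale pretrained reaction model.
* Only molar ratio is binned; moles, concentration, temperature and time
  would need further id vocabularies or additional embedding tables.
* The generator's product templates make "product consistency" trivially
  learnable; models trained on it should not be expected to transfer to real
  reactions.
* Confidence is the cheap distance-from-boundary signal; ensemble- or
  dropout-based uncertainty is out of scope.
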