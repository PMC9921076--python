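"""Labels, masking, the encoder's gradients and training behaviour."""

import copy

import numpy as np
import pytest

import rxnyield as ry
from rxnyield import nn
from rxnyield.embedding import SPECIAL_TOKENS


class TestMakeLabels:
    def test_threshold(self):
        assert ry.make_labels([4.9, 5.0, 0.0, 100.0]) == [0, 1, 0, 1]

    def test_missing_yield_rejected(self):
        with pytest.raises(ValueError):
            ry.make_labels([None])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ry.make_labels([101.0])


class TestMaskTokens:
    def _tr(self, n):
        return ry.TokenizedReaction(tuple("C" * n), (1,) * n)

    def test_target_count_is_ceiling(self, small_vocab):
        masked, pos = ry.mask_tokens(self._tr(10), 0.15, 3, small_vocab)
        assert len(pos) == 2  # ceil(0.15 * 10)
        assert len(masked) == 10

    def test_single_token_gets_one_target(self, small_vocab):
        _, pos = ry.mask_tokens(self._tr(1), 0.01, 3, small_vocab)
        assert pos == [0]

    def test_same_seed_identical(self, small_vocab):
        a = ry.mask_tokens(self._tr(30), 0.15, 11, small_vocab)
        b = ry.mask_tokens(self._tr(30), 0.15, 11, small_vocab)
        assert a == b

    def test_bad_fraction_rejected(self, small_vocab):
        with pytest.raises(ValueError):
            ry.mask_tokens(self._tr(5), 1.5, 0, small_vocab)

    def test_corruptions_are_mask_random_or_kept(self, small_vocab):
        tr = self._tr(200)
        masked, pos = ry.mask_tokens(tr, 0.15, 5, small_vocab)
        kinds = {"mask": 0, "random": 0, "kept": 0}
        for p in pos:
            if masked[p] == "[MASK]":
                kinds["mask"] += 1
            elif masked[p] == tr.tokens[p]:
                kinds["kept"] += 1
            else:
                kinds["random"] += 1
                assert masked[p] not in SPECIAL_TOKENS
        assert kinds["mask"] > kinds["random"] + kinds["kept"]
        # untargeted positions untouched
        untouched = set(range(200)) - set(pos)
        assert all(masked[p] == tr.tokens[p] for p in untouched)


def test_encoder_gradients_match_finite_differences():
    """Analytic backprop equals central finite differences (float64)."""
    rng = np.random.default_rng(0)
    V, K, T, H, L, F, nh, B = 11, 6, 7, 8, 2, 12, 2, 3
    params = nn.init_encoder_params(V, K, T, H, L, F, rng, dtype=np.float64)
    params["head_w"] = rng.normal(0, 0.1, H)
    params["head_b"] = np.zeros(1)
    tok = rng.integers(0, V, (B, T))
    eq = rng.integers(0, K, (B, T))
    pm = np.ones((B, T), bool)
    pm[0, 5:] = False
    y = np.array([0.0, 1.0, 1.0])

    def loss():
        h, cache = nn.encoder_forward(params, tok, eq, pm, L, nh)
        pooled, scatter = nn.mean_pool(h, pm)
        l, hg, dpooled = nn.regression_loss_and_grads(pooled, params, y)
        return l, hg, scatter(dpooled), cache

    l0, hg, dh, cache = loss()
    grads = nn.encoder_backward(params, dh, cache)
    grads.update(hg)
    eps = 1e-6
    for key in params:
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in params[key].shape)
            if key == "eq_emb" and idx[0] == 0:
                continue  # pinned null row
            orig = params[key][idx]
            params[key][idx] = orig + eps
            lp = loss()[0]
            params[key][idx] = orig - eps
            lm = loss()[0]
            params[key][idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, rel=1e-3, abs=1e-9)


@pytest.fixture(scope="module")
def tiny_supervised(small_vocab_module=None):
    """A linearly separable set: success iff the key reagent is present."""
    good = ry.MoleculeEntity("CCN", "reagent", 1.2)
    bad = ry.MoleculeEntity("ClCCl", "reagent", 1.2)
    records = []
    rng = np.random.default_rng(0)
    for i in range(120):
        ok = i % 2 == 0
        rec = ry.ReactionRecord(
            (ry.MoleculeEntity("CCO", "limiting_reactant", 1.0),
             good if ok else bad),
            (ry.MoleculeEntity("CCOC", "product"),),
            percent_yield=80.0 if ok else 1.0,
        )
        records.append(rec)
    return ry.ReactionTable(records)


class TestFinetunePredict:
    def test_separable_set_learned(self, tiny_supervised):
        vocab = ry.build_vocabulary(tiny_supervised)
        cfg = ry.ModelConfig(max_sequence_length=32, hidden_size=16,
                             attention_heads=2, layers=1, dropout=0.0,
                             learning_rate=3e-3, batch_size=16, seed=1)
        model = ry.YieldModel(cfg, vocab)
        trs = [ry.assign_equivalent_ids(r) for r in tiny_supervised]
        model.finetune(trs, epochs=10)
        preds = model.predict(trs)
        acc = np.mean([p.label == t.label for p, t in zip(preds, trs)])
        assert acc >= 0.95

    def test_output_bounded_and_tie_positive(self, tiny_supervised, small_vocab):
        cfg = ry.ModelConfig(max_sequence_length=32, hidden_size=16,
                             attention_heads=2, layers=1, seed=3)
        model = ry.YieldModel(cfg, small_vocab)
        scores = model.scores(list(tiny_supervised))
        assert np.all(scores >= 0.0) and np.all(scores <= 1.0)
        assert ry.PredictionResult.from_score(0.5).label == 1
        assert ry.PredictionResult.from_score(0.2).label == 0
        assert ry.PredictionResult.from_score(0.7).label == 1

    def test_all_positive_training_concentrates_near_one(self, tiny_supervised):
        vocab = ry.build_vocabulary(tiny_supervised)
        cfg = ry.ModelConfig(max_sequence_length=32, hidden_size=16,
                             attention_heads=2, layers=1, dropout=0.0,
                             learning_rate=3e-3, batch_size=16, seed=2)
        model = ry.YieldModel(cfg, vocab)
        import dataclasses
        trs = [dataclasses.replace(ry.assign_equivalent_ids(r), label=1)
               for r in tiny_supervised]
        model.finetune(trs, epochs=8)
        assert model.scores(trs).mean() > 0.85

    def test_seed_determinism(self, tiny_supervised):
        vocab = ry.build_vocabulary(tiny_supervised)
        trs = [ry.assign_equivalent_ids(r) for r in tiny_supervised][:40]

        def run():
            cfg = ry.ModelConfig(max_sequence_length=32, hidden_size=16,
                                 attention_heads=2, layers=1, dropout=0.1,
                                 learning_rate=3e-3, batch_size=16, seed=9)
            m = ry.YieldModel(cfg, vocab)
            m.finetune(trs, epochs=2)
            return m.scores(trs)

        assert np.array_equal(run(), run())

    def test_unknown_tokens_do_not_crash(self, tiny_supervised):
        vocab = ry.build_vocabulary(tiny_supervised)
        cfg = ry.ModelConfig(max_sequence_length=32, hidden_size=16,
                             attention_heads=2, layers=1, seed=4)
        model = ry.YieldModel(cfg, vocab)
        exotic = ry.parse_reaction("[Xe].CC>>CC[Xe]")
        out = model.predict([exotic])
        assert 0.0 <= out[0].score <= 1.0


def test_null_ids_equal_absent_enriched_layer(small_corpus, small_vocab, tiny_config):
    """With all Equivalent Ids nulled, the enriched layer is exactly a no-op."""
    model = ry.YieldModel(copy.deepcopy(tiny_config), small_vocab)
    trs = [ry.null_equivalent_ids(ry.assign_equivalent_ids(r))
           for r in small_corpus.records[:20]]
    tok, eq, pm = model.encode(trs)
    h_null, _ = model._forward(tok, eq, pm, use_enriched=True)
    h_absent, _ = model._forward(tok, eq, pm, use_enriched=False)
    np.testing.assert_array_equal(h_null, h_absent)


def test_classification_head_scores_are_softmax_probabilities(small_corpus, small_vocab):
    cfg = ry.ModelConfig(max_sequence_length=96, hidden_size=16, attention_heads=2,
                         layers=1, head="classification", seed=5)
    model = ry.YieldModel(cfg, small_vocab)
    trs = [ry.assign_equivalent_ids(r) for r in small_corpus.records[:10]]
    tok, eq, pm = model.encode(trs)
    h, _ = model._forward(tok, eq, pm)
    pooled, _ = nn.mean_pool(h, pm)
    probs = nn.classification_head_forward(pooled, model.params)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(model.scores(trs), probs[:, 1], atol=1e-6)


def test_pretraining_reduces_heldout_mlm_loss(small_corpus, small_vocab, tiny_config):
    model = ry.YieldModel(copy.deepcopy(tiny_config), small_vocab)
    history = model.pretrain_mlm(small_corpus, epochs=2)
    assert history[-1].validation_metric < history[0].validation_metric
    assert history[-1].best_epoch <= history[-1].epoch


def test_pretraining_memorizes_repeated_corpus(small_vocab):
    rec = ry.parse_reaction("CCO.CC>>CCOC")
    import dataclasses
    table = ry.ReactionTable([dataclasses.replace(rec) for _ in range(64)])
    cfg = ry.ModelConfig(vocab_size=len(small_vocab), max_sequence_length=32,
                         hidden_size=16, attention_heads=2, layers=1,
                         dropout=0.0, learning_rate=5e-3, batch_size=16, seed=6)
    model = ry.YieldModel(cfg, small_vocab)
    history = model.pretrain_mlm(table, epochs=12)
    assert history[-1].validation_metric < 0.35


def test_truncation_counted(small_vocab):
    cfg = ry.ModelConfig(max_sequence_length=16, hidden_size=16,
                         attention_heads=2, layers=1, seed=0)
    model = ry.YieldModel(cfg, small_vocab)
    long_rec = ry.parse_reaction("C" * 40 + ">>CC")
    model.encode([ry.assign_equivalent_ids(long_rec)])
    assert model.n_truncated == 1


class TestGridSearch:
    def test_exhaustive_and_tiebreak(self, tiny_supervised):
        vocab = ry.build_vocabulary(tiny_supervised)
        trs = [ry.assign_equivalent_ids(r) for r in tiny_supervised]
        base = ry.ModelConfig(max_sequence_length=32, hidden_size=16,
                              attention_heads=2, layers=1, batch_size=16, seed=1)
        best, log = ry.grid_search(base, vocab, trs[:80], trs[80:],
                                   learning_rates=[1e-3, 3e-3],
                                   dropouts=[0.0, 0.1], epochs=4)
        assert len(log) == 4
        top = max(g.validation_metric for g in log)
        winners = [g for g in log if g.validation_metric == top]
        expected = min(winners, key=lambda g: (g.learning_rate, g.dropout))
        assert (best.learning_rate, best.dropout) == (
            expected.learning_rate, expected.dropout)

    def test_degenerate_grid(self, tiny_supervised):
        vocab = ry.build_vocabulary(tiny_supervised)
        trs = [ry.assign_equivalent_ids(r) for r in tiny_supervised]
        base = ry.ModelConfig(max_sequence_length=32, hidden_size=16,
                              attention_heads=2, layers=1, batch_size=16, seed=1)
        best, log = ry.grid_search(base, vocab, trs[:80], trs[80:],
                                   learning_rates=[2e-3], dropouts=[0.05],
                                   epochs=2)
        assert len(log) == 1
        assert (best.learning_rate, best.dropout) == (2e-3, 0.05)

    def test_empty_grid_rejected(self, small_vocab, tiny_config):
        with pytest.raises(ValueError):
            ry.grid_search(tiny_config, small_vocab, [], [], [], [0.1])


def test_checkpoint_roundtrip(tmp_path, tiny_supervised):
    vocab = ry.build_vocabulary(tiny_supervised)
    cfg = ry.ModelConfig(max_sequence_length=32, hidden_size=16,
                         attention_heads=2, layers=1, seed=1)
    model = ry.YieldModel(cfg, vocab)
    trs = [ry.assign_equivalent_ids(r) for r in tiny_supervised][:20]
    model.finetune(trs, epochs=1)
    model.save(tmp_path / "ckpt")
    back = ry.YieldModel.load(tmp_path / "ckpt")
    np.testing.assert_array_equal(model.scores(trs), back.scores(trs))
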