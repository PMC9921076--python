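"""The synthetic corpus generator and the recommender fixture."""

import numpy as np
import pytest

import rxnyield as ry
from rxnyield.embedding import bin_molar_ratio
from rxnyield.simulate import BENEFICIAL_RATIO_CLASS, BENEFICIAL_REAGENTS


def _design_matrix(table, schema):
    """The generator's hidden covariates: key-reagent-in-beneficial-class
    indicator and beneficial-reagent count."""
    ben_id = schema.ratio_class_ids[BENEFICIAL_RATIO_CLASS]
    R, B, y = [], [], []
    for rec in table:
        reagents = [e for e in rec.left_entities if e.role == "reagent"]
        R.append(1 if reagents and bin_molar_ratio(reagents[0].molar_ratio, schema) == ben_id else 0)
        B.append(sum(e.smiles in BENEFICIAL_REAGENTS for e in reagents))
        y.append(0 if rec.percent_yield < 5 else 1)
    return np.array(R), np.array(B), np.array(y)


class TestGenerateCorpus:
    def test_negative_share_calibrated(self):
        table = ry.generate_corpus(ry.SimulationConfig(n_reactions=10_000, seed=7))
        y = np.array([0 if r.percent_yield < 5 else 1 for r in table])
        assert 0.21 <= 1 - y.mean() <= 0.27

    def test_structure_of_records(self, small_corpus):
        for rec in small_corpus:
            lims = [e for e in rec.left_entities if e.role == "limiting_reactant"]
            assert len(lims) == 1
            assert lims[0].molar_ratio == 1.0
            assert len(rec.right_entities) == 1
            assert 0.0 <= rec.percent_yield <= 100.0
            assert rec.date is not None

    def test_seed_determinism(self):
        a = ry.generate_corpus(ry.SimulationConfig(n_reactions=50, seed=3))
        b = ry.generate_corpus(ry.SimulationConfig(n_reactions=50, seed=3))
        assert [r.reaction_smiles() for r in a] == [r.reaction_smiles() for r in b]
        assert [r.percent_yield for r in a] == [r.percent_yield for r in b]
        c = ry.generate_corpus(ry.SimulationConfig(n_reactions=50, seed=4))
        assert [r.reaction_smiles() for r in a] != [r.reaction_smiles() for r in c]

    def test_salt_fraction_one_puts_a_salt_in_every_record(self):
        table = ry.generate_corpus(
            ry.SimulationConfig(n_reactions=100, salt_fraction=1.0, seed=0))
        for rec in table:
            assert any("." in e.smiles for e in rec.left_entities)

    def test_zero_effects_make_yield_independent_of_conditions(self, schema):
        table = ry.generate_corpus(ry.SimulationConfig(
            n_reactions=8000, ratio_effect=0.0, reagent_effect=0.0, seed=1))
        R, B, y = _design_matrix(table, schema)
        # negative share still calibrated, but conditions carry no signal
        assert abs(y[R == 1].mean() - y[R == 0].mean()) < 0.03
        assert 0.21 <= 1 - y.mean() <= 0.27

    def test_label_mechanism_recoverable_by_logistic_regression(self, schema):
        from sklearn.linear_model import LogisticRegression

        table = ry.generate_corpus(ry.SimulationConfig(
            n_reactions=8000, ratio_effect=2.0, reagent_effect=1.0, seed=2))
        R, B, y = _design_matrix(table, schema)
        lr = LogisticRegression().fit(np.c_[R, B], y)
        coef_ratio, coef_reagent = lr.coef_[0]
        assert coef_ratio > 0 and coef_reagent > 0
        assert coef_ratio > coef_reagent  # effect ordering recovered

    def test_dates_within_range(self):
        import datetime
        cfg = ry.SimulationConfig(
            n_reactions=200, seed=5,
            date_range=(datetime.date(2015, 1, 1), datetime.date(2016, 1, 1)))
        table = ry.generate_corpus(cfg)
        for rec in table:
            assert cfg.date_range[0] <= rec.date <= cfg.date_range[1]

    def test_entities_are_valid_smiles(self, small_corpus):
        from rdkit import Chem
        for rec in small_corpus.records[:50]:
            for e in (*rec.left_entities, *rec.right_entities):
                assert Chem.MolFromSmiles(e.smiles) is not None

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ry.SimulationConfig(n_reactions=0)
        with pytest.raises(ValueError):
            ry.SimulationConfig(negative_fraction=1.5)


class TestRecommenderFixture:
    def test_paper_layout_covers_all_7200(self):
        cfg = ry.SimulationConfig(seed=0)
        slate, oracle = ry.make_recommender_fixture(cfg, (12, 3, 5, 1), 40)
        assert ry.count_combinations(slate) == 7200
        reactions = ry.enumerate_reagent_combinations(slate, validate=False)
        labels = [oracle(r) for r in reactions]
        assert set(labels) <= {0, 1}
        assert 0 < sum(labels) < len(labels)  # both outcomes occur

    def test_minimal_layout(self):
        slate, oracle = ry.make_recommender_fixture(
            ry.SimulationConfig(seed=0), (1, 1, 1, 1), 1)
        reactions = ry.enumerate_reagent_combinations(slate, validate=False)
        assert len(reactions) == 1
        assert oracle(reactions[0]) in (0, 1)

    def test_seed_determinism(self):
        cfg = ry.SimulationConfig(seed=9)
        s1, o1 = ry.make_recommender_fixture(cfg, (6, 2, 3, 1), 4)
        s2, o2 = ry.make_recommender_fixture(cfg, (6, 2, 3, 1), 4)
        assert s1.categories == s2.categories and s1.pairs == s2.pairs
        rs = ry.enumerate_reagent_combinations(s1, validate=False)
        assert [o1(r) for r in rs] == [o2(r) for r in rs]

    def test_candidates_parse(self):
        from rdkit import Chem
        slate, _ = ry.make_recommender_fixture(
            ry.SimulationConfig(seed=0), (12, 3, 5, 1), 2)
        for cands in slate.categories.values():
            for smi in cands:
                assert Chem.MolFromSmiles(smi) is not None

    def test_end_to_end_recommendation_beats_random_wells(self):
        """Train on oracle-labelled wells from half a virtual plate; the
        recommender's predicted positives on the other half succeed far more
        often than randomly chosen wells."""
        import dataclasses

        cfg = ry.SimulationConfig(seed=4)
        slate, oracle = ry.make_recommender_fixture(cfg, (12, 3, 5, 1), 4)
        reactions = ry.enumerate_reagent_combinations(slate, validate=False)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(reactions))
        train_idx, screen_idx = idx[: len(idx) // 2], idx[len(idx) // 2:]
        history = [
            dataclasses.replace(
                reactions[i],
                percent_yield=float(rng.uniform(20, 80)) if oracle(reactions[i])
                else float(rng.uniform(0, 4)))
            for i in train_idx
        ]
        vocab = ry.build_vocabulary(ry.ReactionTable(list(reactions)))
        model = ry.YieldModel(
            ry.ModelConfig(max_sequence_length=96, hidden_size=32,
                           attention_heads=2, layers=1, dropout=0.0,
                           learning_rate=5e-3, seed=2),
            vocab)
        model.finetune([ry.assign_equivalent_ids(r) for r in history],
                       epochs=40)
        screen = [reactions[i] for i in screen_idx]
        positives, _ = ry.rank_candidates(screen, model.predict(screen))
        assert len(positives) >= 10
        base_rate = np.mean([oracle(r) for r in screen])
        success = ry.precision_on_selection(
            [oracle(r.reaction) for r in positives])
        assert success > base_rate + 0.15
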