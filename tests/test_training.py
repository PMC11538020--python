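"""Objectives, negative sampling, the trainer, and the HPO harness."""

import numpy as np
import pytest

from kgelp.data import KnowledgeGraph, split as split_kg
from kgelp.models import ModelConfig, init_model
from kgelp.training import (
    TrainConfig, one_vs_all_loss, sample_negatives, margin_loss, train, hpo,
)
from tests.conftest import random_kg


def chain_kg(n_entities=40, n_relations=2, n_triples=200, seed=0):
    rng = np.random.default_rng(seed)
    t = np.unique(np.column_stack([
        rng.integers(0, n_entities, n_triples),
        rng.integers(0, n_relations, n_triples),
        rng.integers(0, n_entities, n_triples),
    ]), axis=0)
    return KnowledgeGraph(
        [f"e{i}" for i in range(n_entities)],
        [f"r{i}" for i in range(n_relations)], t,
    )


class TestOneVsAllLoss:
    def test_uniform_scores_give_log_n(self):
        m = init_model(ModelConfig("DistMult", dim=4, seed=0), 50, 2)
        m.params["entity"][:] = 0.0  # all scores equal (zero)
        batch = np.array([[0, 0, 1], [2, 1, 3]])
        assert one_vs_all_loss(m, batch) == pytest.approx(np.log(50))

    def test_saturated_true_score_vanishes(self):
        m = init_model(ModelConfig("DistMult", dim=2, seed=0), 20, 1)
        m.params["entity"][:] = 0.0
        m.params["entity"][3] = [30.0, 0.0]
        m.params["entity"][5] = [30.0, 0.0]
        m.params["relation"][0] = [1.0, 0.0]
        # score(5, 0, 3) = 900, all other candidates 0 or 900? e5.e3 -> only
        # entities 3 and 5 score 900; still dominated: loss tiny
        batch = np.array([[5, 0, 3]])
        assert one_vs_all_loss(m, batch) < 1e-9 + np.log(2)

    def test_matches_brute_force_logsumexp(self, rng):
        m = init_model(ModelConfig("ComplEx", dim=2, seed=4), 5, 2)
        batch = np.array([[0, 0, 1], [2, 1, 3], [4, 0, 0]])
        expected = 0.0
        for s, p, o in batch:
            tail = np.array([m.score(s, p, i) for i in range(5)])
            head = np.array([m.score(i, p, o) for i in range(5)])
            for scores, target in ((tail, o), (head, s)):
                mx = scores.max()
                lse = mx + np.log(np.exp(scores - mx).sum())
                expected += lse - scores[target]
        expected /= 2 * len(batch)
        assert one_vs_all_loss(m, batch) == pytest.approx(expected, abs=1e-6)

    def test_empty_batch_rejected(self):
        m = init_model(ModelConfig("DistMult", dim=2, seed=0), 5, 1)
        with pytest.raises(ValueError):
            one_vs_all_loss(m, np.empty((0, 3)))


class TestSampleNegatives:
    def test_counts_and_no_identity(self, rng):
        batch = np.column_stack([
            rng.integers(0, 100, 30), rng.integers(0, 2, 30),
            rng.integers(0, 100, 30),
        ])
        neg, slot = sample_negatives(batch, 10, 100, "both", rng)
        assert len(neg) == 300
        pos = np.repeat(batch, 10, axis=0)
        rows = np.arange(300)
        assert (neg[rows, slot] != pos[rows, slot]).all()
        other = np.where(slot == 0, 2, 0)
        assert (neg[rows, other] == pos[rows, other]).all()
        assert (neg[rows, 1] == pos[rows, 1]).all()

    def test_forced_outcome_under_filtering(self):
        # 5 entities; all corruptions of (0, 0, 1) except object=3 are true
        fs = {(0, 0, i) for i in (0, 1, 2, 4)}
        batch = np.array([[0, 0, 1]])
        rng = np.random.default_rng(0)
        for _ in range(10):
            neg, _ = sample_negatives(
                batch, 3, 5, "corrupt-object", rng, filter_set=fs
            )
            assert (neg[:, 2] == 3).all()

    def test_both_mode_slot_frequencies_binomial(self):
        rng = np.random.default_rng(1)
        batch = np.array([[0, 0, 1]])
        neg, slot = sample_negatives(batch, 10_000, 50, "both", rng)
        frac = (slot == 0).mean()
        # binomial(10000, .5): 5 sigma ~ 0.025
        assert abs(frac - 0.5) < 0.025

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            sample_negatives(np.array([[0, 0, 1]]), 0, 5)


class TestMarginLoss:
    def setup_method(self):
        self.m = init_model(ModelConfig("TransE", dim=4, seed=2), 10, 2)

    def test_separated_pairs_zero_loss(self):
        # construct: pos scores 0 (exact translation), neg far away
        E, R = self.m.params["entity"], self.m.params["relation"]
        E[1] = E[0] + R[0]
        E[2] = E[0] + R[0] + 100.0
        pos = np.array([[0, 0, 1]])
        neg = np.array([[0, 0, 2]])
        assert margin_loss(self.m, pos, neg, 1.0) == 0.0

    def test_equal_scores_loss_equals_margin(self):
        pos = np.array([[0, 0, 1]])
        assert margin_loss(self.m, pos, pos, 1.0) == pytest.approx(1.0)

    def test_hand_computed_pairs(self):
        m = init_model(ModelConfig("DistMult", dim=1, seed=0), 6, 1)
        m.params["relation"][0] = [1.0]
        m.params["entity"][:, 0] = [1, 2, 3, 4, 5, 6]
        pos = np.array([[0, 0, 1], [1, 0, 2], [2, 0, 3]])  # scores 2, 6, 12
        neg = np.array([[3, 0, 4], [0, 0, 0], [0, 0, 1]])  # scores 20, 1, 2
        # hinge(1 - 2 + 20), hinge(1 - 6 + 1), hinge(1 - 12 + 2) -> 19, 0, 0
        assert margin_loss(m, pos, neg, 1.0) == pytest.approx(19 / 3)

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(ValueError):
            margin_loss(self.m, np.array([[0, 0, 1]]), np.array([[0, 0, 2]]), 0.0)


class TestTrain:
    def make_split(self, seed=0):
        kg = chain_kg(n_entities=30, n_triples=260, seed=seed)
        return split_kg(kg, (0.8, 0.1, 0.1), seed)

    def test_loss_beats_uniform_baseline_quickly(self):
        sp = self.make_split()
        m = init_model(ModelConfig("ComplEx", dim=16, seed=0), 30, 2)
        tc = TrainConfig(objective="1vsAll-CE", lr=1e-2, max_epochs=5,
                         eval_every=5, batch_size=64, seed=0)
        _, hist = train(m, sp, tc)
        assert hist.train_loss[-1] < np.log(30)

    def test_zero_lr_patience_stops_exactly(self):
        sp = self.make_split()
        m = init_model(ModelConfig("DistMult", dim=4, seed=0), 30, 2)
        tc = TrainConfig(lr=0.0, max_epochs=50, eval_every=1, patience=3, seed=0)
        _, hist = train(m, sp, tc)
        # eval 1 sets best; evals 2-4 do not improve -> stop at epoch 4
        assert hist.stopped == "early_stop"
        assert len(hist.eval_epochs) == 4

    def test_same_seed_identical_history(self):
        sp = self.make_split()
        histories = []
        for _ in range(2):
            m = init_model(ModelConfig("ComplEx", dim=8, seed=1), 30, 2)
            tc = TrainConfig(objective="negsamp-CE", negatives=4, lr=5e-3,
                             max_epochs=6, eval_every=2, seed=7)
            _, hist = train(m, sp, tc)
            histories.append(hist)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].valid_mrr == histories[1].valid_mrr

    def test_best_checkpoint_never_worse_than_any_eval(self):
        sp = self.make_split()
        m = init_model(ModelConfig("DistMult", dim=8, seed=2), 30, 2)
        tc = TrainConfig(lr=2e-2, max_epochs=12, eval_every=2, seed=3)
        _, hist = train(m, sp, tc)
        assert hist.best_mrr == max(hist.valid_mrr)
        assert hist.best_epoch <= max(hist.eval_epochs)

    @pytest.mark.parametrize("objective", ["1vsAll-CE", "negsamp-CE", "negsamp-margin"])
    def test_loss_decreases_all_objectives(self, objective):
        sp = self.make_split(seed=4)
        m = init_model(ModelConfig("ComplEx", dim=8, seed=1), 30, 2)
        tc = TrainConfig(objective=objective, lr=1e-2, max_epochs=12,
                         eval_every=12, batch_size=64, seed=0)
        _, hist = train(m, sp, tc)
        q = len(hist.train_loss) // 4
        assert np.median(hist.train_loss[-q:]) < np.median(hist.train_loss[:q])


class TestHPO:
    def make_split(self):
        kg = chain_kg(n_entities=25, n_triples=200, seed=9)
        return split_kg(kg, (0.8, 0.1, 0.1), 0)

    def test_single_trial_is_best(self):
        sp = self.make_split()
        base = TrainConfig(max_epochs=2, eval_every=2, seed=0)
        res = hpo(sp, "DistMult", {"lr": ("log", 1e-3, 1e-1)}, 1, seed=0,
                  base_train=base)
        assert len(res.trials) == 1 and res.best_index == 0

    def test_identical_trials_tie_goes_to_first(self):
        sp = self.make_split()
        base = TrainConfig(max_epochs=2, eval_every=2, seed=0)
        res = hpo(sp, "DistMult", {"lr": ("choice", [1e-2])}, 3, seed=1,
                  base_train=base)
        mrrs = [m for _, m in res.trials]
        assert len(set(mrrs)) == 1
        assert res.best_index == 0

    def test_low_discrepancy_covers_categories(self):
        sp = self.make_split()
        base = TrainConfig(max_epochs=1, eval_every=1, seed=0)
        space = {"objective": ("choice", ["1vsAll-CE", "negsamp-CE"]),
                 "lr": ("log", 1e-3, 1e-2)}
        res = hpo(sp, "DistMult", space, 4, seed=2, base_train=base)
        seen = {a["objective"] for a, _ in res.trials}
        assert seen == {"1vsAll-CE", "negsamp-CE"}
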