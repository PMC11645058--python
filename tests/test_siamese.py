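from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apneasiam.model import CRNNHyperParams, build_model, embed
from apneasiam.siamese import (
    LossConfig,
    PairSample,
    TrainingConfig,
    contrastive_loss,
    euclidean_distance,
    make_pairs,
    pair_distances,
    sample_balanced_pairs,
    train_siamese,
)


def labels_of(n_apnea, n_non):
    return ["apnea"] * n_apnea + ["non_apnea"] * n_non


class TestMakePairs:
    def test_three_by_two_example(self):
        """3 apnea + 2 non-apnea windows: C(3,2)=3 similar, 3*2=6 dissimilar."""
        pairs = make_pairs(labels_of(3, 2))
        assert sum(p.pair_label == 0 for p in pairs) == 3
        assert sum(p.pair_label == 1 for p in pairs) == 6
        balanced = make_pairs(labels_of(3, 2), balance=True)
        assert sum(p.pair_label == 0 for p in balanced) == 6
        assert sum(p.pair_label == 1 for p in balanced) == 6

    @pytest.mark.parametrize("a,b", [(2, 1), (5, 7), (30, 11), (200, 200)])
    def test_counts_match_closed_forms(self, a, b):
        pairs = make_pairs(labels_of(a, b))
        assert sum(p.pair_label == 0 for p in pairs) == comb(a, 2)
        assert sum(p.pair_label == 1 for p in pairs) == a * b
        # similar pairs enumerate exactly the apnea-apnea combinations
        sim = {(p.index_a, p.index_b) for p in pairs if p.pair_label == 0}
        assert sim == set(combinations(range(a), 2))

    def test_missing_class_is_an_error(self):
        with pytest.raises(ValueError, match="apnea"):
            make_pairs(["non_apnea"] * 4)
        with pytest.raises(ValueError, match="non_apnea"):
            make_pairs(["apnea"] * 4)

    def test_same_seed_same_sequence(self):
        a = make_pairs(labels_of(4, 6), balance=True, seed=3)
        b = make_pairs(labels_of(4, 6), balance=True, seed=3)
        assert a == b

    def test_no_self_pairs(self):
        with pytest.raises(ValueError, match="same window"):
            PairSample(2, 2, 0)

    def test_sampled_epochs_are_exactly_balanced(self, rng):
        labels = np.array(labels_of(10, 30))
        pairs = sample_balanced_pairs(labels, 64, rng)
        assert sum(p.pair_label == 0 for p in pairs) == 32
        assert sum(p.pair_label == 1 for p in pairs) == 32


class TestDistanceAndLoss:
    def test_distance_examples(self):
        z = np.zeros(128)
        assert euclidean_distance(z, z) == 0.0
        v = z.copy()
        v[0], v[1] = 3.0, 4.0
        assert euclidean_distance(z, v) == 5.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_distance_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(16), r.standard_normal(16)
        assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_loss_examples(self):
        cfg = LossConfig(margin=2.0)
        assert contrastive_loss([0.0], [0], cfg) == 0.0
        assert contrastive_loss([2.5], [1], cfg) == 0.0
        assert contrastive_loss([0.5, 1.5], [0, 1], cfg) == pytest.approx(0.25)

    def test_loss_zero_iff_conditions_met(self):
        cfg = LossConfig(margin=2.0)
        # similar at zero distance, dissimilar beyond margin -> exactly zero
        assert contrastive_loss([0.0, 2.0, 3.1], [0, 1, 1], cfg) == 0.0
        assert contrastive_loss([1e-3, 2.0], [0, 1], cfg) > 0.0
        assert contrastive_loss([0.0, 1.99], [0, 1], cfg) > 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            contrastive_loss([-0.1], [1])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_vectorized_loss_matches_per_pair_summation(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 64))
        d = r.uniform(0, 4, n)
        y = r.integers(0, 2, n)
        m = float(r.uniform(0.5, 3))
        expected = sum((1 - yi) * di ** 2 + yi * max(0.0, m - di) ** 2
                       for di, yi in zip(d, y)) / n
        assert contrastive_loss(d, y, LossConfig(margin=m)) == pytest.approx(
            expected, rel=1e-9)


@pytest.fixture(scope="module")
def trained_tiny(tiny_feature_table):
    table = tiny_feature_table
    hp = CRNNHyperParams(kernel_size=(3, 3), n_conv_blocks=2, gru_hidden=32,
                         conv_channels=8)
    cfg = TrainingConfig(epochs=3, seed=0, pairs_per_epoch=128, batch_size=64)
    model = build_model(hp, table.values.shape[1:], seed=0)
    best, history = train_siamese(model, table.values, table.labels, cfg)
    return model, history, table, cfg


class TestTraining:
    def test_best_epoch_is_argmin_of_selection_criterion(self, trained_tiny):
        _, history, _, cfg = trained_tiny
        assert history["best_epoch"] == int(np.argmin(history["train_loss"]))

    def test_training_separates_pair_classes(self, trained_tiny, rng):
        """After metric learning, dissimilar pairs sit farther apart than
        similar pairs on freshly sampled held-out pairs."""
        model, _, table, _ = trained_tiny
        pairs = sample_balanced_pairs(table.labels, 128, rng)
        d = pair_distances(model, table.values, pairs)
        y = np.array([p.pair_label for p in pairs])
        assert d[y == 1].mean() > d[y == 0].mean()

    def test_shared_weights_give_identical_branch_embeddings(self, trained_tiny):
        model, _, table, _ = trained_tiny
        x = table.values[:1]
        both = embed(model, np.concatenate([x, x]))
        np.testing.assert_array_equal(both[0], both[1])

    def test_same_seed_reproduces_loss_history(self, tiny_feature_table):
        table = tiny_feature_table
        hp = CRNNHyperParams(kernel_size=(3, 3), n_conv_blocks=2, gru_hidden=32,
                             conv_channels=4)
        cfg = TrainingConfig(epochs=2, seed=7, pairs_per_epoch=64, batch_size=32)
        histories = []
        for _ in range(2):
            model = build_model(hp, table.values.shape[1:], seed=7)
            _, h = train_siamese(model, table.values, table.labels, cfg)
            histories.append(h["train_loss"])
        assert histories[0] == histories[1]

    def test_val_loss_selection_requires_validation_data(self, tiny_feature_table):
        table = tiny_feature_table
        hp = CRNNHyperParams(conv_channels=4, gru_hidden=32)
        model = build_model(hp, table.values.shape[1:], seed=0)
        cfg = TrainingConfig(epochs=1, selection_criterion="val_loss")
        with pytest.raises(ValueError, match="validation"):
            train_siamese(model, table.values, table.labels, cfg)
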