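"""Metrics against brute-force oracles, the CV protocol, training with
best-checkpoint selection, and grid search."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from milbind.bagcode import BagLayout
from milbind.fusion import FusionParams
from milbind.model import BagClassifier
from milbind.scorer import ModelSpec
from milbind.synthdata import SyntheticSpec, generate_dataset
from milbind.train_eval import (MetricError, TrainConfig, accuracy,
                                cross_validate, encode_for, evaluate, f1,
                                grid_search, pr_auc, roc_auc, split_cv,
                                train)


def pairwise_auc(labels, scores):
    """Independent oracle: fraction of concordant positive/negative
    pairs (ties get half credit)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_roc_auc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            scores = rng.permutation(n) / n  # distinct, tie-free
            assert roc_auc(labels, scores) == pytest.approx(
                pairwise_auc(labels, scores), abs=1e-9)

    def test_roc_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        base = roc_auc(labels, scores)
        assert roc_auc(labels, np.exp(3 * scores)) == pytest.approx(base)
        assert roc_auc(labels, np.log(scores + 1e-9)) == pytest.approx(base)

    def test_hand_computed_eight_item_example(self):
        # ranked by score: labels 1,0,1,1,0,0,1,0
        labels = [1, 0, 1, 1, 0, 0, 1, 0]
        scores = [0.95, 0.85, 0.8, 0.6, 0.55, 0.4, 0.3, 0.1]
        # concordant pairs: 4+3+3+1 = 11 of 16
        assert roc_auc(labels, scores) == pytest.approx(11 / 16, abs=1e-12)
        # average precision: positives at ranks 1,3,4,7 ->
        # (1/1 + 2/3 + 3/4 + 4/7) / 4
        expected_ap = (1 + 2 / 3 + 3 / 4 + 4 / 7) / 4
        assert pr_auc(labels, scores) == pytest.approx(expected_ap,
                                                       abs=1e-12)
        # argmax at 0.5: TP=3, FP=2, FN=1 -> P=3/5, R=3/4, F1=2/3
        predicted = [1 if s > 0.5 else 0 for s in scores]
        assert f1(labels, predicted) == pytest.approx(2 / 3, abs=1e-12)

    def test_perfect_separation(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.2, 0.8, 0.9]
        assert roc_auc(labels, scores) == 1.0
        assert pr_auc(labels, scores) == 1.0
        assert f1(labels, [0, 0, 1, 1]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])
        with pytest.raises(MetricError):
            pr_auc([0, 0], [0.1, 0.2])


class TestSplitCV:
    def test_24_bags_arithmetic(self):
        labels = np.array([0, 1] * 12)
        splits = split_cv(labels, folds=3, val_fraction=1 / 8, seed=0)
        assert len(splits) == 3
        for s in splits:
            assert len(s.test_idx) == 8
            assert len(s.val_idx) == 2
            assert len(s.fit_idx) == 14

    def test_partition_and_determinism(self):
        labels = np.array([0] * 20 + [1] * 10)
        a = split_cv(labels, seed=5)
        b = split_cv(labels, seed=5)
        all_test = np.concatenate([s.test_idx for s in a])
        assert sorted(all_test) == list(range(30))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.test_idx, sb.test_idx)
            np.testing.assert_array_equal(sa.fit_idx, sb.fit_idx)
            # fit / val / test are disjoint
            assert not set(sa.fit_idx) & set(sa.val_idx)
            assert not (set(sa.fit_idx) | set(sa.val_idx)) & set(sa.test_idx)

    def test_stratification_preserves_ratio(self):
        labels = np.array([0] * 30 + [1] * 15)
        for s in split_cv(labels, seed=1):
            ratio = labels[s.test_idx].mean()
            assert 0.2 <= ratio <= 0.47

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_cv(np.array([0, 1, 0, 1]), folds=3)


@pytest.fixture(scope="module")
def toy_training_setup():
    """A linearly separable toy problem: 50 motif-bearing positives vs
    50 background negatives, 60 bp."""
    synth = SyntheticSpec(l=60, n_pos=50, neg_ratio=1.0, seed=11,
                          occurrences=(1, 2))
    seqs, _ = generate_dataset(synth)
    layout = BagLayout(l=60, c=36, s=12, k=1)
    spec = ModelSpec.for_variant("WSCNNLSTM", dropout_ratio=0.1)
    bags, labels, _ = encode_for(spec, layout, seqs)
    return spec, layout, bags, labels


class TestTrain:
    def test_toy_problem_reaches_perfect_training_accuracy(
            self, toy_training_setup):
        spec, layout, bags, labels = toy_training_setup
        config = replace(TrainConfig.desk(seed=3), epochs=60,
                         track_train_accuracy=True)
        model = BagClassifier(spec, layout, rng=np.random.default_rng(3))
        result = train(model, bags[:88], labels[:88], bags[88:],
                       labels[88:], config)
        assert result.history["train_accuracy"].max() == 1.0

    def test_history_length_and_checkpoint_restoration(
            self, toy_training_setup):
        spec, layout, bags, labels = toy_training_setup
        config = replace(TrainConfig.desk(seed=0), epochs=5)
        model = BagClassifier(spec, layout, rng=np.random.default_rng(0))
        result = train(model, bags[:88], labels[:88], bags[88:],
                       labels[88:], config)
        assert len(result.history) == 5
        assert result.best_epoch == \
            int(result.history["val_accuracy"].idxmax())
        # the restored model reproduces the logged best accuracy exactly
        restored_acc = accuracy(labels[88:], model.predict(bags[88:]))
        assert restored_acc == result.best_val_accuracy

    def test_zero_epochs_rejected(self, toy_training_setup):
        spec, layout, bags, labels = toy_training_setup
        config = replace(TrainConfig.desk(), epochs=0)
        model = BagClassifier(spec, layout, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            train(model, bags[:88], labels[:88], bags[88:], labels[88:],
                  config)

    def test_same_seed_reproduces_training(self, toy_training_setup):
        spec, layout, bags, labels = toy_training_setup
        config = replace(TrainConfig.desk(seed=9), epochs=3)
        histories = []
        for _ in range(2):
            model = BagClassifier(spec, layout,
                                  rng=np.random.default_rng(9))
            r = train(model, bags[:88], labels[:88], bags[88:],
                      labels[88:], config)
            histories.append(r.history)
        pd.testing.assert_frame_equal(histories[0], histories[1])


class TestGridSearch:
    def test_single_point_grid(self, toy_training_setup):
        spec, layout, bags, labels = toy_training_setup
        config = replace(TrainConfig.desk(seed=0), epochs=2)
        splits = split_cv(labels, seed=0)
        best, table = grid_search(spec, layout, FusionParams(), bags,
                                  labels, splits[0], config)
        assert len(table) == 1
        assert best["dropout_ratio"] == config.dropout_grid[0]
        assert best["momentum"] == config.momentum_grid[0]

    def test_full_grid_enumerates_all_points(self, toy_training_setup):
        spec, layout, bags, labels = toy_training_setup
        config = replace(TrainConfig(seed=0), epochs=1, batch_size=50)
        splits = split_cv(labels, seed=0)
        best, table = grid_search(spec, layout, FusionParams(), bags,
                                  labels, splits[0], config)
        assert len(table) == 27  # 3 dropout x 3 momentum x 3 delta
        assert (best["dropout_ratio"], best["momentum"], best["delta"]) in \
            set(zip(table.dropout_ratio, table.momentum, table.delta))
        # argmax with earliest-tie rule
        top = table.val_accuracy.max()
        first_top = table[table.val_accuracy == top].iloc[0]
        assert best["val_accuracy"] == top
        assert (first_top[["dropout_ratio", "momentum", "delta"]] ==
                pd.Series(best)[["dropout_ratio", "momentum", "delta"]]).all()


class TestCrossValidate:
    def test_toy_separable_cv(self):
        synth = SyntheticSpec(l=60, n_pos=100, neg_ratio=1.0, seed=21,
                              occurrences=(2, 3))
        seqs, _ = generate_dataset(synth)
        layout = BagLayout(l=60, c=36, s=12, k=1)
        spec = ModelSpec.for_variant("WSCNNLSTM", dropout_ratio=0.1)
        config = replace(TrainConfig.desk(seed=2), epochs=40)
        frame = cross_validate(spec, layout, FusionParams(), seqs, config)
        assert len(frame) == 4  # 3 folds + mean
        assert list(frame["fold"])[:3] == [0, 1, 2]
        assert frame["fold"].iloc[-1] == "mean"
        mean_auc = frame[frame["fold"] == "mean"]["roc_auc"].iloc[0]
        assert mean_auc >= 0.95
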