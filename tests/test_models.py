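"""Scorer training, selection protocol, thresholding, serialization."""

import numpy as np
import pytest

from pocketforge.errors import ParameterError, TrainingError
from pocketforge.features import FeatureMatrix
from pocketforge.models import (
    PRESET_NN_B,
    HyperParams,
    grid_search,
    load_scorer,
    save_scorer,
    score_pocket,
    score_pockets,
    select_threshold,
    train_scorer,
)


def make_matrices(n, n_rows=6, n_features=8, shift=2.0, seed=0, feature_set="B"):
    """Half positives (mean-shifted along a fixed direction), half negatives."""
    # the signal direction is a fixed property of the synthetic task,
    # shared by train and validation draws
    direction = np.random.default_rng(12345).standard_normal(n_features)
    direction /= np.linalg.norm(direction)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = i % 2
        values = rng.standard_normal((n_rows, n_features))
        if label:
            values = values + shift * direction
        out.append(
            FeatureMatrix(values=values, feature_set=feature_set,
                          n_rows=n_rows, label=label)
        )
    return out


@pytest.fixture(scope="module")
def separable_sets():
    return make_matrices(400, seed=1), make_matrices(100, seed=2)


class TestTrainScorer:
    @pytest.mark.parametrize("kind", ["lr", "nn", "cnn"])
    def test_separable_data_high_val_auroc(self, separable_sets, kind):
        train, val = separable_sets
        hp = HyperParams(model_kind=kind, learning_rate=0.01, filter_size=2,
                         pool_size=2, hidden_width=32)
        scorer, history = train_scorer(train, val, hp, epochs=10, seed=0)
        assert max(history.val_auroc) >= 0.95
        scores = score_pockets(scorer, val)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_shuffled_labels_near_chance(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            train = make_matrices(300, shift=2.0, seed=seed)
            for m in train:  # break the feature-label link
                m.label = int(rng.integers(2))
            val = make_matrices(200, shift=0.0, seed=100 + seed)
            _, history = train_scorer(
                train, val, HyperParams("nn", hidden_width=32), epochs=5,
                seed=seed,
            )
            aucs.append(history.val_auroc[-1])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_same_seed_identical_history(self, separable_sets):
        train, val = separable_sets
        hp = HyperParams("nn", hidden_width=16)
        _, h1 = train_scorer(train, val, hp, epochs=3, seed=7)
        _, h2 = train_scorer(train, val, hp, epochs=3, seed=7)
        assert h1.val_auroc == h2.val_auroc
        assert h1.train_loss == h2.train_loss
        assert h1.best_epoch == h2.best_epoch

    def test_auroc_recovers_with_signal_strength(self):
        """Chance at zero shift, monotone improvement (within noise) as the
        class separation grows."""
        aucs = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            train = make_matrices(400, shift=shift, seed=3)
            val = make_matrices(200, shift=shift, seed=4)
            _, hist = train_scorer(
                train, val,
                HyperParams("nn", learning_rate=0.01, hidden_width=32),
                epochs=6, seed=0,
            )
            aucs.append(max(hist.val_auroc))
        assert 0.4 <= aucs[0] <= 0.6
        assert aucs[3] > aucs[1] > aucs[0] - 0.05
        assert aucs[3] >= 0.95

    def test_shape_mismatch_rejected(self, separable_sets):
        train, _ = separable_sets
        bad_val = make_matrices(10, n_rows=5)
        with pytest.raises(TrainingError):
            train_scorer(train, bad_val, HyperParams("nn"))

    def test_empty_sets_rejected(self, separable_sets):
        train, _ = separable_sets
        with pytest.raises(TrainingError):
            train_scorer(train, [], HyperParams("lr"))


class TestLogisticRegression:
    def test_monotone_in_a_positive_weight_feature(self):
        # 1-feature LR: a positive class sitting at larger feature values
        # must yield a positive weight, hence monotone scores
        rng = np.random.default_rng(0)
        mats = []
        for i in range(200):
            label = i % 2
            v = rng.normal(3.0 if label else -3.0, 1.0, size=(1, 1))
            mats.append(FeatureMatrix(v, "A", 1, label=label))
        scorer, _ = train_scorer(mats[:150], mats[150:], HyperParams("lr"))
        lo = score_pocket(scorer, FeatureMatrix(np.array([[-5.0]]), "A", 1))
        mid = score_pocket(scorer, FeatureMatrix(np.array([[0.0]]), "A", 1))
        hi = score_pocket(scorer, FeatureMatrix(np.array([[5.0]]), "A", 1))
        assert lo < mid < hi
        # closed form: score(0) = sigmoid(b)
        b = scorer.params["b"][0]
        assert mid == pytest.approx(1 / (1 + np.exp(-b)), abs=1e-9)

    @pytest.mark.parametrize("penalty", ["none", "l1", "l2", "elasticnet"])
    def test_all_penalties_train(self, penalty, separable_sets):
        train, val = separable_sets
        hp = HyperParams("lr", penalty=penalty, reg_weight=1.0)
        scorer, hist = train_scorer(train[:100], val[:50], hp)
        assert hist.val_auroc[0] > 0.9


class TestScoring:
    def test_batch_equals_single(self, separable_sets):
        train, val = separable_sets
        scorer, _ = train_scorer(
            train, val, HyperParams("nn", hidden_width=16), epochs=2, seed=0
        )
        batch = score_pockets(scorer, val[:10])
        singles = [score_pocket(scorer, m) for m in val[:10]]
        assert np.allclose(batch, singles, atol=1e-6)

    def test_all_zero_matrix_is_legal(self, separable_sets):
        train, val = separable_sets
        scorer, _ = train_scorer(train, val, HyperParams("lr"))
        s = score_pocket(scorer, FeatureMatrix(np.zeros((6, 8)), "B", 6))
        assert 0.0 <= s <= 1.0

    def test_shape_mismatch(self, separable_sets):
        train, val = separable_sets
        scorer, _ = train_scorer(train, val, HyperParams("lr"))
        with pytest.raises(ParameterError):
            score_pocket(scorer, FeatureMatrix(np.zeros((3, 3)), "B", 3))


class TestGridSearch:
    def test_single_config_returned(self, separable_sets):
        train, val = separable_sets
        grid = [HyperParams("lr")]
        best, report = grid_search(train[:60], val[:40], grid, seeds=(0,))
        assert best is grid[0]
        assert len(report) == 1

    def test_dominant_config_wins_and_report_shape(self, separable_sets):
        train, val = separable_sets
        grid = [
            HyperParams("nn", learning_rate=0.0, hidden_width=8),  # can't learn
            HyperParams("nn", learning_rate=0.01, hidden_width=32),
        ]
        best, report = grid_search(
            train[:120], val[:60], grid, seeds=(0, 1, 2), epochs=3
        )
        assert best is grid[1]
        assert len(report) == 2
        assert {"config", "mean_val_auroc", "sd_val_auroc"} <= set(report[0])


class TestThreshold:
    def _mats(self, scores_labels):
        # degenerate 1x1 "identity" matrices so LR maps feature -> score
        return [
            FeatureMatrix(np.array([[s]]), "A", 1, label=l)
            for s, l in scores_labels
        ]

    def test_perfectly_separated(self):
        mats = self._mats([(10.0, 1), (-10.0, 0)] * 10)
        scorer, _ = train_scorer(mats, mats, HyperParams("lr"))
        t = select_threshold(scorer, mats)
        scores = score_pockets(scorer, mats)
        labels = np.array([m.label for m in mats])
        # the candidate maximizing TPR-FPR is the smallest positive score
        assert t == pytest.approx(scores[labels == 1].min())
        # at t all positives score >= t, all negatives < t
        assert np.all(scores[labels == 1] >= t)
        assert np.all(scores[labels == 0] < t)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(0)
        mats = self._mats(
            [(float(rng.normal(2 * l, 1)), l) for l in rng.integers(0, 2, 50)]
        )
        scorer, _ = train_scorer(mats, mats, HyperParams("lr"))
        t1 = select_threshold(scorer, mats)
        t2 = select_threshold(scorer, mats + mats)
        assert t1 == pytest.approx(t2)

    def test_anticorrelated_warns(self):
        mats = self._mats([(-5.0, 1), (5.0, 0)] * 5)
        # train on the TRUE relation, then flip the validation labels
        scorer, _ = train_scorer(mats, mats, HyperParams("lr"))
        flipped = self._mats([(-5.0, 0), (5.0, 1)] * 5)
        with pytest.warns(UserWarning, match="anti-correlated|uninformative"):
            select_threshold(scorer, flipped)

    def test_single_class_rejected(self):
        mats = self._mats([(1.0, 1), (2.0, 1)])
        scorer, _ = train_scorer(
            self._mats([(1.0, 1), (-1.0, 0)] * 3), mats[:1] + self._mats([(0.0, 0)]),
            HyperParams("lr"),
        )
        with pytest.raises(ParameterError):
            select_threshold(scorer, mats)


class TestSerialization:
    @pytest.mark.parametrize("kind", ["lr", "nn", "cnn"])
    def test_roundtrip_identical_scores(self, tmp_path, separable_sets, kind):
        train, val = separable_sets
        hp = HyperParams(model_kind=kind, filter_size=2, pool_size=2,
                         hidden_width=16)
        scorer, _ = train_scorer(train[:100], val[:40], hp, epochs=2, seed=1)
        select_threshold(scorer, val[:40])
        save_scorer(scorer, tmp_path / "model")
        back = load_scorer(tmp_path / "model")
        assert back.threshold_t == scorer.threshold_t
        assert back.hyperparams == scorer.hyperparams
        a = score_pockets(scorer, val[:20])
        b = score_pockets(back, val[:20])
        assert np.allclose(a, b, atol=1e-6)
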