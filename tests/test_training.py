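"""Training-loop mechanics: subsampling, splitting, checkpointing, stopping."""

import numpy as np
import pytest

from rippnet.encoding import encode_batch
from rippnet.io import PeptideRecord, PeptideSet
from rippnet.models import build_model
from rippnet.training import (
    AccuracyReport,
    TrainingConfig,
    evaluate_arrays,
    majority_baseline,
    split_train_heldout,
    subsample_negatives,
    train_arrays,
)


def _random_set(n, label, seed=0, length=25):
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    return PeptideSet(
        records=[
            PeptideRecord(id=f"{label}_{i}", sequence="".join(rng.choice(alphabet, size=length)), label=label)
            for i in range(n)
        ]
    )


class TestSubsampleNegatives:
    def test_curated_corpus_arithmetic(self):
        # floor(0.35 x 19224) negatives plus the 2726 positives per cycle
        assert int(np.floor(0.35 * 19224)) == 6728
        assert 6728 + 2726 == 9454

    def test_floor_size_and_membership(self):
        negatives = _random_set(10, 0)
        out = subsample_negatives(negatives, 0.35, np.random.default_rng(0))
        assert len(out) == 3
        pool = {r.id for r in negatives}
        assert all(r.id in pool for r in out)

    def test_deterministic_given_state(self):
        negatives = _random_set(200, 0)
        draws = []
        for seed in range(20):
            a = subsample_negatives(negatives, 0.35, np.random.default_rng(seed))
            b = subsample_negatives(negatives, 0.35, np.random.default_rng(seed))
            assert [r.id for r in a] == [r.id for r in b]
            draws.append(tuple(r.id for r in a))
        assert len(set(draws)) > 1

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            subsample_negatives(_random_set(2, 0), 0.1, np.random.default_rng(0))


class TestSplit:
    def test_stratified_85_15(self):
        X = np.zeros((100, 20, 120))
        y = np.array([1] * 20 + [0] * 80)
        (trX, trY), (heX, heY) = split_train_heldout(X, y, 0.85, np.random.default_rng(0))
        assert len(trX) + len(heX) == 100
        assert (trY == 1).sum() == 17
        assert (heY == 1).sum() == 3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_train_heldout(np.zeros((10, 1)), np.ones(10), 0.85, np.random.default_rng(0))

    def test_class_ratio_preserved_within_one_record(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(20, 300))
            n_pos = int(rng.integers(2, n - 2))
            y = np.array([1] * n_pos + [0] * (n - n_pos))
            X = np.zeros((n, 1))
            frac = float(rng.uniform(0.5, 0.95))
            (trX, trY), (heX, heY) = split_train_heldout(X, y, frac, rng)
            for cls in (0, 1):
                total = (y == cls).sum()
                in_train = (trY == cls).sum()
                assert abs(in_train - frac * total) <= 1.0


class TestEvaluate:
    def test_always_negative_classifier_scores_majority_rate(self):
        # degenerate scorer: P(positive) = 0 everywhere
        report = AccuracyReport(
            n_positive=2726, n_negative=19224, correct_positive=0, correct_negative=19224
        )
        assert report.total_accuracy == pytest.approx(19224 / 21950)
        assert f"{100 * report.total_accuracy:.1f}" == "87.6"

    def test_counting_matches_brute_force(self):
        rng = np.random.default_rng(1)
        model = build_model("cnn_linear", seed=1)
        X, y = encode_batch(_random_set(30, 1, seed=2))
        for _ in range(10):
            labels = rng.integers(0, 2, size=30)
            report = evaluate_arrays(model, X, labels)
            calls = (model.predict_proba(X)[:, 1] > 0.5).astype(int)
            correct = sum(int(c == t) for c, t in zip(calls, labels))
            assert report.correct_positive + report.correct_negative == correct
            assert report.n_positive == (labels == 1).sum()
            assert report.total_accuracy == pytest.approx(correct / 30)


class TestMajorityBaseline:
    @pytest.mark.parametrize(
        "pos,neg,expected", [(2726, 19224, 19224 / 21950), (5, 5, 0.5), (0, 7, 1.0)]
    )
    def test_values(self, pos, neg, expected):
        assert majority_baseline(pos, neg) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            majority_baseline(0, 0)


@pytest.fixture(scope="module")
def tiny_run():
    pos = _random_set(24, 1, seed=1)
    neg = _random_set(48, 0, seed=2)
    X_pos, _ = encode_batch(pos)
    X_neg, _ = encode_batch(neg)
    model = build_model("cnn_linear", seed=3)
    config = TrainingConfig(seed=3, max_rounds=12, patience=12, resample_interval=5)
    model, history = train_arrays(model, X_pos, X_neg, config)
    return model, history, config


class TestTrainLoop:

    def test_resample_cadence(self, tiny_run):
        _, history, config = tiny_run
        resampled = [r.round for r in history.rounds if r.resampled]
        expected = list(range(1, len(history.rounds) + 1, config.resample_interval))
        assert resampled == expected

    def test_checkpoint_sequence_strictly_increasing(self, tiny_run):
        _, history, _ = tiny_run
        ckpts = [r.heldout_accuracy for r in history.rounds if r.checkpointed]
        assert ckpts == sorted(set(ckpts))
        assert history.best_accuracy == max(r.heldout_accuracy for r in history.rounds)
        assert history.stop_reason in ("patience", "max_rounds")

    def test_best_weights_reproduce_best_accuracy(self, tiny_run):
        model, history, _ = tiny_run
        held_X, held_y = history.best_heldout
        calls = (model.predict_proba(held_X)[:, 1] > 0.5).astype(int)
        assert np.mean(calls == held_y) == pytest.approx(history.best_accuracy)

    def test_identical_config_identical_history(self, tiny_run):
        _, history, config = tiny_run
        X_pos, _ = encode_batch(_random_set(24, 1, seed=1))
        X_neg, _ = encode_batch(_random_set(48, 0, seed=2))
        model = build_model("cnn_linear", seed=3)
        _, history2 = train_arrays(model, X_pos, X_neg, config)
        assert history2.log_lines() == history.log_lines()

    def test_patience_one_stops_immediately_after_perfect_round(self):
        # separable by construction: positives all-A, negatives all-C
        pos = PeptideSet(records=[PeptideRecord(id=f"p{i}", sequence="A" * 30, label=1) for i in range(8)])
        neg = PeptideSet(records=[PeptideRecord(id=f"n{i}", sequence="C" * 30, label=0) for i in range(16)])
        X_pos, _ = encode_batch(pos)
        X_neg, _ = encode_batch(neg)
        model = build_model("cnn_linear", seed=0)
        config = TrainingConfig(seed=0, max_rounds=30, patience=1)
        model, history = train_arrays(model, X_pos, X_neg, config)
        if history.rounds[0].heldout_accuracy == 1.0:
            assert len(history.rounds) == 2
        assert history.stop_reason == "patience"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(negative_subsample_fraction=1.5)
        with pytest.raises(ValueError):
            TrainingConfig(patience=300, max_rounds=200)
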