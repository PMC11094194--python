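import numpy as np
import pytest

from sprde.ensemble import (
    BoostConfig,
    EnsembleModel,
    TrainingFailureError,
    TrainingSet,
    WeakLearner,
    learner_weight,
    predict,
    train,
    update_weights,
    weighted_error,
)


def _toy_separable(n=40, seed=3):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-3, 0.3, (n // 2, 5)), rng.normal(3, 0.3, (n // 2, 5))])
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    return X, y


class TestLearnerWeight:
    def test_vanishes_at_chance(self):
        assert learner_weight(0.5 - 1e-15) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        assert learner_weight(0.2) == pytest.approx(0.5 * np.log(4), abs=1e-12)

    def test_perfect_learner_hits_floor(self):
        w = learner_weight(0.0)
        assert np.isfinite(w)
        assert w == pytest.approx(0.5 * np.log((1 - 1e-10) / 1e-10))

    def test_at_or_above_chance_rejected(self):
        with pytest.raises(ValueError):
            learner_weight(0.5)

    def test_strictly_decreasing_in_error(self):
        eps = np.linspace(0.01, 0.49, 25)
        weights = [learner_weight(e) for e in eps]
        assert all(a > b for a, b in zip(weights, weights[1:]))


class TestWeightedError:
    def test_perfect_learner(self):
        ts = TrainingSet(np.zeros((4, 2)), [1, 1, -1, -1])
        assert weighted_error(np.array([1, 1, -1, -1]), ts) == 0.0

    def test_constant_prediction_on_balanced_uniform(self):
        ts = TrainingSet(np.zeros((4, 2)), [1, 1, -1, -1])
        assert weighted_error(np.array([1, 1, 1, 1]), ts) == pytest.approx(0.5)

    def test_matches_accumulation_loop(self, rng):
        n = 30
        y = rng.choice([-1, 1], n)
        y[:2] = [1, -1]
        w = rng.uniform(0.1, 1.0, n)
        w /= w.sum()
        ts = TrainingSet(np.zeros((n, 2)), y, w)
        pred = rng.choice([-1, 1], n)
        total = sum(w[i] for i in range(n) if pred[i] != y[i])
        assert weighted_error(pred, ts) == pytest.approx(total, abs=1e-14)


class TestUpdateWeights:
    def test_neutral_learner_leaves_weights(self):
        ts = TrainingSet(np.zeros((4, 2)), [1, 1, -1, -1])
        out = update_weights(ts, np.array([1, -1, 1, -1]), alpha=0.0)
        np.testing.assert_allclose(out, ts.weights)

    def test_all_correct_renormalizes_to_original(self):
        ts = TrainingSet(np.zeros((4, 2)), [1, 1, -1, -1])
        out = update_weights(ts, np.array([1, 1, -1, -1]), alpha=0.7)
        np.testing.assert_allclose(out, ts.weights)

    def test_four_sample_hand_oracle(self):
        y = np.array([1, 1, -1, -1])
        pred = np.array([1, -1, -1, 1])  # samples 1 and 3 wrong
        ts = TrainingSet(np.zeros((4, 2)), y)
        out = update_weights(ts, pred, alpha=0.5)
        raw = 0.25 * np.exp(-0.5 * y * pred)
        np.testing.assert_allclose(out, raw / raw.sum(), atol=1e-15)
        assert out[1] > 0.25 and out[3] > 0.25
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_misclassified_mass_is_half_after_update(self, rng):
        n = 50
        y = rng.choice([-1, 1], n)
        y[:2] = [1, -1]
        pred = y.copy()
        wrong = rng.choice(n, 12, replace=False)
        pred[wrong] *= -1
        w = rng.uniform(0.5, 2.0, n)
        w /= w.sum()
        ts = TrainingSet(np.zeros((n, 2)), y, w)
        eps = weighted_error(pred, ts)
        out = update_weights(ts, pred, learner_weight(eps))
        assert out[pred != y].sum() == pytest.approx(0.5, abs=1e-10)


class TestTrain:
    def test_separable_toy_stops_after_one_round(self):
        X, y = _toy_separable()
        model = train(TrainingSet(X, y), BoostConfig(seed=0))
        assert len(model.learners) == 1
        assert model.learners[0].eps == 0.0
        assert model.trace[-1]["train_error"] == 0.0

    def test_contradictory_labels_fail(self):
        X, y = _toy_separable(n=20)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, -y])  # every sample duplicated with both labels
        with pytest.raises(TrainingFailureError):
            train(TrainingSet(X2, y2), BoostConfig(seed=0))

    def test_weights_stay_on_simplex_and_mass_identity(self, rng):
        # overlapped classes so boosting runs several rounds
        n = 120
        X = np.vstack([rng.normal(-0.6, 1.0, (n // 2, 4)),
                       rng.normal(0.6, 1.0, (n // 2, 4))])
        y = np.array([-1] * (n // 2) + [1] * (n // 2))
        model = train(TrainingSet(X, y), BoostConfig(seed=1, T_iters=10))
        assert len(model.learners) > 1
        weights = np.full(n, 1.0 / n)
        for learner in model.learners:
            pred = learner.predict(X)
            eps = float(weights[pred != y].sum())
            assert eps == pytest.approx(learner.eps, abs=1e-12)
            weights = update_weights(TrainingSet(X, y, weights), pred, learner.alpha)
            assert weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert (weights >= 0).all()
            if learner.eps > 0:
                assert weights[pred != y].sum() == pytest.approx(0.5, abs=1e-10)

    def test_training_error_trace_reaches_zero_on_seeded_fixture(self):
        rng = np.random.default_rng(42)
        n = 200
        X = np.vstack([rng.normal(-1.0, 1.0, (n // 2, 8)),
                       rng.normal(1.0, 1.0, (n // 2, 8))])
        y = np.array([-1] * (n // 2) + [1] * (n // 2))
        model = train(TrainingSet(X, y), BoostConfig(seed=2))
        errors = [step["train_error"] for step in model.trace]
        assert errors[-1] <= errors[0]
        assert min(errors) == errors[-1]

    def test_deterministic_given_seed(self):
        X, y = _toy_separable(n=30, seed=9)
        m1 = train(TrainingSet(X, y), BoostConfig(seed=5))
        m2 = train(TrainingSet(X, y), BoostConfig(seed=5))
        assert m1.to_json() == m2.to_json()


class TestPredict:
    def _stub(self, vote, alpha):
        # single support vector at the origin with zero dual coefficient:
        # the decision is the intercept, i.e. a constant vote
        return WeakLearner(support_vectors=np.zeros((1, 2)),
                           dual_coef=np.zeros(1), intercept=float(vote),
                           gamma=1.0, C=1.0, alpha=alpha)

    def test_single_learner_passthrough(self):
        model = EnsembleModel(learners=[self._stub(-1.0, alpha=0.8)])
        assert predict(model, np.zeros((3, 2))).tolist() == [-1, -1, -1]

    def test_tie_resolves_to_supine(self):
        model = EnsembleModel(learners=[self._stub(1.0, 0.5), self._stub(-1.0, 0.5)])
        assert predict(model, np.zeros((2, 2))).tolist() == [1, 1]

    def test_matches_vote_count_loop(self, rng):
        votes = rng.choice([-1.0, 1.0], size=6)
        alphas = rng.uniform(0.1, 1.0, size=6)
        model = EnsembleModel(learners=[self._stub(v, a) for v, a in zip(votes, alphas)])
        X = rng.normal(size=(10, 2))
        expected_score = sum(a * v for a, v in zip(alphas, votes))
        expected = 1 if expected_score >= 0 else -1
        assert (predict(model, X) == expected).all()

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="empty ensemble"):
            predict(EnsembleModel(), np.zeros((1, 2)))


def test_json_roundtrip_preserves_predictions(tmp_path, rng):
    X, y = _toy_separable(n=30, seed=11)
    model = train(TrainingSet(X, y), BoostConfig(seed=0))
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = EnsembleModel.from_json(path)
    Xq = rng.normal(0, 3, (25, 5))
    np.testing.assert_array_equal(predict(model, Xq), predict(loaded, Xq))
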