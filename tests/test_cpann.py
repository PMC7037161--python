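import numpy as np
import pytest

from cpanntox.cpann import (
    CpannModel,
    TrainConfig,
    balanced_subsample,
    predict,
    train_cpann,
)
from cpanntox.som import LearningSchedule, SomGrid


class TestBalancedSubsample:
    def test_study_composition_yields_216(self):
        labels = np.concatenate([np.ones(108, int), np.zeros(296, int)])
        idx = balanced_subsample(labels, np.random.default_rng(0))
        assert len(idx) == 216
        assert int(labels[idx].sum()) == 108
        assert len(set(idx.tolist())) == 216  # without repetition

    def test_already_balanced_returns_everything(self):
        labels = np.array([1] * 5 + [0] * 5)
        idx = balanced_subsample(labels, np.random.default_rng(1))
        assert sorted(idx.tolist()) == list(range(10))

    def test_majority_draw_is_uniform_over_epochs(self):
        """Each majority object appears with frequency ~ minority/majority."""
        labels = np.array([1] * 3 + [0] * 10)
        rng = np.random.default_rng(2)
        hits = np.zeros(13)
        n_draws = 4000
        for _ in range(n_draws):
            idx = balanced_subsample(labels, rng)
            assert len(idx) == 6
            assert sorted(idx[:3].tolist()) == [0, 1, 2]
            assert len(set(idx.tolist())) == 6
            hits[idx] += 1
        freq = hits[3:] / n_draws
        np.testing.assert_allclose(freq, 0.3, atol=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_subsample(np.ones(5, int), np.random.default_rng(0))


def _simple_config(**kw):
    defaults = dict(grid_shape=(2, 1), schedule=LearningSchedule(epochs=60), seed=0)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTrainCpann:
    def test_single_object_output_fixed_point(self):
        X = np.array([[0.2, 0.8]])
        m = train_cpann(X, np.array([1]),
                        _simple_config(grid_shape=(1, 1),
                                       schedule=LearningSchedule(epochs=200)))
        assert m.output_weights[0, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_two_opposite_objects_claim_their_neurons(self):
        # neighborhood cross-talk decays with the radius, so a long horizon
        # is needed before each output weight settles near its own label
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        y = np.array([0, 1])
        m = train_cpann(X, y, _simple_config(schedule=LearningSchedule(epochs=300)))
        _, classes, winners = predict(m, X)
        assert winners[0] != winners[1]
        for i in range(2):
            assert abs(m.output_weights[winners[i]][0] - y[i]) < 0.1
        np.testing.assert_array_equal(classes, y)

    def test_every_epoch_exactly_balanced(self):
        """In balanced-subsample mode each epoch's class ratio is exactly 1:1."""
        rng = np.random.default_rng(3)
        y = np.concatenate([np.ones(12, int), np.zeros(40, int)])
        X = rng.standard_normal((52, 3))
        log: list[np.ndarray] = []
        train_cpann(X, y, _simple_config(grid_shape=(3, 3), mode="balanced_subsample",
                                         schedule=LearningSchedule(epochs=15)),
                    epoch_log=log)
        assert len(log) == 15
        draws = set()
        for idx in log:
            assert len(idx) == 24
            assert int(y[idx].sum()) == 12
            assert len(set(idx.tolist())) == 24
            draws.add(tuple(sorted(int(i) for i in idx if y[i] == 0)))
        assert len(draws) > 1  # a fresh majority draw per epoch

    def test_output_weights_stay_in_unit_interval(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 4))
        y = (rng.random(30) < 0.4).astype(int)
        m = train_cpann(X, y, _simple_config(grid_shape=(4, 4),
                                             schedule=LearningSchedule(epochs=10)))
        assert m.output_weights.min() >= 0.0
        assert m.output_weights.max() <= 1.0

    def test_winner_search_ignores_output_layer(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 3))
        y = (rng.random(25) < 0.5).astype(int)
        m = train_cpann(X, y, _simple_config(grid_shape=(3, 3),
                                             schedule=LearningSchedule(epochs=8)))
        _, _, winners = predict(m, X)
        m.output_weights[:] = 0.5 + 1e-9 * np.arange(m.output_weights.size).reshape(
            m.output_weights.shape)
        _, _, corrupted = predict(m, X)
        assert winners == corrupted

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 5))
        y = (rng.random(40) < 0.3).astype(int)
        cfg = _simple_config(grid_shape=(4, 4), mode="balanced_subsample",
                             schedule=LearningSchedule(epochs=12), seed=9)
        m1 = train_cpann(X, y, cfg)
        m2 = train_cpann(X, y, cfg)
        np.testing.assert_array_equal(m1.grid.weights, m2.grid.weights)
        np.testing.assert_array_equal(m1.output_weights, m2.output_weights)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            train_cpann(np.zeros((3, 2)), np.array([0, 1, 2]), _simple_config())
        with pytest.raises(ValueError):
            train_cpann(np.array([[np.nan, 0.0]]), np.array([1]), _simple_config())


class TestPredict:
    def hand_built_model(self):
        # 2x2 grid in 2-D with output weights 0.9 / 0.1 / 0.8 / 0.2
        kw = np.array([[[0.0, 0.0], [1.0, 0.0]], [[0.0, 1.0], [1.0, 1.0]]])
        out = np.array([[[0.9], [0.1]], [[0.8], [0.2]]])
        return CpannModel(
            grid=SomGrid(kw), output_weights=out,
            descriptor_names=["d1", "d2"],
            norm_mean=np.zeros(2), norm_sd=np.ones(2),
            config=TrainConfig(grid_shape=(2, 2)),
        )

    def test_query_near_low_output_neuron(self):
        m = self.hand_built_model()
        scores, classes, winners = predict(m, np.array([[0.95, 0.05]]))
        assert winners[0] == (0, 1)
        assert scores[0] == pytest.approx(0.1)
        assert classes[0] == 0

    def test_score_at_threshold_is_toxic(self):
        m = self.hand_built_model()
        m.output_weights[0, 0, 0] = 0.5
        _, classes, _ = predict(m, np.array([[0.0, 0.0]]))
        assert classes[0] == 1

    def test_missing_descriptor_column_rejected(self):
        import pandas as pd

        m = self.hand_built_model()
        with pytest.raises(KeyError):
            predict(m, pd.DataFrame({"d1": [0.1], "other": [0.2]}))

    def test_normalization_applied_internally(self):
        m = self.hand_built_model()
        m.norm_mean = np.array([10.0, 10.0])
        m.norm_sd = np.array([2.0, 2.0])
        # raw (11.9, 10.1) -> z = (0.95, 0.05) -> the 0.1-neuron
        scores, _, _ = predict(m, np.array([[11.9, 10.1]]))
        assert scores[0] == pytest.approx(0.1)


class TestSerialization:
    def test_json_round_trip_bit_exact(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 3))
        y = (rng.random(20) < 0.5).astype(int)
        m = train_cpann(X, y, _simple_config(grid_shape=(3, 2),
                                             schedule=LearningSchedule(epochs=5)),
                        descriptor_names=["a", "b", "c"],
                        norm_mean=X.mean(0), norm_sd=X.std(0, ddof=1))
        m2 = CpannModel.from_json(m.to_json())
        np.testing.assert_array_equal(m.grid.weights, m2.grid.weights)
        np.testing.assert_array_equal(m.output_weights, m2.output_weights)
        np.testing.assert_array_equal(m.norm_mean, m2.norm_mean)
        assert m.descriptor_names == m2.descriptor_names
        assert m.config == m2.config
        assert set(m.training_distances) == set(m2.training_distances)
        for k in m.training_distances:
            np.testing.assert_array_equal(m.training_distances[k],
                                          m2.training_distances[k])
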