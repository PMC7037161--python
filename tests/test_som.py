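import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpanntox.som import (
    LearningSchedule,
    NeighborhoodState,
    SomGrid,
    find_winner,
    learning_rate,
    neighborhood_factor,
    top_map,
    train_som,
    update_weights,
)


class TestLearningRate:
    @pytest.mark.parametrize(
        "t, t_max, v_min, v_max, expected",
        [
            (1, 100, 0.01, 0.5, 0.5),     # first iteration hits v_max
            (100, 100, 0.01, 0.5, 0.01),  # last iteration hits v_min
            (50, 99, 0.0, 1.0, 0.5),      # midpoint of a symmetric schedule
        ],
    )
    def test_schedule_values(self, t, t_max, v_min, v_max, expected):
        sched = LearningSchedule(v_max=v_max, v_min=v_min, epochs=1, t_max=t_max)
        assert learning_rate(t, sched) == pytest.approx(expected)

    def test_single_iteration_schedule_returns_v_max(self):
        sched = LearningSchedule(v_max=0.4, v_min=0.1, epochs=1, t_max=1)
        assert learning_rate(1, sched) == 0.4

    def test_out_of_range_iteration_rejected(self):
        sched = LearningSchedule(t_max=10)
        with pytest.raises(ValueError):
            learning_rate(0, sched)
        with pytest.raises(ValueError):
            learning_rate(11, sched)

    @given(t=st.integers(1, 500), t_max=st.integers(2, 500))
    @settings(max_examples=50, derandomize=True)
    def test_affine_and_bounded(self, t, t_max):
        """eta(t) is affine in t and stays within [v_min, v_max]."""
        if t > t_max:
            t = t_max
        sched = LearningSchedule(v_max=0.7, v_min=0.05, epochs=1, t_max=t_max)
        eta = learning_rate(t, sched)
        assert 0.05 <= eta <= 0.7
        if 1 < t < t_max:  # affine: value equals the mean of its neighbors
            mid = (learning_rate(t - 1, sched) + learning_rate(t + 1, sched)) / 2
            assert eta == pytest.approx(mid)


class TestNeighborhood:
    def grid(self, rows=6, cols=6, nvars=2):
        return SomGrid(np.zeros((rows, cols, nvars)))

    def test_winner_always_fully_corrected(self):
        state = NeighborhoodState(radius_start=5, t_max=100)
        assert neighborhood_factor((2, 3), (2, 3), 1, state, self.grid()) == 1.0
        assert neighborhood_factor((2, 3), (2, 3), 100, state, self.grid()) == 1.0

    def test_zero_beyond_radius(self):
        # radius(t)=2 when radius_start=4 and t is halfway through
        state = NeighborhoodState(radius_start=4, t_max=101)
        assert state.radius(51) == pytest.approx(2.0)
        assert neighborhood_factor((0, 0), (5, 5), 51, state, self.grid()) == 0.0

    def test_triangular_value_inside_radius(self):
        state = NeighborhoodState(radius_start=4, t_max=101)
        # d=1 with radius 2 -> 1 - 1/3 = 2/3
        assert neighborhood_factor((0, 0), (0, 1), 51, state, self.grid()) \
            == pytest.approx(2 / 3)

    def test_only_winner_corrected_at_end_of_training(self):
        state = NeighborhoodState(radius_start=5, t_max=50)
        g = self.grid()
        for j in [(0, 1), (1, 1), (3, 4)]:
            assert neighborhood_factor((0, 0), j, 50, state, g) == 0.0

    def test_index_validation(self):
        state = NeighborhoodState(radius_start=5, t_max=10)
        with pytest.raises(IndexError):
            neighborhood_factor((0, 0), (9, 9), 1, state, self.grid())


class TestFindWinner:
    def test_exact_match_wins(self):
        w = np.arange(24, dtype=float).reshape(2, 3, 4)
        x = w[1, 2].copy()
        assert find_winner(SomGrid(w), x) == (1, 2)

    def test_tie_breaks_to_smallest_row_major_index(self):
        # (0,0) and (1,0) are both at distance 1 from x=0
        w = np.array([[[1.0], [3.0]], [[-1.0], [5.0]]])
        assert find_winner(SomGrid(w), np.array([0.0])) == (0, 0)

    def test_two_by_two_exhaustive(self):
        w = np.array([[[0.0, 0.0], [1.0, 0.0]], [[0.0, 1.0], [1.0, 1.0]]])
        assert find_winner(SomGrid(w), np.array([0.9, 0.1])) == (0, 1)

    def test_input_validation(self):
        g = SomGrid(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            find_winner(g, np.zeros(4))
        with pytest.raises(ValueError):
            find_winner(g, np.array([1.0, np.nan, 0.0]))

    def test_agrees_with_exhaustive_scan(self):
        """Vectorized winner search vs a brute-force loop over all neurons."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            g = SomGrid(rng.random((6, 6, 5)))
            for _ in range(5):
                x = rng.random(5)
                best = min(
                    ((r, c) for r in range(6) for c in range(6)),
                    key=lambda rc: (np.linalg.norm(g.weights[rc] - x), rc),
                )
                assert find_winner(g, x) == best


class TestUpdateWeights:
    def test_full_step_lands_on_object(self):
        g = SomGrid(np.full((1, 1, 3), 0.2))
        sched = LearningSchedule(v_max=1.0, v_min=1.0, epochs=1, t_max=10)
        state = NeighborhoodState(radius_start=0, t_max=10)
        x = np.array([0.5, -1.0, 2.0])
        update_weights(g, x, (0, 0), 1, sched, state)
        np.testing.assert_allclose(g.weights[0, 0], x)

    def test_null_step_leaves_grid_unchanged(self):
        g = SomGrid(np.full((2, 2, 2), 0.3))
        before = g.weights.copy()
        sched = LearningSchedule(v_max=0.5, v_min=0.0, epochs=1, t_max=10)
        state = NeighborhoodState(radius_start=0, t_max=10)
        # at t = t_max: eta = v_min = 0 everywhere
        update_weights(g, np.ones(2), (0, 0), 10, sched, state)
        np.testing.assert_array_equal(g.weights, before)

    def test_partial_step_arithmetic(self):
        # eta=0.5, neighbor at d=1 with radius 1 -> a=0.5 -> step 0.25
        g = SomGrid(np.zeros((1, 2, 1)))
        sched = LearningSchedule(v_max=0.5, v_min=0.5, epochs=1, t_max=100)
        state = NeighborhoodState(radius_start=1, t_max=100)
        update_weights(g, np.array([1.0]), (0, 0), 1, sched, state)
        assert g.weights[0, 0, 0] == pytest.approx(0.5)   # winner: eta*1
        assert g.weights[0, 1, 0] == pytest.approx(0.25)  # neighbor: eta*0.5

    def test_geometric_convergence_to_single_object(self):
        """|w_k - x| = |w_0 - x| * prod(1 - eta_k) on a 1x1 grid."""
        g = SomGrid(np.zeros((1, 1, 1)))
        sched = LearningSchedule(v_max=0.5, v_min=0.1, epochs=1, t_max=20)
        state = NeighborhoodState(radius_start=0, t_max=20)
        x = np.array([1.0])
        expected = 1.0
        for t in range(1, 21):
            update_weights(g, x, (0, 0), t, sched, state)
            expected *= 1 - learning_rate(t, sched)
            assert abs(g.weights[0, 0, 0] - 1.0) == pytest.approx(expected)


class TestTrainSom:
    def test_single_object_fixed_point(self):
        X = np.array([[0.3, 0.7, 0.1]])
        g = train_som(X, (1, 1), LearningSchedule(epochs=100), seed=0)
        np.testing.assert_allclose(g.weights[0, 0], X[0], atol=1e-6)

    def test_seeded_determinism(self):
        X = np.random.default_rng(5).random((30, 4))
        g1 = train_som(X, (3, 3), LearningSchedule(epochs=10), seed=11)
        g2 = train_som(X, (3, 3), LearningSchedule(epochs=10), seed=11)
        np.testing.assert_array_equal(g1.weights, g2.weights)

    def test_two_clusters_on_two_neurons(self):
        """On two well-separated clusters, a 2x1 grid recovers the two-mean
        solution: each neuron sits by one cluster mean and the winner
        partition equals the true cluster split."""
        rng = np.random.default_rng(7)
        a = 0.05 * rng.random((20, 2))          # cluster near (0, 0)
        b = 0.05 * rng.random((20, 2)) + 0.95   # cluster near (1, 1)
        X = np.vstack([a, b])
        g = train_som(X, (2, 1), LearningSchedule(epochs=50), seed=1)
        centers = g.weights.reshape(2, 2)
        means = np.array([a.mean(0), b.mean(0)])  # brute-force two-mean oracle
        # each neuron matches one distinct cluster mean
        assignment = {int(np.argmin(np.linalg.norm(means - w, axis=1)))
                      for w in centers}
        assert assignment == {0, 1}
        for w in centers:
            assert min(np.linalg.norm(means - w, axis=1)) < 0.1
        mapping = top_map(g, X)
        parts = {tuple(sorted(v)) for v in mapping.values()}
        assert parts == {tuple(range(20)), tuple(range(20, 40))}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_som(np.empty((0, 3)), (2, 2), LearningSchedule(), seed=0)


class TestTopMap:
    def test_identical_objects_share_a_neuron(self):
        X = np.tile([0.5, 0.5], (7, 1))
        g = train_som(X, (3, 3), LearningSchedule(epochs=5), seed=0)
        mapping = top_map(g, X)
        assert len(mapping) == 1
        assert sorted(next(iter(mapping.values()))) == list(range(7))

    def test_objects_at_neuron_weights_map_identically(self):
        w = np.random.default_rng(3).random((2, 2, 3))
        g = SomGrid(w)
        mapping = top_map(g, w.reshape(4, 3))
        assert mapping == {(0, 0): [0], (0, 1): [1], (1, 0): [2], (1, 1): [3]}

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        X = rng.random((40, 3))
        g = train_som(X, (4, 4), LearningSchedule(epochs=5), seed=2)
        mapping = top_map(g, X)
        members = sorted(i for lst in mapping.values() for i in lst)
        assert members == list(range(40))
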