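"""Kohonen self-organizing map primitives.

A SOM is a rectangular grid of neurons, each holding a weight vector of the
same dimensionality as the input objects.  Training is competitive: for each
presented object the nearest neuron (Euclidean distance, the "winning
neuron") is found, and all weights are pulled toward the object by an amount
that decays both with topological distance from the winner (triangular
neighborhood on a non-toroidal grid, Chebyshev metric) and with the
iteration count (linearly decreasing learning rate and radius).  At the last
iteration the radius is zero, so only the winning neuron is still corrected.

These primitives are shared by plain Kohonen mapping (used for descriptor
reduction and data-set splitting) and by the counter-propagation classifier,
which adds an output layer on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LearningSchedule",
    "NeighborhoodState",
    "SomGrid",
    "learning_rate",
    "neighborhood_factor",
    "find_winner",
    "update_weights",
    "train_som",
    "top_map",
]


@dataclass(frozen=True)
class LearningSchedule:
    """Linear learning-rate schedule.

    The rate decreases linearly from ``v_max`` at the first iteration
    (``t = 1``) to ``v_min`` at the last (``t = t_max``)::

        eta(t) = v_min + (v_max - v_min) * (t_max - t) / (t_max - 1)

    ``t`` counts individual object presentations, not epochs.  ``t_max`` is
    normally derived by the trainer as ``epochs * objects_per_epoch`` and
    may be left as ``None`` until then.
    """

    v_max: float = 0.5
    v_min: float = 0.01
    epochs: int = 50
    t_max: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.v_max <= 1.0:
            raise ValueError(f"v_max must be in (0, 1], got {self.v_max}")
        if not 0.0 <= self.v_min <= self.v_max:
            raise ValueError(f"need 0 <= v_min <= v_max, got v_min={self.v_min}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.t_max is not None and self.t_max < 1:
            raise ValueError("t_max must be >= 1")

    def with_t_max(self, objects_per_epoch: int) -> "LearningSchedule":
        """Return a copy with ``t_max = epochs * objects_per_epoch``."""
        return replace(self, t_max=self.epochs * int(objects_per_epoch))


@dataclass(frozen=True)
class NeighborhoodState:
    """Triangular neighborhood with a linearly shrinking radius.

    ``radius_start`` defaults to the maximum Chebyshev distance on the grid
    so that initially every neuron is corrected; the radius reaches 0 at
    ``t = t_max``.
    """

    radius_start: float
    t_max: int

    def radius(self, t: int) -> float:
        if self.t_max <= 1:
            return 0.0
        return self.radius_start * (self.t_max - t) / (self.t_max - 1)


class SomGrid:
    """Rectangular grid of Kohonen neurons.

    Parameters
    ----------
    weights
        Array of shape ``(n_rows, n_cols, n_vars)``; finite everywhere.
    """

    def __init__(self, weights: np.ndarray):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 3:
            raise ValueError("weights must have shape (n_rows, n_cols, n_vars)")
        if not np.isfinite(weights).all():
            raise ValueError("weights must be finite")
        self.weights = weights

    @property
    def n_rows(self) -> int:
        return self.weights.shape[0]

    @property
    def n_cols(self) -> int:
        return self.weights.shape[1]

    @property
    def n_vars(self) -> int:
        return self.weights.shape[2]

    @property
    def max_grid_distance(self) -> int:
        """Largest Chebyshev distance between two neurons on the grid."""
        return max(self.n_rows - 1, self.n_cols - 1)

    @classmethod
    def random(cls, n_rows: int, n_cols: int, n_vars: int,
               rng: np.random.Generator) -> "SomGrid":
        """Seeded uniform random initialization in [0, 1)."""
        if min(n_rows, n_cols, n_vars) < 1:
            raise ValueError("grid dimensions must be positive")
        return cls(rng.random((n_rows, n_cols, n_vars)))

    def grid_distances(self, c: tuple[int, int]) -> np.ndarray:
        """Chebyshev distance of every neuron to neuron ``c``, shape (R, C)."""
        r, col = c
        rr = np.abs(np.arange(self.n_rows) - r)[:, None]
        cc = np.abs(np.arange(self.n_cols) - col)[None, :]
        return np.maximum(rr, cc)


def learning_rate(t: int, schedule: LearningSchedule) -> float:
    """Learning rate at iteration ``t`` (1-based), linear in ``t``."""
    t_max = schedule.t_max
    if t_max is None:
        raise ValueError("schedule.t_max is unset; call with_t_max() first")
    if not 1 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [1, {t_max}]")
    if t_max == 1:
        return schedule.v_max
    return schedule.v_min + (schedule.v_max - schedule.v_min) * (t_max - t) / (t_max - 1)


def neighborhood_factor(c: tuple[int, int], j: tuple[int, int], t: int,
                        state: NeighborhoodState, grid: SomGrid) -> float:
    """Triangular neighborhood factor a(c, j, t) in [0, 1].

    ``a = max(0, 1 - d / (radius(t) + 1))`` with ``d`` the Chebyshev grid
    distance between winner ``c`` and neuron ``j``; equals 1 at the winner
    and 0 beyond the current radius.
    """
    for idx in (c, j):
        if not (0 <= idx[0] < grid.n_rows and 0 <= idx[1] < grid.n_cols):
            raise IndexError(f"neuron index {idx} outside grid")
    d = max(abs(c[0] - j[0]), abs(c[1] - j[1]))
    return float(max(0.0, 1.0 - d / (state.radius(t) + 1.0)))


def _neighborhood_grid(c: tuple[int, int], t: int, state: NeighborhoodState,
                       grid: SomGrid) -> np.ndarray:
    """Vectorized a(c, j, t) over all neurons j, shape (R, C)."""
    d = grid.grid_distances(c)
    return np.maximum(0.0, 1.0 - d / (state.radius(t) + 1.0))


def find_winner(grid: SomGrid, x: np.ndarray) -> tuple[int, int]:
    """Index of the neuron closest to ``x`` in Euclidean distance.

    Ties are broken toward the smallest row-major index, which makes the
    search deterministic.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (grid.n_vars,):
        raise ValueError(f"object has shape {x.shape}, expected ({grid.n_vars},)")
    if not np.isfinite(x).all():
        raise ValueError("object vector must be finite")
    d2 = np.einsum("rcv,rcv->rc", grid.weights - x, grid.weights - x)
    flat = int(np.argmin(d2))  # argmin returns the first (row-major) minimum
    return flat // grid.n_cols, flat % grid.n_cols


def update_weights(grid: SomGrid, x: np.ndarray, c: tuple[int, int], t: int,
                   schedule: LearningSchedule, state: NeighborhoodState) -> None:
    """Pull every weight toward ``x`` by the fraction eta(t) * a(c, j, t).

    Operates in place; weights with ``eta * a = 0`` are untouched.
    """
    eta = learning_rate(t, schedule)
    a = _neighborhood_grid(c, t, state, grid)
    grid.weights += (eta * a)[:, :, None] * (x - grid.weights)


def train_som(X: np.ndarray, grid_shape: tuple[int, int],
              schedule: LearningSchedule, seed: int) -> SomGrid:
    """Train a SOM on the rows of ``X``.

    Each epoch presents every object exactly once in a fresh seeded random
    order; ``t_max = epochs * n_objects``.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    n_objects, n_vars = X.shape
    rng = np.random.default_rng(seed)
    grid = SomGrid.random(grid_shape[0], grid_shape[1], n_vars, rng)
    sched = schedule.with_t_max(n_objects)
    state = NeighborhoodState(radius_start=grid.max_grid_distance, t_max=sched.t_max)
    t = 0
    for _ in range(schedule.epochs):
        order = rng.permutation(n_objects)
        for i in order:
            t += 1
            c = find_winner(grid, X[i])
            update_weights(grid, X[i], c, t, sched, state)
    return grid


def top_map(grid: SomGrid, X: np.ndarray) -> dict[tuple[int, int], list[int]]:
    """Assign every object to its winning neuron.

    Returns a mapping neuron index -> list of object row indices; the lists
    partition ``range(n_objects)``.
    """
    X = np.asarray(X, dtype=float)
    mapping: dict[tuple[int, int], list[int]] = {}
    for i in range(X.shape[0]):
        c = find_winner(grid, X[i])
        mapping.setdefault(c, []).append(i)
    return mapping
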