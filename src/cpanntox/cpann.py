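"""Counter-propagation neural network (CPANN) classifier.

A CPANN stacks two layers of weights on the same neuron grid: a Kohonen
layer trained competitively on the descriptors, and an output (Grossberg)
layer whose weights are pulled toward the target values of the objects that
excite each neighborhood.  The winning neuron is always chosen from the
Kohonen layer alone — targets never influence the winner search — and both
layers are corrected with the same learning rate and triangular
neighborhood.  Because the targets are 0/1 and every correction is a convex
step toward a target, trained output weights stay inside [0, 1] and can be
read directly as class scores.

Two training regimes are provided for imbalanced data:

``full_epoch``
    the classical scheme — one epoch presents every training object once;

``balanced_subsample``
    before *each* epoch, a fresh balanced subsample is drawn: all
    minority-class objects plus an equally sized without-replacement random
    draw from the majority class.  One epoch then presents each subsample
    member exactly once, so majority objects are simply used less often
    over the whole run while all of them remain in play.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .som import (
    LearningSchedule,
    NeighborhoodState,
    SomGrid,
    find_winner,
    learning_rate,
)

__all__ = ["TrainConfig", "CpannModel", "balanced_subsample", "train_cpann", "predict"]

_MODES = ("full_epoch", "balanced_subsample")


@dataclass(frozen=True)
class TrainConfig:
    """Everything needed to (re)train a CPANN.

    ``n_outputs=1`` trains a single 0/1 target (score = output weight,
    class 1 iff score >= ``class_threshold``, ties to class 1).
    ``n_outputs=2`` trains one-hot targets and decides by argmax.
    """

    grid_shape: tuple[int, int] = (6, 6)
    schedule: LearningSchedule = field(default_factory=LearningSchedule)
    mode: str = "full_epoch"
    seed: int = 0
    class_threshold: float = 0.5
    n_outputs: int = 1

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.n_outputs not in (1, 2):
            raise ValueError("n_outputs must be 1 or 2")


@dataclass
class CpannModel:
    """Trained two-layer network plus the context needed to apply it.

    ``grid`` holds the Kohonen layer, ``output_weights`` the Grossberg layer
    (shape ``(n_rows, n_cols, n_outputs)``).  ``descriptor_names`` and the
    z-score ``norm_mean`` / ``norm_sd`` describe exactly which raw columns
    the model consumes and how they are scaled; ``predict`` applies both.
    ``training_distances`` maps each neuron to the Euclidean distances of
    the training objects it won, for the applicability-domain check.
    """

    grid: SomGrid
    output_weights: np.ndarray
    descriptor_names: list[str]
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    config: TrainConfig
    training_distances: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.output_weights.shape[:2] != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("output layer shape does not match the grid")
        if np.any(self.norm_sd <= 0):
            raise ValueError("normalization standard deviations must be positive")

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Serialize to a single JSON document (weights at full precision)."""
        cfg = self.config
        doc = {
            "grid_shape": [self.grid.n_rows, self.grid.n_cols],
            "kohonen_weights": self.grid.weights.tolist(),
            "output_weights": self.output_weights.tolist(),
            "descriptor_names": list(self.descriptor_names),
            "norm_mean": self.norm_mean.tolist(),
            "norm_sd": self.norm_sd.tolist(),
            "config": {
                "grid_shape": list(cfg.grid_shape),
                "v_max": cfg.schedule.v_max,
                "v_min": cfg.schedule.v_min,
                "epochs": cfg.schedule.epochs,
                "mode": cfg.mode,
                "seed": cfg.seed,
                "class_threshold": cfg.class_threshold,
                "n_outputs": cfg.n_outputs,
            },
            "training_distances": {
                f"{r},{c}": d.tolist() for (r, c), d in self.training_distances.items()
            },
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "CpannModel":
        doc = json.loads(text)
        cfg = doc["config"]
        config = TrainConfig(
            grid_shape=tuple(cfg["grid_shape"]),
            schedule=LearningSchedule(v_max=cfg["v_max"], v_min=cfg["v_min"],
                                      epochs=cfg["epochs"]),
            mode=cfg["mode"],
            seed=cfg["seed"],
            class_threshold=cfg["class_threshold"],
            n_outputs=cfg["n_outputs"],
        )
        dists = {
            tuple(int(v) for v in key.split(",")): np.asarray(val, dtype=float)
            for key, val in doc["training_distances"].items()
        }
        return cls(
            grid=SomGrid(np.asarray(doc["kohonen_weights"], dtype=float)),
            output_weights=np.asarray(doc["output_weights"], dtype=float),
            descriptor_names=list(doc["descriptor_names"]),
            norm_mean=np.asarray(doc["norm_mean"], dtype=float),
            norm_sd=np.asarray(doc["norm_sd"], dtype=float),
            config=config,
            training_distances=dists,
        )


def balanced_subsample(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subsample.

    All minority-class indices plus an equally large without-replacement
    uniform draw from the majority class; size = 2 x minority count.  Called
    with a fresh ``rng`` state before every epoch.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for balanced subsampling")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    drawn = rng.choice(majority, size=len(minority), replace=False)
    return np.concatenate([minority, drawn])


def train_cpann(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    *,
    descriptor_names: list[str] | None = None,
    norm_mean: np.ndarray | None = None,
    norm_sd: np.ndarray | None = None,
    epoch_log: list[np.ndarray] | None = None,
) -> CpannModel:
    """Train a CPANN on z-scored descriptors ``X`` and binary targets ``y``.

    ``X`` must already be normalized with training-set statistics; pass the
    statistics through ``norm_mean`` / ``norm_sd`` so the model can apply
    them to raw queries (identity scaling is assumed when omitted).  If
    ``epoch_log`` is given, the index array used in each epoch is appended
    to it (training instrumentation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per target")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("targets must be binary 0/1")
    n_objects, n_vars = X.shape

    if config.n_outputs == 1:
        targets = y.astype(float)[:, None]
    else:
        targets = np.stack([(y == 0).astype(float), (y == 1).astype(float)], axis=1)

    rng = np.random.default_rng(config.seed)
    grid = SomGrid.random(config.grid_shape[0], config.grid_shape[1], n_vars, rng)
    out = rng.random((config.grid_shape[0], config.grid_shape[1], config.n_outputs))

    if config.mode == "balanced_subsample":
        per_epoch = 2 * min(int(np.sum(y == 1)), int(np.sum(y == 0)))
        if per_epoch == 0:
            raise ValueError("both classes must be present for balanced subsampling")
    else:
        per_epoch = n_objects
    sched = config.schedule.with_t_max(per_epoch)
    state = NeighborhoodState(radius_start=grid.max_grid_distance, t_max=sched.t_max)

    t = 0
    for _ in range(config.schedule.epochs):
        if config.mode == "balanced_subsample":
            idx = balanced_subsample(y, rng)
        else:
            idx = np.arange(n_objects)
        idx = rng.permutation(idx)
        if epoch_log is not None:
            epoch_log.append(idx.copy())
        for i in idx:
            t += 1
            c = find_winner(grid, X[i])
            eta = learning_rate(t, sched)
            a = np.maximum(0.0, 1.0 - grid.grid_distances(c) / (state.radius(t) + 1.0))
            step = (eta * a)[:, :, None]
            grid.weights += step * (X[i] - grid.weights)
            out += step * (targets[i] - out)

    # per-neuron training distances of the final map, for the AD check
    dists: dict[tuple[int, int], list[float]] = {}
    for i in range(n_objects):
        c = find_winner(grid, X[i])
        dists.setdefault(c, []).append(float(np.linalg.norm(X[i] - grid.weights[c])))

    if descriptor_names is None:
        descriptor_names = [f"x{j}" for j in range(n_vars)]
    if norm_mean is None:
        norm_mean = np.zeros(n_vars)
    if norm_sd is None:
        norm_sd = np.ones(n_vars)
    return CpannModel(
        grid=grid,
        output_weights=out,
        descriptor_names=list(descriptor_names),
        norm_mean=np.asarray(norm_mean, dtype=float),
        norm_sd=np.asarray(norm_sd, dtype=float),
        config=config,
        training_distances={k: np.asarray(v) for k, v in dists.items()},
    )


def _normalize_query(model: CpannModel, X_raw, descriptor_names=None) -> np.ndarray:
    """Select the model's descriptor columns and apply its z-scaling."""
    import pandas as pd

    if isinstance(X_raw, pd.DataFrame):
        missing = [n for n in model.descriptor_names if n not in X_raw.columns]
        if missing:
            raise KeyError(f"query is missing descriptor columns: {missing}")
        X = X_raw[model.descriptor_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X_raw, dtype=float)
        if descriptor_names is not None:
            lookup = {n: j for j, n in enumerate(descriptor_names)}
            missing = [n for n in model.descriptor_names if n not in lookup]
            if missing:
                raise KeyError(f"query is missing descriptor columns: {missing}")
            X = X[:, [lookup[n] for n in model.descriptor_names]]
        elif X.shape[1] != len(model.descriptor_names):
            raise ValueError(
                f"query has {X.shape[1]} columns, model expects "
                f"{len(model.descriptor_names)}"
            )
    return (X - model.norm_mean) / model.norm_sd


def predict(model: CpannModel, X_raw, descriptor_names: list[str] | None = None):
    """Predict classes for raw descriptor rows.

    Returns ``(scores, classes, winners)``: the winning neuron's output
    weight, the thresholded class (score >= threshold -> class 1; with two
    outputs, argmax with ties to class 1), and the winner indices.
    """
    X = _normalize_query(model, X_raw, descriptor_names)
    n = X.shape[0]
    scores = np.empty(n)
    classes = np.empty(n, dtype=int)
    winners: list[tuple[int, int]] = []
    for i in range(n):
        c = find_winner(model.grid, X[i])
        winners.append(c)
        w = model.output_weights[c]
        if model.config.n_outputs == 1:
            scores[i] = w[0]
            classes[i] = 1 if w[0] >= model.config.class_threshold else 0
        else:
            scores[i] = w[1]
            classes[i] = 1 if w[1] >= w[0] else 0
    return scores, classes, winners
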