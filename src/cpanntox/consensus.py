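"""Consensus prediction, applicability domain, and descriptor importance.

Accepted models each carry their own descriptor subset and normalization,
so they can vote independently on raw descriptor rows.  The consensus class
is the majority vote, with ties resolved toward the toxic class — the
conservative default in toxicology.

The applicability-domain (AD) check is a distance-to-winning-neuron rule:
a query is inside the domain of a model when its Euclidean distance to its
winning neuron does not exceed a chosen percentile (default: the maximum,
i.e. the 100th percentile) of the training-set distances recorded for that
same neuron; neurons never hit in training fall back to the pooled training
distance distribution.

Descriptor importance aggregates the selection behavior of many accepted
models.  For a descriptor d:

    I_d = (1 / nm) * sum over models [ s * (a / n) ]

where ``nm`` is the number of models in which d could have been selected,
``s`` is 1 when the model selected d and 0 otherwise, ``a`` is the size of
the model's candidate descriptor pool and ``n`` the number of descriptors
it actually selected.  The statistic is large for descriptors selected
often, from large pools, into small models.  Descriptors appearing fewer
than four times across the accepted models are dropped (to suppress chance
selections), and the report keeps those with I_d >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cpann import CpannModel, predict, _normalize_query
from .som import find_winner

__all__ = [
    "ImportanceRecord",
    "ModelSelection",
    "consensus_predict",
    "applicability_domain",
    "descriptor_importance",
    "importance_filter",
    "importance_report",
]


@dataclass
class ImportanceRecord:
    descriptor: str
    nm: int
    selection_count: int
    importance: float

    def __post_init__(self) -> None:
        if self.selection_count > self.nm:
            raise ValueError("selection_count cannot exceed nm")
        if (self.selection_count == 0) != (self.importance == 0.0):
            raise ValueError("importance must be 0 exactly when never selected")


@dataclass(frozen=True)
class ModelSelection:
    """One accepted model's selection facts: pool, pool size, chosen set."""

    candidate_pool: tuple[str, ...]
    selected: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.selected) == 0:
            raise ValueError("a model must select at least one descriptor")
        unknown = set(self.selected) - set(self.candidate_pool)
        if unknown:
            raise ValueError(f"selected descriptors outside the pool: {sorted(unknown)}")

    @property
    def a(self) -> int:
        return len(self.candidate_pool)

    @property
    def n(self) -> int:
        return len(self.selected)


def consensus_predict(models: list[CpannModel], X_raw, descriptor_names=None):
    """Majority vote over models; ties go to the toxic class (1).

    Returns ``(classes, vote_fractions, per_model_classes)`` where
    ``vote_fractions`` is the fraction of models voting toxic and
    ``per_model_classes`` has shape ``(n_models, n_objects)``.
    """
    if not models:
        raise ValueError("need at least one model for consensus prediction")
    votes = []
    for model in models:
        _, classes, _ = predict(model, X_raw, descriptor_names=descriptor_names)
        votes.append(classes)
    votes = np.asarray(votes)
    frac = votes.mean(axis=0)
    classes = (frac >= 0.5).astype(int)  # tie -> toxic
    return classes, frac, votes


def applicability_domain(
    model: CpannModel, X_raw, descriptor_names=None, percentile: float = 100.0
) -> np.ndarray:
    """Boolean per object: inside the model's applicability domain.

    Inside iff the distance to the winning neuron is <= the given
    percentile (boundary inclusive) of the training distances stored for
    that neuron; unseen neurons use the pooled distribution.
    """
    X = _normalize_query(model, X_raw, descriptor_names)
    all_d = np.concatenate([d for d in model.training_distances.values()]) \
        if model.training_distances else np.array([0.0])
    global_cut = float(np.percentile(all_d, percentile))
    inside = np.empty(X.shape[0], dtype=bool)
    for i in range(X.shape[0]):
        c = find_winner(model.grid, X[i])
        d = float(np.linalg.norm(X[i] - model.grid.weights[c]))
        local = model.training_distances.get(c)
        cut = float(np.percentile(local, percentile)) if local is not None else global_cut
        inside[i] = d <= cut
    return inside


def descriptor_importance(selections: list[ModelSelection]) -> list[ImportanceRecord]:
    """Aggregate I_d over a list of accepted-model selections.

    ``nm`` for a descriptor counts the models whose candidate pool contains
    it.  Descriptors never appearing in any pool are not reported.
    """
    if not selections:
        return []
    pools: dict[str, int] = {}
    contrib: dict[str, float] = {}
    count: dict[str, int] = {}
    for sel in selections:
        chosen = set(sel.selected)
        ratio = sel.a / sel.n
        for name in sel.candidate_pool:
            pools[name] = pools.get(name, 0) + 1
            if name in chosen:
                contrib[name] = contrib.get(name, 0.0) + ratio
                count[name] = count.get(name, 0) + 1
    return [
        ImportanceRecord(
            descriptor=name,
            nm=nm,
            selection_count=count.get(name, 0),
            importance=contrib.get(name, 0.0) / nm,
        )
        for name, nm in pools.items()
    ]


def importance_filter(
    records: list[ImportanceRecord], min_count: int = 4, min_importance: float = 2.0
) -> list[ImportanceRecord]:
    """Keep records with selection_count >= min_count and I_d >= min_importance
    (both inclusive), sorted by importance descending (name as tie-break)."""
    kept = [
        r for r in records
        if r.selection_count >= min_count and r.importance >= min_importance
    ]
    return sorted(kept, key=lambda r: (-r.importance, r.descriptor))


def importance_report(records: list[ImportanceRecord]) -> str:
    """TSV report: descriptor, selection_count, nm, importance."""
    lines = ["descriptor\tselection_count\tnm\tId"]
    for r in records:
        lines.append(f"{r.descriptor}\t{r.selection_count}\t{r.nm}\t{r.importance:.6f}")
    return "\n".join(lines) + "\n"
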