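"""Descriptor filtering, normalization, SOM-based reduction and splitting.

The preparation pipeline mirrors common QSAR practice for descriptor tables
(rows = compounds, columns = numeric molecular descriptors):

1. drop near-constant descriptors (most frequent value in more than 70% of
   the rows) and, greedily in column order, the later member of any pair
   with absolute Pearson correlation at or above 0.95;
2. z-score every retained descriptor with training-set statistics;
3. reduce the descriptor pool by mapping the *transposed* matrix on a SOM
   and keeping, per occupied neuron, the descriptor closest to and the one
   farthest from the neuron weights (so a fully occupied 5x5 map yields at
   most 50 descriptors, a 7x7 map at most 98, and so on);
4. split compounds into training (TR), two test sets (TE1, TE2) and an
   external validation set (VA) from the compound top-map, honoring exact
   per-class quotas while spreading each set across the occupied map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .som import LearningSchedule, train_som, top_map

__all__ = [
    "DescriptorDataset",
    "NormalizationParams",
    "SET_LABELS",
    "filter_descriptors",
    "zscore_fit",
    "zscore_apply",
    "reduce_descriptors_som",
    "split_sets_som",
]

SET_LABELS = ("TR", "TE1", "TE2", "VA", "unassigned")


@dataclass
class DescriptorDataset:
    """A compound table: ids, descriptor matrix, binary labels, set labels."""

    ids: list[str]
    X: np.ndarray
    descriptor_names: list[str]
    y: np.ndarray
    set_label: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes[:5]}")
        if self.X.shape != (len(self.ids), len(self.descriptor_names)):
            raise ValueError("X shape does not match ids x descriptor_names")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("class labels must be binary 0/1")
        if self.set_label is None:
            self.set_label = np.array(["unassigned"] * len(self.ids), dtype=object)
        self.set_label = np.asarray(self.set_label, dtype=object)
        bad = set(self.set_label) - set(SET_LABELS)
        if bad:
            raise ValueError(f"unknown set labels: {sorted(bad)}")

    @property
    def n_compounds(self) -> int:
        return len(self.ids)

    def subset(self, mask: np.ndarray) -> "DescriptorDataset":
        idx = np.flatnonzero(mask)
        return DescriptorDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            descriptor_names=list(self.descriptor_names),
            y=self.y[idx],
            set_label=self.set_label[idx],
        )

    def members(self, label: str) -> "DescriptorDataset":
        return self.subset(self.set_label == label)

    def select_descriptors(self, names: list[str]) -> "DescriptorDataset":
        lookup = {n: j for j, n in enumerate(self.descriptor_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"unknown descriptors: {missing[:5]}")
        cols = [lookup[n] for n in names]
        return DescriptorDataset(
            ids=list(self.ids),
            X=self.X[:, cols],
            descriptor_names=list(names),
            y=self.y.copy(),
            set_label=self.set_label.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.descriptor_names)
        df.insert(0, "set", self.set_label)
        df.insert(0, "class", self.y)
        df.insert(0, "compound_id", self.ids)
        return df


@dataclass(frozen=True)
class NormalizationParams:
    """Per-descriptor mean and sample (n-1) standard deviation."""

    mean: np.ndarray
    sd: np.ndarray
    descriptor_names: tuple[str, ...]


def filter_descriptors(
    X: np.ndarray,
    names: list[str],
    corr_limit: float = 0.95,
    const_frac: float = 0.70,
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Remove near-constant and highly correlated descriptors.

    A descriptor is near-constant when its single most frequent value covers
    more than ``const_frac`` of the rows.  Among the survivors, pairs with
    ``|Pearson r| >= corr_limit`` are resolved by dropping the later column
    (scan in column order), so the surviving set has all pairwise
    ``|r| < corr_limit`` and the outcome is deterministic.  Returns the
    reduced matrix, names, and a removal log of (name, reason).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two compounds to filter descriptors")
    n = X.shape[0]
    log: list[tuple[str, str]] = []

    keep: list[int] = []
    for j, name in enumerate(names):
        _, counts = np.unique(X[:, j], return_counts=True)
        frac = counts.max() / n
        if frac > const_frac:
            log.append((name, f"near-constant: most frequent value in {frac:.0%} of rows"))
        else:
            keep.append(j)

    if keep:
        sub = X[:, keep]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(np.nan_to_num(corr))
        kept_mask = np.ones(len(keep), dtype=bool)
        for j in range(len(keep)):
            if not kept_mask[j]:
                continue
            for i in range(j):
                if kept_mask[i] and abs(corr[i, j]) >= corr_limit:
                    kept_mask[j] = False
                    log.append(
                        (names[keep[j]],
                         f"correlated: |r|={abs(corr[i, j]):.3f} with {names[keep[i]]}")
                    )
                    break
        keep = [k for k, m in zip(keep, kept_mask) if m]

    kept_names = [names[k] for k in keep]
    return X[:, keep], kept_names, log


def zscore_fit(X_train: np.ndarray, names: list[str] | None = None) -> NormalizationParams:
    """Training-set mean and sample standard deviation per descriptor.

    The sample (n-1) convention is used, so the column (1, 2, 3) maps to
    (-1, 0, 1) exactly.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ValueError("need at least two training rows")
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    if np.any(sd == 0):
        if names is None:
            names = [f"x{j}" for j in range(X_train.shape[1])]
        bad = [names[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance descriptors in the training set: {bad}")
    if names is None:
        names = [f"x{j}" for j in range(X_train.shape[1])]
    return NormalizationParams(mean=mean, sd=sd, descriptor_names=tuple(names))


def zscore_apply(X: np.ndarray, params: NormalizationParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(params.mean):
        raise ValueError("column count does not match normalization parameters")
    return (X - params.mean) / params.sd


def reduce_descriptors_som(
    X: np.ndarray,
    names: list[str],
    grid_shape: tuple[int, int],
    schedule: LearningSchedule | None = None,
    seed: int = 0,
) -> list[str]:
    """Select a reduced descriptor pool from a SOM of the transposed matrix.

    Descriptors (columns of the z-scored ``X``) are mapped as objects; for
    every occupied neuron the closest and the farthest descriptor are kept
    (one descriptor when the neuron holds a single one), so the pool size is
    at most twice the neuron count.  Names are returned in original column
    order.
    """
    if schedule is None:
        schedule = LearningSchedule(epochs=10)
    Xt = np.asarray(X, dtype=float).T
    grid = train_som(Xt, grid_shape, schedule, seed)
    mapping = top_map(grid, Xt)
    selected: set[int] = set()
    for neuron, members in mapping.items():
        d = [float(np.linalg.norm(Xt[i] - grid.weights[neuron])) for i in members]
        selected.add(members[int(np.argmin(d))])
        selected.add(members[int(np.argmax(d))])
    return [names[j] for j in sorted(selected)]


def _take(pool: list[int], rng: np.random.Generator) -> int:
    """Remove and return a random element of ``pool`` (seeded)."""
    k = int(rng.integers(len(pool)))
    return pool.pop(k)


def split_sets_som(
    dataset: DescriptorDataset,
    grid_shape: tuple[int, int],
    quotas: dict[str, tuple[int, int]],
    schedule: LearningSchedule | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Assign TR / TE1 / TE2 / VA labels from a compound top-map.

    ``quotas`` maps each set name to ``(n_positive, n_negative)`` and must
    partition the per-class totals exactly.  The heuristic: (1) train a SOM
    on all compounds and draw VA members uniformly over compounds of the
    needed class, which spreads the set across occupied neurons in
    proportion to their occupancy; (2) among the remainder, compounds on
    neurons holding at most two objects are reserved for TR; (3) TE1 and
    TE2 quotas are filled round-robin, one compound per multiply-occupied
    neuron per pass (falling back to the TR reserve only if the map runs
    dry); (4) everything left goes to TR.  Deterministic for a fixed seed.
    """
    if schedule is None:
        schedule = LearningSchedule(epochs=10)
    y = dataset.y
    totals = {1: int(np.sum(y == 1)), 0: int(np.sum(y == 0))}
    for name in ("TR", "TE1", "TE2", "VA"):
        if name not in quotas:
            raise ValueError(f"missing quota for set {name}")
    want = {1: sum(q[0] for q in quotas.values()),
            0: sum(q[1] for q in quotas.values())}
    if want != totals:
        raise ValueError(
            f"quotas do not partition the classes: need {want}, have {totals}"
        )

    rng = np.random.default_rng(seed)
    grid = train_som(dataset.X, grid_shape, schedule, seed)
    mapping = top_map(grid, dataset.X)
    labels = np.array(["unassigned"] * dataset.n_compounds, dtype=object)

    # neurons ordered by occupancy (dense regions first), then row-major
    neurons = sorted(mapping, key=lambda k: (-len(mapping[k]), k))
    remaining = {k: list(v) for k, v in mapping.items()}

    def take(i: int, set_name: str) -> None:
        for members in remaining.values():
            if i in members:
                members.remove(i)
                break
        labels[i] = set_name

    def fill_uniform(set_name: str, n_pos: int, n_neg: int) -> None:
        """Uniform draw over remaining compounds of each class (so dense
        neurons contribute proportionally to their occupancy)."""
        for cls, need in ((1, n_pos), (0, n_neg)):
            for _ in range(need):
                pool = sorted(i for members in remaining.values()
                              for i in members if y[i] == cls)
                if not pool:
                    raise ValueError(
                        f"infeasible quota for {set_name}: ran out of "
                        f"class-{cls} compounds"
                    )
                take(pool[int(rng.integers(len(pool)))], set_name)

    def fill(set_name: str, n_pos: int, n_neg: int, eligible) -> None:
        need = {1: n_pos, 0: n_neg}
        progress = True
        while (need[1] > 0 or need[0] > 0) and progress:
            progress = False
            for neuron in neurons:
                if neuron not in remaining or not eligible(neuron):
                    continue
                members = remaining[neuron]
                for cls in (1, 0):
                    if need[cls] <= 0:
                        continue
                    pool = [i for i in members if y[i] == cls]
                    if not pool:
                        continue
                    take(pool[int(rng.integers(len(pool)))], set_name)
                    need[cls] -= 1
                    progress = True
                    break  # one compound per neuron per pass
        # fallback: draw from whatever is left anywhere on the map
        for cls in (1, 0):
            while need[cls] > 0:
                pool = [i for members in remaining.values() for i in members
                        if y[i] == cls]
                if not pool:
                    raise ValueError(
                        f"infeasible quota for {set_name}: short {need[cls]} "
                        f"compounds of class {cls}"
                    )
                take(pool[int(rng.integers(len(pool)))], set_name)
                need[cls] -= 1

    # 1. external validation set, spread across the whole occupied map
    fill_uniform("VA", *quotas["VA"])

    # 2. sparse neurons (<= 2 objects left) are reserved for the training set
    tr_reserved = {n for n in neurons if n in remaining and len(remaining[n]) <= 2}

    # 3. test sets from multiply-occupied neurons, round-robin
    fill("TE1", *quotas["TE1"], eligible=lambda n: n not in tr_reserved)
    fill("TE2", *quotas["TE2"], eligible=lambda n: n not in tr_reserved)

    # 4. remainder is the training set (quota arithmetic guarantees the counts)
    labels[labels == "unassigned"] = "TR"
    return labels
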