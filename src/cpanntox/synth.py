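"""Seeded generator of QSAR-like imbalanced descriptor datasets.

The generator emulates the shape of a curated drug hepatotoxicity table:
a few hundred compounds with binary labels at roughly 1:3 imbalance, a few
hundred block-correlated numeric descriptor columns of which only a
minority is informative, and an optional admixture of "activity cliffs" —
near-identical descriptor vectors carrying opposite labels, the hardest
failure mode of similarity-based classifiers.

Descriptors are drawn from correlated Gaussian blocks: each block shares a
latent factor so that within-block pairwise correlation equals
``block_correlation`` in expectation, which gives closed-form control over
both the correlation filter and the SOM clustering behavior.  Informative
columns are shifted by ``effect_size`` (in within-class standard-deviation
units) for the positive class.  Cliff pairs are created by copying positive
compounds with tiny descriptor noise and a negative label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataprep import DescriptorDataset, filter_descriptors, zscore_fit, zscore_apply
from .dataprep import reduce_descriptors_som, split_sets_som
from .som import LearningSchedule

__all__ = [
    "SynthSpec",
    "generate_dataset",
    "SET_LAYOUTS",
    "StudyShapeBundle",
    "study_shape_fixture",
]

#: Per-class (positive, negative) quotas of the two study set layouts.
#: Layout "a": imbalanced training set of 404 compounds (108 toxic / 296
#: non-toxic) with small equal test and validation sets.  Layout "b":
#: manually balanced training set (108 / 108) with the surplus negatives
#: pushed into the test and validation sets.  Both partition 168 positives
#: and 356 negatives (524 compounds).
SET_LAYOUTS: dict[str, dict[str, tuple[int, int]]] = {
    "a": {"TR": (108, 296), "TE1": (20, 20), "TE2": (20, 20), "VA": (20, 20)},
    "b": {"TR": (108, 108), "TE1": (20, 83), "TE2": (20, 83), "VA": (20, 82)},
}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic dataset draw."""

    n_pos: int = 108
    n_neg: int = 296
    n_descriptors: int = 300
    n_informative: int = 20
    block_correlation: float = 0.5
    effect_size: float = 1.0
    cliff_fraction: float = 0.0
    seed: int = 0
    block_size: int = 10

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.n_descriptors) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_informative <= self.n_descriptors:
            raise ValueError("need 0 <= n_informative <= n_descriptors")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        if not 0.0 <= self.cliff_fraction <= 1.0:
            raise ValueError("cliff_fraction must be in [0, 1]")


def generate_dataset(spec: SynthSpec) -> DescriptorDataset:
    """Draw one dataset; exact class counts, bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    n_cliffs = int(round(spec.cliff_fraction * spec.n_pos))
    n_cliffs = min(n_cliffs, spec.n_pos, spec.n_neg)
    n_base = spec.n_pos + (spec.n_neg - n_cliffs)

    n_blocks = -(-spec.n_descriptors // spec.block_size)  # ceil
    rho = spec.block_correlation
    factors = rng.standard_normal((n_base, n_blocks))
    X = np.empty((n_base, spec.n_descriptors))
    for j in range(spec.n_descriptors):
        # soft block membership: each descriptor mixes its primary block
        # factor with a random second block, so the descriptor vectors form
        # a correlated continuum rather than tight, well-separated clusters
        b1 = j // spec.block_size
        b2 = int((b1 + 1 + rng.integers(n_blocks - 1)) % n_blocks) if n_blocks > 1 else b1
        u = float(rng.random()) if n_blocks > 1 else 0.0
        shared = np.sqrt(1 - u) * factors[:, b1] + np.sqrt(u) * factors[:, b2]
        eps = rng.standard_normal(n_base)
        X[:, j] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps

    y = np.concatenate([np.ones(spec.n_pos, dtype=int),
                        np.zeros(spec.n_neg - n_cliffs, dtype=int)])
    X[:spec.n_pos, :spec.n_informative] += spec.effect_size

    if n_cliffs:
        # near-duplicates of the first positives, labelled negative
        cliffs = X[:n_cliffs] + 0.01 * rng.standard_normal((n_cliffs, spec.n_descriptors))
        X = np.vstack([X, cliffs])
        y = np.concatenate([y, np.zeros(n_cliffs, dtype=int)])

    n_total = spec.n_pos + spec.n_neg
    ids = [f"C{i + 1:04d}" for i in range(n_total)]
    names = [f"D{j + 1:04d}" for j in range(spec.n_descriptors)]
    return DescriptorDataset(ids=ids, X=X, descriptor_names=names, y=y)


@dataclass
class StudyShapeBundle:
    """Study-scale preparation bundle: one dataset, both set layouts.

    ``set_labels[layout]`` is the per-compound TR/TE1/TE2/VA assignment for
    that layout; ``pools[layout]`` maps SOM grid size ("5x5", "7x7",
    "10x10") to the reduced candidate descriptor pool computed on the
    non-validation compounds.
    """

    dataset: DescriptorDataset
    set_labels: dict[str, np.ndarray] = field(default_factory=dict)
    pools: dict[str, dict[str, list[str]]] = field(default_factory=dict)


def study_shape_fixture(seed: int = 0) -> StudyShapeBundle:
    """Full preparation pipeline at study scale.

    Generates 524 compounds (168 toxic / 356 non-toxic) with 600
    block-correlated descriptors built to pass the constant/correlation
    filters, then for each set layout: splits compounds on a compound
    top-map to the exact per-class quotas, and reduces the descriptor pool
    on 5x5, 7x7 and 10x10 maps of the transposed (descriptor) matrix using
    the non-validation compounds.
    """
    spec = SynthSpec(
        n_pos=168, n_neg=356, n_descriptors=600, n_informative=40,
        block_correlation=0.5, effect_size=1.0, cliff_fraction=0.02, seed=seed,
    )
    ds = generate_dataset(spec)
    Xf, names, log = filter_descriptors(ds.X, ds.descriptor_names)
    ds = ds.select_descriptors(names)

    schedule = LearningSchedule(epochs=5)
    bundle = StudyShapeBundle(dataset=ds)
    for k, layout in enumerate(SET_LAYOUTS):
        labels = split_sets_som(
            ds, grid_shape=(10, 10), quotas=SET_LAYOUTS[layout],
            schedule=schedule, seed=seed + 1000 * (k + 1),
        )
        bundle.set_labels[layout] = labels
        model_rows = labels != "VA"
        Xm = ds.X[model_rows]
        norm = zscore_fit(Xm, ds.descriptor_names)
        Z = zscore_apply(Xm, norm)
        bundle.pools[layout] = {
            f"{g}x{g}": reduce_descriptors_som(
                Z, ds.descriptor_names, (g, g), schedule,
                seed=seed + 1000 * (k + 1) + g,
            )
            for g in (5, 7, 10)
        }
    return bundle
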