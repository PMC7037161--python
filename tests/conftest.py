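import numpy as np
import pytest

from cpanntox.dataprep import DescriptorDataset
from cpanntox.synth import study_shape_fixture


@pytest.fixture(scope="session")
def study_bundle():
    """Study-scale preparation bundle (524 compounds, 600 descriptors)."""
    return study_shape_fixture(seed=0)


def make_split_problem(seed: int, n_descriptors: int = 8, n_tr: int = 60,
                       n_te: int = 40, effect: float = 3.0) -> DescriptorDataset:
    """TR/TE1 toy problem where only the first descriptor separates classes."""
    rng = np.random.default_rng(seed)
    n = n_tr + n_te
    X = rng.standard_normal((n, n_descriptors))
    y = rng.permutation(np.concatenate([np.ones(n // 4, int),
                                        np.zeros(n - n // 4, int)]))
    X[y == 1, 0] += effect
    labels = np.array(["TR"] * n_tr + ["TE1"] * n_te, dtype=object)
    labels = labels[rng.permutation(n)]
    return DescriptorDataset(
        ids=[f"C{i:03d}" for i in range(n)],
        X=X,
        descriptor_names=[f"D{j + 1}" for j in range(n_descriptors)],
        y=y,
        set_label=labels,
    )
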