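"""Published per-model statistics bundled as a numeric fixture.

``reported_model_stats()`` loads a published per-model sensitivity/
specificity table for 148 accepted hepatotoxicity models (three
optimization criteria, three descriptor pools; mean and standard deviation
over 100 retrains on the training, two test, and external validation
sets).  Rows are grouped by training regime: group ``a`` — the
fixed manually-balanced training set (24 models); group ``b`` — the
imbalanced training set with per-epoch balanced subsampling (124 models).

These numbers are inputs, not outputs: the package uses them for summary
arithmetic (group counts, column means), never as training data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["reported_model_stats", "group_summary"]


def reported_model_stats() -> pd.DataFrame:
    """Load the bundled per-model statistics table."""
    ref = resources.files("cpanntox.data") / "reported_model_stats.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def group_summary(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-group model counts and external-validation column means.

    Returns one row per training-regime group with columns ``n_models``,
    ``va_sens_mean`` and ``va_spec_mean``.
    """
    if df is None:
        df = reported_model_stats()
    out = df.groupby("group").agg(
        n_models=("model", "size"),
        va_sens_mean=("va_sens", "mean"),
        va_spec_mean=("va_spec", "mean"),
    )
    return out.reset_index()
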