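"""Dataset, config and model-store I/O.

The on-disk dataset format is a CSV/TSV table with a header row::

    compound_id, class, [set,] <descriptor columns...>

``class`` is 0/1 (1 = hepatotoxic); the optional ``set`` column holds
TR/TE1/TE2/VA/unassigned.  Values round-trip at full precision.  Model
stores are directories of one JSON document per accepted model plus an
``index.json`` listing them; run configs are flat JSON objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cpann import CpannModel
from .dataprep import DescriptorDataset, SET_LABELS

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_config",
    "write_config",
    "save_models",
    "load_models",
]

_RESERVED = ("compound_id", "class", "set")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_dataset(path: str | Path) -> DescriptorDataset:
    """Read a descriptor table, validating schema and values."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"compound_id": str},
                     float_precision="round_trip")
    for col in ("compound_id", "class"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    ids = df["compound_id"].tolist()
    dupes = df["compound_id"][df["compound_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path.name}: duplicate compound ids: {dupes[:5]}")
    cls = df["class"]
    bad = ~cls.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path.name}: class must be 0 or 1; row {row + 1} "
            f"(id {ids[row]}) has {cls.iloc[row]!r}"
        )
    if "set" in df.columns:
        labels = df["set"].astype(str).to_numpy(dtype=object)
        unknown = sorted(set(labels) - set(SET_LABELS))
        if unknown:
            raise ValueError(f"{path.name}: unknown set labels {unknown}")
    else:
        labels = None
    desc_cols = [c for c in df.columns if c not in _RESERVED]
    if not desc_cols:
        raise ValueError(f"{path.name}: no descriptor columns found")
    X = np.empty((len(df), len(desc_cols)))
    for j, col in enumerate(desc_cols):
        numeric = pd.to_numeric(df[col], errors="coerce")
        nan = numeric.isna()
        if nan.any():
            row = int(np.flatnonzero(nan)[0])
            raise ValueError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in "
                f"column {col!r}, row {row + 1} (id {ids[row]})"
            )
        X[:, j] = numeric.to_numpy(dtype=float)
    return DescriptorDataset(
        ids=ids, X=X, descriptor_names=desc_cols,
        y=cls.to_numpy(dtype=int), set_label=labels,
    )


def write_dataset(dataset: DescriptorDataset, path: str | Path) -> None:
    path = Path(path)
    # default float formatting is repr-based: shortest exact round-trip
    dataset.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def read_config(path: str | Path) -> dict:
    """Flat key-value run config (JSON)."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


def save_models(models: list[CpannModel], directory: str | Path,
                meta: list[dict] | None = None) -> None:
    """Write one JSON document per model plus an index file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for k, model in enumerate(models):
        name = f"model_{k:03d}.json"
        (directory / name).write_text(model.to_json())
        entry = {"file": name, "n_descriptors": len(model.descriptor_names)}
        if meta is not None:
            entry.update(meta[k])
        index.append(entry)
    write_config({"models": index}, directory / "index.json")


def load_models(directory: str | Path) -> list[CpannModel]:
    directory = Path(directory)
    index = read_config(directory / "index.json")
    return [
        CpannModel.from_json((directory / entry["file"]).read_text())
        for entry in index["models"]
    ]
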