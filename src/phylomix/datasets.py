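"""In-memory dataset containers and TSV/CSV readers/writers.

Abundance tables are samples x taxa: the first column holds sample IDs and
the header row holds taxon IDs that must match tree leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "read_abundance",
    "read_labels",
    "write_abundance",
    "write_labels",
]


@dataclass
class LabeledDataset:
    """An abundance matrix with aligned labels.

    ``X`` is ``(n, p)`` nonnegative; ``y`` is length ``n`` (binary 0/1 on
    input; possibly continuous after augmentation). ``mode`` declares whether
    rows are raw counts or relative abundances. ``provenance`` carries
    per-synthetic-row records when the dataset was produced by augmentation.
    """

    X: np.ndarray
    y: np.ndarray
    taxa: tuple[str, ...]
    sample_ids: tuple[str, ...] | None = None
    mode: str = "count"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.taxa = tuple(self.taxa)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x taxa)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        if self.X.shape[1] != len(self.taxa):
            raise ValueError("X and taxa disagree on the number of taxa")
        if np.any(self.X < 0):
            raise ValueError("negative abundance values")
        if self.mode not in ("count", "relative"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.sample_ids is None:
            self.sample_ids = tuple(f"S{i}" for i in range(self.n))
        else:
            self.sample_ids = tuple(self.sample_ids)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_abundance(path) -> pd.DataFrame:
    """Read a samples x taxa abundance table (TSV or CSV by extension)."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError("abundance table needs at least 2 taxon columns")
    if (df.values < 0).any():
        raise ValueError("abundance table contains negative values")
    return df


def read_labels(path) -> pd.Series:
    df = _read_table(path)
    return df.iloc[:, 0]


def make_dataset(
    abundance: pd.DataFrame, labels: pd.Series, mode: str = "count"
) -> LabeledDataset:
    """Align labels to abundance rows by sample ID and bundle them."""
    missing = [s for s in abundance.index if s not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    y = labels.loc[abundance.index].to_numpy(dtype=float)
    return LabeledDataset(
        X=abundance.to_numpy(dtype=float),
        y=y,
        taxa=tuple(abundance.columns),
        sample_ids=tuple(str(s) for s in abundance.index),
        mode=mode,
    )


def write_abundance(ds: LabeledDataset, path) -> None:
    df = pd.DataFrame(ds.X, index=list(ds.sample_ids), columns=list(ds.taxa))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_labels(ds: LabeledDataset, path) -> None:
    ser = pd.Series(ds.y, index=list(ds.sample_ids), name="label")
    ser.index.name = "sample_id"
    ser.to_csv(Path(path), sep="\t")
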