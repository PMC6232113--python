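"""Molecular-matrix and survival-table harmonization.

Abundance matrices arrive normalized and log-scaled per dataset (array
normalization is upstream of this package); here each feature is z-scored
within its dataset, samples are median-dichotomized into binary risk groups,
and multiple datasets are pooled over their shared feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "zscore",
    "dichotomize",
    "pool_datasets",
]


@dataclass
class ExpressionMatrix:
    """Features × samples matrix of normalized, log-scale abundance."""

    dataset_id: str
    values: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, path: str | Path, dataset_id: str | None = None
                 ) -> "ExpressionMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(dataset_id or path.stem, df.astype(float))

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


@dataclass
class SurvivalTable:
    """Right-censored time-to-event outcomes, one row per sample."""

    data: pd.DataFrame = field(repr=False)  # index sample_id; time, event

    def __post_init__(self) -> None:
        d = self.data
        if not {"time", "event"} <= set(d.columns):
            raise ValueError("survival table needs 'time' and 'event' columns")
        if d.index.has_duplicates:
            raise ValueError("duplicate sample ids in survival table")
        if (d["time"] <= 0).any():
            bad = d.index[d["time"] <= 0][0]
            raise ValueError(f"non-positive survival time (sample {bad})")
        if not d["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        d = d[["time", "event"]].astype({"time": float, "event": int})
        d.index.name = "sample_id"
        self.data = d

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def subset(self, sample_ids) -> "SurvivalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples missing from survival table: {missing[:5]}")
        return SurvivalTable(self.data.loc[list(sample_ids)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SurvivalTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if "sample_id" not in df.columns:
            raise ValueError(f"{path}: missing 'sample_id' column")
        df["sample_id"] = df["sample_id"].astype(str)
        return cls(df.set_index("sample_id"))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    def prefix_samples(self, prefix: str) -> "SurvivalTable":
        d = self.data.copy()
        d.index = [f"{prefix}:{s}" for s in d.index]
        return SurvivalTable(d)


def zscore(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert each feature to z-scores within the dataset.

    Per feature: (x − mean) / sd with the n−1 sample standard deviation.
    Constant features and features with missing entries cannot be scaled and
    are dropped with a logged warning.
    """
    vals = matrix.values
    finite = vals.notna().all(axis=1)
    sd = vals.std(axis=1, ddof=1)
    keep = finite & (sd > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d constant or incomplete feature(s) during z-scoring",
            matrix.dataset_id, n_dropped,
        )
    v = vals.loc[keep]
    z = v.sub(v.mean(axis=1), axis=0).div(v.std(axis=1, ddof=1), axis=0)
    return ExpressionMatrix(matrix.dataset_id, z)


def dichotomize(values: pd.Series, threshold: float) -> pd.Series:
    """Binary risk grouping: 1 if strictly above threshold, else 0.

    Values exactly at the threshold fall in group 0, so a median split puts
    at most half the samples in the high group.
    """
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values cannot be dichotomized")
    return pd.Series((arr > threshold).astype(int), index=values.index,
                     name=values.name)


def pool_datasets(matrices: list[ExpressionMatrix],
                  dataset_id: str = "pooled") -> ExpressionMatrix:
    """Concatenate independently z-scored datasets over shared features.

    Features outside the intersection are dropped (logged); sample ids are
    prefixed with their dataset id so pooled columns stay unique.
    """
    if not matrices:
        raise ValueError("no matrices to pool")
    common = set(matrices[0].feature_ids)
    union = set(matrices[0].feature_ids)
    for m in matrices[1:]:
        common &= set(m.feature_ids)
        union |= set(m.feature_ids)
    if not common:
        raise ValueError("empty feature intersection across datasets")
    if union - common:
        logger.info("pooling lost %d feature(s) outside the intersection",
                    len(union - common))
    order = sorted(common)
    blocks = []
    for m in matrices:
        block = m.values.loc[order].copy()
        block.columns = [f"{m.dataset_id}:{s}" for s in block.columns]
        blocks.append(block)
    return ExpressionMatrix(dataset_id, pd.concat(blocks, axis=1))
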