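"""Feature matrix container (samples x electrode-wise coefficients + label).

Serialized layout: one row per sample, columns ``sample_id``, the E*M feature
columns, and a final ``sample_type`` label column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """N samples x (E·M) real-valued features plus one class label each."""

    feature_names: list[str]
    values: np.ndarray = field(repr=False)
    labels: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, f = self.values.shape
        if len(self.feature_names) != f:
            raise ValueError("feature name count != column count")
        if len(set(self.feature_names)) != f:
            raise ValueError("feature names must be unique")
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids must align with rows")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        df["sample_type"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "sample_type" not in df.columns:
            raise ValueError("missing sample_type column")
        ids = (df["sample_id"].astype(str).tolist()
               if "sample_id" in df.columns
               else [str(i) for i in range(len(df))])
        feats = [c for c in df.columns if c not in ("sample_id", "sample_type")]
        return cls(feature_names=feats,
                   values=df[feats].to_numpy(dtype=float),
                   labels=df["sample_type"].astype(str).tolist(),
                   sample_ids=ids)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_dataframe(pd.read_csv(path))

    def select(self, rows: np.ndarray | Sequence[int] | None = None,
               columns: Sequence[str] | None = None) -> "FeatureMatrix":
        """Row/column subset, preserving order of the given selectors."""
        rows = np.arange(self.n_samples) if rows is None else np.asarray(rows)
        if columns is None:
            cols = np.arange(self.n_features)
            names = self.feature_names
        else:
            index = {n: i for i, n in enumerate(self.feature_names)}
            cols = np.array([index[c] for c in columns])
            names = list(columns)
        return FeatureMatrix(
            feature_names=names,
            values=self.values[np.ix_(rows, cols)],
            labels=[self.labels[i] for i in rows],
            sample_ids=[self.sample_ids[i] for i in rows])

    def relabel(self, mapping: dict[str, str]) -> "FeatureMatrix":
        return FeatureMatrix(
            feature_names=list(self.feature_names),
            values=self.values.copy(),
            labels=[mapping.get(l, l) for l in self.labels],
            sample_ids=list(self.sample_ids))


def assemble_matrix(vectors: Sequence[np.ndarray],
                    labels: Sequence[str],
                    feature_names: Sequence[str] | None = None,
                    sample_ids: Sequence[str] | None = None) -> FeatureMatrix:
    """Stack per-subject feature vectors into a :class:`FeatureMatrix`.

    All vectors must share one length; ``labels`` must align with ``vectors``.
    """
    if len(vectors) == 0:
        raise ValueError("no feature vectors to assemble")
    if len(labels) != len(vectors):
        raise ValueError("labels must align with vectors")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"ragged feature vectors: lengths {sorted(lengths)}")
    values = np.vstack([np.asarray(v, dtype=float) for v in vectors])
    if feature_names is None:
        feature_names = [f"f{i:04d}" for i in range(values.shape[1])]
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(values.shape[0])]
    return FeatureMatrix(list(feature_names), values, list(labels),
                         list(sample_ids))
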