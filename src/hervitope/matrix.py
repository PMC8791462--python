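"""Expression matrix container.

A thin, validated wrapper around a features x samples :class:`pandas.DataFrame`
with an explicit *layer* tag so downstream stages can assert they received
raw counts versus CPM versus log2-CPM values.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LAYERS = ("raw_counts", "cpm", "log2cpm")


class ExpressionMatrix:
    """Features x samples abundance matrix with a named normalization layer.

    Parameters
    ----------
    values
        Nonnegative matrix, one row per feature, one column per sample.
    feature_ids, sample_ids
        Unique identifiers for rows and columns.
    layer
        One of ``raw_counts``, ``cpm``, ``log2cpm``.  ``raw_counts`` must be
        (numerically) nonnegative integers.
    """

    def __init__(
        self,
        values: np.ndarray | pd.DataFrame,
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
        layer: str = "raw_counts",
    ) -> None:
        if isinstance(values, pd.DataFrame):
            feature_ids = list(values.index) if feature_ids is None else list(feature_ids)
            sample_ids = list(values.columns) if sample_ids is None else list(sample_ids)
            values = values.to_numpy()
        if feature_ids is None or sample_ids is None:
            raise ValueError("feature_ids and sample_ids are required for array input")
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if values.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(feature_ids)} features "
                f"x {len(sample_ids)} samples"
            )
        if layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {layer!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if np.any(values < 0):
            raise ValueError("values must be nonnegative")
        if layer == "raw_counts" and not np.allclose(values, np.round(values)):
            raise ValueError("raw_counts layer must contain integer counts")
        if len(set(feature_ids)) != len(feature_ids):
            raise ValueError("feature_ids must be unique")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique")
        self.values = values
        self.feature_ids = list(feature_ids)
        self.sample_ids = list(sample_ids)
        self.layer = layer

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, layer: str = "raw_counts") -> "ExpressionMatrix":
        return cls(df, layer=layer)

    # -- views ------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.values[:, idx], self.feature_ids, sample_ids, self.layer)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        feature_ids = list(feature_ids)
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return ExpressionMatrix(self.values[idx, :], feature_ids, self.sample_ids, self.layer)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_features} features x {self.n_samples} samples, "
            f"layer={self.layer!r})"
        )
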