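"""Standardization, winsorization and correlation summaries of the design.

The analysis convention: each column is z-scored against its own sample mean
and SD (divisor n-1), then clamped to +/- 5 SD.  Means and SDs are computed
before clamping and retained so component-unit effects can be converted back
to raw exposure units; they are never recomputed after winsorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


class ZeroVarianceError(ValueError):
    """A column has no variance and cannot be standardized."""


@dataclass
class StandardizedMatrix:
    """Column-standardized (and optionally winsorized) design matrix."""

    frame: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    clip_bound: float | None = None
    units: dict[str, str | None] = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


class ClippedStandardizer(TransformerMixin, BaseEstimator):
    """Z-score columns (sample SD, divisor n-1), then clamp to ``+/- clip``.

    ``clip=None`` disables winsorization.  Raw means and SDs are stored as
    ``mean_`` and ``scale_`` for unit back-conversion.
    """

    def __init__(self, clip: float | None = 5.0):
        self.clip = clip

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.isna().any().any():
            bad = list(X.columns[X.isna().any()])
            raise ValueError(f"missing values are not supported (columns {bad})")
        sds = X.std(ddof=1)
        zero = sds[(sds == 0) | sds.isna()]
        if len(zero):
            raise ZeroVarianceError(
                f"zero-variance column(s): {list(zero.index)}"
            )
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean()
        self.scale_ = sds
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        Z = (X[list(self.feature_names_in_)] - self.mean_) / self.scale_
        if self.clip is not None:
            Z = Z.clip(lower=-self.clip, upper=self.clip)
        return Z


def standardize(table: pd.DataFrame, units: dict[str, str | None] | None = None) -> StandardizedMatrix:
    """Z-score each column (no winsorization yet)."""
    est = ClippedStandardizer(clip=None).fit(table)
    return StandardizedMatrix(
        frame=est.transform(table),
        means=est.mean_,
        sds=est.scale_,
        clip_bound=None,
        units=dict(units or {}),
    )


def winsorize(matrix: StandardizedMatrix, c: float = 5.0) -> StandardizedMatrix:
    """Clamp standardized values to [-c, c]; moments are left untouched."""
    if c <= 0:
        raise ValueError("winsorization bound must be > 0")
    return StandardizedMatrix(
        frame=matrix.frame.clip(lower=-c, upper=c),
        means=matrix.means,
        sds=matrix.sds,
        clip_bound=c,
        units=matrix.units,
    )


def correlation_matrix(matrix: StandardizedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations (symmetric, unit diagonal)."""
    frame = matrix.frame if isinstance(matrix, StandardizedMatrix) else pd.DataFrame(matrix)
    if len(frame) < 2:
        raise ValueError("correlation requires at least 2 rows")
    R = np.corrcoef(frame.to_numpy(), rowvar=False)
    R = np.atleast_2d(R)
    return pd.DataFrame(R, index=frame.columns, columns=frame.columns)
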