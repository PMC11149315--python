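"""The five data-quality scores, each in [0, 1] with higher = better.

Fixed component order: Pearson, Spearman, Missing, Outliers, ClassOverlap.

Conventions (declared once, used everywhere):

* Correlation qualities aggregate the mean of **absolute** pairwise
  coefficients over pairwise-complete observations; undefined pairs
  (constant column, fewer than 2 complete pairs) contribute 0.
* The outlier rule flags a cell when ``|x - median| / MAD > 3`` with no
  consistency scaling; a column with ``MAD == 0`` flags nothing.  The score
  is 1 minus the fraction of rows containing at least one flagged cell.
* Class overlap uses Euclidean distance on unstandardized features with
  per-column median imputation; a sample is overlapped when strictly more
  than ``theta`` of its ``k`` nearest neighbors (self excluded, distance
  ties broken by ascending row index) carry a foreign label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

if TYPE_CHECKING:  # pragma: no cover
    from .io import MasterTable, SearchConfig

#: Names of the five components, in the fixed order of :class:`QualityVector`.
METRIC_NAMES = ("pc_q", "spearman_q", "missing_q", "outlier_q", "overlap_q")


@dataclass(frozen=True)
class QualityVector:
    """The five quality scores of one (sub-)table, each in [0, 1]."""

    pc_quality: float
    spearman_quality: float
    missing_quality: float
    outlier_quality: float
    overlap_quality: float

    def __post_init__(self) -> None:
        for name, value in zip(METRIC_NAMES, self.as_array()):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} = {value} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.pc_quality,
                self.spearman_quality,
                self.missing_quality,
                self.outlier_quality,
                self.overlap_quality,
            ]
        )


@dataclass(frozen=True)
class OutlierReport:
    """Per-column MAD statistics and the cell-level outlier flags."""

    median: np.ndarray
    mad: np.ndarray
    flags: np.ndarray  # boolean, same shape as the feature matrix
    flagged_row_count: int


@dataclass(frozen=True)
class OverlapReport:
    """Per-sample foreign-neighbor counts and the overlap (R) value."""

    foreign_counts: np.ndarray
    overlapped: np.ndarray  # boolean per sample
    r_value: float


def _mean_abs_offdiagonal(corr: np.ndarray) -> float:
    """Mean |coefficient| over the upper triangle; NaN entries count as 0."""
    iu = np.triu_indices(corr.shape[0], k=1)
    values = np.abs(corr[iu])
    return float(np.where(np.isnan(values), 0.0, values).mean())


def _correlation_quality(features: np.ndarray, method: str) -> float:
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] < 2:
        raise ValueError("correlation quality needs at least 2 feature columns")
    corr = pd.DataFrame(features).corr(method=method, min_periods=2).to_numpy()
    return 1.0 - _mean_abs_offdiagonal(corr)


def pearson_quality(features: np.ndarray) -> float:
    """1 minus the mean absolute pairwise Pearson correlation."""
    return _correlation_quality(features, "pearson")


def spearman_quality(features: np.ndarray) -> float:
    """1 minus the mean absolute pairwise Spearman rank correlation.

    Mid-ranks are used for ties, which reduces to the classical
    ``1 - 6 * sum(d_i^2) / (n (n^2 - 1))`` rank-difference formula when the
    data are tie-free.
    """
    return _correlation_quality(features, "spearman")


def missing_quality(features: np.ndarray) -> float:
    """1 minus the fraction of missing feature cells."""
    features = np.asarray(features, dtype=float)
    if features.size == 0:
        raise ValueError("missing quality needs at least one feature cell")
    return 1.0 - float(np.isnan(features).mean())


def outlier_quality(features: np.ndarray) -> tuple[float, OutlierReport]:
    """Row-level outlier score under the 3-MAD rule.

    Returns ``1 - (#rows with >= 1 flagged cell) / N`` and the full report.
    """
    features = np.asarray(features, dtype=float)
    if features.size == 0 or np.isnan(features).all():
        raise ValueError("outlier quality needs at least one non-missing value")
    median = np.nanmedian(features, axis=0)
    mad = np.nanmedian(np.abs(features - median), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        deviation = np.abs(features - median) / np.where(mad > 0, mad, np.nan)
    flags = np.where(np.isnan(deviation), False, deviation > 3.0)
    flagged_rows = int(flags.any(axis=1).sum())
    score = 1.0 - flagged_rows / features.shape[0]
    return score, OutlierReport(
        median=median, mad=mad, flags=flags, flagged_row_count=flagged_rows
    )


def _median_impute(features: np.ndarray) -> np.ndarray:
    """Fill NaNs with per-column medians (all-missing columns become 0)."""
    features = np.array(features, dtype=float, copy=True)
    if not np.isnan(features).any():
        return features
    with np.errstate(all="ignore"):
        fill = np.nanmedian(features, axis=0)
    fill = np.where(np.isnan(fill), 0.0, fill)
    mask = np.isnan(features)
    features[mask] = np.broadcast_to(fill, features.shape)[mask]
    return features


_OVERLAP_BLOCK = 1024  # rows per pairwise-distance block, caps memory at ~N*8KB


def class_overlap_quality(
    features: np.ndarray,
    labels: np.ndarray,
    knn_k: int = 7,
    knn_theta: int = 3,
) -> tuple[float, OverlapReport]:
    """1 minus the class-overlap R value.

    A sample is overlapped when strictly more than ``knn_theta`` of its
    ``knn_k`` nearest neighbors belong to another class.  With the default
    k=7, theta=3 a sample needs at least four foreign neighbors.
    """
    features = _median_impute(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    n = features.shape[0]
    if n <= knn_k:
        raise ValueError(f"class overlap needs more than knn_k={knn_k} samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("class overlap needs at least 2 classes")

    foreign_counts = np.empty(n, dtype=int)
    for start in range(0, n, _OVERLAP_BLOCK):
        stop = min(start + _OVERLAP_BLOCK, n)
        distances = cdist(features[start:stop], features)
        for offset in range(stop - start):
            i = start + offset
            row = distances[offset].copy()
            row[i] = np.inf  # exclude self
            # stable sort => ties broken by ascending row index
            neighbors = np.argsort(row, kind="stable")[:knn_k]
            foreign_counts[i] = int(np.sum(labels[neighbors] != labels[i]))

    overlapped = foreign_counts > knn_theta
    r_value = float(overlapped.mean())
    return 1.0 - r_value, OverlapReport(
        foreign_counts=foreign_counts, overlapped=overlapped, r_value=r_value
    )


def compute_quality_vector(table: "MasterTable", config: "SearchConfig") -> QualityVector:
    """All five scores for one (sub-)table, in fixed order."""
    out_score, _ = outlier_quality(table.features)
    ovl_score, _ = class_overlap_quality(
        table.features, table.labels, config.knn_k, config.knn_theta
    )
    return QualityVector(
        pc_quality=pearson_quality(table.features),
        spearman_quality=spearman_quality(table.features),
        missing_quality=missing_quality(table.features),
        outlier_quality=out_score,
        overlap_quality=ovl_score,
    )
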