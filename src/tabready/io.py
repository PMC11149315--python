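"""Typed data model for labeled tabular datasets and CSV/JSON ingestion.

The master table is an ``N x M`` delimited file with a header row, one
designated categorical label column, and (after coercion) only numeric
feature columns.  Non-numeric feature columns are dropped with a warning
rather than raising, mirroring how clinical exports are usually cleaned.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tabready")

#: Tokens (case-insensitive) treated as missing cells on ingestion.
NA_TOKENS = frozenset({"", "na", "nan", "null"})

#: Minimum fraction of non-missing entries that must parse as numbers for a
#: column to be retained as numeric; stragglers below 1 - this become NaN.
NUMERIC_PARSE_THRESHOLD = 0.99


class SchemaError(ValueError):
    """Raised when a table cannot be coerced into a valid master table."""


@dataclass
class MasterTable:
    """A labeled numeric dataset: ``N`` rows by ``F`` feature columns.

    Parameters
    ----------
    features : ndarray of shape (N, F), dtype float64
        Feature matrix; missing cells are NaN.
    feature_names : list of str
        Unique names of the F feature columns.
    labels : ndarray of shape (N,)
        Categorical label per row (stored as strings).
    label_name : str
        Name of the label column; never among ``feature_names``.
    row_ids : ndarray of shape (N,), dtype int
        Positional identifiers of the rows in the source file (0-based).
    """

    features: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    label_name: str
    row_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise SchemaError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels).astype(str)
        if self.row_ids is None:
            self.row_ids = np.arange(self.n_rows)
        self.row_ids = np.asarray(self.row_ids, dtype=int)
        self._validate()

    def _validate(self) -> None:
        n, f = self.features.shape
        if n < 1:
            raise SchemaError("master table needs at least one row")
        if f < 2:
            raise SchemaError(
                f"master table needs at least 2 numeric feature columns, got {f}"
            )
        if len(self.feature_names) != f:
            raise SchemaError("feature_names length does not match feature matrix")
        if len(set(self.feature_names)) != f:
            raise SchemaError("feature_names must be unique")
        if self.label_name in self.feature_names:
            raise SchemaError("label column cannot also be a feature column")
        if self.labels.shape != (n,) or self.row_ids.shape != (n,):
            raise SchemaError("labels/row_ids length does not match row count")
        if len(np.unique(self.labels)) < 2:
            raise SchemaError("label column must have at least 2 distinct classes")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subtable(self, row_indices: Sequence[int], column_indices: Sequence[int]) -> "MasterTable":
        """Materialize ``master[row_indices, column_indices ∪ label]``."""
        rows = np.asarray(row_indices, dtype=int)
        cols = np.asarray(column_indices, dtype=int)
        return MasterTable(
            features=self.features[np.ix_(rows, cols)],
            feature_names=[self.feature_names[c] for c in cols],
            labels=self.labels[rows],
            label_name=self.label_name,
            row_ids=self.row_ids[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        """Features plus label column, in original column order with label last."""
        frame = pd.DataFrame(self.features, columns=self.feature_names)
        frame[self.label_name] = self.labels
        return frame

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.features)


@dataclass
class SearchConfig:
    """Parameters of the readiness search.

    Defaults follow the reference configuration: drop at most 20% of rows
    (RER) and 50% of columns (CER) per sub-table, class overlap with k=7
    neighbors and threshold 3, 10-fold cross-validation, 20 trees for both
    the classifier and the weight regressor.
    """

    d: int = 100
    R: int = 1
    RER: float = 0.2
    CER: float = 0.5
    knn_k: int = 7
    knn_theta: int = 3
    cv_folds: int = 10
    n_estimators: int = 20
    seed: int = 0
    jobs: int = 1
    standardize: bool = False
    exclude: tuple[str, ...] = ()
    delimiter: str = ","

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.d < 1:
            raise ValueError("d (sub-tables per run) must be a positive integer")
        if self.R < 1:
            raise ValueError("R (number of runs) must be a positive integer")
        if not (0.0 <= self.RER < 1.0):
            raise ValueError(f"RER must lie in [0, 1), got {self.RER}")
        if not (0.0 <= self.CER < 1.0):
            raise ValueError(f"CER must lie in [0, 1), got {self.CER}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be a positive integer")
        if not (0 <= self.knn_theta <= self.knn_k / 2):
            raise ValueError(
                f"knn_theta must lie in [0, knn_k/2] = [0, {self.knn_k / 2}]"
            )
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be a positive integer")
        if self.jobs < 1:
            raise ValueError("jobs must be a positive integer")
        self.exclude = tuple(self.exclude)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SearchConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SearchConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_mapping(json.load(handle))

    def to_dict(self) -> dict:
        out = {f: getattr(self, f) for f in self.__dataclass_fields__}
        out["exclude"] = list(self.exclude)
        return out

    def with_overrides(self, **kwargs) -> "SearchConfig":
        return replace(self, **kwargs)


def _normalize_missing(frame: pd.DataFrame) -> pd.DataFrame:
    """Map NA tokens (case-insensitive) to NaN across all columns."""

    def _clean(value):
        if isinstance(value, str) and value.strip().lower() in NA_TOKENS:
            return np.nan
        return value

    return frame.map(_clean)


def coerce_schema(
    frame: pd.DataFrame,
    label_name: str,
    exclude: Iterable[str] = (),
) -> MasterTable:
    """Coerce a raw parsed table into a :class:`MasterTable`.

    Every feature column whose non-missing entries are not at least 99%
    number-parseable is dropped (and logged); parse failures below that
    threshold become missing cells.  Columns named in ``exclude`` are dropped
    regardless of type.  Rows with a missing label are dropped with a warning.
    """
    if label_name not in frame.columns:
        raise SchemaError(f"label column {label_name!r} not found in table")
    frame = _normalize_missing(frame)

    labels = frame[label_name]
    label_missing = labels.isna()
    if label_missing.any():
        logger.warning(
            "dropping %d rows with a missing label", int(label_missing.sum())
        )
        frame = frame.loc[~label_missing]
        labels = frame[label_name]
    if frame.shape[0] < 1:
        raise SchemaError("no rows remain after removing missing labels")

    exclude = set(exclude)
    dropped: list[str] = sorted(exclude & (set(frame.columns) - {label_name}))
    kept_names: list[str] = []
    kept_columns: list[np.ndarray] = []
    for name in frame.columns:
        if name == label_name or name in exclude:
            continue
        column = frame[name]
        numeric = pd.to_numeric(column, errors="coerce")
        non_missing = column.notna()
        if non_missing.any():
            parse_rate = numeric[non_missing].notna().mean()
        else:
            parse_rate = 1.0  # all-missing column is trivially numeric
        if parse_rate >= NUMERIC_PARSE_THRESHOLD:
            kept_names.append(str(name))
            # re-parse with float() for exact round-tripping; pd.to_numeric
            # only decides parseability (its fast path loses the last ulp)
            exact = column.where(numeric.notna(), np.nan).astype(float)
            kept_columns.append(exact.to_numpy(dtype=float))
        else:
            dropped.append(str(name))

    if dropped:
        logger.warning("dropped non-numeric/excluded columns: %s", dropped)
    if len(kept_names) < 2:
        raise SchemaError(
            "fewer than 2 numeric feature columns remain after coercion "
            f"(kept {kept_names!r}, dropped {dropped!r})"
        )

    row_ids = (
        frame.index.to_numpy(dtype=int)
        if frame.index.is_unique and pd.api.types.is_integer_dtype(frame.index)
        else np.arange(frame.shape[0])
    )
    return MasterTable(
        features=np.column_stack(kept_columns),
        feature_names=kept_names,
        labels=labels.to_numpy(),
        label_name=str(label_name),
        row_ids=row_ids,
    )


def load_master(
    path: str | os.PathLike,
    label_name: str,
    *,
    delimiter: str = ",",
    exclude: Iterable[str] = (),
) -> MasterTable:
    """Read a delimited file with a header row into a :class:`MasterTable`."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    return coerce_schema(raw, label_name, exclude=exclude)


def write_master(table: MasterTable, path: str | os.PathLike) -> None:
    """Write a master table back to CSV (features then label, header row).

    Round-trips exactly through :func:`load_master`: float values are
    serialized with ``repr`` precision and missing cells as empty strings.
    """
    table.to_frame().to_csv(path, index=False, na_rep="")
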