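"""Readiness space construction, weight learning, and the random-restart
search for the highest-quality cleansed sub-table.

Each run samples ``d`` random sub-tables (uniform drop counts bounded by
the row/column exclusion ratios), scores each with the five quality
metrics plus the combined ML accuracy, and learns metric weights by forest
regression of accuracy on the metrics.  The mean weight vector across runs
scores every stored record; the global best is the cleansed output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestRegressor

from .evaluate import AccuracyRecord, evaluate_subtable
from .io import MasterTable, SearchConfig
from .metrics import QualityVector, compute_quality_vector

logger = logging.getLogger("tabready")

_MAX_SAMPLE_ATTEMPTS = 100

#: Weights fall back to uniform when the regression target is constant.
UNIFORM_WEIGHTS = np.full(5, 0.2)


@dataclass(frozen=True)
class SubTableIndex:
    """Row/column index sets into the master (label implicitly included)."""

    row_indices: np.ndarray
    column_indices: np.ndarray

    def __post_init__(self) -> None:
        for name in ("row_indices", "column_indices"):
            values = np.asarray(getattr(self, name), dtype=int)
            object.__setattr__(self, name, values)
            if values.size and np.any(np.diff(values) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    def materialize(self, master: MasterTable) -> MasterTable:
        return master.subtable(self.row_indices, self.column_indices)

    @property
    def n_rows(self) -> int:
        return len(self.row_indices)

    @property
    def n_columns(self) -> int:
        return len(self.column_indices)


@dataclass
class RunRecord:
    """One row of the readiness space: a sub-table and its scores."""

    index: SubTableIndex
    quality: QualityVector
    accuracy: AccuracyRecord
    f_tilde: float | None = None  # filled in once mean weights exist


@dataclass(frozen=True)
class WeightVector:
    """Non-negative, unit-sum weights for the five quality metrics."""

    w: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", values)
        if values.shape != (5,):
            raise ValueError("weight vector must have exactly 5 components")
        if np.any(values < 0):
            raise ValueError("weights must be non-negative")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {values.sum()}")

    @classmethod
    def normalized(cls, values) -> "WeightVector":
        """Rescale non-negative values to unit sum (e.g. externally supplied
        weights rounded for printing, which rarely sum to exactly 1)."""
        values = np.asarray(values, dtype=float)
        total = values.sum()
        if total <= 0:
            raise ValueError("weights must have a positive sum")
        return cls(w=values / total)


@dataclass
class SearchResult:
    """Everything the search produced, ordered and schedule-invariant."""

    per_run_best: list[tuple[int, RunRecord, float]]
    mean_weights: WeightVector
    global_best: RunRecord
    global_best_run: int
    run_records: list[list[RunRecord]]
    run_weights: list[WeightVector]
    baseline: RunRecord  # the master table scored under the mean weights
    provenance: dict = field(default_factory=dict)

    @property
    def best_f_tilde(self) -> float:
        return float(self.global_best.f_tilde)


def sample_subtable(
    master: MasterTable, config: SearchConfig, rng: np.random.Generator
) -> SubTableIndex:
    """Draw one random sub-table index within the RER/CER bounds.

    Drop counts are uniform on ``{0..floor(RER*N)}`` and
    ``{0..min(F-2, floor(CER*F))}``; the dropped sets are then uniform
    without replacement.  Draws whose kept rows leave fewer than 2 classes,
    or any class with fewer than 2 members, are rejected and resampled.
    """
    n, f = master.n_rows, master.n_features
    max_drop_rows = int(np.floor(config.RER * n))
    max_drop_cols = min(f - 2, int(np.floor(config.CER * f)))

    for _ in range(_MAX_SAMPLE_ATTEMPTS):
        n_drop_rows = int(rng.integers(0, max_drop_rows + 1))
        n_drop_cols = int(rng.integers(0, max_drop_cols + 1))
        dropped_rows = rng.choice(n, size=n_drop_rows, replace=False)
        dropped_cols = rng.choice(f, size=n_drop_cols, replace=False)
        rows = np.setdiff1d(np.arange(n), dropped_rows)
        cols = np.setdiff1d(np.arange(f), dropped_cols)
        _, counts = np.unique(master.labels[rows], return_counts=True)
        if len(counts) >= 2 and counts.min() >= 2:
            return SubTableIndex(row_indices=rows, column_indices=cols)
    raise RuntimeError(
        f"could not sample a valid sub-table in {_MAX_SAMPLE_ATTEMPTS} attempts; "
        "the label distribution may be degenerate"
    )


def _standardized(table: MasterTable) -> MasterTable:
    """Z-score feature columns (NaN-aware); constant columns become 0."""
    mean = np.nanmean(table.features, axis=0)
    std = np.nanstd(table.features, axis=0)
    std = np.where(std > 0, std, 1.0)
    return MasterTable(
        features=(table.features - mean) / std,
        feature_names=table.feature_names,
        labels=table.labels,
        label_name=table.label_name,
        row_ids=table.row_ids,
    )


def _score_table(
    table: MasterTable, config: SearchConfig, rng: np.random.Generator
) -> tuple[QualityVector, AccuracyRecord]:
    if config.standardize:
        table = _standardized(table)
    return compute_quality_vector(table, config), evaluate_subtable(table, config, rng)


def build_readiness_table(
    master: MasterTable,
    config: SearchConfig,
    rng: np.random.Generator,
    d: int | None = None,
) -> list[RunRecord]:
    """Sample and score ``d`` sub-tables (one run's readiness-space rows)."""
    d = config.d if d is None else d
    records: list[RunRecord] = []
    while len(records) < d:
        index = sample_subtable(master, config, rng)
        try:
            quality, accuracy = _score_table(index.materialize(master), config, rng)
        except ValueError as exc:  # degenerate sub-table: resample
            logger.debug("resampling sub-table after scoring error: %s", exc)
            continue
        records.append(RunRecord(index=index, quality=quality, accuracy=accuracy))
    return records


def learn_weights(
    records: list[RunRecord], config: SearchConfig, rng: np.random.Generator
) -> WeightVector:
    """Forest-regression feature importances of accuracy on the metrics.

    Importances are normalized to unit sum; a constant target (or an
    all-zero importance vector) falls back to uniform weights.
    """
    if len(records) < 2:
        raise ValueError("weight learning needs at least 2 readiness records")
    quality = np.array([r.quality.as_array() for r in records])
    target = np.array([r.accuracy.combined_accuracy for r in records])
    if np.ptp(target) == 0:
        return WeightVector(w=UNIFORM_WEIGHTS.copy())
    seed = int(rng.integers(2**31 - 1))
    forest = RandomForestRegressor(
        n_estimators=config.n_estimators, random_state=seed
    ).fit(quality, target)
    importances = forest.feature_importances_
    if importances.sum() <= 0:
        return WeightVector(w=UNIFORM_WEIGHTS.copy())
    return WeightVector(w=importances / importances.sum())


def total_quality(quality: QualityVector, weights: WeightVector) -> float:
    """Weighted total quality: the dot product of scores and weights."""
    value = float(np.dot(quality.as_array(), weights.w))
    return min(1.0, max(0.0, value))


def _execute_run(
    master: MasterTable, config: SearchConfig, run_seed: int
) -> tuple[list[RunRecord], WeightVector]:
    rng = np.random.default_rng(run_seed)
    records = build_readiness_table(master, config, rng)
    weights = learn_weights(records, config, rng)
    return records, weights


def _best_record(
    scored: list[tuple[int, int, RunRecord]]
) -> tuple[int, int, RunRecord]:
    """Max f_tilde; ties broken by higher accuracy, lower run id, lower record id."""
    return max(
        scored,
        key=lambda item: (
            item[2].f_tilde,
            item[2].accuracy.combined_accuracy,
            -item[0],
            -item[1],
        ),
    )


def run_search(master: MasterTable, config: SearchConfig) -> SearchResult:
    """Random-restart search over ``config.R`` runs of ``config.d`` sub-tables.

    Runs execute independently with pre-assigned seeds ``seed + r`` so the
    result is identical regardless of worker count.
    """
    run_seeds = [config.seed + r for r in range(1, config.R + 1)]
    logger.info("starting %d run(s) of %d sub-tables each", config.R, config.d)
    try:
        outcomes = Parallel(n_jobs=config.jobs)(
            delayed(_execute_run)(master, config, seed) for seed in run_seeds
        )
    except Exception as exc:
        raise RuntimeError(f"a search run failed (seeds {run_seeds}): {exc}") from exc

    run_records = [records for records, _ in outcomes]
    run_weights = [weights for _, weights in outcomes]

    mean = np.mean([w.w for w in run_weights], axis=0)
    mean_weights = WeightVector(w=mean / mean.sum())

    per_run_best: list[tuple[int, RunRecord, float]] = []
    best_so_far = -np.inf
    for run_id, records in enumerate(run_records, start=1):
        for record in records:
            record.f_tilde = total_quality(record.quality, mean_weights)
        _, _, best = _best_record(
            [(run_id, i, rec) for i, rec in enumerate(records)]
        )
        per_run_best.append((run_id, best, float(best.f_tilde)))
        best_so_far = max(best_so_far, float(best.f_tilde))
        logger.info(
            "run %d done: best f~ = %.6f (best so far %.6f)",
            run_id,
            best.f_tilde,
            best_so_far,
        )

    global_run, _, global_best = _best_record(
        [(run_id, i, rec) for run_id, recs in enumerate(run_records, start=1)
         for i, rec in enumerate(recs)]
    )

    baseline_rng = np.random.default_rng(config.seed)
    base_quality, base_accuracy = _score_table(master, config, baseline_rng)
    baseline = RunRecord(
        index=SubTableIndex(
            row_indices=np.arange(master.n_rows),
            column_indices=np.arange(master.n_features),
        ),
        quality=base_quality,
        accuracy=base_accuracy,
        f_tilde=total_quality(base_quality, mean_weights),
    )
    logger.info(
        "search finished: global best f~ = %.6f (run %d), master baseline f~ = %.6f",
        global_best.f_tilde,
        global_run,
        baseline.f_tilde,
    )

    return SearchResult(
        per_run_best=per_run_best,
        mean_weights=mean_weights,
        global_best=global_best,
        global_best_run=global_run,
        run_records=run_records,
        run_weights=run_weights,
        baseline=baseline,
        provenance={"config": config.to_dict(), "run_seeds": run_seeds},
    )
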