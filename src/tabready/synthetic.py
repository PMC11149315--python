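"""Synthetic labeled tables with planted quality defects.

Each defect axis maps onto one of the five quality metrics: duplicated
features (correlation), MCAR missingness (missing values), shifted cells
(outliers), label flips and class proximity (class overlap), and
pure-noise columns (search junk).  Generation is deterministic given the
spec's seed, and the ground-truth annotation records every planted defect
so detector recall and search behavior are testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import MasterTable


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    n_rows: int = 200
    n_informative_features: int = 5
    n_classes: int = 2
    class_separation: float = 3.0
    n_duplicate_features: int = 0
    n_noise_features: int = 0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    mislabel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < self.n_classes * 2:
            raise ValueError("need at least 2 rows per class")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_informative_features < 1:
            raise ValueError("need at least one informative feature")
        if self.n_duplicate_features > 0 and self.n_informative_features < 1:
            raise ValueError("cannot duplicate without informative features")
        for name in ("missing_rate", "outlier_rate", "mislabel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {rate}")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Indices of every planted defect, for detector/search validation."""

    duplicate_columns: np.ndarray
    noise_columns: np.ndarray
    outlier_cells: np.ndarray  # (n_outliers, 2) array of (row, col)
    mislabeled_rows: np.ndarray
    missing_cells: np.ndarray  # (n_missing, 2) array of (row, col)

    @property
    def junk_columns(self) -> np.ndarray:
        """Columns a good search should preferentially exclude."""
        return np.concatenate([self.duplicate_columns, self.noise_columns])


def _class_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Class centers with pairwise distance == class_separation.

    Uses scaled coordinate axes when the informative dimension allows,
    otherwise random directions rescaled so the closest pair of centers
    sits at the requested separation.
    """
    c, p = spec.n_classes, spec.n_informative_features
    if p >= c:
        means = np.zeros((c, p))
        for label in range(c):
            means[label, label] = spec.class_separation / np.sqrt(2.0)
        return means
    means = rng.normal(size=(c, p))
    gaps = [
        np.linalg.norm(means[i] - means[j])
        for i in range(c)
        for j in range(i + 1, c)
    ]
    smallest = min(gaps)
    if smallest == 0:
        raise ValueError("degenerate random class centers; change the seed")
    return means * (spec.class_separation / smallest)


def generate_dataset(spec: SyntheticSpec) -> tuple[MasterTable, GroundTruth]:
    """Build the table and the annotation of planted junk.

    Outlier cells are overwritten with ``median ± magnitude * (3*MAD + eps)``
    relative to the column's pre-injection statistics, so the 3-MAD rule
    recovers them whenever ``magnitude >= 1`` (at injection rates low enough
    to leave the median and MAD essentially unchanged).
    """
    rng = np.random.default_rng(spec.seed)

    per_class = np.full(spec.n_classes, spec.n_rows // spec.n_classes)
    per_class[: spec.n_rows % spec.n_classes] += 1
    labels = np.repeat(np.arange(spec.n_classes), per_class)

    means = _class_means(spec, rng)
    informative = rng.normal(size=(spec.n_rows, spec.n_informative_features))
    informative += means[labels]

    blocks = [informative]
    names = [f"inf_{i}" for i in range(spec.n_informative_features)]

    n_dup = spec.n_duplicate_features
    if n_dup:
        source = np.arange(n_dup) % spec.n_informative_features
        blocks.append(informative[:, source].copy())
        names += [f"dup_{i}" for i in range(n_dup)]
    dup_cols = np.arange(
        spec.n_informative_features, spec.n_informative_features + n_dup
    )

    if spec.n_noise_features:
        blocks.append(rng.normal(size=(spec.n_rows, spec.n_noise_features)))
        names += [f"noise_{i}" for i in range(spec.n_noise_features)]
    noise_cols = np.arange(
        spec.n_informative_features + n_dup,
        spec.n_informative_features + n_dup + spec.n_noise_features,
    )

    features = np.concatenate(blocks, axis=1)
    n_cells = features.size

    # outliers before missingness so every planted outlier stays observable
    outlier_cells = np.empty((0, 2), dtype=int)
    if spec.outlier_rate > 0:
        n_outliers = int(round(spec.outlier_rate * n_cells))
        flat = rng.choice(n_cells, size=n_outliers, replace=False)
        outlier_cells = np.column_stack(np.unravel_index(flat, features.shape))
        median = np.median(features, axis=0)
        mad = np.median(np.abs(features - median), axis=0)
        eps = 1e-6
        for row, col in outlier_cells:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            features[row, col] = median[col] + sign * spec.outlier_magnitude * (
                3.0 * mad[col] + eps
            )

    missing_cells = np.empty((0, 2), dtype=int)
    if spec.missing_rate > 0:
        n_missing = int(round(spec.missing_rate * n_cells))
        taken = {tuple(cell) for cell in outlier_cells}
        candidates = np.array(
            [i for i in range(n_cells)
             if tuple(np.unravel_index(i, features.shape)) not in taken]
        )
        n_missing = min(n_missing, len(candidates))
        flat = rng.choice(candidates, size=n_missing, replace=False)
        missing_cells = np.column_stack(np.unravel_index(flat, features.shape))
        features[missing_cells[:, 0], missing_cells[:, 1]] = np.nan

    mislabeled_rows = np.empty(0, dtype=int)
    if spec.mislabel_rate > 0:
        n_flip = int(round(spec.mislabel_rate * spec.n_rows))
        mislabeled_rows = np.sort(
            rng.choice(spec.n_rows, size=n_flip, replace=False)
        )
        for row in mislabeled_rows:
            wrong = [c for c in range(spec.n_classes) if c != labels[row]]
            labels[row] = wrong[int(rng.integers(len(wrong)))]

    table = MasterTable(
        features=features,
        feature_names=names,
        labels=np.array([f"class_{label}" for label in labels]),
        label_name="label",
    )
    truth = GroundTruth(
        duplicate_columns=dup_cols,
        noise_columns=noise_cols,
        outlier_cells=outlier_cells,
        mislabeled_rows=mislabeled_rows,
        missing_cells=missing_cells,
    )
    return table, truth
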