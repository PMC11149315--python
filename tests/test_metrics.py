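"""Unit and property tests for the five quality metrics.

Every non-trivial expected value is computed by an independent brute-force
oracle written here (textbook correlation loops, hand MAD evaluation,
exhaustive neighbor enumeration), never by the code under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabready import (
    MasterTable,
    QualityVector,
    SearchConfig,
    class_overlap_quality,
    compute_quality_vector,
    missing_quality,
    outlier_quality,
    pearson_quality,
    spearman_quality,
)

# ---------------------------------------------------------------- oracles


def pearson_pair_oracle(x, y):
    """Textbook Pearson correlation by direct summation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt((xm**2).sum() * (ym**2).sum())
    return float((xm * ym).sum() / denom) if denom > 0 else np.nan


def mean_abs_corr_oracle(features, pair_fn):
    """Brute-force double loop over all unordered feature pairs."""
    _, f = features.shape
    values = []
    for i in range(f):
        for j in range(i + 1, f):
            r = pair_fn(features[:, i], features[:, j])
            values.append(0.0 if np.isnan(r) else abs(r))
    return float(np.mean(values))


def spearman_tie_free_oracle(x, y):
    """Classical rank-difference formula; valid only without ties."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = ((rx - ry) ** 2).sum()
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def overlap_oracle(features, labels, k, theta):
    """Exhaustive O(N^2) neighbor enumeration, ties by ascending index."""
    n = len(labels)
    flagged = 0
    for i in range(n):
        dists = sorted(
            (math.dist(features[i], features[j]), j) for j in range(n) if j != i
        )
        foreign = sum(1 for _, j in dists[:k] if labels[j] != labels[i])
        if foreign > theta:
            flagged += 1
    return flagged / n


# ------------------------------------------------------------- correlation


def test_identical_features_give_zero_pc_quality():
    x = np.arange(10.0)
    assert pearson_quality(np.column_stack([x, x])) == pytest.approx(0.0)


def test_pearson_matches_brute_force_pair_loop():
    rng = np.random.default_rng(42)
    features = rng.normal(size=(8, 4))
    expected = 1.0 - mean_abs_corr_oracle(features, pearson_pair_oracle)
    assert pearson_quality(features) == pytest.approx(expected, abs=1e-12)


def test_monotone_transform_gives_unit_spearman():
    rng = np.random.default_rng(1)
    x = rng.normal(size=20)
    features = np.column_stack([x, np.exp(x)])
    assert spearman_quality(features) == pytest.approx(0.0, abs=1e-12)


def test_spearman_matches_tie_free_formula():
    rng = np.random.default_rng(7)
    features = rng.permuted(np.arange(18.0)).reshape(6, 3)  # tie-free columns
    expected = 1.0 - mean_abs_corr_oracle(
        features, lambda x, y: spearman_tie_free_oracle(x, y)
    )
    assert spearman_quality(features) == pytest.approx(expected, abs=1e-12)


def test_constant_column_contributes_zero_correlation():
    rng = np.random.default_rng(3)
    features = np.column_stack([rng.normal(size=10), np.full(10, 2.0)])
    assert pearson_quality(features) == pytest.approx(1.0)
    assert spearman_quality(features) == pytest.approx(1.0)


def test_single_feature_column_rejected():
    with pytest.raises(ValueError):
        pearson_quality(np.ones((5, 1)))
    with pytest.raises(ValueError):
        spearman_quality(np.ones((5, 1)))


def test_pairwise_complete_observations():
    # column pair shares only 3 complete rows; oracle uses the same subset
    x = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
    y = np.array([2.0, np.nan, 5.0, 9.0, 1.0])
    z = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
    features = np.column_stack([x, y, z])
    mask_xy = ~np.isnan(x) & ~np.isnan(y)
    mask_xz = ~np.isnan(x)
    expected = 1.0 - np.mean(
        [
            abs(pearson_pair_oracle(x[mask_xy], y[mask_xy])),
            abs(pearson_pair_oracle(x[mask_xz], z[mask_xz])),
            abs(pearson_pair_oracle(y[~np.isnan(y)], z[~np.isnan(y)])),
        ]
    )
    assert pearson_quality(features) == pytest.approx(expected, abs=1e-12)


def test_appending_duplicate_feature_never_increases_pc_quality():
    rng = np.random.default_rng(11)
    features = rng.normal(size=(30, 4))
    with_dup = np.column_stack([features, features[:, 0]])
    assert pearson_quality(with_dup) <= pearson_quality(features) + 1e-12


# ----------------------------------------------------------------- missing


def test_missing_quality_complete_table():
    assert missing_quality(np.ones((4, 3))) == 1.0


def test_missing_quality_direct_ratio():
    features = np.ones((4, 3))
    features[0, 0] = features[1, 1] = features[2, 2] = np.nan
    assert missing_quality(features) == pytest.approx(0.75)


@given(st.integers(0, 30), st.integers(2, 6), st.integers(2, 8))
@settings(max_examples=25, deadline=None)
def test_missing_quality_plus_missing_fraction_is_one(n_missing, f, n):
    rng = np.random.default_rng(n_missing + 13 * f + 101 * n)
    features = rng.normal(size=(n, f))
    flat = rng.choice(n * f, size=min(n_missing, n * f), replace=False)
    features.ravel()[flat] = np.nan
    assert missing_quality(features) + np.isnan(features).mean() == pytest.approx(1.0)


# ----------------------------------------------------------------- outliers


def test_outlier_constant_columns_score_one():
    score, report = outlier_quality(np.full((8, 3), 7.0))
    assert score == 1.0
    assert report.flagged_row_count == 0
    assert (report.mad == 0).all()


def test_outlier_hand_evaluated_mad_rule():
    # median 5.5, MAD 2.5; only 1000 exceeds |x-5.5|/2.5 > 3
    column = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 1000.0])
    score, report = outlier_quality(column.reshape(-1, 1))
    assert report.median[0] == pytest.approx(5.5)
    assert report.mad[0] == pytest.approx(2.5)
    assert report.flags.sum() == 1
    assert report.flags[9, 0]
    assert score == pytest.approx(0.9)


def test_outlier_tight_sample_scores_one():
    rng = np.random.default_rng(5)
    features = rng.uniform(0.0, 1.0, size=(50, 2))  # bounded: max dev/MAD small
    # verify the premise of the example before asserting the conclusion
    median = np.median(features, axis=0)
    mad = np.median(np.abs(features - median), axis=0)
    assert (np.abs(features - median) / mad <= 3).all()
    score, _ = outlier_quality(features)
    assert score == 1.0


def test_outlier_all_missing_rejected():
    with pytest.raises(ValueError):
        outlier_quality(np.full((3, 2), np.nan))


# ------------------------------------------------------------ class overlap


def test_separated_blobs_have_no_overlap():
    rng = np.random.default_rng(2)
    features = np.vstack(
        [rng.normal(0, 0.1, size=(20, 2)), rng.normal(100, 0.1, size=(20, 2))]
    )
    labels = np.array(["a"] * 20 + ["b"] * 20)
    score, report = class_overlap_quality(features, labels, 7, 3)
    assert score == 1.0
    assert report.r_value == 0.0


def test_overlap_16_point_hand_instance_matches_enumeration():
    features = np.arange(16.0).reshape(-1, 1)
    labels = np.array(list("aabbababbaabbaba"))
    expected_r = overlap_oracle(features, labels, 7, 3)
    score, report = class_overlap_quality(features, labels, 7, 3)
    assert report.r_value == pytest.approx(expected_r, abs=1e-12)
    assert score == pytest.approx(1.0 - expected_r, abs=1e-12)


@given(
    st.integers(8, 60),
    st.integers(1, 3),
    st.integers(0, 10_000),
)
@settings(max_examples=30, deadline=None)
def test_overlap_matches_brute_force_oracle(n, f, seed):
    rng = np.random.default_rng(seed)
    features = rng.normal(size=(n, f))
    labels = rng.choice(["a", "b"], size=n)
    if len(np.unique(labels)) < 2:
        labels[0] = "a"
        labels[1] = "b"
    score, report = class_overlap_quality(features, labels, 7, 3)
    assert report.r_value == pytest.approx(
        overlap_oracle(features, labels, 7, 3), abs=1e-12
    )


def test_overlap_large_instance_matches_oracle():
    rng = np.random.default_rng(99)
    features = rng.normal(size=(200, 3))
    labels = rng.choice(["a", "b", "c"], size=200)
    _, report = class_overlap_quality(features, labels, 7, 3)
    assert report.r_value == pytest.approx(
        overlap_oracle(features, labels, 7, 3), abs=1e-12
    )


def test_overlap_rejects_degenerate_inputs():
    features = np.zeros((5, 2))
    with pytest.raises(ValueError):
        class_overlap_quality(features, np.array(["a"] * 5), 7, 3)
    with pytest.raises(ValueError):
        class_overlap_quality(
            np.zeros((6, 2)), np.array(["a", "b"] * 3), 7, 3
        )  # N <= k


def test_overlap_missing_cells_are_median_imputed():
    features = np.vstack(
        [np.zeros((10, 2)), np.full((10, 2), 50.0)]
    )
    features[0, 0] = np.nan  # nanmedian of the remaining 19 values is 50.0
    labels = np.array(["a"] * 10 + ["b"] * 10)
    imputed = features.copy()
    imputed[0, 0] = 50.0
    _, expect = class_overlap_quality(imputed, labels, 7, 3)
    _, got = class_overlap_quality(features, labels, 7, 3)
    assert got.r_value == expect.r_value
    np.testing.assert_array_equal(got.foreign_counts, expect.foreign_counts)


# ------------------------------------------------------------ quality vector


def _quality_of(table: MasterTable, config: SearchConfig) -> np.ndarray:
    return compute_quality_vector(table, config).as_array()


def test_quality_vector_order_and_recomputation(toy_master, default_config):
    vec = compute_quality_vector(toy_master, default_config)
    assert isinstance(vec, QualityVector)
    expected = np.array(
        [
            pearson_quality(toy_master.features),
            spearman_quality(toy_master.features),
            missing_quality(toy_master.features),
            outlier_quality(toy_master.features)[0],
            class_overlap_quality(
                toy_master.features, toy_master.labels, 7, 3
            )[0],
        ]
    )
    np.testing.assert_allclose(vec.as_array(), expected, atol=1e-12)
    assert ((vec.as_array() >= 0) & (vec.as_array() <= 1)).all()


def test_quality_vector_deterministic(toy_master, default_config):
    first = _quality_of(toy_master, default_config)
    second = _quality_of(toy_master, default_config)
    np.testing.assert_array_equal(first, second)


def test_scores_invariant_to_row_and_column_order(default_config):
    rng = np.random.default_rng(8)
    features = rng.normal(size=(40, 4))
    features[:20] += 4.0
    labels = np.array(["a"] * 20 + ["b"] * 20)
    table = MasterTable(features, ["a", "b", "c", "d"], labels, "y")
    rows = rng.permutation(40)
    cols = rng.permutation(4)
    shuffled = MasterTable(
        features[np.ix_(rows, cols)],
        [table.feature_names[c] for c in cols],
        labels[rows],
        "y",
    )
    np.testing.assert_allclose(
        _quality_of(table, default_config),
        _quality_of(shuffled, default_config),
        atol=1e-9,
    )


def test_quality_vector_rejects_out_of_range():
    with pytest.raises(ValueError):
        QualityVector(1.2, 0.5, 0.5, 0.5, 0.5)
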