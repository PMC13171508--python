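import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hmgrqsar.eda import (
    PCAResult,
    class_summary_table,
    mann_whitney,
    rank_test_table,
    run_pca,
    summarize_class,
)
from hmgrqsar.errors import ConfigurationError

# ---------------------------------------------------------------- summaries


def test_symmetric_sample_summary():
    s = summarize_class([1.0, 2.0, 3.0], "active", "mw")
    assert s.mean == pytest.approx(2.0)
    assert s.median == pytest.approx(2.0)
    assert s.skewness == pytest.approx(0.0, abs=1e-12)
    assert s.min <= s.median <= s.max


def test_right_tail_positive_skew():
    s = summarize_class([0.0, 0.0, 0.0, 10.0], "active", "mw")
    assert s.skewness > 0


def _moment_oracle(values):
    """Population-moment skewness and excess kurtosis by direct summation."""
    x = list(map(float, values))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    return m3 / m2**1.5, m4 / m2**2 - 3.0


@pytest.mark.parametrize(
    "sample",
    [
        [1, 2, 2, 3, 10],
        [4.2, 4.2, 5.1, 9.9, 0.3, 2.2],
        list(range(12)),
    ],
)
def test_moments_match_direct_summation(sample):
    s = summarize_class(sample, "c", "d")
    g1, g2 = _moment_oracle(sample)
    assert s.skewness == pytest.approx(g1, rel=1e-12)
    assert s.kurtosis == pytest.approx(g2, rel=1e-12)


def test_tiny_or_constant_samples_flagged():
    assert summarize_class([1.0, 2.0], "c", "d").skewness is None
    assert summarize_class([3.0, 3.0, 3.0, 3.0], "c", "d").kurtosis is None
    with pytest.raises(ValueError):
        summarize_class([], "c", "d")


def test_class_summary_table_layout():
    frame = pd.DataFrame({"mw": [1.0, 2.0, 3.0, 10.0], "tpsa": [0, 5, 9, 2]})
    classes = pd.Series(["a", "a", "b", "b"])
    out = class_summary_table(frame, classes)
    assert len(out) == 4  # 2 descriptors x 2 classes
    assert set(out.columns) >= {"descriptor_name", "class_label", "mean", "median"}


# ---------------------------------------------------------------- rank test


def _exact_p_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(
        1.0 if xi > yj else 0.5 if xi == yj else 0.0
        for xi in x for yj in y
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(
            sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)
        )
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


def test_complete_separation():
    r = mann_whitney([1, 2, 3], [4, 5, 6])
    assert r.u_statistic == 0.0
    assert r.method == "exact"


def test_identical_multisets_not_significant():
    r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
    assert r.p_value > 0.9
    assert not r.significant


def test_degenerate_constant_data():
    r = mann_whitney([5, 5, 5], [5, 5])
    assert r.degenerate
    assert r.p_value == 1.0
    assert r.u_statistic == pytest.approx(3.0)  # n1*n2/2


@pytest.mark.parametrize(
    "x,y",
    [
        ([1, 3, 5], [2, 4]),
        ([1, 2, 3], [4, 5, 6]),
        ([10, 30, 50, 70], [20, 40, 60]),
        ([0.5, 2.5, 4.5, 6.5, 8.5], [1.5, 3.5, 5.5, 7.5]),
        ([12, 1, 7], [3, 9, 5, 11]),
    ],
)
def test_exact_p_matches_permutation_oracle(x, y):
    r = mann_whitney(x, y)
    assert r.method == "exact"
    assert r.p_value == pytest.approx(_exact_p_oracle(x, y), abs=1e-12)


@given(
    st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=8),
    st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=8),
)
def test_u_statistics_are_complementary(x, y):
    if max(x + y) == min(x + y):
        return  # degenerate case reports U = n1*n2/2 on both sides anyway
    uxy = mann_whitney(x, y).u_statistic
    uyx = mann_whitney(y, x).u_statistic
    assert uxy + uyx == pytest.approx(len(x) * len(y))
    assert 0 <= uxy <= len(x) * len(y)


def test_large_or_tied_samples_use_asymptotic(rng):
    x = rng.normal(0, 1, 40)
    y = rng.normal(1, 1, 40)
    r = mann_whitney(x, y)
    assert r.method == "asymptotic"
    assert r.significant
    r2 = mann_whitney([1, 1, 2, 3], [2, 2, 4])  # ties -> asymptotic
    assert r2.method == "asymptotic"


def test_rank_test_table_covers_all_pairs():
    frame = pd.DataFrame({"mw": np.arange(12.0)})
    classes = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    out = rank_test_table(frame, classes)
    assert sorted(out["class_pair"]) == ["a|b", "a|c", "b|c"]


# ---------------------------------------------------------------- PCA


def test_perfectly_correlated_columns():
    x = np.arange(10.0)
    m = pd.DataFrame({"a": x, "b": 2 * x + 3})
    res = run_pca(m)
    assert res.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-9)


def test_isotropic_data_splits_variance(rng):
    m = pd.DataFrame(rng.normal(size=(4000, 4)))
    res = run_pca(m)
    assert np.allclose(res.explained_variance_pct, 25.0, atol=3.0)


def _eigh_oracle(matrix):
    """Independent eigen-solve of the correlation matrix."""
    z = (matrix - matrix.mean(0)) / matrix.std(0)
    corr = np.corrcoef(matrix, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] *= -1
    return vals / vals.sum() * 100.0, vecs


HAND_MATRIX = np.array(
    [
        [1.0, 2.0, 0.5],
        [2.0, 1.0, 0.3],
        [3.0, 5.0, 1.0],
        [4.0, 3.0, 2.0],
        [5.0, 6.0, 1.5],
    ]
)


def test_hand_matrix_matches_eigendecomposition():
    res = run_pca(pd.DataFrame(HAND_MATRIX, columns=["a", "b", "c"]))
    pct_oracle, vecs_oracle = _eigh_oracle(HAND_MATRIX)
    assert np.allclose(res.explained_variance_pct, pct_oracle, atol=1e-8)
    assert np.allclose(res.loadings, vecs_oracle, atol=1e-8)
    assert res.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)


def test_loadings_orthonormal_and_variance_monotone(rng):
    m = pd.DataFrame(rng.normal(size=(60, 6)))
    res = run_pca(m)
    gram = res.loadings.T @ res.loadings
    assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
    assert np.all(np.diff(res.explained_variance_pct) <= 1e-10)
    assert np.all(np.diff(res.cumulative_variance_pct) >= -1e-10)
    assert res.cumulative_variance_pct[-1] <= 100 + 1e-9


def test_full_reconstruction(rng):
    m = pd.DataFrame(rng.normal(size=(30, 5)))
    res = run_pca(m)
    z = (m - m.mean(0)) / m.std(0, ddof=0)
    recon = res.scores @ res.loadings.T
    assert np.allclose(recon, z.to_numpy(), atol=1e-8)


def test_zero_variance_column_dropped(rng):
    m = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
    m["flat"] = 7.0
    with pytest.warns(UserWarning, match="flat"):
        res = run_pca(m)
    assert res.dropped_columns == ["flat"]
    assert res.loadings.shape[0] == 3


def test_pca_input_validation():
    with pytest.raises(ConfigurationError):
        run_pca(pd.DataFrame({"a": [1.0, 2.0]}))
    with pytest.raises(ConfigurationError):
        run_pca(pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]}))


def test_scores_and_loadings_frames_labelled():
    res = run_pca(pd.DataFrame(HAND_MATRIX, columns=["a", "b", "c"]))
    lf = res.loadings_frame()
    assert list(lf.index) == ["a", "b", "c"]
    assert list(lf.columns) == ["PC1", "PC2", "PC3"]
    assert res.scores_frame().shape == (5, 3)
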