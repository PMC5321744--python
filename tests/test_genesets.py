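"""Clustering, thresholds, overlap and correlation statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nucdis import (
    GeneSet,
    ValidationError,
    dependence_summary,
    hypergeometric_overlap,
    kmeans_cluster,
    pearson_r,
    read_gene_set,
    select_extreme_cluster,
    threshold_gene_set,
    tukey_pairwise,
    write_gene_set,
)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

WELL_SEPARATED = pd.Series(
    [0.10, 0.11, 0.12, 5.0, 5.1, 9.9, 10.0],
    index=[f"g{i}" for i in range(7)],
)


def test_kmeans_separates_obvious_groups():
    res = kmeans_cluster(WELL_SEPARATED, k=3, seed=0)
    groups = {}
    for gid, lab in res.labels.items():
        groups.setdefault(lab, set()).add(gid)
    assert sorted(map(len, groups.values())) == [2, 2, 3]
    assert {"g0", "g1", "g2"} in groups.values()
    assert {"g5", "g6"} in groups.values()


def test_kmeans_k1_mean_is_global_mean():
    res = kmeans_cluster(WELL_SEPARATED, k=1, seed=0)
    assert res.cluster_means[0, 0] == pytest.approx(WELL_SEPARATED.mean())


def test_kmeans_duplication_invariance():
    doubled = pd.concat([WELL_SEPARATED, WELL_SEPARATED.rename(lambda g: g + "_bis")])
    a = kmeans_cluster(WELL_SEPARATED, k=3, seed=0)
    b = kmeans_cluster(doubled, k=3, seed=0)
    np.testing.assert_allclose(
        np.sort(a.cluster_means.ravel()), np.sort(b.cluster_means.ravel()), atol=1e-9
    )


def test_kmeans_seed_reproducible():
    X = pd.DataFrame(np.random.default_rng(1).normal(size=(60, 4)))
    a = kmeans_cluster(X, k=4, seed=11)
    b = kmeans_cluster(X, k=4, seed=11)
    pd.testing.assert_series_equal(a.labels, b.labels)
    assert a.inertia == b.inertia


def test_kmeans_input_validation():
    with pytest.raises(ValidationError, match="k="):
        kmeans_cluster(WELL_SEPARATED, k=7, seed=0)
    with pytest.raises(ValidationError, match="missing"):
        kmeans_cluster(pd.Series([1.0, np.nan, 2.0, 3.0]), k=2, seed=0)


def test_select_extreme_cluster():
    res = kmeans_cluster(WELL_SEPARATED, k=3, seed=0)
    high = select_extreme_cluster(res, "highest")
    assert high.members == {"g5", "g6"}
    assert high.universe == frozenset(WELL_SEPARATED.index)
    low = select_extreme_cluster(res, "lowest")
    assert low.members == {"g0", "g1", "g2"}


def test_degenerate_identical_values_flagged():
    res = kmeans_cluster(pd.Series([2.0] * 6, index=list("abcdef")), k=3, seed=0)
    assert res.degenerate
    picked = select_extreme_cluster(res, "highest")
    assert picked.members  # still returns the (single) populated cluster


# ---------------------------------------------------------------------------
# threshold sets
# ---------------------------------------------------------------------------

def test_threshold_inclusive_boundary():
    changes = pd.Series({"a": -0.6, "b": -0.5, "c": -0.49, "d": 0.1})
    s = threshold_gene_set(changes, cutoff=-0.5, direction="le")
    assert s.members == {"a", "b"}
    assert s.universe_size == 4


def test_threshold_empty_set_keeps_universe():
    changes = pd.Series({"a": 0.2, "b": 0.5})
    s = threshold_gene_set(changes, cutoff=-5.0, direction="le")
    assert s.members == frozenset() and s.universe_size == 2


def test_threshold_ge_direction_and_missing():
    changes = pd.Series({"a": -1.0, "b": 0.0, "c": 2.0, "d": np.nan})
    s = threshold_gene_set(changes, cutoff=0.0, direction="ge")
    assert s.members == {"b", "c"}
    assert s.universe_size == 3  # NaN gene excluded from the universe
    with pytest.raises(ValidationError):
        threshold_gene_set(pd.Series({"a": np.nan}), cutoff=0, direction="le")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=30),
    c1=st.floats(-5, 5, allow_nan=False),
    c2=st.floats(-5, 5, allow_nan=False),
)
def test_threshold_monotone_in_cutoff(values, c1, c2):
    lo, hi = min(c1, c2), max(c1, c2)
    series = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
    assert threshold_gene_set(series, lo, "le").members <= threshold_gene_set(series, hi, "le").members
    assert threshold_gene_set(series, hi, "ge").members <= threshold_gene_set(series, lo, "ge").members


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------

def enumeration_pvalue(N, K, n, k):
    """Exhaustive oracle: fraction of n-subsets of [N] with >= k of the first K."""
    universe = range(N)
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if sum(1 for x in subset if x < K) >= k:
            hits += 1
    return hits / total if total else 1.0


def make_sets(N, K, n, k):
    universe = frozenset(f"g{i}" for i in range(N))
    a = frozenset(f"g{i}" for i in range(K))
    b = frozenset(f"g{i}" for i in range(k)) | frozenset(
        f"g{K + i}" for i in range(n - k)
    )
    return (GeneSet("A", a, universe), GeneSet("B", b, universe))


def test_worked_example_66_over_252():
    a, b = make_sets(10, 4, 5, 3)
    res = hypergeometric_overlap(a, b)
    assert res.n_overlap == 3
    assert res.p_value == pytest.approx(66 / 252, rel=1e-12)
    assert res.p_value == pytest.approx(enumeration_pvalue(10, 4, 5, 3), rel=1e-12)


def test_zero_overlap_p_is_one():
    a, b = make_sets(8, 3, 2, 0)
    assert hypergeometric_overlap(a, b).p_value == pytest.approx(1.0)


def test_full_sets_p_is_one():
    universe = frozenset(f"g{i}" for i in range(6))
    full = GeneSet("U", universe, universe)
    res = hypergeometric_overlap(full, full)
    assert res.n_overlap == 6 and res.p_value == pytest.approx(1.0)


def test_universe_intersection_used():
    a = GeneSet("A", frozenset({"g1", "g2"}), frozenset({"g1", "g2", "g3", "x"}))
    b = GeneSet("B", frozenset({"g1", "g3"}), frozenset({"g1", "g2", "g3", "y"}))
    res = hypergeometric_overlap(a, b)
    assert res.n_universe == 3 and res.n_a == 2 and res.n_b == 2 and res.n_overlap == 1


@pytest.mark.parametrize("N", [4, 7, 9])
def test_matches_enumeration_small_sweep(N):
    for K in range(N + 1):
        for n in range(N + 1):
            for k in range(max(0, K + n - N), min(K, n) + 1):
                a, b = make_sets(N, K, n, k)
                res = hypergeometric_overlap(a, b)
                assert res.p_value == pytest.approx(
                    enumeration_pvalue(N, K, n, k), rel=1e-10, abs=1e-12
                ), (N, K, n, k)


def test_gene_set_file_round_trip(tmp_path):
    s = GeneSet("demo", frozenset({"g1", "g2"}), frozenset({"g1", "g2", "g3"}))
    p = tmp_path / "set.txt"
    write_gene_set(s, p)
    back = read_gene_set(p)
    assert back.name == "demo" and back.members == s.members
    assert back.universe_size == 3 and back.universe is None


# ---------------------------------------------------------------------------
# Pearson and dependence
# ---------------------------------------------------------------------------

def test_pearson_known_values():
    assert pearson_r([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [-1, -2, -3]).r == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]).r == pytest.approx(0.8)


def test_pearson_missing_and_degenerate():
    res = pearson_r([1, 2, np.nan, 4, 5], [2, 1, 9, np.nan, 5])
    assert res.n_used == 3
    flat = pearson_r([1.0, 1.0, 1.0], [1, 2, 3])
    assert not flat.defined and math.isnan(flat.r)
    with pytest.raises(ValidationError):
        pearson_r([1, 2], [3, 4])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    xs=st.lists(st.floats(-100, 100, allow_nan=False), min_size=3, max_size=40),
    a=st.floats(0.01, 10), b=st.floats(-5, 5),
)
def test_pearson_affine_invariance(xs, a, b):
    rng = np.random.default_rng(0)
    ys = rng.normal(size=len(xs))
    base = pearson_r(xs, ys)
    if not base.defined:
        return
    same = pearson_r(a * np.asarray(xs) + b, ys)
    flipped = pearson_r(-a * np.asarray(xs) + b, ys)
    assert same.r == pytest.approx(base.r, abs=1e-9)
    assert flipped.r == pytest.approx(-base.r, abs=1e-9)


def test_dependence_summary_threshold_calls(tmp_path):
    rng = np.random.default_rng(5)
    x = pd.Series(rng.normal(size=200))
    assert dependence_summary(x, x * 2 + 1)["meaningful"]
    assert dependence_summary(x, -x)["meaningful"]  # absolute value
    noise = pd.Series(rng.normal(size=200), index=x.index)
    weak = dependence_summary(x, noise)
    assert abs(weak["r"]) < 0.4 and not weak["meaningful"]
    out = tmp_path / "scatter.tsv"
    dependence_summary(x, noise, scatter_path=out)
    assert len(pd.read_csv(out, sep="\t")) == 200


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def test_tukey_identical_means_p_one():
    res = tukey_pairwise({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
    np.testing.assert_allclose(res["p_adj"], 1.0)
    np.testing.assert_allclose(res["mean_diff"], 0.0)


def test_tukey_extreme_separation():
    res = tukey_pairwise({"lo": [0, 0.1, -0.1], "hi": [10, 10.1, 9.9]})
    assert res.loc[0, "p_adj"] < 1e-3
    assert res.loc[0, "mean_diff"] == pytest.approx(-10.0, abs=0.2)


def test_tukey_agrees_with_permutation_oracle():
    """Adjusted p for the extreme pair ~ permutation tail probability of the
    max studentized pairwise difference (1e5 shuffles)."""
    rng = np.random.default_rng(42)
    groups = {
        "a": rng.normal(0.0, 1.0, 6),
        "b": rng.normal(0.9, 1.0, 6),
        "c": rng.normal(0.3, 1.0, 6),
    }
    res = tukey_pairwise(groups)
    observed_min_p = res["p_adj"].min()

    pooled = np.concatenate(list(groups.values()))
    sizes = [len(v) for v in groups.values()]

    def max_stat(arr):
        parts = np.split(arr, np.cumsum(sizes)[:-1])
        means = [p.mean() for p in parts]
        sw = np.sqrt(sum(((p - p.mean()) ** 2).sum() for p in parts) / (len(arr) - len(parts)))
        return max(abs(m1 - m2) for m1, m2 in itertools.combinations(means, 2)) / sw

    obs = max_stat(pooled)
    count = 0
    n_perm = 100_000
    for _ in range(n_perm):
        count += max_stat(rng.permutation(pooled)) >= obs
    p_perm = count / n_perm
    assert observed_min_p == pytest.approx(p_perm, abs=0.05)


def test_tukey_validation():
    with pytest.raises(ValidationError):
        tukey_pairwise({"a": [1, 2, 3]})
    with pytest.raises(ValidationError):
        tukey_pairwise({"a": [1], "b": [2, 3]})
    with pytest.raises(ValidationError):
        tukey_pairwise({"a": [1.0, 1.0], "b": [2.0, 2.0]})
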