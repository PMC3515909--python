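"""Rank meta-analysis: statistics, ranks, permutation null, FDR, pooling."""

import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metavote import (
    InputError,
    intersect_pool,
    mean_rank,
    mean_rank_significance,
    rank_within_study,
    signal_to_noise,
)
from metavote.meta_rank import GeneRankTable, benjamini_hochberg

from conftest import make_study


class TestSignalToNoise:
    def test_hand_computed_value(self):
        # (2 - 0) / (sqrt(2) + sqrt(2)) with sample sds
        assert signal_to_noise([1, 3], [-1, 1]) == pytest.approx(0.7071, abs=1e-4)

    def test_equal_means_give_zero(self):
        assert signal_to_noise([5, 5, 5], [5, 5, 5]) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
    )
    def test_antisymmetric_in_class_order(self, a, b):
        assert signal_to_noise(a, b) == pytest.approx(-signal_to_noise(b, a), abs=1e-9)

    def test_small_class_rejected(self):
        with pytest.raises(InputError):
            signal_to_noise([1.0], [0.0, 1.0])


class TestRankWithinStudy:
    def test_matches_per_gene_statistic_order(self):
        rng = np.random.default_rng(0)
        study = make_study(rng.normal(size=(12, 20)), [1] * 5 + [0] * 15)
        table = rank_within_study(study).table
        expected = np.array(
            [signal_to_noise(*study.class_values(g)) for g in study.gene_ids]
        )
        np.testing.assert_allclose(table["s2n"].to_numpy(), expected, atol=1e-12)
        # rank 1 = largest statistic: rank = 1 + #{genes with larger s2n}
        expected_ranks = 1 + (expected[:, None] < expected[None, :]).sum(axis=1)
        np.testing.assert_array_equal(table["rank"].to_numpy(), expected_ranks)
        np.testing.assert_allclose(
            table["norm_rank"], table["rank"] / (len(table) + 1)
        )

    def test_all_ties_resolved_lexicographically(self):
        X = np.tile(np.arange(8.0), (4, 1))
        study = make_study(X, [1, 1, 0, 0, 1, 0, 0, 1], gene_ids=list("dcba"))
        table = rank_within_study(study).table
        assert sorted(table["rank"]) == [1, 2, 3, 4]
        assert list(table.sort_values("rank").index) == ["a", "b", "c", "d"]

    def test_strong_shift_improves_rank(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 24))
        y = [1] * 6 + [0] * 18
        before = rank_within_study(make_study(X, y)).table
        X2 = X.copy()
        X2[7, :6] += 10.0  # large class-1 shift on gene 7
        after = rank_within_study(make_study(X2, y)).table
        assert after["rank"].iloc[7] == 1
        assert after["rank"].iloc[7] <= before["rank"].iloc[7]

    def test_single_class_rejected(self):
        study = make_study(np.ones((3, 6)), [0] * 6)
        with pytest.raises(InputError):
            rank_within_study(study)


def _toy_table(study_id, genes, norm_ranks):
    frame = pd.DataFrame(
        {"s2n": 0.0, "rank": 0, "norm_rank": norm_ranks},
        index=pd.Index(genes, name="gene_id"),
    )
    return GeneRankTable(study_id, frame)


class TestMeanRank:
    def test_arithmetic_mean_of_normalized_ranks(self):
        tables = [
            _toy_table("s1", ["a", "b"], [0.25, 0.75]),
            _toy_table("s2", ["a", "b"], [0.75, 0.25]),
        ]
        out = mean_rank(tables)
        assert out["a"] == pytest.approx(0.5)
        assert out["b"] == pytest.approx(0.5)

    def test_min_studies_filter_drops_sparse_genes(self):
        tables = [
            _toy_table("s1", ["a", "b"], [0.25, 0.75]),
            _toy_table("s2", ["a"], [0.75]),
        ]
        out = mean_rank(tables, min_studies=2)
        assert list(out.index) == ["a"]

    def test_first_everywhere_attains_minimum(self):
        # rank 1 in every study -> mean normalized rank 1/(n+1)
        n = 4
        tables = [
            _toy_table(f"s{i}", list("abcd"), [1 / (n + 1), 0.4, 0.6, 0.8])
            for i in range(3)
        ]
        out = mean_rank(tables)
        assert out["a"] == pytest.approx(1 / (n + 1))
        assert out["a"] == out.min()


def test_benjamini_hochberg_step_up_by_hand():
    np.testing.assert_allclose(
        benjamini_hochberg([0.01, 0.02, 0.50]), [0.03, 0.03, 0.50]
    )


def brute_force_pooled_p(studies):
    """Independent enumeration oracle for the pooled permutation p-value.

    Enumerates every joint within-study label assignment with plain-python
    loops, ranks by signal-to-noise with lexicographic tie-break, and pools
    the null mean normalized ranks across genes.
    """
    genes = sorted(studies[0].gene_ids)

    def s2n(values, labels):
        x1 = [v for v, l in zip(values, labels) if l == 1]
        x0 = [v for v, l in zip(values, labels) if l == 0]
        denom = max(statistics.stdev(x1) + statistics.stdev(x0), 1e-8)
        return (statistics.mean(x1) - statistics.mean(x0)) / denom

    def norm_ranks(study, labels):
        stats_ = {
            g: s2n(list(study.expression.loc[g]), labels) for g in study.gene_ids
        }
        ordered = sorted(stats_, key=lambda g: (-stats_[g], g))
        n = len(ordered)
        return {g: (i + 1) / (n + 1) for i, g in enumerate(ordered)}

    def assignments(study):
        y = list(study.outcome)
        n1 = sum(y)
        out = []
        for pos in itertools.combinations(range(len(y)), n1):
            out.append([1 if i in pos else 0 for i in range(len(y))])
        return out

    observed = {g: 0.0 for g in genes}
    for s in studies:
        nr = norm_ranks(s, list(s.outcome))
        for g in genes:
            observed[g] += nr[g] / len(studies)

    pool = []
    for combo in itertools.product(*(assignments(s) for s in studies)):
        means = {g: 0.0 for g in genes}
        for s, labels in zip(studies, combo):
            nr = norm_ranks(s, labels)
            for g in genes:
                means[g] += nr[g] / len(studies)
        pool.extend(abs(means[g] - 0.5) for g in genes)

    p = {}
    for g in genes:
        dev = abs(observed[g] - 0.5)
        p[g] = sum(1 for v in pool if v >= dev) / len(pool)
    return p


def test_permutation_p_matches_exhaustive_enumeration():
    """On a 36-assignment toy the permutation p equals the brute-force p."""
    rng = np.random.default_rng(7)
    y = [1, 1, 0, 0]
    s1 = make_study(rng.normal(size=(3, 4)), y, gene_ids=list("abc"), study_id="s1")
    s2 = make_study(rng.normal(size=(3, 4)), y, gene_ids=list("abc"), study_id="s2")
    assert math.comb(4, 2) ** 2 == 36  # below the sampling threshold
    result = mean_rank_significance([s1, s2], n_permutations=100, seed=0)
    oracle = brute_force_pooled_p([s1, s2])
    for g in "abc":
        assert result.loc[g, "p_value"] == pytest.approx(oracle[g], abs=1e-12)


def test_central_mean_rank_has_p_one():
    """Genes whose mean normalized rank is exactly 0.5 sit at the null's center."""
    # two genes, opposite ranks in the two studies -> both means are 0.5
    X1 = np.array([[3.0, 3.0, 0.0, 0.0], [0.1, -0.1, 0.05, -0.05]])
    X2 = np.array([[0.1, -0.1, 0.05, -0.05], [3.0, 3.0, 0.0, 0.0]])
    y = [1, 1, 0, 0]
    s1 = make_study(X1, y, gene_ids=["a", "b"], study_id="s1")
    s2 = make_study(X2, y, gene_ids=["a", "b"], study_id="s2")
    result = mean_rank_significance([s1, s2], n_permutations=100, seed=0)
    assert np.allclose(result["mean_normalized_rank"], 0.5)
    assert np.all(result["p_value"] == 1.0)


def test_genes_below_min_studies_are_dropped():
    rng = np.random.default_rng(3)
    y = [1] * 6 + [0] * 18
    s1 = make_study(rng.normal(size=(6, 24)), y, gene_ids=list("abcdef"), study_id="s1")
    s2 = make_study(rng.normal(size=(4, 24)), y, gene_ids=list("abcd"), study_id="s2")
    out = mean_rank_significance([s1, s2], n_permutations=100, seed=1, min_studies=2)
    assert set(out.index) == set("abcd")
    out_all = mean_rank_significance([s1, s2], n_permutations=100, seed=1, min_studies=1)
    assert set(out_all.index) == set("abcdef")
    assert (out_all["n_studies"].loc[list("abcd")] == 2).all()


def test_intersect_pool_preserves_order_and_filters():
    s1 = make_study(np.zeros((2, 4)), [1, 1, 0, 0], gene_ids=["A", "B"], study_id="s1")
    s2 = make_study(
        np.zeros((3, 4)), [1, 1, 0, 0], gene_ids=["A", "B", "C"], study_id="s2"
    )
    assert intersect_pool(["C", "A", "B"], [s1, s2]) == ["A", "B"]
    assert intersect_pool([], [s1, s2]) == []


def test_planted_genes_survive_pool_intersection(small_collection):
    _, studies, truth = small_collection
    result = mean_rank_significance(studies, n_permutations=200, seed=5)
    selected = list(result.index[result["selected"]])
    pool = intersect_pool(selected, studies[:2])
    assert set(truth) <= set(pool)
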