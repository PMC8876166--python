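import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mscompare import enrichment
from mscompare.diffexp import Thresholds
from mscompare.io import ExpressionMatrix, GeneSet, GeneSetCollection


def oracle_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact P[X >= k] by direct summation of the hypergeometric PMF."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


class TestHypergeomPvalue:
    def test_matches_exhaustive_pmf_summation_small_universes(self):
        for N in range(2, 26):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    ks = range(max(0, n + K - N), min(n, K) + 1)
                    for k in ks:
                        p = enrichment.hypergeom_pvalue(k, n, K, N)
                        assert p == pytest.approx(oracle_upper_tail(k, n, K, N), abs=1e-12)

    def test_extreme_containment(self):
        # query entirely inside a term of the same size
        N, n = 30, 5
        p = enrichment.hypergeom_pvalue(5, n, 5, N)
        assert p == pytest.approx(1 / math.comb(N, n), rel=1e-12)
        assert enrichment.fold_enrichment(5, 5, 5, N) == pytest.approx(N / n)

    def test_ease_is_more_conservative(self):
        plain = enrichment.hypergeom_pvalue(6, 60, 50, 1000)
        ease = enrichment.hypergeom_pvalue(6, 60, 50, 1000, ease=True)
        assert ease > plain


class TestFoldEnrichment:
    def test_arithmetic_identity(self):
        assert enrichment.fold_enrichment(6, 60, 50, 1000) == pytest.approx(2.0)

    @pytest.mark.parametrize("c", [2, 5, 10])
    def test_scale_invariance(self, c):
        base = enrichment.fold_enrichment(6, 60, 50, 1000)
        scaled = enrichment.fold_enrichment(6 * c, 60 * c, 50 * c, 1000 * c)
        assert scaled == pytest.approx(base, rel=1e-12)


class TestGoCircleZscore:
    def test_arithmetic_examples(self):
        directions = {f"u{i}": "up" for i in range(9)} | {f"d{i}": "down" for i in range(16)}
        z = enrichment.go_circle_zscore(directions.keys(), directions)
        assert z == pytest.approx(-1.4)
        all_up = {f"u{i}": "up" for i in range(4)}
        assert enrichment.go_circle_zscore(all_up.keys(), all_up) == pytest.approx(2.0)
        assert enrichment.go_circle_zscore([], {}) == 0.0

    def test_standardisation_under_random_directions(self):
        # z over k genes with fair up/down coin: mean ~ 0, variance ~ 1
        rng = np.random.default_rng(21)
        k = 25
        zs = []
        genes = [f"g{i}" for i in range(k)]
        for _ in range(10_000):
            directions = {g: ("up" if rng.random() < 0.5 else "down") for g in genes}
            zs.append(enrichment.go_circle_zscore(genes, directions))
        assert np.mean(zs) == pytest.approx(0.0, abs=0.05)
        assert np.var(zs) == pytest.approx(1.0, abs=0.1)


class TestHypergeomEnrich:
    @staticmethod
    def _collection():
        return GeneSetCollection(
            (
                GeneSet("T1", "hit", frozenset(f"g{i}" for i in range(10))),
                GeneSet("T2", "background", frozenset(f"g{i}" for i in range(40, 90))),
                GeneSet("T3", "outside", frozenset(["x1", "x2", "x3"])),
            )
        )

    def test_rows_and_gates(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        th = Thresholds()
        rows = hyper = enrichment.hypergeom_enrich(
            query, self._collection(), universe, thresholds=th, min_count=10
        )
        t1 = rows[rows["term_id"] == "T1"].iloc[0]
        assert t1["k"] == 10 and t1["K"] == 10
        assert t1["fold_enrichment"] == pytest.approx(10.0)
        assert bool(t1["passes"])
        # T3 is entirely outside the universe: no row at all
        assert "T3" not in set(rows["term_id"])
        # passes is exactly the conjunction of the three gates
        for _, row in rows.iterrows():
            expected = (
                row["k"] >= 10
                and row["fold_enrichment"] > th.min_fold_enrichment
                and row["p_value"] < th.alpha
            )
            assert bool(row["passes"]) == expected

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            enrichment.hypergeom_enrich({"zz"}, self._collection(), {"g1"})

    def test_null_query_pvalues_roughly_uniform(self):
        # uniformly drawn queries should not over-trigger the alpha gate
        rng = np.random.default_rng(31)
        universe = {f"g{i}" for i in range(400)}
        terms = GeneSetCollection(
            tuple(
                GeneSet(
                    f"T{j}",
                    "",
                    frozenset(f"g{i}" for i in rng.choice(400, size=40, replace=False)),
                )
                for j in range(150)
            )
        )
        hits = total = 0
        for _ in range(30):
            query = {f"g{i}" for i in rng.choice(400, size=40, replace=False)}
            rows = enrichment.hypergeom_enrich(query, terms, universe, min_count=1)
            hits += int((rows["p_value"] < 0.05).sum())
            total += len(rows)
        assert hits / total < 0.10


def _gene_matrix(values, genes):
    cols = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), "FPKM")


class TestMarkerOverlap:
    def test_sample_odds_ratio_identity(self):
        # construct a universe where the 2x2 table is known exactly
        genes = [f"g{i:03d}" for i in range(75)]
        values = np.linspace(100, 1, 75)[:, None] * np.ones((1, 4))
        m = _gene_matrix(values, genes)
        markers = set(genes[:10]) | set(genes[30:50])  # 10 in top 30, 20 outside
        res = enrichment.marker_overlap_fisher(m, markers, top_n=30)
        assert (res.a, res.b, res.c, res.d) == (10, 20, 20, 25)
        assert res.odds_ratio == pytest.approx((10 * 25) / (20 * 20))
        assert res.universe_size == 75

    def test_fisher_p_matches_enumeration_oracle(self):
        genes = [f"g{i:02d}" for i in range(40)]
        values = np.arange(40, 0, -1.0)[:, None] * np.ones((1, 3))
        m = _gene_matrix(values, genes)
        markers = {genes[i] for i in [0, 1, 2, 5, 11, 17, 23, 31]}
        res = enrichment.marker_overlap_fisher(m, markers, top_n=12)
        # enumeration over all tables with fixed margins, upper tail at >= a
        n_mark, top_n, N = len(markers), 12, 40
        total = math.comb(N, top_n)
        p_oracle = sum(
            math.comb(n_mark, a) * math.comb(N - n_mark, top_n - a)
            for a in range(res.a, min(n_mark, top_n) + 1)
        ) / total
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_disjoint_markers_are_anti_enriched(self):
        genes = [f"g{i:02d}" for i in range(50)]
        values = np.arange(50, 0, -1.0)[:, None] * np.ones((1, 2))
        m = _gene_matrix(values, genes)
        markers = set(genes[30:45])  # all outside the top 10
        res = enrichment.marker_overlap_fisher(m, markers, top_n=10)
        assert res.a == 0
        assert res.p_value >= 0.5

    def test_infinite_odds_ratio_flag_and_haldane(self):
        genes = [f"g{i:02d}" for i in range(20)]
        values = np.arange(20, 0, -1.0)[:, None] * np.ones((1, 2))
        m = _gene_matrix(values, genes)
        markers = set(genes[:5])  # fully inside the top 5
        res = enrichment.marker_overlap_fisher(m, markers, top_n=5)
        assert res.infinite_or and math.isinf(res.odds_ratio)
        res_h = enrichment.marker_overlap_fisher(m, markers, top_n=5, haldane=True)
        assert not res_h.infinite_or and math.isfinite(res_h.odds_ratio)

    def test_random_marker_sets_have_median_or_near_one(self):
        rng = np.random.default_rng(41)
        genes = [f"g{i:03d}" for i in range(300)]
        values = rng.lognormal(2, 1, size=(300, 4))
        m = _gene_matrix(values, genes)
        ors = []
        for _ in range(51):
            markers = {genes[i] for i in rng.choice(300, size=40, replace=False)}
            ors.append(enrichment.marker_overlap_fisher(m, markers, top_n=100).odds_ratio)
        assert 0.6 < float(np.median(ors)) < 1.6

    def test_top_n_must_be_smaller_than_universe(self, small_matrix):
        with pytest.raises(ValueError, match="top_n"):
            enrichment.marker_overlap_fisher(small_matrix, {"f1"}, top_n=3)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_hypergeom_tail_property(data):
    """Random (N, K, n, k) configurations: the tail matches the exact
    summation oracle and decreases monotonically in k."""
    N = data.draw(st.integers(2, 80))
    K = data.draw(st.integers(1, N))
    n = data.draw(st.integers(1, N))
    lo = max(0, n + K - N)
    k = data.draw(st.integers(lo, min(n, K)))
    p = enrichment.hypergeom_pvalue(k, n, K, N)
    assert p == pytest.approx(oracle_upper_tail(k, n, K, N), abs=1e-10)
    if k - 1 >= lo:
        assert enrichment.hypergeom_pvalue(k - 1, n, K, N) >= p
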