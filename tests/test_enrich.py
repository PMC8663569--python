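"""Hypergeometric enrichment and preranked GSEA against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from becdistill.enrich import (
    enrichment_score,
    gsea_library,
    gsea_preranked,
    hypergeom_enrich,
    top_terms,
)
from becdistill.io import GeneSet, GeneSetLibrary


def exhaustive_overlap_p(universe: list, members: set, query_size: int, observed: int) -> float:
    """P(overlap >= observed) by enumerating all draws of the query size."""
    total = hits = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(set(draw) & members) >= observed:
            hits += 1
    return hits / total


def naive_es(scores: np.ndarray, is_hit: np.ndarray, weight_p: float = 1.0) -> float:
    """Independent O(N) running-sum trace of the weighted KS statistic."""
    w = np.abs(scores) ** weight_p
    total = w[is_hit].sum()
    if total == 0:
        w = np.ones_like(w)
        total = is_hit.sum()
    n_miss = (~is_hit).sum()
    running = np.where(is_hit, w / total, -1.0 / n_miss).cumsum()
    peak = np.argmax(np.abs(running))
    candidates = [running[peak], 0.0]
    return max(candidates, key=lambda v: (abs(v), v))


class TestHypergeom:
    def test_worked_example_universe_10(self):
        universe = [f"g{i}" for i in range(1, 11)]
        lib = GeneSetLibrary()
        lib.add(GeneSet("S", "BP", ("g1", "g2", "g3", "g4")))
        table = hypergeom_enrich(["g1", "g2", "g5"], lib, universe)
        assert table.loc["S", "p"] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(5, 13))
            universe = [f"g{i}" for i in range(n)]
            set_size = int(rng.integers(1, n))
            query_size = int(rng.integers(1, n))
            members = set(rng.choice(universe, set_size, replace=False))
            query = list(rng.choice(universe, query_size, replace=False))
            lib = GeneSetLibrary()
            lib.add(GeneSet("S", "BP", tuple(sorted(members))))
            table = hypergeom_enrich(query, lib, universe)
            observed = len(set(query) & members)
            expected = exhaustive_overlap_p(universe, members, query_size, observed)
            assert table.loc["S", "p"] == pytest.approx(expected, abs=1e-12)

    def test_disjoint_query_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        lib = GeneSetLibrary()
        lib.add(GeneSet("S", "BP", ("g0", "g1")))
        table = hypergeom_enrich(["g5", "g6"], lib, universe)
        assert table.loc["S", "p"] == 1.0

    def test_query_equals_universe(self):
        universe = [f"g{i}" for i in range(6)]
        lib = GeneSetLibrary()
        lib.add(GeneSet("S", "BP", tuple(universe)))
        table = hypergeom_enrich(universe, lib, universe)
        assert table.loc["S", "overlap"] == 6
        assert table.loc["S", "p"] == 1.0

    def test_empty_inputs_rejected(self):
        lib = GeneSetLibrary()
        lib.add(GeneSet("S", "BP", ("g0",)))
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrich(["g0"], lib, [])
        with pytest.raises(ValueError, match="query"):
            hypergeom_enrich(["not_in_universe"], lib, ["g0"])


class TestTopTerms:
    def _table(self, rows):
        t = pd.DataFrame(rows).set_index("term")
        return t

    def test_all_significant_returned_in_p_order(self):
        t = self._table(
            [
                {"term": "a", "p": 0.002, "q": 0.01, "overlap": 5},
                {"term": "b", "p": 0.001, "q": 0.01, "overlap": 5},
                {"term": "c", "p": 0.003, "q": 0.01, "overlap": 5},
            ]
        )
        assert top_terms(t, n=5) == ["b", "a", "c"]

    def test_tie_broken_by_overlap_then_name(self):
        t = self._table(
            [
                {"term": "x", "p": 0.001, "q": 0.01, "overlap": 3},
                {"term": "y", "p": 0.001, "q": 0.01, "overlap": 9},
                {"term": "a", "p": 0.001, "q": 0.01, "overlap": 3},
            ]
        )
        assert top_terms(t, n=3) == ["y", "a", "x"]

    def test_nothing_significant_empty(self):
        t = self._table([{"term": "a", "p": 0.5, "q": 0.9, "overlap": 1}])
        assert top_terms(t) == []


class TestEnrichmentScore:
    def test_hand_traced_example(self):
        scores = np.array([2.0, 1.0, 0.5, -1.0, -2.0])
        hits = np.array([True, False, False, True, False])
        assert enrichment_score(scores, hits) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_single_top_gene_es_one(self):
        scores = np.array([3.0, 1.0, 0.5])
        hits = np.array([True, False, False])
        assert enrichment_score(scores, hits) == pytest.approx(1.0)

    def test_matches_naive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            m = int(rng.integers(2, max(3, n // 3)))
            hits = np.zeros(n, dtype=bool)
            hits[rng.choice(n, m, replace=False)] = True
            assert enrichment_score(scores, hits) == pytest.approx(
                naive_es(scores, hits), abs=1e-12
            )

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(14)
        scores = np.sort(rng.normal(0, 1, 50))[::-1]
        hits = np.zeros(50, dtype=bool)
        hits[rng.choice(50, 8, replace=False)] = True
        es_fwd = enrichment_score(scores, hits)
        # reversing all score signs reverses the ranking; a symmetric set
        # position flips the ES sign
        es_rev = enrichment_score(-scores[::-1], hits[::-1])
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)


@pytest.fixture(scope="module")
def ranked():
    rng = np.random.default_rng(21)
    genes = [f"g{i}" for i in range(300)]
    return pd.Series(rng.normal(0, 1, 300), index=genes)


class TestGseaPreranked:
    def test_reproducible_under_seed(self, ranked):
        r1 = gsea_preranked(ranked, ranked.index[:20], n_perm=300, seed=4)
        r2 = gsea_preranked(ranked, ranked.index[:20], n_perm=300, seed=4)
        assert (r1.es, r1.nes, r1.p) == (r2.es, r2.nes, r2.p)

    def test_p_converges_with_permutations(self, ranked):
        gene_set = list(ranked.sort_values(ascending=False).index[:15])
        p1 = gsea_preranked(ranked, gene_set, n_perm=500, seed=1).p
        p2 = gsea_preranked(ranked, gene_set, n_perm=1000, seed=2).p
        se = np.sqrt(max(p1, 1 / 501) * (1 - min(p1, 1 - 1 / 501)) / 500)
        assert abs(p1 - p2) < 3 * se + 1e-9

    def test_top_ranked_set_significant(self, ranked):
        gene_set = list(ranked.sort_values(ascending=False).index[:15])
        res = gsea_preranked(ranked, gene_set, n_perm=500, seed=3)
        assert res.es > 0.5
        assert res.p < 0.01

    def test_small_set_skipped_with_warning(self, ranked, caplog):
        with caplog.at_level("WARNING"):
            res = gsea_preranked(ranked, [ranked.index[0]], n_perm=100, min_size=2)
        assert res is None

    def test_non_finite_scores_rejected(self):
        s = pd.Series({"a": 1.0, "b": np.nan, "c": 0.0})
        with pytest.raises(ValueError, match="finite"):
            gsea_preranked(s, ["a"], n_perm=10)

    def test_library_q_values_present(self, ranked):
        lib = GeneSetLibrary()
        rng = np.random.default_rng(5)
        for i in range(4):
            genes = tuple(rng.choice(ranked.index, 20, replace=False))
            lib.add(GeneSet(f"S{i}", "BP", genes))
        table = gsea_library(ranked, lib, n_perm=200, seed=0)
        assert set(table.columns) >= {"ES", "NES", "p", "q"}
        assert len(table) == 4
        assert (table["q"] >= table["p"] - 1e-12).all()
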