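"""Pattern queries, PSI recovery and hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pytest

from conftest import matrix_from, naive_tripartition
from spliceindex.ef_index import build_index
from spliceindex.query import (
    PatternQuery,
    hyper_query_cell_types,
    hypergeom_pvalue,
    matching_positions,
    pools_matching,
    recover_psi,
)
from spliceindex.synthetic import random_psi_matrix


def naive_query(matrix, query, tau=0.2):
    """Dense dPSI scan oracle for pools_matching."""
    tri = naive_tripartition(matrix, tau=tau)
    sets = []
    for node, direction in query.terms:
        above, below, _ = tri[node]
        sets.append(above if direction == "above" else below)
    agg = set.intersection(*sets) if query.combinator == "AND" else set.union(*sets)
    return sorted(agg)


class TestPatternQuery:
    def test_needs_terms_and_unique_directions(self):
        with pytest.raises(ValueError):
            PatternQuery(())
        with pytest.raises(ValueError, match="duplicate"):
            PatternQuery((("n", "above"), ("n", "above")))
        with pytest.raises(ValueError, match="combinator"):
            PatternQuery((("n", "above"),), combinator="XOR")

    def test_single_term_returns_build_side(self, toy_matrix, toy_index):
        # by construction pool p2 is the only one above node G1_1's mean
        assert pools_matching(toy_index, PatternQuery.include("G1_1")) == ["p2"]
        assert pools_matching(toy_index, PatternQuery.exclude("G1_1")) == ["p0"]

    def test_and_of_disjoint_terms_is_empty(self, toy_index):
        q = PatternQuery((("G1_1", "above"), ("G1_1", "below")))
        assert pools_matching(toy_index, q) == []

    def test_unknown_node_named_in_error(self, toy_index):
        with pytest.raises(KeyError, match="Nope_1"):
            pools_matching(toy_index, PatternQuery.include("Nope_1"))

    def test_random_queries_match_naive_dense_scan(self):
        rng = np.random.default_rng(21)
        matrix = random_psi_matrix(60, 300, rng=rng)
        index = build_index(matrix)
        labels = matrix.node_labels
        for _ in range(40):
            n_terms = int(rng.integers(1, 6))
            chosen = rng.choice(len(labels), size=n_terms, replace=False)
            terms = tuple(
                (labels[j], "above" if rng.random() < 0.5 else "below") for j in chosen
            )
            comb = "AND" if rng.random() < 0.5 else "OR"
            q = PatternQuery(terms, combinator=comb)
            assert matching_positions(index, q).tolist() == naive_query(matrix, q)

    def test_and_or_set_algebra_against_per_term_results(self, random_index):
        rng = np.random.default_rng(3)
        labels = [n.label for n in random_index.nodes]
        for _ in range(20):
            chosen = rng.choice(len(labels), size=3, replace=False)
            terms = tuple((labels[j], "above") for j in chosen)
            singles = [
                set(matching_positions(random_index, PatternQuery((t,))).tolist())
                for t in terms
            ]
            got_and = set(matching_positions(random_index, PatternQuery(terms, "AND")).tolist())
            got_or = set(matching_positions(random_index, PatternQuery(terms, "OR")).tolist())
            assert got_and == set.intersection(*singles)
            assert got_or == set.union(*singles)


class TestRecoverPsi:
    def test_mask_pools_recover_the_mean_exactly(self, toy_index):
        j = toy_index.node_index("G1_2")
        rec = recover_psi(toy_index, "G1_2")
        assert np.allclose(rec, toy_index.stats[j].mean_psi)

    def test_singleton_sides_recover_exactly(self, toy_index):
        # node G1_1 has one value per side: its bin representative is the value itself
        rec = recover_psi(toy_index, "G1_1")
        assert rec.tolist() == pytest.approx([0.1, 0.5, 0.9])

    def test_unquantified_pools_stay_missing(self, toy_index):
        rec = recover_psi(toy_index, "G1_3")
        assert np.isnan(rec[0]) and not np.isnan(rec[1:]).any()

    def test_error_bounds_on_random_matrices(self):
        rng = np.random.default_rng(31)
        matrix = random_psi_matrix(50, 150, rng=rng)
        tau = 0.2
        index = build_index(matrix, tau=tau)
        tri = naive_tripartition(matrix, tau=tau)
        for j, node in enumerate(matrix.nodes):
            rec = recover_psi(index, node.label)
            col = matrix.values[:, j]
            above, below, mask = tri[node.label]
            for i in mask:
                assert abs(rec[i] - col[i]) <= tau + 1e-12
            jj = index.node_index(node.label)
            for side_name, pools in (("above", above), ("below", below)):
                side = getattr(index, side_name)[jj]
                if not pools:
                    continue
                vals = np.abs(col[sorted(pools)] - index.stats[jj].mean_psi)
                bins = side.value_bins
                for k in np.unique(bins):
                    sel = bins == k
                    rng_k = vals[sel].max() - vals[sel].min()
                    err = np.abs(rec[side.positions[sel]] - col[side.positions[sel]])
                    assert err.max() <= rng_k + 1e-9


def enumerate_tail(k, n, K, N):
    """Brute-force P(X >= k): enumerate all C(N, n) draws."""
    pop = range(N)
    hits = 0
    total = 0
    for draw in itertools.combinations(pop, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_zero_successes_gives_one(self):
        assert hypergeom_pvalue(0, 5, 5, 10) == 1.0

    def test_all_draws_in_pattern(self):
        assert hypergeom_pvalue(5, 5, 5, 10) == pytest.approx(1 / math.comb(10, 5))

    def test_small_enumeration_example(self):
        # 1 of 2 draws hits the single marked pool of 4
        assert hypergeom_pvalue(1, 2, 1, 4) == pytest.approx(0.5)

    def test_infeasible_counts_rejected(self):
        for bad in [(3, 2, 5, 10), (1, 2, 0, 4), (1, 5, 2, 4)]:
            with pytest.raises(ValueError):
                hypergeom_pvalue(*bad)

    def test_matches_enumeration_for_all_feasible_counts(self):
        for N in range(1, 9):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(min(n, K) + 1):
                        expected = enumerate_tail(k, n, K, N)
                        got = hypergeom_pvalue(k, n, K, N)
                        assert got == pytest.approx(expected, rel=1e-12, abs=1e-15)


@pytest.fixture(scope="module")
def typed_index():
    # 20 pools, 4 types x 5 pools; node 1 deviates upward exactly in type A
    rng = np.random.default_rng(5)
    types = [t for t in "ABCD" for _ in range(5)]
    base = 0.5 + rng.normal(0, 0.01, size=(20, 4))
    base[:5, 0] += 0.4  # type A pools above for node 1
    values = np.clip(base, 0, 1)
    return build_index(matrix_from(values, cell_types=types))


class TestHyperQueryCellTypes:
    def test_type_exclusive_pattern_enriched(self, typed_index):
        res = hyper_query_cell_types(typed_index, PatternQuery.include("G1_1"))
        top = res[0]
        assert top.cell_type == "A"
        assert (top.k, top.n, top.K, top.N) == (5, 5, 5, 20)
        assert top.p_value == pytest.approx(1 / math.comb(20, 5))
        assert top.significant
        assert all(not r.significant for r in res[1:])

    def test_empty_match_gives_all_pvalues_one(self, typed_index):
        res = hyper_query_cell_types(typed_index, PatternQuery.include("G1_2"))
        assert all(r.k == 0 and r.p_value == 1.0 and not r.significant for r in res)

    def test_results_sorted_by_pvalue_then_name(self, typed_index):
        res = hyper_query_cell_types(typed_index, PatternQuery.include("G1_1"))
        keys = [(r.p_value, r.cell_type) for r in res]
        assert keys == sorted(keys)

    def test_uniform_pattern_not_enriched(self):
        # pattern spread evenly over types: no cell type should reach p <= 0.05
        types = [t for t in "ABCD" for _ in range(6)]
        values = np.full((24, 1), 0.5)
        values[::2, 0] = 0.95  # alternating pools above, balanced across types
        index = build_index(matrix_from(values, cell_types=types))
        res = hyper_query_cell_types(index, PatternQuery.include("G1_1"))
        assert all(not r.significant for r in res)

    def test_permutation_null_type_I_rate(self):
        """Fraction of p <= 0.05 under random labels stays near or below alpha."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(15):
            matrix = random_psi_matrix(
                48, 40, n_cell_types=4, na_rate=0.1, rng=rng
            )
            index = build_index(matrix)
            for j in rng.choice(40, size=10, replace=False):
                lab = matrix.nodes[j].label
                res = hyper_query_cell_types(index, PatternQuery.include(lab))
                pvals.extend(r.p_value for r in res)
        pvals = np.asarray(pvals)
        frac = float((pvals <= 0.05).mean())
        se = math.sqrt(0.05 * 0.95 / pvals.size)
        assert frac <= 0.05 + 3 * se
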