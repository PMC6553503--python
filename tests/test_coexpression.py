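import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ricetf.coexpression import (
    CoexpressionNetwork,
    CoexpressionNetworkBuilder,
    attach_terms,
    coexpressed_genes,
    overlay_ppi,
    term_enrichment,
)
from ricetf.synthetic import make_coexpression_block


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by exact enumeration of the hypergeometric pmf."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += (
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        )
    return total


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(1)
    q = rng.normal(size=30)
    rows = {"query": q}
    for i in range(3):  # affine copies correlate perfectly
        rows[f"copy{i}"] = 2.0 * q + i
    for i in range(20):
        rows[f"noise{i}"] = rng.normal(size=30)
    frame = pd.DataFrame(rows).T
    frame.columns = [f"s{j}" for j in range(30)]
    return frame


class TestNeighbors:
    def test_affine_copies_are_perfect_neighbors(self, small_matrix):
        got = coexpressed_genes(small_matrix, "query", min_pcc=0.75, top_k=50)
        assert [g for g, _ in got[:3]] == ["copy0", "copy1", "copy2"]
        assert all(p == pytest.approx(1.0) for _, p in got[:3])

    def test_query_excluded_from_neighbors(self, small_matrix):
        got = coexpressed_genes(small_matrix, "query")
        assert "query" not in [g for g, _ in got]

    def test_truncation_to_top_k(self):
        matrix, query = make_coexpression_block(n_planted=80, seed=7)
        got = coexpressed_genes(matrix, query, min_pcc=0.75, top_k=50)
        assert len(got) == 50
        pccs = [p for _, p in got]
        assert pccs == sorted(pccs, reverse=True)
        assert min(pccs) > 0.75

    def test_no_gene_above_cutoff_returns_empty(self, small_matrix):
        got = coexpressed_genes(small_matrix, "noise0", min_pcc=0.99)
        assert got == []

    def test_absent_query_raises(self, small_matrix):
        with pytest.raises(KeyError):
            coexpressed_genes(small_matrix, "nope")

    def test_zero_variance_query_raises(self, small_matrix):
        m = small_matrix.copy()
        m.loc["flat"] = 1.0
        with pytest.raises(ValueError):
            coexpressed_genes(m, "flat")

    def test_anti_monotone_in_cutoff_and_k(self, small_matrix):
        base = set(g for g, _ in coexpressed_genes(small_matrix, "query", 0.5, 50))
        stricter = set(g for g, _ in coexpressed_genes(small_matrix, "query", 0.9, 50))
        fewer = set(g for g, _ in coexpressed_genes(small_matrix, "query", 0.5, 2))
        assert stricter <= base and fewer <= base

    def test_node_set_invariant_to_sample_permutation(self, small_matrix):
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_matrix.columns)
        shuffled = small_matrix[perm]
        a = {g for g, _ in coexpressed_genes(small_matrix, "query", 0.5)}
        b = {g for g, _ in coexpressed_genes(shuffled, "query", 0.5)}
        assert a == b


class TestTermsAndPPI:
    def net(self):
        return CoexpressionNetwork("q", [("a", 0.9), ("b", 0.8), ("c", 0.78)])

    def test_attach_terms_and_unassigned_marker(self):
        net = attach_terms(self.net(), {"a": ["development"], "q": ["development"]})
        assert net.terms["a"] == ["development"]
        assert net.terms["b"] == ["unassigned"]

    def test_term_counts_on_toy_network(self):
        table = {"q": ["dev"], "a": ["dev", "stress"], "b": ["stress"], "c": []}
        net = attach_terms(self.net(), table)
        counts = {}
        for terms in net.terms.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        assert counts == {"dev": 2, "stress": 2, "unassigned": 1}

    def test_overlay_ppi_keeps_only_internal_edges(self):
        net = overlay_ppi(self.net(), [("a", "b"), ("a", "zzz"), ("b", "a")])
        ppi = [(x, y) for x, y, kind, _ in net.edges if kind == "ppi"]
        assert ppi == [("a", "b")]

    def test_overlay_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(8)]
        net = CoexpressionNetwork("n0", [(n, 0.9) for n in nodes[1:]])
        universe = [f"n{i}" for i in range(12)]
        ppi = [
            tuple(rng.choice(universe, 2, replace=False)) for _ in range(20)
        ]
        out = overlay_ppi(net, ppi)
        got = {frozenset((a, b)) for a, b, kind, _ in out.edges if kind == "ppi"}
        expected = {
            frozenset(e)
            for e in ppi
            if e[0] in set(net.nodes) and e[1] in set(net.nodes) and e[0] != e[1]
        }
        assert got == expected


class TestEnrichment:
    def test_term_covering_all_background_has_p_one(self):
        net = CoexpressionNetwork("q", [("a", 0.9)])
        table = {g: ["everything"] for g in ["q", "a", "x", "y", "z"]}
        res = term_enrichment(net, table, table.keys())
        assert res[0].p_value == pytest.approx(1.0)

    def test_concentrated_term_matches_closed_form(self):
        # 10-gene network all carrying a term held by 10 of 1000 background genes
        members = [f"m{i}" for i in range(10)]
        net = CoexpressionNetwork(members[0], [(m, 0.9) for m in members[1:]])
        table = {m: ["dev"] for m in members}
        background = members + [f"bg{i}" for i in range(990)]
        for g in background[10:]:
            table[g] = ["other"]
        res = {r.term: r for r in term_enrichment(net, table, background)}
        expected = hypergeom_tail_oracle(10, 1000, 10, 10)
        assert res["dev"].p_value == pytest.approx(expected, rel=1e-9)

    def test_zero_hits_gives_p_one(self):
        net = CoexpressionNetwork("q", [])
        table = {"q": ["other"], "x": ["dev"], "y": ["dev"]}
        res = {r.term: r for r in term_enrichment(net, table, table.keys())}
        assert "dev" not in res  # no network gene carries it
        assert res["other"].p_value <= 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle_small_universes(self, seed):
        rng = np.random.default_rng(400 + seed)
        N = int(rng.integers(5, 31))
        genes = [f"g{i}" for i in range(N)]
        table = {}
        for g in genes:
            table[g] = ["A"] if rng.random() < 0.4 else ["B"]
        n_net = int(rng.integers(1, N))
        members = list(rng.choice(genes, n_net, replace=False))
        net = CoexpressionNetwork(members[0], [(m, 0.9) for m in members[1:]])
        for r in term_enrichment(net, table, genes):
            expected = hypergeom_tail_oracle(
                r.k_in_network, r.N_background, r.K_in_background, r.n_network
            )
            assert r.p_value == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestBuilder:
    def test_builder_network_with_annotations(self, small_matrix):
        builder = CoexpressionNetworkBuilder(min_pcc=0.75, top_k=2).fit(small_matrix)
        net = builder.network("query", term_table={"copy0": ["dev"]},
                              ppi_edges=[("copy0", "copy1")])
        assert len(net.neighbors) == 2
        assert net.terms["copy0"] == ["dev"]
        g = net.to_networkx()
        assert g.number_of_nodes() == 3

    def test_sklearn_params(self):
        from sklearn.base import clone

        est = CoexpressionNetworkBuilder(min_pcc=0.8, top_k=10)
        assert clone(est).get_params() == {"min_pcc": 0.8, "top_k": 10}
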