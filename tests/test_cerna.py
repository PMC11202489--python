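"""ceRNA screens: Spearman, the shared-miRNA hypergeometric test, triple
assembly, connectivity ranking and network export."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from shellnet.cerna import (build_cerna_triples, build_network,
                            connectivity_rank, hypergeom_shared_test,
                            network_edge_table, network_from_edge_table,
                            sankey_table, screen_negative_pairs,
                            triples_to_frame)
from shellnet.design import make_design
from shellnet.stats import spearman
from shellnet.synthetic import make_cerna_truth, simulate_cerna_expression


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman(x, x ** 3) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_tied_data_matches_scipy_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        expected = sps.spearmanr(x, y).statistic
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_defined_as_zero(self):
        assert spearman(np.ones(5), np.arange(5.0)) == 0.0

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=13)
        y = rng.normal(size=13)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.arange(5.0), np.arange(6.0))


class TestHypergeom:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_shared_test(0, 4, 5, 10) == 1.0

    def test_enumeration_example(self):
        """N=10, K=5, n=4, m=4: only C(5,4)=5 of the C(10,4)=210 draws have
        4 marked items -> 1/42."""
        assert hypergeom_shared_test(4, 4, 5, 10) == pytest.approx(1 / 42)

    def test_forced_total_overlap(self):
        assert hypergeom_shared_test(6, 6, 6, 6) == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_m(self):
        ps = [hypergeom_shared_test(m, 8, 9, 20) for m in range(9)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_shared_test(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_shared_test(1, 4, 11, 10)

    def test_small_universe_enumeration(self):
        """Exhaustive subset enumeration agrees for a grid of small cases."""
        for N in (5, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    marked = set(range(K))
                    tail = {m: 0 for m in range(min(n, K) + 1)}
                    total = 0
                    for draw in combinations(range(N), n):
                        total += 1
                        ov = len(marked & set(draw))
                        for m in tail:
                            if ov >= m:
                                tail[m] += 1
                    for m, cnt in tail.items():
                        assert hypergeom_shared_test(m, n, K, N) == pytest.approx(
                            cnt / total, abs=1e-12)


@pytest.fixture(scope="module")
def planted():
    # the hypergeometric screen needs a non-trivial miRNA universe:
    # with n = K = m = 1 the pair p-value is 1/N, so N must exceed
    # 1/alpha for even a perfectly coupled triple to pass
    design = make_design()
    truth = make_cerna_truth(n_triples=15, n_decoys=200, seed=2)
    expr = simulate_cerna_expression(design, truth, coupling=1.0,
                                     noise_sd=0.0, seed=3)
    return truth, expr


class TestScreens:

    def test_perfectly_coupled_pairs_retained_at_minus_one(self, planted):
        truth, expr = planted
        rna = pd.concat([expr["circ"].counts, expr["mrna"].counts]).astype(float)
        pairs = screen_negative_pairs(expr["mirna"].counts.astype(float), rna,
                                      truth.target_edges)
        kept = {(p.a, p.b) for p in pairs}
        for circ, mir, mrna in truth.cerna_triples:
            assert (mir, circ) in kept and (mir, mrna) in kept
        planted_rhos = [p.rho for p in pairs if "T" in p.a.split("-")[1]]
        assert all(r == pytest.approx(-1.0) for r in planted_rhos)

    def test_boundary_rho_is_retained_nonstrict(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = -0.5 exactly needs sum(d^2) = 30
        # at n = 5: ranks (1,2,3,4,5) vs (3,4,5,1,2)
        expr_m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["m"],
                              columns=list("abcde"))
        expr_r = pd.DataFrame([[3.0, 4.0, 5.0, 1.0, 2.0]], index=["r"],
                              columns=list("abcde"))
        assert spearman(expr_m.loc["m"], expr_r.loc["r"]) == pytest.approx(-0.5)
        pairs = screen_negative_pairs(expr_m, expr_r, {"m": {"r"}})
        assert len(pairs) == 1

    def test_planted_triples_emitted(self, planted):
        truth, expr = planted
        rna = pd.concat([expr["circ"].counts, expr["mrna"].counts]).astype(float)
        neg = screen_negative_pairs(expr["mirna"].counts.astype(float), rna,
                                    truth.target_edges)
        triples = build_cerna_triples(neg, expr["circ"].counts.astype(float),
                                      expr["mrna"].counts.astype(float))
        emitted = {(t.circ, t.mirna, t.mrna) for t in triples}
        assert set(truth.cerna_triples) <= emitted

    def test_pair_sharing_whole_universe_rejected(self):
        """If the shared set is the whole universe, p = 1 and nothing passes."""
        rng = np.random.default_rng(5)
        z = rng.normal(size=13)
        cols = [f"s{i}" for i in range(13)]
        mirna = pd.DataFrame([np.exp(z)], index=["m1"], columns=cols)
        circ = pd.DataFrame([np.exp(-z)], index=["c1"], columns=cols)
        mrna = pd.DataFrame([np.exp(-z) * 1.01], index=["g1"], columns=cols)
        neg = screen_negative_pairs(mirna, pd.concat([circ, mrna]),
                                    {"m1": {"c1", "g1"}})
        assert len(neg) == 2
        triples = build_cerna_triples(neg, circ, mrna)
        assert triples == []

    def test_every_emitted_triple_satisfies_all_screens(self, planted):
        truth, expr = planted
        rna = pd.concat([expr["circ"].counts, expr["mrna"].counts]).astype(float)
        neg = screen_negative_pairs(expr["mirna"].counts.astype(float), rna,
                                    truth.target_edges)
        for t in build_cerna_triples(neg, expr["circ"].counts.astype(float),
                                     expr["mrna"].counts.astype(float)):
            assert t.rho_mir_circ <= -0.5
            assert t.rho_mir_mrna <= -0.5
            assert t.rho_circ_mrna > 0.5
            assert 0 < t.p < 0.05
            assert t.shared <= min(t.circ_mirnas, t.mrna_mirnas) <= t.universe


class TestNetwork:
    def _star(self):
        from shellnet.cerna import CeRNATriple
        triples = [CeRNATriple("c1", f"m{i}", "hub", -0.8, -0.8, 0.9,
                               1, 1, 5, 10, 0.01) for i in range(5)]
        triples.append(CeRNATriple("c2", "m0", "leaf", -0.8, -0.8, 0.9,
                                   1, 1, 1, 10, 0.01))
        return triples

    def test_star_centre_ranked_first(self):
        net = build_network(self._star())
        ranked = connectivity_rank(net)
        assert ranked["mRNA"][0][0] == "hub"
        assert ranked["mRNA"][0][1] == 5

    def test_top_k_larger_than_nodes_returns_all(self):
        net = build_network(self._star())
        ranked = connectivity_rank(net, top_k=100)
        assert len(ranked["mRNA"]) == 2

    def test_empty_network_empty_ranking(self):
        ranked = connectivity_rank(nx.Graph())
        assert all(v == [] for v in ranked.values())

    def test_degrees_match_bruteforce_recount(self):
        triples = self._star()
        net = build_network(triples)
        adjacency = {}
        for t in triples:
            adjacency.setdefault(t.circ, set()).add(t.mirna)
            adjacency.setdefault(t.mirna, set()).update({t.circ, t.mrna})
            adjacency.setdefault(t.mrna, set()).add(t.mirna)
        for node, partners in adjacency.items():
            assert net.degree(node) == len(partners)

    def test_one_triple_two_edges(self):
        from shellnet.cerna import CeRNATriple
        net = build_network([CeRNATriple("c", "m", "g", -1, -1, 1,
                                         1, 1, 1, 5, 0.01)])
        table = network_edge_table(net)
        assert len(table) == 2
        assert set(table["interaction"]) == {"circ-miRNA", "miRNA-mRNA"}

    def test_edge_table_round_trip(self):
        net = build_network(self._star())
        table = network_edge_table(net)
        rebuilt = network_from_edge_table(table)
        assert nx.utils.graphs_equal(
            nx.Graph(net.edges), nx.Graph(rebuilt.edges))
        for n in net.nodes:
            assert rebuilt.nodes[n]["node_type"] == net.nodes[n]["node_type"]

    def test_edge_count_matches_triple_recount(self):
        triples = self._star()
        net = build_network(triples)
        circ_mir = {(t.circ, t.mirna) for t in triples}
        mir_mrna = {(t.mirna, t.mrna) for t in triples}
        assert net.number_of_edges() == len(circ_mir) + len(mir_mrna)

    def test_sankey_restricted_to_top_nodes(self):
        triples = self._star()
        net = build_network(triples)
        tab = sankey_table(triples, net, top_k=1)
        assert set(tab["target"]) <= {"hub"} | {t.mirna for t in triples}

    def test_triples_frame_columns(self):
        frame = triples_to_frame(self._star())
        assert list(frame.columns)[:3] == ["circ", "mirna", "mrna"]
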