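"""Commonality scoring: degree null, Obs/Exp, and the composite score."""

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

import guiltnet as gn
from guiltnet.litnet import CooccurrenceNetwork


def _net(gene_edges, universe_genes, extra_concepts=()):
    """Network with edges (gene, concept) given as a mapping concept->genes."""
    g = nx.Graph()
    for gene in universe_genes:
        g.add_node(gene, concept_type="gene", doc_count=1)
    for concept, genes in gene_edges.items():
        g.add_node(concept, concept_type="disease", doc_count=1)
        for gene in genes:
            g.add_edge(gene, concept, weight=1)
    for c in extra_concepts:
        g.add_node(c, concept_type="disease", doc_count=1)
    return CooccurrenceNetwork(g)


class TestConceptDegrees:
    def test_counts_universe_genes_only(self):
        uni = [f"g{i}" for i in range(10)]
        net = _net({"C": uni[:4] + ["outside"]}, uni + ["outside"])
        assert gn.concept_degrees(net, uni)["C"] == 4

    def test_zero_degree_concept_present(self):
        net = _net({}, ["g1", "g2"], extra_concepts=["C0"])
        assert gn.concept_degrees(net, ["g1", "g2"]) == {"C0": 0}

    def test_empty_universe_rejected(self):
        net = _net({}, ["g1"])
        with pytest.raises(ValueError, match="universe"):
            gn.concept_degrees(net, [])


class TestScoreCommonalities:
    def test_arithmetic_from_the_null(self):
        # |query|=40, d_c=10, N=100, shared=8 -> expected 4, obs/exp 2, score 16
        uni = [f"g{i:03d}" for i in range(100)]
        query = uni[:40]
        linked = query[:8] + uni[90:92]  # d_c = 10, 8 in the query
        net = _net({"C": linked}, uni)
        (res,) = gn.score_commonalities(query, net, uni)
        assert res.shared_rels == 8
        assert res.expected == pytest.approx(4.0)
        assert res.obs_exp == pytest.approx(2.0)
        assert res.score == pytest.approx(16.0)

    def test_saturated_concept_scores_by_coverage_only(self):
        uni = [f"g{i}" for i in range(20)]
        query = uni[:7]
        net = _net({"C": uni}, uni)  # d_c = N
        (res,) = gn.score_commonalities(query, net, uni)
        assert res.obs_exp == pytest.approx(1.0)
        assert res.score == pytest.approx(len(query))

    def test_min_shared_threshold_excludes(self):
        uni = [f"g{i}" for i in range(10)]
        net = _net({"C": [uni[0]]}, uni)
        assert gn.score_commonalities(uni[:5], net, uni, min_shared=2) == []

    def test_query_outside_universe_rejected_by_name(self):
        net = _net({}, ["g1", "g2"])
        with pytest.raises(ValueError, match="g9"):
            gn.score_commonalities(["g9"], net, ["g1", "g2"])

    def test_score_identity_exact(self, scenario):
        """score = shared_rels * obs_exp on every emitted record (exact)."""
        net = gn.build_network(scenario["corpus"], scenario["thesaurus"])
        uni = scenario["universe"]
        for gene in uni[:20]:
            degrees = gn.concept_degrees(net, uni)
            for r in gn.score_commonalities([gene] + uni[50:60], net, uni):
                assert r.score == r.shared_rels * r.obs_exp  # float-exact
                exact = Fraction(r.shared_rels) / (
                    Fraction(11 * degrees[r.concept], len(uni)))
                assert r.obs_exp == pytest.approx(float(exact), rel=1e-12)

    def test_monotone_in_shared_rels(self):
        # same d_c, N, |query|: more sharing genes must strictly raise the score
        uni = [f"g{i:02d}" for i in range(20)]
        query = uni[:8]
        scores = []
        # constant degree d_c=8: shared genes from the query, rest outside it
        for shared in (2, 4, 6, 8):
            linked = query[:shared] + uni[8 : 8 + (8 - shared)]
            net = _net({"C": linked}, uni)
            (res,) = gn.score_commonalities(query, net, uni)
            scores.append(res.score)
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_expected_matches_exhaustive_enumeration(self):
        """Oracle: `expected` equals the mean of shared_rels over all
        C(N, |query|) uniform query draws."""
        uni = [f"g{i}" for i in range(8)]
        net = _net({"C1": uni[:3], "C2": uni[2:7]}, uni)
        q = 3
        query = uni[:q]
        results = {r.concept: r for r in
                   gn.score_commonalities(query, net, uni, min_shared=0)}
        for concept, linked in (("C1", set(uni[:3])), ("C2", set(uni[2:7]))):
            total = Fraction(0)
            count = 0
            for subset in itertools.combinations(uni, q):
                total += len(set(subset) & linked)
                count += 1
            assert results[concept].expected == pytest.approx(
                float(total / count), abs=1e-12)


class TestGammaProfile:
    def test_identical_neighbor_sets_give_identical_lists(self, scenario):
        net = gn.build_network(scenario["corpus"], scenario["thesaurus"])
        uni = scenario["universe"]
        nn = gn.coexpression.NeighborList(
            3, {"A": [(g, 0.9) for g in uni[:3]],
                "B": [(g, 0.5) for g in uni[:3]]})
        ra = gn.gamma_profile("A", nn, net, uni, min_shared=1)
        rb = gn.gamma_profile("B", nn, net, uni, min_shared=1)
        assert [(r.concept, r.score) for r in ra] == \
            [(r.concept, r.score) for r in rb]

    def test_gene_without_entry_rejected(self, scenario):
        nn = gn.coexpression.NeighborList(1, {})
        net = gn.build_network(scenario["corpus"], scenario["thesaurus"])
        with pytest.raises(ValueError, match="ZZZ"):
            gn.gamma_profile("ZZZ", nn, net, scenario["universe"])

    def test_neighbors_without_literature_edges_give_empty_list(self):
        uni = [f"g{i}" for i in range(6)]
        net = _net({"C": uni[:2]}, uni)
        nn = gn.coexpression.NeighborList(2, {"g5": [("g3", 0.8), ("g4", 0.7)]})
        assert gn.gamma_profile("g5", nn, net, uni) == []

    def test_planted_concept_ranks_first(self, scenario):
        """End-to-end: the planted concept tops the list for module genes."""
        expr = gn.quantile_normalize(scenario["expression"])
        nn = gn.knn_neighbors(gn.correlation_matrix(expr), 10)
        net = gn.build_network(scenario["corpus"], scenario["thesaurus"])
        module = scenario["truth"].modules[0]
        gene = module.gene_ids[0]
        res = gn.gamma_profile(gene, nn, net, scenario["universe"])
        assert res[0].concept == module.linked_concepts[0]


def test_null_corpus_obs_exp_calibrated_against_permutation():
    """With no planted signal, observed Obs/Exp at shared>=2 stays within the
    spread of a permutation oracle that redraws query sets uniformly."""
    scen = gn.demo_scenario(seed=21, n_docs=400, p_signal=0.0)
    net = gn.build_network(scen["corpus"], scen["thesaurus"])
    uni = scen["universe"]
    rng = np.random.default_rng(21)
    obs = []
    for _ in range(30):
        query = list(rng.choice(uni, size=10, replace=False))
        obs.extend(r.obs_exp for r in gn.score_commonalities(query, net, uni))
    perm = []
    for _ in range(120):
        query = list(rng.choice(uni, size=10, replace=False))
        perm.extend(r.obs_exp for r in gn.score_commonalities(query, net, uni))
    q95_obs = np.quantile(obs, 0.95)
    q99_perm = np.quantile(perm, 0.99)
    assert q95_obs <= q99_perm * 1.1
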