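"""Planted-structure generators: reproducibility and recoverability."""

import numpy as np
import pytest

import guiltnet as gn
from guiltnet.synthetic import gene_labels


def _module(genes, rho, concepts=()):
    return gn.ModuleSpec("M1", tuple(genes), rho, tuple(concepts))


class TestSimulateExpression:
    def test_rho_one_gives_exact_unit_correlation(self):
        labels = gene_labels(5)
        expr, _ = gn.simulate_expression(5, 10, [_module(labels[:2], 1.0)],
                                         seed=1)
        r = np.corrcoef(expr.iloc[0], expr.iloc[1])[0, 1]
        assert r == pytest.approx(1.0)

    def test_null_structure_has_small_correlations(self):
        expr, _ = gn.simulate_expression(50, 500, [], seed=2)
        r = np.corrcoef(expr.to_numpy())
        off = r[~np.eye(50, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.1

    def test_mean_within_module_r_matches_rho(self):
        """Monte-Carlo: E[sample r] ~ rho under the factor model
        (rho=0.8, 10-gene module, 200 samples, 200 replicate seeds)."""
        labels = gene_labels(12)
        rs = []
        for seed in range(200):
            expr, _ = gn.simulate_expression(
                12, 200, [_module(labels[:10], 0.8)], seed=seed)
            r = np.corrcoef(expr.iloc[:10].to_numpy())
            rs.append(r[~np.eye(10, dtype=bool)].mean())
        assert 0.75 <= np.mean(rs) <= 0.85

    def test_overlapping_modules_rejected_naming_gene(self):
        labels = gene_labels(6)
        mods = [gn.ModuleSpec("A", (labels[0], labels[1]), 0.5),
                gn.ModuleSpec("B", (labels[1], labels[2]), 0.5)]
        with pytest.raises(ValueError, match=labels[1]):
            gn.simulate_expression(6, 5, mods, seed=0)

    def test_reproducible_per_seed(self):
        a, _ = gn.simulate_expression(20, 15, [], seed=42)
        b, _ = gn.simulate_expression(20, 15, [], seed=42)
        c, _ = gn.simulate_expression(20, 15, [], seed=43)
        assert a.equals(b)
        assert not a.equals(c)


class TestSimulateCorpus:
    def _setup(self, n_modules=2):
        labels = gene_labels(20)
        modules = [
            gn.ModuleSpec(f"M{i+1}",
                          tuple(labels[i * 8 : i * 8 + 8]), 0.8,
                          (f"DIS{i+1:02d}",))
            for i in range(n_modules)
        ]
        concepts = {m.linked_concepts[0]: "disease" for m in modules}
        thesaurus = gn.make_thesaurus(labels, concepts)
        truth = gn.SyntheticTruth(modules=modules)
        return labels, thesaurus, truth

    def test_pure_signal_always_pairs_gene_with_concept(self):
        _, thesaurus, truth = self._setup(n_modules=1)
        corpus = gn.simulate_corpus(thesaurus, truth, 100, p_signal=1.0,
                                    mentions_per_doc=3, seed=0)
        for doc in corpus:
            terms = gn.recognize_terms(doc.text, thesaurus)
            genes = {t for t in terms if thesaurus[t].concept_type == "gene"}
            if genes:
                assert "DIS01" in terms

    def test_planted_concept_outweighs_other_modules_concept(self):
        """On a half-signal corpus, nearly every module gene co-occurs more
        with its own concept than with the other module's concept."""
        labels, thesaurus, truth = self._setup(n_modules=2)
        corpus = gn.simulate_corpus(thesaurus, truth, 2000, p_signal=0.5,
                                    mentions_per_doc=4, seed=5)
        net = gn.build_network(corpus, thesaurus)
        wins = total = 0
        for m, other in ((truth.modules[0], "DIS02"),
                         (truth.modules[1], "DIS01")):
            own = m.linked_concepts[0]
            for g in m.gene_ids:
                total += 1
                wins += net.weight(g, own) > net.weight(g, other)
        assert wins / total >= 0.95

    def test_missing_planted_concept_rejected(self):
        labels, thesaurus, truth = self._setup(n_modules=1)
        bad = gn.SyntheticTruth(modules=[
            gn.ModuleSpec("M1", truth.modules[0].gene_ids, 0.5, ("GHOST",))])
        with pytest.raises(ValueError, match="GHOST"):
            gn.simulate_corpus(thesaurus, bad, 10, 0.5, 3, seed=0)

    def test_surface_form_appears_exactly_once(self):
        _, thesaurus, truth = self._setup()
        corpus = gn.simulate_corpus(thesaurus, truth, 50, 0.5, 4, seed=9)
        for doc in corpus:
            tokens = doc.text.split()
            for t in gn.recognize_terms(doc.text, thesaurus):
                forms = [f for f in thesaurus[t].surface_forms
                         if f in tokens]
                assert sum(tokens.count(f) for f in forms) == 1


class TestSimulateTraits:
    def test_noiseless_unit_effect_copies_the_gene_row(self):
        expr, _ = gn.simulate_expression(5, 10, [], seed=3)
        gene = expr.index[2]
        traits = gn.simulate_traits(
            expr, [gn.TraitEffect(gene, "T", beta=1.0, sigma=0.0)], seed=0)
        assert np.allclose(traits["T"].to_numpy(), expr.loc[gene].to_numpy())
        r, _, _ = gn.pearson_assoc(expr.loc[gene], traits["T"])
        assert r == pytest.approx(1.0)

    def test_unknown_gene_rejected(self):
        expr, _ = gn.simulate_expression(5, 10, [], seed=3)
        with pytest.raises(ValueError, match="NOPE"):
            gn.simulate_traits(expr, [gn.TraitEffect("NOPE", "T", 1.0, 1.0)],
                               seed=0)

    def test_reproducible_per_seed(self):
        expr, _ = gn.simulate_expression(5, 10, [], seed=3)
        eff = [gn.TraitEffect(expr.index[0], "T", 1.0, 1.0)]
        assert gn.simulate_traits(expr, eff, seed=4).equals(
            gn.simulate_traits(expr, eff, seed=4))


class TestMakeGenesets:
    def _truth(self):
        labels = gene_labels(500)
        module = gn.ModuleSpec("M1", tuple(labels[:10]), 0.8)
        return labels, gn.SyntheticTruth(
            modules=[module], enriched_sets=[("SET_M1", "M1")])

    def test_single_planted_set_count(self):
        labels, truth = self._truth()
        coll = gn.make_genesets(truth, n_decoy_sets=0, set_size=20,
                                universe=labels, seed=0)
        assert len(coll) == 1

    def test_planted_set_contains_whole_module(self):
        labels, truth = self._truth()
        coll = gn.make_genesets(truth, 5, 20, labels, seed=0)
        planted = set(coll["SET_M1"].genes)
        assert len(planted & set(truth.modules[0].gene_ids)) == 10
        assert len(planted) == 20

    def test_generated_artifacts_satisfy_consumer_preconditions(self, scenario):
        """Round trip: the scenario's artifacts pass every reader/validator."""
        import guiltnet.io as gio
        gio.validate_expression(scenario["expression"])
        assert len(scenario["genesets"]) == 23  # 3 planted + 20 decoys
        assert set(scenario["traits"].index) == set(
            scenario["expression"].columns)
        for m in scenario["truth"].modules:
            for c in m.linked_concepts:
                assert c in scenario["thesaurus"]
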