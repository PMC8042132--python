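"""Synthetic data with planted, recoverable structure.

Every downstream stage is testable without external downloads because the
generators plant known structure and return it as a :class:`SyntheticTruth`:

* **Expression**: a single-factor model per module. Each gene in module m is
  ``x_g = sqrt(rho) * f_m + sqrt(1 - rho) * eps_g`` with the module factor
  f_m and gene noise eps_g independent standard normals per sample, so any
  two module genes have population correlation exactly rho; genes outside
  every module are independent standard normal.
* **Corpus**: a signal document picks one module uniformly, mentions a
  random subset of its genes plus the module's linked concepts; a
  background document mentions thesaurus terms uniformly at random.
  Document text is a space-separated concatenation of surface forms
  (synonyms chosen uniformly) interleaved with filler tokens.
* **Traits**: linear gene effects over the strain panel,
  ``trait_s = sum(beta * x_{g,s}) + N(0, sigma^2)``; the default panel size
  downstream is 38 strains, the scale of a recombinant-inbred aorta panel.
* **Gene sets**: one planted set per (name, module) pair, the module's
  genes padded with random universe genes, plus uniformly drawn decoys.

All randomness flows from one explicit integer seed per operation; no
global state, and identical seed + parameters reproduce outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guiltnet.io import GeneSet, GeneSetCollection, Corpus, Document, Thesaurus, ThesaurusEntry


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module and its linked literature concepts."""

    module_id: str
    gene_ids: tuple[str, ...]
    rho: float
    linked_concepts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")


@dataclass(frozen=True)
class TraitEffect:
    gene_id: str
    trait_id: str
    beta: float
    sigma: float


@dataclass
class SyntheticTruth:
    """Planted structure: what a recovery test is entitled to find."""

    modules: list[ModuleSpec] = field(default_factory=list)
    trait_effects: list[TraitEffect] = field(default_factory=list)
    #: (gene_set_name, module_id) pairs: sets that truly contain a module
    enriched_sets: list[tuple[str, str]] = field(default_factory=list)

    def module(self, module_id: str) -> ModuleSpec:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)


def _check_disjoint(modules: list[ModuleSpec]) -> None:
    seen: dict[str, str] = {}
    for m in modules:
        for g in m.gene_ids:
            if g in seen:
                raise ValueError(
                    f"gene {g!r} appears in both module {seen[g]!r} "
                    f"and module {m.module_id!r}"
                )
            seen[g] = m.module_id


def gene_labels(n_genes: int) -> list[str]:
    """Default gene labels G0001..Gnnnn used by the generators."""
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def simulate_expression(
    n_genes: int,
    n_samples: int,
    modules: list[ModuleSpec],
    seed: int,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a genes x samples matrix with planted correlated modules.

    Module gene ids must be drawn from :func:`gene_labels`(n_genes) and be
    disjoint across modules. Returns the matrix and the truth record.
    """
    if n_samples < 3:
        raise ValueError("need n_samples >= 3")
    _check_disjoint(modules)
    labels = gene_labels(n_genes)
    label_set = set(labels)
    for m in modules:
        unknown = [g for g in m.gene_ids if g not in label_set]
        if unknown:
            raise ValueError(
                f"module {m.module_id!r} references unknown gene(s): "
                f"{', '.join(unknown)}"
            )
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    index = {g: i for i, g in enumerate(labels)}
    for m in modules:
        factor = rng.standard_normal(n_samples)
        w = np.sqrt(m.rho)
        v = np.sqrt(1.0 - m.rho)
        for g in m.gene_ids:
            values[index[g]] = w * factor + v * values[index[g]]
    expr = pd.DataFrame(values, index=pd.Index(labels, name="gene_id"),
                        columns=[f"S{j:03d}" for j in range(1, n_samples + 1)])
    return expr, SyntheticTruth(modules=list(modules))


_FILLERS = ("qq0f", "qq1x", "qq2m", "qq3r", "qq4t", "qq5k", "qq6w", "qq7z")


def make_thesaurus(
    gene_ids: list[str],
    concepts: dict[str, str],
    *,
    n_synonyms: int = 1,
) -> Thesaurus:
    """Build a thesaurus with one entry per gene and per concept.

    ``concepts`` maps term_id to concept_type (disease, phenotype, ...).
    Each term gets its id as canonical plus deterministic synonym variants
    (lowercase with a ``-v<k>`` suffix), unique case-insensitively.
    """
    entries = []
    for g in gene_ids:
        syns = tuple(f"{g.lower()}-v{k}" for k in range(1, n_synonyms + 1))
        entries.append(ThesaurusEntry(g, "gene", g, syns))
    for term_id, ctype in concepts.items():
        syns = tuple(f"{term_id.lower()}-v{k}" for k in range(1, n_synonyms + 1))
        entries.append(ThesaurusEntry(term_id, ctype, term_id, syns))
    return Thesaurus(entries)


def simulate_corpus(
    thesaurus: Thesaurus,
    truth: SyntheticTruth,
    n_docs: int,
    p_signal: float,
    mentions_per_doc: int,
    seed: int,
) -> Corpus:
    """Generate abstracts in which module genes co-occur with their concepts.

    With probability ``p_signal`` a document is a module document: one
    module is chosen uniformly and the text mentions
    ``min(mentions_per_doc, module size)`` of its genes (sampled without
    replacement) plus all its linked concepts. Otherwise the document
    mentions ``mentions_per_doc`` thesaurus terms drawn uniformly without
    replacement. Each chosen term appears exactly once, as one of its
    surface forms chosen uniformly, interleaved with filler tokens.
    """
    if not (0.0 <= p_signal <= 1.0):
        raise ValueError("p_signal must be a probability")
    if mentions_per_doc < 1:
        raise ValueError("mentions_per_doc must be >= 1")
    for m in truth.modules:
        for c in m.linked_concepts:
            if c not in thesaurus:
                raise ValueError(
                    f"planted concept {c!r} of module {m.module_id!r} "
                    "is missing from the thesaurus"
                )
    rng = np.random.default_rng(seed)
    all_terms = thesaurus.term_ids()
    docs: list[Document] = []
    modules = truth.modules
    for i in range(n_docs):
        if modules and rng.random() < p_signal:
            m = modules[rng.integers(len(modules))]
            k = min(mentions_per_doc, len(m.gene_ids))
            genes = list(rng.choice(list(m.gene_ids), size=k, replace=False))
            terms = genes + list(m.linked_concepts)
        else:
            k = min(mentions_per_doc, len(all_terms))
            terms = list(rng.choice(all_terms, size=k, replace=False))
        words = []
        for t in terms:
            forms = thesaurus[t].surface_forms
            words.append(forms[rng.integers(len(forms))])
            words.append(_FILLERS[rng.integers(len(_FILLERS))])
        docs.append(Document(f"D{i + 1:06d}", " ".join(words)))
    return Corpus(docs)


def simulate_traits(
    expr: pd.DataFrame,
    effects: list[TraitEffect],
    seed: int,
) -> pd.DataFrame:
    """Generate a samples x traits table with planted linear gene effects.

    Each trait is the beta-weighted sum of its effect genes' expression per
    sample plus Gaussian noise N(0, sigma^2); all effects of one trait must
    agree on sigma (one noise term per trait).
    """
    rng = np.random.default_rng(seed)
    by_trait: dict[str, list[TraitEffect]] = {}
    for e in effects:
        if e.gene_id not in expr.index:
            raise ValueError(f"effect references unknown gene {e.gene_id!r}")
        by_trait.setdefault(e.trait_id, []).append(e)
    n_samples = expr.shape[1]
    data = {}
    for trait_id, eff in by_trait.items():
        sigmas = {e.sigma for e in eff}
        if len(sigmas) > 1:
            raise ValueError(
                f"trait {trait_id!r} has conflicting noise sigmas: {sorted(sigmas)}"
            )
        sigma = eff[0].sigma
        signal = np.zeros(n_samples)
        for e in eff:
            signal += e.beta * expr.loc[e.gene_id].to_numpy(dtype=float)
        noise = sigma * rng.standard_normal(n_samples) if sigma > 0 else 0.0
        data[trait_id] = signal + noise
    return pd.DataFrame(data, index=pd.Index(expr.columns, name="sample_id"))


def make_genesets(
    truth: SyntheticTruth,
    n_decoy_sets: int,
    set_size: int,
    universe: list[str],
    seed: int,
) -> GeneSetCollection:
    """Planted gene sets (module genes padded with random universe genes)
    plus uniformly drawn decoy sets.
    """
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe size")
    rng = np.random.default_rng(seed)
    uni = np.array(universe)
    sets: list[GeneSet] = []
    for name, module_id in truth.enriched_sets:
        genes = list(truth.module(module_id).gene_ids)
        pool = [g for g in universe if g not in set(genes)]
        pad = set_size - len(genes)
        if pad < 0:
            raise ValueError(
                f"set_size {set_size} smaller than module {module_id!r} "
                f"({len(genes)} genes)"
            )
        padding = list(rng.choice(pool, size=pad, replace=False)) if pad else []
        sets.append(GeneSet(name, f"planted:{module_id}", tuple(genes + padding)))
    for d in range(1, n_decoy_sets + 1):
        members = rng.choice(uni, size=set_size, replace=False)
        sets.append(GeneSet(f"DECOY{d:04d}", "decoy", tuple(members)))
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Default end-to-end scenario

def demo_scenario(seed: int = 0, *, n_genes: int = 120, n_samples: int = 120,
                  module_size: int = 12, n_modules: int = 3, rho: float = 0.85,
                  n_docs: int = 800, p_signal: float = 0.6,
                  mentions_per_doc: int = 5):
    """One coherent synthetic study: expression, thesaurus, corpus, traits,
    gene sets, and the truth record.

    Three 12-gene modules (rho = 0.85) in a 120-gene, 120-sample panel,
    each linked to one disease concept; 800 abstracts at 60% signal; one
    trait per module driven by the module's first gene; one planted gene
    set per module among decoys. Returns a dict of artifacts.
    """
    labels = gene_labels(n_genes)
    modules = []
    concepts: dict[str, str] = {}
    for i in range(n_modules):
        genes = tuple(labels[i * module_size : (i + 1) * module_size])
        concept = f"DIS{i + 1:02d}"
        concepts[concept] = "disease"
        modules.append(ModuleSpec(f"M{i + 1}", genes, rho, (concept,)))
    for j in range(1, 9):  # decoy concepts, never linked
        concepts[f"PHE{j:02d}"] = "phenotype"
    truth = SyntheticTruth(
        modules=modules,
        trait_effects=[
            TraitEffect(m.gene_ids[0], f"T{m.module_id}", beta=1.0, sigma=1.0)
            for m in modules
        ],
        enriched_sets=[(f"SET_{m.module_id}", m.module_id) for m in modules],
    )
    expr, _ = simulate_expression(n_genes, n_samples, modules, seed)
    thesaurus = make_thesaurus(labels, concepts)
    corpus = simulate_corpus(
        thesaurus, truth, n_docs, p_signal, mentions_per_doc, seed + 1
    )
    traits = simulate_traits(expr, truth.trait_effects, seed + 2)
    genesets = make_genesets(truth, n_decoy_sets=20, set_size=2 * module_size,
                             universe=labels, seed=seed + 3)
    return {
        "expression": expr,
        "thesaurus": thesaurus,
        "corpus": corpus,
        "traits": traits,
        "genesets": genesets,
        "truth": truth,
        "universe": labels,
    }
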