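"""Commonality enrichment over a literature network (guilt by association).

Given a query gene set — typically a gene's KNN co-expression neighbors —
and a co-occurrence network, every non-gene concept is scored by three
linked statistics:

* ``shared_rels``: how many query genes have a literature edge to the
  concept;
* ``obs_exp``: shared_rels divided by its chance expectation
  ``|query| * d_c / N`` under uniform query draws from a universe of N
  genes, where d_c is the concept's gene degree within that universe (the
  hypergeometric mean, i.e. a degree-proportional null);
* ``score = shared_rels * obs_exp``, the composite ranking value: Obs/Exp
  alone favors rare concepts with thin evidence, raw counts favor abundant
  concepts, and the product balances the two.

Edge weights are ignored at scoring time (a connection either exists or
not); ``min_weight`` optionally requires a minimum co-occurrence count for
an edge to count as a connection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from guiltnet.coexpression import NeighborList
from guiltnet.litnet import CooccurrenceNetwork


@dataclass(frozen=True)
class CommonalityResult:
    concept: str
    concept_type: str
    shared_rels: int
    expected: float
    obs_exp: float
    score: float


def concept_degrees(
    net: CooccurrenceNetwork,
    universe: list[str],
    *,
    min_weight: int = 1,
) -> dict[str, int]:
    """Gene degree d_c of every non-gene concept against ``universe``.

    d_c counts universe genes with an edge (of weight >= ``min_weight``) to
    the concept; edges to genes outside the universe do not count. Concepts
    with d_c = 0 are present with value 0.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    uni = set(universe)
    degrees: dict[str, int] = {}
    for concept in net.terms():
        if net.concept_type(concept) == "gene":
            continue
        d = sum(
            1
            for g in uni
            if net.has_edge(g, concept) and net.weight(g, concept) >= min_weight
        )
        degrees[concept] = d
    return degrees


def score_commonalities(
    query: list[str],
    net: CooccurrenceNetwork,
    universe: list[str],
    min_shared: int = 2,
    *,
    min_weight: int = 1,
    concept_types: set[str] | None = None,
) -> list[CommonalityResult]:
    """Rank concepts shared by the query genes against the degree null.

    Concepts with fewer than ``min_shared`` sharing genes or with zero gene
    degree are never reported. Results are sorted by score descending, ties
    by shared_rels descending then concept id ascending. ``concept_types``
    optionally restricts output to the given types (e.g. the downstream
    curation of disease/phenotype concepts).
    """
    if not query:
        raise ValueError("query must contain at least one gene")
    uni = set(universe)
    for g in query:
        if g not in uni:
            raise ValueError(f"query gene {g!r} is not in the universe")
    n_universe = len(uni)
    n_query = len(set(query))
    degrees = concept_degrees(net, universe, min_weight=min_weight)
    results: list[CommonalityResult] = []
    for concept, d_c in degrees.items():
        if d_c < 1:
            continue
        if concept_types is not None and net.concept_type(concept) not in concept_types:
            continue
        shared = sum(
            1
            for g in set(query)
            if net.has_edge(g, concept) and net.weight(g, concept) >= min_weight
        )
        if shared < min_shared:
            continue
        expected = n_query * d_c / n_universe
        obs_exp = shared / expected
        results.append(
            CommonalityResult(
                concept=concept,
                concept_type=net.concept_type(concept),
                shared_rels=shared,
                expected=expected,
                obs_exp=obs_exp,
                score=shared * obs_exp,
            )
        )
    results.sort(key=lambda r: (-r.score, -r.shared_rels, r.concept))
    return results


def gamma_profile(
    gene: str,
    neighbors: NeighborList,
    net: CooccurrenceNetwork,
    universe: list[str],
    min_shared: int = 2,
    *,
    min_weight: int = 1,
    concept_types: set[str] | None = None,
) -> list[CommonalityResult]:
    """Predicted functions for one gene from its co-expression neighborhood.

    Scores the commonalities of the gene's KNN set; the input gene itself is
    excluded from the query.
    """
    if gene not in neighbors:
        raise ValueError(f"gene {gene!r} has no neighbor entry")
    query = neighbors.query_set(gene)
    if not query:
        return []
    return score_commonalities(
        query, net, universe, min_shared,
        min_weight=min_weight, concept_types=concept_types,
    )


def results_frame(
    per_gene: dict[str, list[CommonalityResult]]
) -> pd.DataFrame:
    rows = [
        (gene, r.concept, r.concept_type, r.shared_rels, r.expected,
         r.obs_exp, r.score)
        for gene, lst in per_gene.items()
        for r in lst
    ]
    return pd.DataFrame(
        rows,
        columns=["query_gene", "concept", "concept_type", "shared_rels",
                 "expected", "obs_exp", "score"],
    )
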