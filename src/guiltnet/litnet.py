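"""Thesaurus-driven term recognition and the literature co-occurrence network.

Documents are tokenized by splitting on non-alphanumeric characters except
internal hyphens, so gene symbols ("Tspan12", "EWI-2") and multi-word
phrases ("blood pressure") both survive. Recognition is case-insensitive,
token-boundary, longest-match-wins: a shorter term wholly inside a longer
match is suppressed, and repeated mentions count once per document.

The network records, for every unordered pair of recognized terms, the
number of documents in which both appear; a term recognized at least once is
kept as a node even if isolated. No co-occurrence threshold is applied at
build time — thresholding belongs to the scoring stage.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from guiltnet.io import Corpus, FormatError, Thesaurus

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+(?:-[0-9A-Za-z]+)*")


def _tokenize(text: str) -> list[str]:
    return [t.casefold() for t in _TOKEN_RE.findall(text)]


def _surface_index(t: Thesaurus) -> tuple[dict[tuple[str, ...], str], int]:
    index: dict[tuple[str, ...], str] = {}
    max_len = 1
    for entry in t.entries:
        for surface in entry.surface_forms:
            toks = tuple(_tokenize(surface))
            if not toks:
                continue
            index[toks] = entry.term_id
            max_len = max(max_len, len(toks))
    return index, max_len


def recognize_terms(text: str, t: Thesaurus) -> set[str]:
    """Term ids recognized in ``text`` (each at most once, longest match wins)."""
    index, max_len = _surface_index(t)
    return _recognize(_tokenize(text), index, max_len)


def _recognize(
    tokens: list[str], index: dict[tuple[str, ...], str], max_len: int
) -> set[str]:
    found: set[str] = set()
    i = 0
    n = len(tokens)
    while i < n:
        for length in range(min(max_len, n - i), 0, -1):
            term = index.get(tuple(tokens[i : i + length]))
            if term is not None:
                found.add(term)
                i += length
                break
        else:
            i += 1
    return found


@dataclass
class CooccurrenceNetwork:
    """Document-level co-occurrence counts over thesaurus terms.

    ``graph`` is an undirected networkx graph; nodes carry ``concept_type``
    and ``doc_count`` (documents mentioning the term), edges carry integer
    ``weight`` = number of documents in which both endpoints were recognized.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def weight(self, a: str, b: str) -> int:
        if self.graph.has_edge(a, b):
            return self.graph[a][b]["weight"]
        return 0

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def terms(self, concept_type: str | None = None) -> list[str]:
        if concept_type is None:
            return list(self.graph.nodes)
        return [
            n for n, d in self.graph.nodes(data=True)
            if d.get("concept_type") == concept_type
        ]

    def concept_type(self, term_id: str) -> str:
        return self.graph.nodes[term_id]["concept_type"]

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            (min(a, b), max(a, b), d["weight"])
            for a, b, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["term_a", "term_b", "weight"])

    def nodes_frame(self) -> pd.DataFrame:
        rows = sorted(
            (n, d["concept_type"], d["doc_count"])
            for n, d in self.graph.nodes(data=True)
        )
        return pd.DataFrame(rows, columns=["term_id", "concept_type", "doc_count"])

    @classmethod
    def from_frames(
        cls, nodes: pd.DataFrame, edges: pd.DataFrame
    ) -> "CooccurrenceNetwork":
        g = nx.Graph()
        for row in nodes.itertuples(index=False):
            g.add_node(row.term_id, concept_type=row.concept_type,
                       doc_count=int(row.doc_count))
        for row in edges.itertuples(index=False):
            if row.term_a == row.term_b:
                raise FormatError(f"self-loop on term {row.term_a!r}")
            w = int(row.weight)
            if w < 1:
                raise FormatError(f"non-positive weight on ({row.term_a}, {row.term_b})")
            g.add_edge(row.term_a, row.term_b, weight=w)
        return cls(g)


def build_network(corpus: Corpus, t: Thesaurus) -> CooccurrenceNetwork:
    """Count document-level term co-occurrences over a whole corpus.

    The result is independent of document order; an empty corpus yields an
    empty network.
    """
    index, max_len = _surface_index(t)
    ctypes = t.concept_type_of
    g = nx.Graph()
    for doc in corpus:
        terms = _recognize(_tokenize(doc.text), index, max_len)
        for term in terms:
            if term in g:
                g.nodes[term]["doc_count"] += 1
            else:
                g.add_node(term, concept_type=ctypes[term], doc_count=1)
        for a, b in itertools.combinations(sorted(terms), 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return CooccurrenceNetwork(g)
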