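"""On-disk formats and validated in-memory containers.

Stage boundaries are file-based so every intermediate artifact can be
inspected. Conventions:

* Expression matrices: TSV, genes in rows (first column ``gene_id``), samples
  in columns, fully numeric, no missing values. Held in memory as a pandas
  DataFrame indexed by gene_id.
* Trait tables: TSV, strains/samples in rows, traits in columns; missing
  values written as ``NA``.
* Thesauri: TSV with columns term_id, concept_type, canonical, synonyms
  (pipe-separated).
* Corpora: JSONL, one ``{"doc_id": ..., "text": ...}`` object per line.
* Gene sets: standard GMT (name TAB description TAB gene ids...).

Validation is strict: a file that violates an invariant is rejected with a
located message rather than silently repaired, because silent repair (e.g.
first-wins synonym resolution) would corrupt downstream co-occurrence counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONCEPT_TYPES = frozenset(
    {"gene", "disease", "phenotype", "chemical", "drug", "go_category"}
)

#: significant digits preserved by the TSV round trip
FLOAT_DIGITS = 12


class FormatError(ValueError):
    """An on-disk artifact violated a format invariant."""


# ---------------------------------------------------------------------------
# Thesaurus

@dataclass(frozen=True)
class ThesaurusEntry:
    term_id: str
    concept_type: str
    canonical: str
    synonyms: tuple[str, ...]

    @property
    def surface_forms(self) -> tuple[str, ...]:
        return (self.canonical, *self.synonyms)


@dataclass
class Thesaurus:
    """A term dictionary mapping surface strings to typed concept ids.

    Invariants: term_ids unique; every synonym nonempty; no surface form
    (case-insensitive) maps to two distinct term_ids.
    """

    entries: list[ThesaurusEntry]
    _by_id: dict[str, ThesaurusEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_id: dict[str, ThesaurusEntry] = {}
        surface_owner: dict[str, str] = {}
        for e in self.entries:
            if e.term_id in by_id:
                raise FormatError(f"duplicate term_id {e.term_id!r} in thesaurus")
            if e.concept_type not in CONCEPT_TYPES:
                raise FormatError(
                    f"unknown concept_type {e.concept_type!r} for {e.term_id!r}; "
                    f"allowed: {', '.join(sorted(CONCEPT_TYPES))}"
                )
            by_id[e.term_id] = e
            for s in e.surface_forms:
                if not s:
                    raise FormatError(f"empty surface form under term {e.term_id!r}")
                key = s.casefold()
                owner = surface_owner.get(key)
                if owner is not None and owner != e.term_id:
                    raise FormatError(
                        f"ambiguous surface form {s!r}: maps to both "
                        f"{owner!r} and {e.term_id!r}"
                    )
                surface_owner[key] = e.term_id
        self._by_id = by_id

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._by_id

    def __getitem__(self, term_id: str) -> ThesaurusEntry:
        return self._by_id[term_id]

    def term_ids(self, concept_type: str | None = None) -> list[str]:
        if concept_type is None:
            return [e.term_id for e in self.entries]
        return [e.term_id for e in self.entries if e.concept_type == concept_type]

    @property
    def concept_type_of(self) -> dict[str, str]:
        return {e.term_id: e.concept_type for e in self.entries}


# ---------------------------------------------------------------------------
# Corpus

@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str


@dataclass
class Corpus:
    documents: list[Document]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.documents:
            if d.doc_id in seen:
                raise FormatError(f"duplicate doc_id {d.doc_id!r} in corpus")
            seen.add(d.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


# ---------------------------------------------------------------------------
# Gene sets

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"gene set {self.name!r} contains duplicate genes")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate gene set name(s): {', '.join(dup)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Expression matrices (genes x samples)

def validate_expression(df: pd.DataFrame, *, allow_missing: bool = False) -> None:
    """Check expression-matrix invariants on a genes x samples DataFrame."""
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dup))}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dup))}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("expression matrix contains non-numeric values")
    if not allow_missing and not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite value at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV into a float DataFrame indexed by gene_id.

    Raises :class:`FormatError` naming the offending gene/line for duplicate
    ids and the row/column coordinates for non-numeric cells.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        for pos, gene in enumerate(raw.index):
            if (raw.index[: pos] == gene).any():
                raise FormatError(
                    f"duplicate gene id {gene!r} at line {pos + 2} of {path}"
                )
    out = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & (raw[col].str.strip() != "")
        missing = raw[col].str.strip() == ""
        if bad.any() or missing.any():
            gene = raw.index[(bad | missing).to_numpy()][0]
            raise FormatError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
            )
        out[col] = converted
    df = pd.DataFrame(out, index=raw.index)
    df.index.name = "gene_id"
    validate_expression(df)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    validate_expression(df)
    df = df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=f"%.{FLOAT_DIGITS}g", lineterminator="\n")


# ---------------------------------------------------------------------------
# Trait tables (samples x traits, NA allowed)

def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dup))}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate trait id(s): {', '.join(map(str, dup))}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            raise FormatError(
                f"non-numeric cell at sample {bad.index[0]!r}, trait {col!r}"
            )
    df.index.name = "sample_id"
    return df.astype(float)


def write_traits(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df.index.name = "sample_id"
    df.to_csv(
        path, sep="\t", na_rep="NA",
        float_format=f"%.{FLOAT_DIGITS}g", lineterminator="\n",
    )


# ---------------------------------------------------------------------------
# Thesaurus TSV

def read_thesaurus(path: str | Path) -> Thesaurus:
    entries: list[ThesaurusEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("term_id\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(parts)}"
                )
            term_id, ctype, canonical, syn = parts
            synonyms = tuple(s for s in syn.split("|") if s != "")
            if not synonyms:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has no synonyms")
            entries.append(ThesaurusEntry(term_id, ctype, canonical, synonyms))
    return Thesaurus(entries)


def write_thesaurus(t: Thesaurus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term_id\tconcept_type\tcanonical\tsynonyms\n")
        for e in t.entries:
            fh.write(f"{e.term_id}\t{e.concept_type}\t{e.canonical}\t"
                     f"{'|'.join(e.synonyms)}\n")


# ---------------------------------------------------------------------------
# Corpus JSONL

def read_corpus(path: str | Path) -> Corpus:
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            if "doc_id" not in obj or "text" not in obj:
                raise FormatError(f"{path}:{lineno}: missing doc_id or text key")
            docs.append(Document(str(obj["doc_id"]), str(obj["text"])))
    return Corpus(docs)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for d in corpus:
            fh.write(json.dumps({"doc_id": d.doc_id, "text": d.text}) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: gene set line has no genes "
                    f"(need name, description, >=1 gene)"
                )
            name, desc, *genes = parts
            genes = [g for g in genes if g != ""]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name, desc, tuple(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
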