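"""Gene-name disambiguation against an annotation release.

Investigator gene lists routinely mix official HGNC symbols with historical
synonyms, and the same string can be the official symbol of one gene while
being a synonym of another (the classic case: ADRA1A is the official symbol
of the alpha-1A adrenergic receptor, gene 148 on chromosome 8, and
simultaneously a synonym of ADRA1D, gene 146 on chromosome 20 — picking the
wrong one moves the analysis to a different chromosome).  This module
builds a bidirectional term index, classifies each query term into an
explicit ambiguity class, resolves lists under a named policy, and computes
release-wide ambiguity censuses.

Term comparison is case-insensitive (lists arrive as "Toso", "TOSO", ...);
original casing is preserved in the underlying records.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .annotation_io import GeneRecord, GeneTable, Provenance, ValidationError

__all__ = [
    "TermClass",
    "SymbolIndex",
    "TermClassification",
    "AmbiguityCensus",
    "ResolvedTerm",
    "ResolutionReport",
    "CrossVersionOverlap",
    "normalize_term",
    "build_index",
    "classify_term",
    "resolve_terms",
    "ambiguity_census",
    "cross_version_overlap",
]

POLICIES = ("strict", "official_first")


def normalize_term(term: str) -> str:
    """Deterministic normalization used for all term comparisons."""
    return term.strip().casefold()


class TermClass(str, Enum):
    """Ambiguity class of a query term against one annotation release.

    Exactly one class holds for any term:

    - OFFICIAL_UNIQUE: official symbol of exactly one gene, synonym of none.
    - SYNONYM_UNIQUE: synonym of exactly one gene, official symbol of none.
    - DUAL_ROLE: official symbol of >=1 gene AND synonym of >=1 gene.
    - SYNONYM_AMBIGUOUS: official of none, synonym of >=2 genes.
    - OFFICIAL_MULTIPLE: official symbol of >=2 genes (malformed release);
      reported as an integrity warning rather than silently resolved.
    - UNKNOWN: appears nowhere in the release.
    """

    OFFICIAL_UNIQUE = "OFFICIAL_UNIQUE"
    SYNONYM_UNIQUE = "SYNONYM_UNIQUE"
    DUAL_ROLE = "DUAL_ROLE"
    SYNONYM_AMBIGUOUS = "SYNONYM_AMBIGUOUS"
    OFFICIAL_MULTIPLE = "OFFICIAL_MULTIPLE"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class SymbolIndex:
    """Bidirectional association from normalized term to gene sets."""

    official_of: Mapping[str, frozenset[int]]
    synonym_of: Mapping[str, frozenset[int]]
    provenance: Provenance

    @property
    def official_terms(self) -> frozenset[str]:
        return frozenset(self.official_of)

    @property
    def synonym_terms(self) -> frozenset[str]:
        return frozenset(self.synonym_of)


@dataclass(frozen=True)
class TermClassification:
    term: str
    term_class: TermClass
    official_candidates: frozenset[int]
    synonym_candidates: frozenset[int]

    @property
    def all_candidates(self) -> frozenset[int]:
        return self.official_candidates | self.synonym_candidates


@dataclass(frozen=True)
class AmbiguityCensus:
    """Release-wide ambiguity counts.

    n_dual_role_terms counts terms that are simultaneously an official
    symbol and a synonym of at least one other gene; n_multi_gene_synonyms
    counts terms listed as a synonym of two or more genes.
    """

    n_unique_symbols: int
    n_unique_synonyms: int
    n_dual_role_terms: int
    n_multi_gene_synonyms: int
    provenance: Provenance

    def __post_init__(self) -> None:
        if min(self.n_unique_symbols, self.n_unique_synonyms,
               self.n_dual_role_terms, self.n_multi_gene_synonyms) < 0:
            raise ValidationError("census counts must be non-negative")
        if self.n_dual_role_terms > min(self.n_unique_symbols, self.n_unique_synonyms):
            raise ValidationError(
                "n_dual_role_terms cannot exceed either vocabulary size"
            )

    def to_dict(self) -> dict:
        return {
            "n_unique_symbols": self.n_unique_symbols,
            "n_unique_synonyms": self.n_unique_synonyms,
            "n_dual_role_terms": self.n_dual_role_terms,
            "n_multi_gene_synonyms": self.n_multi_gene_synonyms,
            "provenance": self.provenance.to_dict(),
        }


@dataclass(frozen=True)
class ResolvedTerm:
    term: str
    classification: TermClassification
    gene_id: int | None          # None <=> needs review
    needs_review: bool
    note: str = ""


@dataclass(frozen=True)
class ResolutionReport:
    entries: tuple[ResolvedTerm, ...]
    policy: str
    provenance: Provenance

    @property
    def resolved(self) -> tuple[ResolvedTerm, ...]:
        return tuple(e for e in self.entries if not e.needs_review)

    @property
    def flagged(self) -> tuple[ResolvedTerm, ...]:
        return tuple(e for e in self.entries if e.needs_review)

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "provenance": self.provenance.to_dict(),
            "entries": [
                {
                    "term": e.term,
                    "class": e.classification.term_class.value,
                    "official_candidates": sorted(e.classification.official_candidates),
                    "synonym_candidates": sorted(e.classification.synonym_candidates),
                    "gene_id": e.gene_id,
                    "needs_review": e.needs_review,
                    "note": e.note,
                }
                for e in self.entries
            ],
        }


@dataclass(frozen=True)
class CrossVersionOverlap:
    n_symbols_a: int
    n_symbols_b: int
    n_overlap: int

    def to_dict(self) -> dict:
        return {"n_symbols_a": self.n_symbols_a, "n_symbols_b": self.n_symbols_b,
                "n_overlap": self.n_overlap}


def build_index(
    records: Iterable[GeneRecord] | GeneTable,
    provenance: Provenance | None = None,
) -> SymbolIndex:
    """Index every official symbol and synonym of an annotation release.

    Accepts a :class:`GeneTable` (provenance taken from it) or a bare
    record iterable with an explicit provenance.
    """
    if isinstance(records, GeneTable):
        provenance = provenance or records.provenance
        records = records.records
    if provenance is None:
        raise ValidationError("build_index requires a provenance "
                              "(pass a GeneTable or provenance=...)")
    official: dict[str, set[int]] = {}
    synonym: dict[str, set[int]] = {}
    for rec in records:
        official.setdefault(normalize_term(rec.official_symbol), set()).add(rec.gene_id)
        for syn in rec.synonyms:
            synonym.setdefault(normalize_term(syn), set()).add(rec.gene_id)
    return SymbolIndex(
        official_of={t: frozenset(g) for t, g in official.items()},
        synonym_of={t: frozenset(g) for t, g in synonym.items()},
        provenance=provenance,
    )


def classify_term(index: SymbolIndex, term: str) -> TermClassification:
    """Place a query term into exactly one ambiguity class.

    Candidate sets are always returned in full, never truncated.
    """
    if not term.strip():
        raise ValidationError("empty query term")
    key = normalize_term(term)
    off = index.official_of.get(key, frozenset())
    syn = index.synonym_of.get(key, frozenset())
    if off and syn:
        cls = TermClass.DUAL_ROLE
    elif len(off) == 1:
        cls = TermClass.OFFICIAL_UNIQUE
    elif len(off) >= 2:
        cls = TermClass.OFFICIAL_MULTIPLE
    elif len(syn) == 1:
        cls = TermClass.SYNONYM_UNIQUE
    elif len(syn) >= 2:
        cls = TermClass.SYNONYM_AMBIGUOUS
    else:
        cls = TermClass.UNKNOWN
    return TermClassification(term=term, term_class=cls,
                              official_candidates=off, synonym_candidates=syn)


def resolve_terms(
    index: SymbolIndex,
    terms: Sequence[str],
    policy: str = "strict",
) -> ResolutionReport:
    """Resolve an investigator gene list under an explicit policy.

    strict: only OFFICIAL_UNIQUE and SYNONYM_UNIQUE terms auto-resolve;
    every ambiguous term (dual-role, multi-gene synonym, duplicated
    official, unknown) is flagged for review with its full candidate set.

    official_first: additionally, a DUAL_ROLE term with a single official
    candidate resolves to that official gene, with a warning note recorded
    — the synonym candidates remain visible in the entry.

    Ambiguous terms are never resolved silently under either policy.
    """
    if policy not in POLICIES:
        raise ValidationError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    entries: list[ResolvedTerm] = []
    for term in terms:
        cl = classify_term(index, term)
        gene_id: int | None = None
        needs_review = True
        note = ""
        if cl.term_class is TermClass.OFFICIAL_UNIQUE:
            (gene_id,) = cl.official_candidates
            needs_review = False
        elif cl.term_class is TermClass.SYNONYM_UNIQUE:
            (gene_id,) = cl.synonym_candidates
            needs_review = False
            note = "resolved via synonym"
        elif cl.term_class is TermClass.DUAL_ROLE:
            if policy == "official_first" and len(cl.official_candidates) == 1:
                (gene_id,) = cl.official_candidates
                needs_review = False
                note = (
                    f"dual-role term: official symbol of gene {gene_id} but also "
                    f"synonym of {sorted(cl.synonym_candidates)}; resolved to the "
                    "official gene under policy=official_first"
                )
            else:
                note = "dual-role term requires manual review"
        elif cl.term_class is TermClass.SYNONYM_AMBIGUOUS:
            note = f"synonym of multiple genes {sorted(cl.synonym_candidates)}"
        elif cl.term_class is TermClass.OFFICIAL_MULTIPLE:
            note = "official symbol of multiple records (table integrity warning)"
        else:
            note = "not found in this annotation release"
        entries.append(ResolvedTerm(term=term, classification=cl, gene_id=gene_id,
                                    needs_review=needs_review, note=note))
    return ResolutionReport(entries=tuple(entries), policy=policy,
                            provenance=index.provenance)


def ambiguity_census(index: SymbolIndex) -> AmbiguityCensus:
    """Count the release-wide ambiguity structure of an index."""
    dual = index.official_terms & index.synonym_terms
    multi = [t for t, genes in index.synonym_of.items() if len(genes) >= 2]
    return AmbiguityCensus(
        n_unique_symbols=len(index.official_of),
        n_unique_synonyms=len(index.synonym_of),
        n_dual_role_terms=len(dual),
        n_multi_gene_synonyms=len(multi),
        provenance=index.provenance,
    )


def cross_version_overlap(index_a: SymbolIndex, index_b: SymbolIndex) -> CrossVersionOverlap:
    """Official-symbol overlap between two annotation releases.

    Both vocabularies are compared under the same normalization the
    indexes were built with.
    """
    a, b = index_a.official_terms, index_b.official_terms
    return CrossVersionOverlap(n_symbols_a=len(a), n_symbols_b=len(b),
                               n_overlap=len(a & b))
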