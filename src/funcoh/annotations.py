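"""Annotation corpora: GAF/TSV parsing, extended sets, information content.

An annotation corpus maps proteins to their direct GO term annotations and
to the ancestor-extended sets used by all similarity metrics.  The corpus
also carries the inverse term -> protein index and the size M of the
annotated universe, which together define the 2x2 contingency tables of the
enrichment module and the term frequencies behind information content.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .ontology import Ontology, UnknownTermError

logger = logging.getLogger("funcoh")

# GAF aspect column letter per GO namespace
ASPECT_CODES = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}

GAF_COLUMNS = 17


class AnnotationError(Exception):
    pass


class GafParseError(AnnotationError):
    pass


class UndefinedICError(AnnotationError, KeyError):
    """Raised when information content is requested for an unseen term."""


@dataclass
class AnnotationCorpus:
    """Protein -> term annotations with ancestor closure and inverse index.

    Attributes
    ----------
    direct
        protein -> set of directly annotated terms (canonicalized).
    extended
        protein -> direct terms plus all their ancestors (true-path rule).
    term_index
        term -> set of proteins whose *extended* set contains the term;
        exact inverse of ``extended``.
    universe
        All registered protein identifiers, annotated or not.  Family
        members absent from the annotation file live here with empty sets.
    """

    direct: dict[str, set[str]] = field(default_factory=dict)
    extended: dict[str, set[str]] = field(default_factory=dict)
    term_index: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    @property
    def M(self) -> int:
        """Number of proteins with at least one direct annotation."""
        return sum(1 for terms in self.direct.values() if terms)

    @property
    def annotated_proteins(self) -> set[str]:
        return {p for p, terms in self.direct.items() if terms}

    def direct_terms(self, protein: str) -> set[str]:
        return self.direct.get(protein, set())

    def extended_terms(self, protein: str) -> set[str]:
        return self.extended.get(protein, set())

    def proteins_with(self, term: str) -> set[str]:
        """Proteins whose extended annotation set contains ``term``."""
        return self.term_index.get(term, set())

    def register(self, proteins: Iterable[str]) -> None:
        """Add proteins to the universe (with empty sets if unannotated)."""
        for p in proteins:
            self.universe.add(p)
            self.direct.setdefault(p, set())
            self.extended.setdefault(p, set())

    def add_annotation(self, protein: str, term: str, ontology: Ontology) -> None:
        """Attach one direct annotation and its ancestor closure."""
        term = ontology.canonical(term)
        self.universe.add(protein)
        self.direct.setdefault(protein, set()).add(term)
        ext = self.extended.setdefault(protein, set())
        new_terms = ontology.ancestors(term, reflexive=True) - ext
        ext.update(new_terms)
        for t in new_terms:
            self.term_index.setdefault(t, set()).add(protein)

    def validate(self, ontology: Ontology) -> None:
        """Check closure and index invariants; raise on violation."""
        for protein, terms in self.direct.items():
            for t in terms:
                if not ontology.ancestors(t, reflexive=True) <= self.extended[protein]:
                    raise AnnotationError(f"closure violated for {protein}/{t}")
        inverse: dict[str, set[str]] = {}
        for protein, ext in self.extended.items():
            for t in ext:
                inverse.setdefault(t, set()).add(protein)
        if inverse != {t: ps for t, ps in self.term_index.items() if ps}:
            raise AnnotationError("term_index is not the inverse of extended")


def parse_gaf(
    stream: TextIO | str,
    ontology: Ontology,
    evidence_filter: set[str] | None = None,
) -> AnnotationCorpus:
    """Parse GAF 2.x (GOA dialect) annotations into a corpus.

    Rows are kept only when the aspect column matches the ontology aspect,
    the qualifier carries no NOT, and (when a filter is given) the evidence
    code is allowed.  Annotations to alternate identifiers are silently
    canonicalized; annotations to obsolete or unknown terms are dropped
    with a warning.

    GAF columns used: 2 (DB object ID), 4 (qualifier), 5 (GO ID),
    7 (evidence code), 9 (aspect).
    """
    text = stream if isinstance(stream, str) else stream.read()
    aspect_code = ASPECT_CODES.get(ontology.aspect, "F")
    corpus = AnnotationCorpus()
    n_dropped = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("!"):
            continue
        fields = raw.split("\t")
        if len(fields) < 15:  # GAF 2.x bodies are 17 columns; 15 are mandatory
            raise GafParseError(
                f"line {lineno}: expected >= 15 tab-separated columns, got {len(fields)}"
            )
        protein, qualifier, term = fields[1], fields[3], fields[4]
        evidence, aspect = fields[6], fields[8]
        if aspect != aspect_code:
            continue
        if "NOT" in qualifier.split("|"):
            continue
        if evidence_filter is not None and evidence not in evidence_filter:
            continue
        if term in ontology.obsolete:
            logger.warning("line %d: dropping annotation to obsolete term %s", lineno, term)
            n_dropped += 1
            continue
        try:
            corpus.add_annotation(protein, term, ontology)
        except UnknownTermError:
            logger.warning("line %d: dropping annotation to unknown term %s", lineno, term)
            n_dropped += 1
    logger.debug("parsed GAF: %d annotated proteins, %d rows dropped", corpus.M, n_dropped)
    return corpus


def parse_tsv(stream: TextIO | str, ontology: Ontology) -> AnnotationCorpus:
    """Parse a minimal 2-column protein<TAB>term annotation table."""
    text = stream if isinstance(stream, str) else stream.read()
    corpus = AnnotationCorpus()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise GafParseError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        protein, term = fields
        if term in ontology.obsolete:
            logger.warning("line %d: dropping annotation to obsolete term %s", lineno, term)
            continue
        corpus.add_annotation(protein, term, ontology)
    return corpus


def parse_family_list(stream: TextIO | str) -> list[str]:
    """Read a plain-text family membership list, one protein ID per line."""
    text = stream if isinstance(stream, str) else stream.read()
    members: list[str] = []
    seen: set[str] = set()
    for raw in text.splitlines():
        pid = raw.strip()
        if not pid or pid.startswith("#") or pid in seen:
            continue
        seen.add(pid)
        members.append(pid)
    return members


@dataclass
class ICTable:
    """Term information content from extended annotation frequencies.

    IC(t) = -ln(n_t / M) with n_t the number of proteins whose extended
    set contains t and M the annotated-corpus size.  Natural log,
    unnormalized; any base cancels in the simGIC ratio.  The root always
    has IC 0 (every annotated protein reaches it), and IC is monotone
    non-increasing along ancestry.
    """

    ic: dict[str, float]
    corpus_size: int

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise UndefinedICError(term) from None

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def get(self, term: str, default: float | None = None) -> float | None:
        return self.ic.get(term, default)

    @classmethod
    def from_corpus(cls, corpus: AnnotationCorpus) -> "ICTable":
        m = corpus.M
        if m == 0:
            return cls(ic={}, corpus_size=0)
        ic = {
            term: (0.0 if len(proteins) == m else -math.log(len(proteins) / m))
            for term, proteins in corpus.term_index.items()
            if proteins
        }
        return cls(ic=ic, corpus_size=m)

    @classmethod
    def uniform(cls, terms: Iterable[str], value: float = 1.0) -> "ICTable":
        """Constant-IC table; under it simGIC reduces exactly to simUI."""
        table = {t: value for t in terms}
        return cls(ic=table, corpus_size=0)


def information_content(corpus: AnnotationCorpus, term: str) -> float:
    """-ln of the term's extended annotation frequency in the corpus.

    Raises :class:`UndefinedICError` when no protein in the corpus carries
    the term; the caller decides the fallback.
    """
    m = corpus.M
    count = len(corpus.proteins_with(term))
    if count == 0 or m == 0:
        raise UndefinedICError(term)
    return 0.0 if count == m else -math.log(count / m)
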