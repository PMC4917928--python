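"""Term-for-term over-representation with topology-based elimination (Elim).

For every term in the extended annotation sets of a study set, a one-sided
Fisher exact test compares the term's study count against its count in the
background corpus.  Because ancestor terms inherit the annotations of their
descendants, raw per-term p-values are statistically dependent up the DAG;
the Elim adjustment mitigates this by processing terms leaves-first and,
whenever a term is significant, removing its annotated proteins from the
counts of all proper ancestors before those are tested.  Elim p-values are
conditioned on descendants and are read without further multiple-testing
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from scipy.stats import hypergeom

from .annotations import AnnotationCorpus
from .metrics import ProteinSet
from .ontology import Ontology

logger = logging.getLogger("funcoh")

DEFAULT_ALPHA = 0.05


class EnrichmentError(Exception):
    pass


class MembershipError(EnrichmentError):
    """A study protein is not part of the corpus universe."""


@dataclass(frozen=True)
class ContingencyTable:
    """The (nt, N, mt, M) quadruple of a 2x2 enrichment table.

    nt: study proteins annotated with the term; N: annotated study size;
    mt: background proteins annotated with the term; M: background size.
    Cell layout: [[nt, mt-nt], [N-nt, (M-N)-(mt-nt)]].
    """

    nt: int
    N: int
    mt: int
    M: int

    def __post_init__(self) -> None:
        cells = (
            self.nt,
            self.mt - self.nt,
            self.N - self.nt,
            (self.M - self.N) - (self.mt - self.nt),
        )
        if self.N > self.M or self.mt > self.M or any(c < 0 for c in cells):
            raise ValueError(
                f"invalid contingency table nt={self.nt} N={self.N} mt={self.mt} M={self.M}"
            )


@dataclass
class EnrichmentResult:
    term: str
    p_classic: float
    nt: int
    N: int
    mt: int
    M: int
    p_elim: float | None = None
    significant: bool = False
    name: str = ""
    # proteins removed from this term's ancestor counts when significant
    eliminated: set[str] = field(default_factory=set, repr=False)


def fisher_over(table: ContingencyTable) -> float:
    """One-sided over-representation p-value: P(X >= nt), X ~ Hypergeom(M, mt, N).

    Equivalent to scipy's ``fisher_exact(..., alternative="greater")`` but
    computed directly from the hypergeometric survival function.
    """
    if table.N == 0 or table.mt == 0:
        return 1.0  # P(X >= 0) over the whole support
    return float(hypergeom.sf(table.nt - 1, table.M, table.mt, table.N))


def term_for_term(
    study: ProteinSet, corpus: AnnotationCorpus
) -> list[EnrichmentResult]:
    """Classic per-term Fisher tests over the study's extended annotations.

    One result per term appearing in the extended set of at least one study
    member; counts use extended annotation (a term's proteins are those
    whose extended set contains it).  N counts the annotated study members
    so that N <= M holds when the study carries unannotated proteins.
    """
    missing = [p for p in study if p not in corpus.universe]
    if missing:
        raise MembershipError(f"study proteins absent from corpus universe: {missing[:5]}")
    study_members = set(study.members)
    annotated_members = {p for p in study_members if corpus.extended_terms(p)}
    n_study = len(annotated_members)
    m_total = corpus.M
    study_terms: set[str] = set()
    for p in annotated_members:
        study_terms |= corpus.extended_terms(p)
    results = []
    for term in sorted(study_terms):
        carriers = corpus.proteins_with(term)
        nt = len(carriers & annotated_members)
        mt = len(carriers)
        table = ContingencyTable(nt=nt, N=n_study, mt=mt, M=m_total)
        results.append(
            EnrichmentResult(
                term=term, p_classic=fisher_over(table),
                nt=nt, N=n_study, mt=mt, M=m_total,
            )
        )
    return results


def elim_adjust(
    results: list[EnrichmentResult],
    study: ProteinSet,
    corpus: AnnotationCorpus,
    ontology: Ontology,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Fill Elim-adjusted p-values, processing terms deepest-first.

    Terms are visited in order of decreasing longest-path depth (ties
    broken by ascending identifier), so every child precedes all of its
    ancestors.  When a term's recomputed p-value falls below ``alpha``, its
    currently annotated proteins — study and background alike — are marked
    eliminated for all proper ancestors; each ancestor's p_elim is then the
    Fisher p on the reduced nt and mt (N and M stay fixed).  Significance
    is strict: p_elim < alpha.  No multiple-testing correction is applied;
    Elim p-values are conditioned on descendants by construction.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    annotated_members = {p for p in study.members if corpus.extended_terms(p)}
    by_term = {r.term: r for r in results}
    order = sorted(by_term, key=lambda t: (-ontology.depth(t), t))
    eliminated: dict[str, set[str]] = {t: set() for t in by_term}
    adjusted: list[EnrichmentResult] = []
    for term in order:
        res = by_term[term]
        removed = eliminated[term]
        carriers = corpus.proteins_with(term) - removed
        nt = len(carriers & annotated_members)
        mt = len(carriers)
        table = ContingencyTable(nt=nt, N=res.N, mt=mt, M=res.M)
        p_elim = fisher_over(table)
        significant = p_elim < alpha
        out = replace(res, p_elim=p_elim, significant=significant)
        if significant:
            out.eliminated = set(carriers)
            for anc in ontology.ancestors(term):
                if anc in eliminated:
                    eliminated[anc] |= carriers
            logger.debug(
                "elim: %s significant (p=%.3g), removing %d proteins from ancestors",
                term, p_elim, len(carriers),
            )
        adjusted.append(out)
    adjusted.sort(key=lambda r: r.term)
    return adjusted


def analyze(
    study: ProteinSet,
    corpus: AnnotationCorpus,
    ontology: Ontology,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Term-for-term testing followed by Elim adjustment, names attached."""
    results = term_for_term(study, corpus)
    results = elim_adjust(results, study, corpus, ontology, alpha=alpha)
    for r in results:
        r.name = ontology.names.get(r.term, "")
    return results
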