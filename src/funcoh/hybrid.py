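"""Hybrid coherence metrics mUI and mGIC: enrichment-filtered simUI/simGIC.

The hybrid metrics score only the statistically characteristic core of a
protein set.  Enrichment with the Elim adjustment selects the terms that
are over-represented in the set against the background corpus (the "shadow
graph"); each protein's annotation set is intersected with those enriched
terms, and simUI / simGIC are averaged over the proteins that carry at
least one enriched term.  Because random replacement proteins rarely carry
the set's enriched core, these metrics stay high (plateau) under noise
levels that collapse the plain metrics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .annotations import AnnotationCorpus, ICTable
from .enrichment import DEFAULT_ALPHA, elim_adjust, term_for_term
from .metrics import ProteinSet, SetScore, UndefinedScoreError, sim_gic, sim_ui
from .ontology import Ontology

logger = logging.getLogger("funcoh")


@dataclass
class ShadowGraph:
    """Enriched terms of a study set and the proteins carrying them."""

    enriched_terms: set[str] = field(default_factory=set)
    core_proteins: set[str] = field(default_factory=set)


def build_shadow(
    study: ProteinSet,
    corpus: AnnotationCorpus,
    ontology: Ontology,
    alpha: float = DEFAULT_ALPHA,
) -> ShadowGraph:
    """Select the enriched-term subgraph and the study's core proteins.

    A term enters the shadow graph when its Elim-adjusted p-value is
    strictly below alpha; core proteins are the study members whose
    extended annotation set intersects the enriched terms.
    """
    results = term_for_term(study, corpus)
    results = elim_adjust(results, study, corpus, ontology, alpha=alpha)
    enriched = {r.term for r in results if r.significant}
    core = {
        p for p in study.members
        if corpus.extended_terms(p) & enriched
    }
    return ShadowGraph(enriched_terms=enriched, core_proteins=core)


def _hybrid_score(
    study: ProteinSet,
    corpus: AnnotationCorpus,
    shadow: ShadowGraph,
    pairwise,
    core_only: bool = True,
) -> SetScore:
    """All-pairs average over effective (enriched-filtered) term sets.

    ``core_only=True`` (default) averages over the core proteins only, the
    reading under which the hybrid metrics measure local-core coherence;
    ``core_only=False`` keeps every study member in the denominator, with
    non-core members contributing empty effective sets.
    """
    if len(study) < 2:
        raise UndefinedScoreError(
            f"set {study.label!r} has {len(study)} member(s); need >= 2"
        )
    scope = (
        sorted(shadow.core_proteins) if core_only else list(study.members)
    )
    n = len(scope)
    if n < 2:
        logger.warning(
            "set %r: %d core protein(s) after enrichment filtering; score is 0",
            study.label, n,
        )
        return SetScore(value=0.0, n_pairs=0, n_considered=n)
    effective = [
        corpus.extended_terms(p) & shadow.enriched_terms for p in scope
    ]
    total = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(effective, 2):
        total += pairwise(a, b)
        n_pairs += 1
    return SetScore(value=total / n_pairs, n_pairs=n_pairs, n_considered=n)


def m_ui(
    study: ProteinSet,
    corpus: AnnotationCorpus,
    ontology: Ontology,
    alpha: float = DEFAULT_ALPHA,
    core_only: bool = True,
    shadow: ShadowGraph | None = None,
) -> SetScore:
    """Enrichment-filtered simUI over the study's core proteins.

    A precomputed ``shadow`` may be passed to share the enrichment step
    with :func:`m_gic` on the same study.
    """
    if shadow is None:
        shadow = build_shadow(study, corpus, ontology, alpha=alpha)
    return _hybrid_score(study, corpus, shadow, sim_ui, core_only=core_only)


def m_gic(
    study: ProteinSet,
    corpus: AnnotationCorpus,
    ontology: Ontology,
    ic: ICTable,
    alpha: float = DEFAULT_ALPHA,
    core_only: bool = True,
    shadow: ShadowGraph | None = None,
) -> SetScore:
    """Enrichment-filtered simGIC; IC comes from the full reference corpus."""
    if shadow is None:
        shadow = build_shadow(study, corpus, ontology, alpha=alpha)
    pairwise = lambda a, b: sim_gic(a, b, ic)  # noqa: E731
    return _hybrid_score(study, corpus, shadow, pairwise, core_only=core_only)
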