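"""Set-level functional coherence metrics: agreement, simUI, simGIC.

Agreement is the naive baseline over *direct* annotations — the fraction of
annotations shared across a set, normalized to [0, 1].  simUI and simGIC are
pairwise groupwise semantic similarities over ancestor-extended annotation
sets: simUI is the Jaccard overlap of the two extended sets, simGIC the
information-content-weighted version.  Set scores are all-pairs averages.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

from .annotations import AnnotationCorpus, ICTable

logger = logging.getLogger("funcoh")

PairwiseMetric = Callable[[set[str], set[str]], float]


class MetricError(Exception):
    pass


class UndefinedScoreError(MetricError):
    """Set-level score requested for a set too small to have pairs."""


@dataclass(frozen=True)
class ProteinSet:
    """An ordered set of unique protein identifiers with a label."""

    members: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("a protein set needs at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in protein set {self.label!r}")

    @classmethod
    def from_ids(cls, ids: Sequence[str], label: str = "") -> "ProteinSet":
        return cls(members=tuple(ids), label=label)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, protein: str) -> bool:
        return protein in self.members


@dataclass(frozen=True)
class SetScore:
    """A set-level similarity with its averaging bookkeeping.

    ``n_considered`` proteins entered the all-pairs average, producing
    ``n_pairs`` = n_considered·(n_considered−1)/2 unordered pairs.
    """

    value: float
    n_pairs: int
    n_considered: int

    def __post_init__(self) -> None:
        expected = (
            self.n_considered * (self.n_considered - 1) // 2
            if self.n_considered >= 2
            else 0
        )
        if self.n_pairs != expected:
            raise ValueError(
                f"n_pairs={self.n_pairs} inconsistent with n_considered={self.n_considered}"
            )

    def __float__(self) -> float:
        return self.value


def agreement(protein_set: ProteinSet, corpus: AnnotationCorpus) -> float:
    """Fraction of direct annotations shared across the set, in [0, 1].

    With x_i the number of members directly annotated with distinct term i,
    t the number of distinct direct terms in the set and N the set size,
    returns (Σ x_i) / (t · N).  A set where every member carries the exact
    same term set scores 1; a set with no annotations at all scores 0.

    Direct annotations only — crediting shared ancestors would hide the
    annotation-incompleteness sensitivity this baseline is meant to expose.
    """
    n = len(protein_set)
    term_counts: dict[str, int] = {}
    for protein in protein_set:
        for term in corpus.direct_terms(protein):
            term_counts[term] = term_counts.get(term, 0) + 1
    t = len(term_counts)
    if t == 0:
        return 0.0
    return sum(term_counts.values()) / (t * n)


def sim_ui(ext_a: set[str], ext_b: set[str]) -> float:
    """Jaccard overlap of two extended annotation sets; 0 when both empty."""
    if not ext_a and not ext_b:
        return 0.0
    union = len(ext_a | ext_b)
    if union == 0:
        return 0.0
    return len(ext_a & ext_b) / union


def sim_gic(ext_a: set[str], ext_b: set[str], ic: ICTable) -> float:
    """IC-weighted overlap: Σ IC over the intersection / Σ IC over the union.

    Zero when the union carries no information (e.g. both sets are empty or
    contain only the root).  Terms without defined IC raise
    :class:`~funcoh.annotations.UndefinedICError`.
    """
    union = ext_a | ext_b
    if not union:
        return 0.0
    # summation in sorted term order keeps the metric exactly symmetric
    # (set iteration order depends on operand order, so naive sums can
    # differ in the last bit between (a, b) and (b, a))
    denom = sum(ic[t] for t in sorted(union))
    if denom == 0.0:
        return 0.0
    num = sum(ic[t] for t in sorted(ext_a & ext_b))
    return num / denom


def make_pairwise(
    name: str,
    ic: ICTable | None = None,
    exclude_root: str | None = None,
) -> PairwiseMetric:
    """Resolve a pairwise metric handle ("ui" | "gic") to a callable.

    ``exclude_root`` optionally removes the root term from both sets before
    comparison, dropping the small similarity floor that the shared root
    otherwise gives every annotated pair.
    """
    if name == "ui":
        base: PairwiseMetric = sim_ui
    elif name == "gic":
        if ic is None:
            raise ValueError("simGIC needs an ICTable")
        base = lambda a, b: sim_gic(a, b, ic)  # noqa: E731
    else:
        raise ValueError(f"unknown pairwise metric {name!r}; expected 'ui' or 'gic'")
    if exclude_root is None:
        return base
    root = exclude_root
    return lambda a, b: base(a - {root}, b - {root})


def set_similarity(
    protein_set: ProteinSet,
    corpus: AnnotationCorpus,
    pairwise: PairwiseMetric,
) -> SetScore:
    """All-pairs average of a pairwise metric over a protein set.

    Every unordered pair of distinct members enters the average, including
    proteins with empty annotation sets (their pairs score 0): randomly
    introduced proteins without molecular-function annotations must drag a
    set's coherence down rather than silently vanish from the denominator.
    """
    n = len(protein_set)
    if n < 2:
        raise UndefinedScoreError(
            f"set {protein_set.label!r} has {n} member(s); need >= 2 for pairwise averaging"
        )
    ext = [corpus.extended_terms(p) for p in protein_set]
    total = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(ext, 2):
        total += pairwise(a, b)
        n_pairs += 1
    return SetScore(value=total / n_pairs, n_pairs=n_pairs, n_considered=n)
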