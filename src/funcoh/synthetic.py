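"""Synthetic ontologies, corpora and families with controlled structure.

Real studies pair a GO aspect with a GOA annotation file and curated
protein families; this module generates all three with planted structure
so every other module can be exercised end-to-end without downloads.  A
family is defined by a core of terms shared by (a fraction of) its
members, with optional depth attrition emulating annotation
incompleteness: an annotation stops at an ancestor of its intended term,
so counts dwindle toward the leaves.  Writers emit standard OBO and GAF
2.2 so synthetic data can flow through the real parsers.

Three named presets cover the canonical annotation scenarios:
``incompleteness`` (full core coverage but heavy depth attrition),
``agreement`` (every member annotated to the identical term set) and
``coherence`` (a strict subset of members shares an exclusive core).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, TextIO

import networkx as nx
import numpy as np

from .annotations import AnnotationCorpus
from .metrics import ProteinSet
from .ontology import Ontology

logger = logging.getLogger("funcoh")

TERM_PREFIX = "SYN"


class SpecError(Exception):
    pass


def _term_id(i: int) -> str:
    return f"{TERM_PREFIX}:{i:07d}"


@dataclass(frozen=True)
class FamilySpec:
    """Blueprint for one synthetic protein family.

    n_proteins members; each member carries the family core with
    probability ``core_coverage`` (all core terms or none, so a strict
    subset of the family shares the core when coverage < 1).  For every
    core annotation, with probability ``depth_attrition`` (applied
    repeatedly) the annotation retreats one step to a random parent
    before being recorded — the incompleteness pattern where specific
    terms lose annotations to generic ancestors.  ``background_terms``
    contributes to the shared decoy pool that background proteins draw
    from.
    """

    label: str
    n_proteins: int
    core_terms: tuple[str, ...]
    core_coverage: float = 1.0
    depth_attrition: float = 0.0
    background_terms: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.core_coverage <= 1.0:
            raise SpecError("core_coverage must be in [0, 1]")
        if not 0.0 <= self.depth_attrition < 1.0:
            raise SpecError("depth_attrition must be in [0, 1)")
        if self.n_proteins < 1:
            raise SpecError("n_proteins must be >= 1")


def make_ontology(n_terms: int, max_children: int = 4, seed: int = 0) -> Ontology:
    """Random single-rooted is_a DAG, deterministic per seed.

    Terms are added one at a time; each attaches to a uniformly chosen
    existing term with spare child capacity, and with probability 0.2 to a
    second parent, producing diamonds.  Every term reaches the root by
    construction and the graph is acyclic (edges only point to earlier
    terms).
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    graph: nx.DiGraph = nx.DiGraph()
    names: dict[str, str] = {}
    root = _term_id(0)
    graph.add_node(root)
    names[root] = "synthetic root"
    child_count = {root: 0}
    terms = [root]
    for i in range(1, n_terms):
        tid = _term_id(i)
        graph.add_node(tid)
        names[tid] = f"synthetic term {i}"
        open_terms = [t for t in terms if child_count[t] < max_children]
        if not open_terms:  # all full: attach to a random term anyway
            open_terms = terms
        parent = open_terms[rng.integers(len(open_terms))]
        graph.add_edge(tid, parent, relation="is_a")
        child_count[parent] = child_count.get(parent, 0) + 1
        if len(terms) > 1 and rng.random() < 0.2:
            others = [t for t in open_terms if t != parent]
            if others:
                second = others[rng.integers(len(others))]
                graph.add_edge(tid, second, relation="is_a")
                child_count[second] = child_count.get(second, 0) + 1
        child_count[tid] = 0
        terms.append(tid)
    onto = Ontology(graph=graph, root=root, aspect="molecular_function", names=names)
    onto.validate()
    return onto


def chain_ontology(length: int, branch: Sequence[int] = ()) -> Ontology:
    """Deterministic root chain with optional sibling leaves at the end.

    ``chain_ontology(3)`` gives root <- t1 <- t2 <- t3; ``branch=(k,)``
    additionally hangs k sibling leaves under the chain's last term.
    Handy for hand-traceable fixtures.
    """
    graph: nx.DiGraph = nx.DiGraph()
    root = _term_id(0)
    graph.add_node(root)
    names = {root: "synthetic root"}
    prev = root
    idx = 0
    for _ in range(length):
        idx += 1
        tid = _term_id(idx)
        graph.add_edge(tid, prev, relation="is_a")
        names[tid] = f"chain term {idx}"
        prev = tid
    anchor = prev
    for n_leaves in branch:
        for _ in range(n_leaves):
            idx += 1
            tid = _term_id(idx)
            graph.add_edge(tid, anchor, relation="is_a")
            names[tid] = f"leaf term {idx}"
    onto = Ontology(graph=graph, root=root, aspect="molecular_function", names=names)
    onto.validate()
    return onto


def _attrit(term: str, ontology: Ontology, attrition: float, rng) -> str:
    """Walk the annotation up to a random ancestor with per-step probability."""
    current = term
    while current != ontology.root and rng.random() < attrition:
        parents = sorted(ontology.parents(current))
        current = parents[rng.integers(len(parents))]
    return current


def make_corpus(
    ontology: Ontology,
    specs: Sequence[FamilySpec],
    n_background: int = 0,
    seed: int = 0,
    background_terms_per_protein: int = 1,
) -> tuple[AnnotationCorpus, dict[str, ProteinSet]]:
    """Generate an annotation corpus plus family membership from specs.

    Family members draw their core annotations per their spec; background
    proteins draw decoy terms from the union of the specs'
    ``background_terms`` pools (falling back to every term outside the
    cores and their ancestries).  Decoys are drawn without replacement
    across the whole background while the pool lasts, so decoy terms stay
    rare; reuse begins only once the pool is exhausted.  All randomness
    flows from the single ``seed``.
    """
    rng = np.random.default_rng(seed)
    for spec in specs:
        for t in spec.core_terms:
            if t not in ontology:
                raise SpecError(f"unknown core term {t!r} in family {spec.label!r}")
    corpus = AnnotationCorpus()
    families: dict[str, ProteinSet] = {}
    for spec in specs:
        members = [f"{spec.label}_P{j:04d}" for j in range(spec.n_proteins)]
        corpus.register(members)
        for protein in members:
            if rng.random() >= spec.core_coverage:
                continue  # this member misses the core entirely
            for core in spec.core_terms:
                annotated = _attrit(core, ontology, spec.depth_attrition, rng)
                corpus.add_annotation(protein, annotated, ontology)
        families[spec.label] = ProteinSet.from_ids(members, label=spec.label)

    if n_background > 0:
        pool = sorted({t for spec in specs for t in spec.background_terms})
        if not pool:
            cores = {t for spec in specs for t in spec.core_terms}
            excluded: set[str] = set()
            for core in cores:
                excluded |= ontology.ancestors(core, reflexive=True)
            pool = sorted(set(ontology.terms) - excluded)
            if not pool:  # cores' ancestries span the ontology: spare only the cores
                pool = sorted(set(ontology.terms) - cores)
        if not pool:
            raise SpecError("no background terms available for decoy annotation")
        bg_members = [f"BG_P{j:04d}" for j in range(n_background)]
        corpus.register(bg_members)
        shuffled = list(pool)
        rng.shuffle(shuffled)
        cursor = 0
        for protein in bg_members:
            for _ in range(background_terms_per_protein):
                if cursor >= len(shuffled):  # pool exhausted: reshuffle and reuse
                    rng.shuffle(shuffled)
                    cursor = 0
                corpus.add_annotation(protein, shuffled[cursor], ontology)
                cursor += 1
        families["BG"] = ProteinSet.from_ids(bg_members, label="BG")
    return corpus, families


def planted_core_fixture(
    n_family: int = 20,
    n_core_terms: int = 3,
    n_background: int = 180,
    core_coverage: float = 1.0,
    depth_attrition: float = 0.0,
    decoy_depth: int = 4,
    seed: int = 0,
) -> tuple[Ontology, AnnotationCorpus, dict[str, ProteinSet], tuple[str, ...]]:
    """A hand-designed cohesive family against a diffuse background.

    The ontology holds a dedicated core branch (root <- core-parent <-
    n_core_terms sibling leaves) plus one private root-anchored chain of
    ``decoy_depth`` terms per background protein.  Family members carry
    the full core; each background protein is annotated to the leaf of
    its own chain, so no two background proteins share any term below the
    root.  The planted counts make the core terms' one-sided Fisher
    p-values astronomically small (nt = mt = n_family against a
    background where no one else carries them) while each decoy term,
    carried by a single protein, can never reach significance at
    conventional alpha (p = N/M for nt = mt = 1).

    With the default ``decoy_depth`` of 4 every extended set — core or
    decoy — has exactly n_core_terms + 2 = 5 terms, so any pair not
    sharing the core overlaps only at the root and scores the same simUI
    floor (1/9); the family's mean simUI/simGIC then decline strictly
    monotonically as members are replaced by background proteins.
    """
    graph: nx.DiGraph = nx.DiGraph()
    root = _term_id(0)
    core_parent = _term_id(1)
    names = {root: "synthetic root", core_parent: "core branch"}
    graph.add_edge(core_parent, root, relation="is_a")
    core_terms = tuple(_term_id(2 + i) for i in range(n_core_terms))
    for i, t in enumerate(core_terms):
        graph.add_edge(t, core_parent, relation="is_a")
        names[t] = f"core activity {i}"
    decoys = []
    idx = 2 + n_core_terms
    for j in range(n_background):
        prev = root
        for step in range(decoy_depth):
            tid = _term_id(idx)
            idx += 1
            graph.add_edge(tid, prev, relation="is_a")
            names[tid] = f"decoy activity {j} level {step + 1}"
            prev = tid
        decoys.append(prev)  # the chain's leaf is the annotated decoy
    ontology = Ontology(graph=graph, root=root, aspect="molecular_function", names=names)
    ontology.validate()
    spec = FamilySpec(
        label="FAM",
        n_proteins=n_family,
        core_terms=core_terms,
        core_coverage=core_coverage,
        depth_attrition=depth_attrition,
        background_terms=tuple(decoys),
    )
    corpus, families = make_corpus(ontology, [spec], n_background=n_background, seed=seed)
    return ontology, corpus, families, core_terms


PRESETS = ("incompleteness", "agreement", "coherence")


def preset_corpus(
    name: str, seed: int = 0
) -> tuple[Ontology, AnnotationCorpus, dict[str, ProteinSet], tuple[str, ...]]:
    """Named fixture scenarios for the three annotation aspects.

    ``agreement``: every member of the family carries the identical core —
    the full-agreement situation where the agreement metric reaches 1.
    ``incompleteness``: full core coverage but strong depth attrition, so
    many members are annotated only to ancestors of the core and specific
    terms lose annotation counts.  ``coherence``: only half the family
    carries the exclusive core (the rest draw decoys), the local-core
    situation the hybrid metrics are built to capture.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    if name == "agreement":
        return planted_core_fixture(seed=seed)
    if name == "incompleteness":
        return planted_core_fixture(seed=seed, depth_attrition=0.5)
    # coherence: exclusive core covering half the family, decoys elsewhere
    onto, corpus, families, core_terms = planted_core_fixture(
        seed=seed, core_coverage=0.5
    )
    # members that missed the core get one decoy each so they are annotated
    rng = np.random.default_rng(seed + 1)
    decoy_pool = sorted(onto.leaves() - set(core_terms))
    for protein in families["FAM"]:
        if not corpus.direct_terms(protein):
            corpus.add_annotation(
                protein, decoy_pool[rng.integers(len(decoy_pool))], onto
            )
    return onto, corpus, families, core_terms


def write_obo(ontology: Ontology, stream: TextIO) -> None:
    """Serialize as OBO 1.2 (is_a edges only), round-trippable by parse_obo."""
    stream.write("format-version: 1.2\nontology: funcoh-synthetic\n")
    for term in sorted(ontology.terms):
        stream.write(f"\n[Term]\nid: {term}\n")
        stream.write(f"name: {ontology.names.get(term, term)}\n")
        stream.write(f"namespace: {ontology.aspect}\n")
        for parent in sorted(ontology.parents(term)):
            rel = ontology.graph.edges[term, parent].get("relation", "is_a")
            if rel == "is_a":
                stream.write(f"is_a: {parent} ! {ontology.names.get(parent, '')}\n")
            else:
                stream.write(f"relationship: {rel} {parent}\n")


def write_gaf(
    corpus: AnnotationCorpus, stream: TextIO, aspect_code: str = "F"
) -> None:
    """Serialize direct annotations as GAF 2.2 (17 columns)."""
    stream.write("!gaf-version: 2.2\n")
    for protein in sorted(corpus.direct):
        for term in sorted(corpus.direct[protein]):
            fields = [
                "FUNCOH", protein, protein, "enables", term, "FUNCOH:0000001",
                "IEA", "", aspect_code, "", "", "protein", "taxon:0",
                "20160623", "FUNCOH", "", "",
            ]
            stream.write("\t".join(fields) + "\n")


def write_family_list(members: Sequence[str], stream: TextIO) -> None:
    for protein in members:
        stream.write(protein + "\n")
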