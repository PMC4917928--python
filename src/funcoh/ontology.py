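"""Rooted Gene Ontology DAGs restricted to a single aspect.

The metrics in this package operate on the subgraph of GO (or any
single-rooted ontology in OBO format) spanned by one namespace and a chosen
set of traversed relations.  Edges point child -> parent, following the
is_a direction of OBO files; the unique term with no outgoing edge is the
aspect root.  Ancestor closure ("true-path rule") and longest-path depth
are the two queries every other module relies on.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx
import obonet

logger = logging.getLogger("funcoh")

DEFAULT_ASPECT = "molecular_function"
DEFAULT_RELATIONS = frozenset({"is_a"})


class OntologyError(Exception):
    """Base class for ontology construction / lookup failures."""


class OboParseError(OntologyError):
    """Malformed OBO input; message names the offending line."""


class EmptyOntologyError(OntologyError):
    """The requested aspect contains no terms."""


class UnknownTermError(OntologyError, KeyError):
    """A term identifier not present in the ontology (after alt_id mapping)."""


@dataclass
class Ontology:
    """A single-rooted DAG of terms for one ontology aspect.

    Attributes
    ----------
    graph
        Directed graph with child -> parent edges; edge attribute
        ``relation`` records the OBO relation label.
    root
        The unique term with no parents within the aspect.
    aspect
        Namespace label (e.g. ``molecular_function``).
    alt_id_map
        Alternate -> canonical identifier mapping.
    obsolete
        Obsolete term identifiers; never part of ``graph``.
    names
        term -> human-readable name (empty string when absent).
    """

    graph: nx.DiGraph
    root: str
    aspect: str
    alt_id_map: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    names: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _depth_cache: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph or term in self.alt_id_map

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def canonical(self, term: str) -> str:
        """Resolve alternate identifiers to their canonical term.

        Raises :class:`UnknownTermError` for identifiers absent from the
        ontology (obsolete terms are not resolvable).
        """
        if term in self.graph:
            return term
        if term in self.alt_id_map:
            return self.alt_id_map[term]
        raise UnknownTermError(term)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(self.canonical(term)))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(self.canonical(term)))

    def ancestors(self, term: str, reflexive: bool = False) -> set[str]:
        """Transitive closure over the traversed relations.

        With ``reflexive=True`` the term itself is included, which is the
        form used to build extended annotation sets.
        """
        term = self.canonical(term)
        if term not in self._ancestor_cache:
            self._ancestor_cache[term] = frozenset(nx.descendants(self.graph, term))
        anc = set(self._ancestor_cache[term])
        if reflexive:
            anc.add(term)
        return anc

    def descendants(self, term: str, reflexive: bool = False) -> set[str]:
        term = self.canonical(term)
        desc = set(nx.ancestors(self.graph, term))
        if reflexive:
            desc.add(term)
        return desc

    def depth(self, term: str) -> int:
        """Length of the LONGEST root-to-term path.

        Longest-path depth guarantees every child is strictly deeper than
        all of its parents, which the Elim processing order requires.
        """
        term = self.canonical(term)
        if not self._depth_cache:
            self._compute_depths()
        return self._depth_cache[term]

    def _compute_depths(self) -> None:
        # DP over reverse topological order of the child->parent graph:
        # parents come first there, so each node sees finished parents.
        order = list(nx.topological_sort(self.graph))
        depths: dict[str, int] = {}
        for node in reversed(order):
            ps = list(self.graph.successors(node))
            depths[node] = 0 if not ps else 1 + max(depths[p] for p in ps)
        self._depth_cache = depths

    def leaves(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.in_degree(n) == 0}

    def validate(self) -> None:
        """Check the structural invariants; raise OntologyError on failure."""
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OntologyError("ontology graph contains a cycle")
        roots = [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]
        if roots != [self.root] and set(roots) != {self.root}:
            raise OntologyError(f"expected single root {self.root!r}, found {roots!r}")
        for node in self.graph.nodes:
            if node != self.root and self.root not in self.ancestors(node):
                raise OntologyError(f"term {node!r} does not reach the root")
        if self.obsolete & set(self.graph.nodes):
            raise OntologyError("obsolete terms participate in the closure graph")


def _prescan_obo(text: str) -> None:
    """Cheap well-formedness scan so parse errors can name a line."""
    in_stanza = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") :
            if not line.endswith("]"):
                raise OboParseError(f"line {lineno}: malformed stanza header {raw!r}")
            in_stanza = True
            continue
        if in_stanza and ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {raw!r}")


def parse_obo(
    stream: TextIO | str,
    aspect: str = DEFAULT_ASPECT,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> Ontology:
    """Parse an OBO 1.2/1.4 file into a single-aspect rooted DAG.

    Parameters
    ----------
    stream
        Text stream or string with OBO content.
    aspect
        Namespace to keep; terms of other namespaces are dropped.
    relations
        Relation labels traversed for closure (default ``{"is_a"}``;
        add ``part_of`` to also traverse part-of links).

    Raises
    ------
    OboParseError
        Malformed stanza (the message names the line).
    EmptyOntologyError
        No term of ``aspect`` found.
    OntologyError
        Cycle, or not exactly one root within the aspect.
    """
    text = stream if isinstance(stream, str) else stream.read()
    _prescan_obo(text)
    relations = frozenset(relations)
    multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    obsolete: set[str] = set()
    keep: set[str] = set()
    alt_id_map: dict[str, str] = {}
    names: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
            continue
        if data.get("namespace", aspect) != aspect:
            continue
        keep.add(node)
        names[node] = data.get("name", "")
        for alt in data.get("alt_id", []):
            alt_id_map[alt] = node

    if not keep:
        raise EmptyOntologyError(f"no terms with namespace {aspect!r} in input")

    graph: nx.DiGraph = nx.DiGraph()
    graph.add_nodes_from(keep)
    for child, parent, rel in multigraph.edges(keys=True):
        if rel in relations and child in keep and parent in keep:
            graph.add_edge(child, parent, relation=rel)

    if not nx.is_directed_acyclic_graph(graph):
        raise OntologyError("cycle detected among traversed relations")
    roots = sorted(n for n in graph.nodes if graph.out_degree(n) == 0)
    if len(roots) != 1:
        raise OntologyError(
            f"expected exactly one root in aspect {aspect!r}, found {len(roots)}: {roots}"
        )

    onto = Ontology(
        graph=graph,
        root=roots[0],
        aspect=aspect,
        alt_id_map=alt_id_map,
        obsolete=obsolete,
        names=names,
    )
    logger.debug(
        "parsed ontology: %d terms, %d edges, root %s, %d obsolete",
        len(keep), graph.number_of_edges(), roots[0], len(obsolete),
    )
    return onto


def ancestors(ontology: Ontology, term: str, reflexive: bool = False) -> set[str]:
    """Functional alias for :meth:`Ontology.ancestors`."""
    return ontology.ancestors(term, reflexive=reflexive)


def depth(ontology: Ontology, term: str) -> int:
    """Functional alias for :meth:`Ontology.depth`."""
    return ontology.depth(term)
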