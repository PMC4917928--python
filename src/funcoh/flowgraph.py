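"""Annotation-flow graphs: term subgraphs weighted by protein counts.

The flow graph of a protein set is the ontology subgraph spanned by the
members' extended annotation sets, with each term labelled by the number
of set proteins carrying it.  Unlike the usual child->parent GO rendering,
edges here point parent->child with widths proportional to the child's
protein count, so generic-to-specific "annotation flow" — and bottlenecks
where annotation stops at a generic term — are visible at a glance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TextIO

from .annotations import AnnotationCorpus
from .metrics import ProteinSet
from .ontology import Ontology

logger = logging.getLogger("funcoh")

PENWIDTH_MIN = 1.0
PENWIDTH_MAX = 8.0


@dataclass
class FlowGraph:
    """Term nodes with (name, protein count) and parent->child edges."""

    nodes: dict[str, tuple[str, int]] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)  # (parent, child)

    def count(self, term: str) -> int:
        return self.nodes[term][1]

    def validate(self) -> None:
        """Extended annotation is monotone up the DAG: child <= parent count."""
        for parent, child in self.edges:
            if self.count(child) > self.count(parent):
                raise ValueError(
                    f"flow edge {parent}->{child} violates count monotonicity"
                )


def build_flow_graph(
    protein_set: ProteinSet, corpus: AnnotationCorpus, ontology: Ontology
) -> FlowGraph:
    """Build the annotation-flow graph for a protein set.

    Nodes are exactly the terms appearing in the members' extended sets,
    counted over the set; edges are the ontology edges between those
    terms, oriented parent -> child.
    """
    counts: dict[str, int] = {}
    for protein in protein_set:
        for term in corpus.extended_terms(protein):
            counts[term] = counts.get(term, 0) + 1
    nodes = {
        term: (ontology.names.get(term, ""), n) for term, n in counts.items()
    }
    edges = [
        (parent, child)
        for child, parent in ontology.graph.edges()
        if child in counts and parent in counts
    ]
    graph = FlowGraph(nodes=nodes, edges=sorted(edges))
    graph.validate()
    return graph


def export_dot(graph: FlowGraph, stream: TextIO) -> None:
    """Write the flow graph as a DOT digraph with count-scaled edge widths.

    Node labels are "term\\nname\\n(count)"; edge penwidth is linear in the
    child's protein count, normalized to [1, 8].  Output ordering is
    sorted by term identifier so repeated exports are byte-identical.
    """
    counts = [graph.count(child) for _, child in graph.edges]
    lo = min(counts) if counts else 0
    hi = max(counts) if counts else 0

    def penwidth(count: int) -> float:
        if hi == lo:
            return PENWIDTH_MIN
        frac = (count - lo) / (hi - lo)
        return PENWIDTH_MIN + frac * (PENWIDTH_MAX - PENWIDTH_MIN)

    stream.write("digraph annotation_flow {\n")
    stream.write("  node [shape=box, fontsize=10];\n")
    for term in sorted(graph.nodes):
        name, count = graph.nodes[term]
        label = f"{term}\\n{name}\\n({count})"
        stream.write(f'  "{term}" [label="{label}"];\n')
    for parent, child in sorted(graph.edges):
        stream.write(
            f'  "{parent}" -> "{child}" [penwidth={penwidth(graph.count(child)):.2f}];\n'
        )
    stream.write("}\n")
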