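"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: reachability by
graph-walking recursion instead of networkx closure, hypergeometric tails
by exact integer arithmetic instead of scipy, all-pairs averages by plain
double loops, and a from-scratch leaves-first elimination trace.
"""

from math import comb
from fractions import Fraction


def reachable_ancestors(edges: set[tuple[str, str]], term: str) -> set[str]:
    """Transitive closure over child->parent edges by naive iteration."""
    out: set[str] = set()
    frontier = {term}
    while frontier:
        nxt = {p for (c, p) in edges for t in frontier if c == t}
        nxt -= out
        out |= nxt
        frontier = nxt
    return out


def longest_path_depth(edges: set[tuple[str, str]], root: str, term: str) -> int:
    """Longest root-to-term path by exhaustive recursion on parents."""
    if term == root:
        return 0
    parents = [p for (c, p) in edges if c == term]
    return 1 + max(longest_path_depth(edges, root, p) for p in parents)


def hypergeom_tail(nt: int, N: int, mt: int, M: int) -> float:
    """P(X >= nt) for X ~ Hypergeom(M, mt, N), exact integer arithmetic."""
    total = comb(M, N)
    upper = min(N, mt)
    acc = Fraction(0)
    for x in range(nt, upper + 1):
        acc += Fraction(comb(mt, x) * comb(M - mt, N - x), total)
    return float(acc)


def naive_pairwise_mean(term_sets: list[set[str]], pairwise) -> float:
    """Plain double-loop all-pairs average."""
    n = len(term_sets)
    total, count = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            total += pairwise(term_sets[i], term_sets[j])
            count += 1
    return total / count if count else 0.0


def naive_jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def naive_ic_overlap(a: set[str], b: set[str], ic: dict[str, float]) -> float:
    union = a | b
    denom = sum(ic[t] for t in union)
    if denom == 0.0:
        return 0.0
    return sum(ic[t] for t in a & b) / denom


def naive_elim_enriched(
    study_proteins: set[str],
    extended: dict[str, set[str]],
    edges: set[tuple[str, str]],
    root: str,
    alpha: float,
) -> set[str]:
    """Enriched terms by a from-scratch leaves-first elimination trace.

    Mirrors the contract: terms ordered by decreasing longest-path depth
    (ties by id), counts on extended annotation, and a significant term's
    current carriers removed from the counts of all proper ancestors.
    """
    annotated = {p for p, ts in extended.items() if ts}
    study_ann = study_proteins & annotated
    M = len(annotated)
    N = len(study_ann)
    carriers = {}
    study_terms: set[str] = set()
    for p in study_ann:
        study_terms |= extended[p]
    for t in study_terms:
        carriers[t] = {p for p in annotated if t in extended[p]}
    order = sorted(study_terms, key=lambda t: (-longest_path_depth(edges, root, t), t))
    removed: dict[str, set[str]] = {t: set() for t in study_terms}
    enriched: set[str] = set()
    for t in order:
        current = carriers[t] - removed[t]
        nt = len(current & study_ann)
        mt = len(current)
        p = hypergeom_tail(nt, N, mt, M)
        if p < alpha:
            enriched.add(t)
            for anc in reachable_ancestors(edges, t):
                if anc in removed:
                    removed[anc] |= current
    return enriched
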