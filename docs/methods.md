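# Methods

## Model and scope

`funcoh` treats functional annotation as a bipartite relation between
proteins and terms of a single-rooted, acyclic ontology (one GO aspect;
molecular function by default).  All similarity computations operate on
**extended annotation sets**: a protein's direct terms unioned with every
ancestor reachable over the traversed relations.  Traversal defaults to
`is_a` only; `part_of` can be added via the `relations` option.  This
keeps closure semantics simple — `part_of` chains in GO can cross
granularity levels in ways that make "shares an ancestor" hard to
interpret — and the default can be revisited per analysis without
touching any other component.

Term **depth** is the length of the *longest* root-to-term path.  The
Elim adjustment processes terms deepest-first, and longest-path depth is
the only depth notion that guarantees every child is strictly deeper
than all of its parents on a DAG, so no parent is ever tested before one
of its descendants.

Obsolete terms never participate in closure; annotations to them are
dropped with a warning.  Annotations to alternate identifiers are
silently canonicalized.

## Metrics

*Agreement* uses **direct** annotations only, normalized as
`(Σ x_i)/(t·N)` with N the set size.  Two choices are deliberate.
First, crediting shared ancestors would blunt exactly the sensitivity to
annotation incompleteness that makes this baseline informative.  Second,
the unnormalized product form `(Σ x_i)·t/N` grows without bound (a fully
agreeing set of N proteins with t terms each scores t²); the normalized
form is the one that reaches its maximum of exactly 1 in the
full-agreement situation and stays in [0, 1], so set scores remain
comparable across sets and across metrics.

*Information content* is `−ln(n_t/M)` with `n_t` counted on extended
sets and `M` the number of annotated proteins in the **full loaded
corpus** — families are compared within the annotation space they were
drawn from, not against themselves, and a family-local IC would make
scores incomparable across families.  Natural log, unnormalized: simGIC
is a ratio, so the base cancels; the choice is purely conventional.
Terms never seen in the corpus have no defined IC and raise rather than
default — a silent 0 would make unseen terms look maximally common, and
a silent large value would make them maximally rare; the caller knows
which fallback the analysis wants.

*Set scores* average the pairwise metric over all unordered member
pairs.  Proteins without annotations stay in the denominator and score 0
against everyone: in the degeneration assay, replacement proteins
without molecular-function annotations must drag a family's score down
rather than silently shrink the sample.  The root term participates in
extended sets, giving annotated pairs a small similarity floor (its IC
is 0, so simGIC is unaffected); a flag removes it for users who want
strict-overlap semantics.  IC summation runs in sorted term order so the
metrics are exactly symmetric, independent of argument order and hash
seed.

## Enrichment and the Elim adjustment

Each term in the study's extended sets gets a one-sided
over-representation p-value, the hypergeometric tail
`P(X ≥ n_t), X ~ Hypergeom(M, m_t, N)` (equivalent to Fisher's exact
test with the "greater" alternative; computed via `scipy.stats.hypergeom`).
Counts use extended annotation: a term's proteins are those whose
extended set contains it.  When a study contains unannotated proteins, N
counts only the annotated members, preserving N ≤ M and the table
invariants.  Depletion is not tested.

Elim processes terms by decreasing longest-path depth, ties broken by
ascending identifier (a deterministic, reproducible order).  When a
term's recomputed p-value falls below alpha, its currently annotated
proteins — study and background alike — are marked eliminated for all
proper ancestors; each ancestor's adjusted p-value is then computed on
the reduced `n_t` and `m_t` with N and M held fixed.  Removing the
proteins from both margins is the reading under which a parent whose
entire signal came from one significant child collapses to p = 1, which
is the behavior the adjustment exists to produce.  Significance is
strict (`p < alpha`, default alpha 0.05, configurable); values exactly
equal to alpha are not significant.  No multiple-testing correction is
applied: Elim p-values are conditioned on descendants, so the usual
corrections do not apply, and the per-term elimination log is kept on
each result for auditability.

## Hybrid metrics

`build_shadow` collects the Elim-significant terms and the study
proteins carrying at least one of them ("core proteins").  mUI and mGIC
are simUI/simGIC averaged over the core proteins only, with every
protein's term set intersected with the enriched terms; IC still comes
from the full-corpus table.  Averaging over core proteins only is the
reading consistent with the metrics' purpose — measuring the coherence
of the characteristic core a set carries, not diluting it with members
that missed the core; the complementary whole-set denominator is exposed
behind `core_only=False` for comparison.  Fewer than two core proteins
yields a score of 0 with a logged warning instead of an error, so
degeneration sweeps never abort at high noise.

## Degeneration assay

For each replacement level x, `k = round-half-up(x·N)` members are
replaced: N−k survivors are sampled without replacement from the family
and k newcomers without replacement from the pool (default: the union of
all other loaded families), so a degenerate set never contains
duplicates and level 1.0 is fully disjoint from the original.  On the
standard 10 % grid with family sizes that are multiples of 10 the
rounding is exact.  Replacement proteins keep whatever annotations the
corpus has for them, possibly none.  Defaults follow the standard assay
design: levels 0.0–1.0 in steps of 0.1, 100 iterations per level,
minimum family size 20.  Each (level, iteration) cell draws from its own
`SeedSequence([seed, level_index, iteration])` substream, so profiles
are bit-reproducible and independent of execution order.  Profiles
report per-level mean and population standard deviation; `resolution` is
the per-family max−min of mean score across levels, averaged over
families.

## Synthetic data

The generator emulates the structure the metrics assume: a rooted is_a
DAG (random attachment with bounded fan-out, occasional double parents
for diamonds) and families defined by a planted term core.  Core
coverage is a per-member coin flip — a member carries the whole core or
none of it — so coverage < 1 produces the local-core scenario the hybrid
metrics target.  Depth attrition retreats an annotation toward the root
with per-step probability, reproducing annotation incompleteness (counts
dwindling toward the leaves).  Background proteins draw decoy terms
without replacement while the pool lasts, keeping decoys rare.  Three
presets name the canonical scenarios: `agreement` (identical annotation,
agreement = 1), `incompleteness` (full coverage, attrition 0.5), and
`coherence` (coverage 0.5 plus decoys for the rest).

`planted_core_fixture` is the designed benchmark family: 20 proteins
sharing a 3-term core branch against 180 background proteins, each
annotated to the leaf of its own private 4-term chain.  The sizes are
chosen so the analytics are unambiguous: core terms have
`n_t = m_t = 20` in `M = 200` (Fisher p ≈ 10⁻²⁶), while a decoy carried
by one protein can never reach significance (p = N/M ≥ 0.1).  With
chain depth 4 every extended set has exactly 5 terms, so any pair not
sharing the core overlaps only at the root and scores the same 1/9
simUI floor — the family's mean similarity then declines strictly
monotonically with replacement, with zero sampling variance, which makes
the assay's expected behavior checkable to machine precision.  What
passing on such fixtures does **not** show: robustness to the skewed
term-frequency and evidence-code distributions, shared ancestry between
unrelated proteins, and multi-aspect annotation of real GOA corpora —
those affect absolute score levels, not the identities and orderings the
tests assert.

## Problem sizes and numerics

The shipped verification runs use scaled problem sizes chosen for tight
analytic control: 25 assay iterations on the planted fixture (its
variance is zero by construction, so more iterations add nothing),
exhaustive Fisher verification for all backgrounds M ≤ 60 against exact
integer arithmetic (631,655 tables; agreement to ~4·10⁻¹⁶), and 50
random corpora (≤ 20 proteins, ≤ 50 terms) for the all-pairs oracles.
Ties in the Elim ordering break on term identifier; TSV output prints 4
decimals; DOT export orders nodes and edges by term identifier so
repeated exports are byte-identical.

## Known limitations

- GS² is not implemented; external set metrics can be plugged into the
  assay via `register_metric`, and published GS² numbers are used only
  as inputs to the resolution summary.
- Enrichment offers no FDR/Bonferroni variants and only the Elim
  topology adjustment (no weight or parent-child schemes).
- Aggregation is all-pairs average only; best-match-average and
  max-style schemes are out of scope, as are term-level metrics
  (Resnik/Lin/Jiang).
- No identifier mapping: annotation files must use the same protein IDs
  as the family lists.
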