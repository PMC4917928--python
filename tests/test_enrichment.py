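"""Fisher over-representation tests and the Elim adjustment."""

import pytest

from funcoh import (
    ContingencyTable,
    ProteinSet,
    analyze,
    chain_ontology,
    elim_adjust,
    fisher_over,
    term_for_term,
)
from funcoh.annotations import AnnotationCorpus
from funcoh.enrichment import MembershipError

from .oracles import hypergeom_tail


class TestContingencyTable:
    @pytest.mark.parametrize("quad", [(3, 2, 3, 10), (2, 2, 1, 10), (1, 2, 5, 4)])
    def test_invalid_counts_rejected(self, quad):
        nt, N, mt, M = quad
        with pytest.raises(ValueError):
            ContingencyTable(nt=nt, N=N, mt=mt, M=M)


class TestFisherOver:
    def test_zero_observed_is_one(self):
        assert fisher_over(ContingencyTable(nt=0, N=3, mt=2, M=10)) == 1.0

    def test_two_of_two_in_four(self):
        # C(2,2)*C(2,0)/C(4,2) = 1/6
        p = fisher_over(ContingencyTable(nt=2, N=2, mt=2, M=4))
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_term_annotating_everything_is_one(self):
        assert fisher_over(ContingencyTable(nt=5, N=5, mt=20, M=20)) == pytest.approx(1.0)

    @pytest.mark.parametrize("M", [5, 11, 17, 23, 30])
    def test_matches_exact_integer_tail(self, M):
        """Spot-check against the exact-arithmetic oracle on all tables (small M)."""
        for N in range(1, M + 1):
            for mt in range(1, M + 1):
                for nt in range(0, min(N, mt) + 1):
                    if (M - N) - (mt - nt) < 0:
                        continue
                    got = fisher_over(ContingencyTable(nt=nt, N=N, mt=mt, M=M))
                    assert got == pytest.approx(hypergeom_tail(nt, N, mt, M), abs=1e-10)


class TestTermForTerm:
    def test_study_equals_background_all_p_one(self, toy_ontology):
        corpus = AnnotationCorpus()
        for protein, term in [("P1", "GO:0000004"), ("P2", "GO:0000005")]:
            corpus.add_annotation(protein, term, toy_ontology)
        results = term_for_term(ProteinSet.from_ids(["P1", "P2"]), corpus)
        assert results and all(r.p_classic == pytest.approx(1.0) for r in results)

    def test_exclusive_term_small_p(self, toy_ontology):
        # a1 annotates exactly the 2-protein study within a 4-protein universe
        corpus = AnnotationCorpus()
        for protein, term in [
            ("P1", "GO:0000004"), ("P2", "GO:0000004"),
            ("P3", "GO:0000003"), ("P4", "GO:0000003"),
        ]:
            corpus.add_annotation(protein, term, toy_ontology)
        results = {r.term: r for r in term_for_term(ProteinSet.from_ids(["P1", "P2"]), corpus)}
        assert results["GO:0000004"].p_classic == pytest.approx(1 / 6, abs=1e-12)
        # terms absent from the study's extended sets get no row
        assert "GO:0000003" not in results

    def test_unknown_study_protein_raises(self, toy_corpus):
        with pytest.raises(MembershipError):
            term_for_term(ProteinSet.from_ids(["P1", "GHOST"]), toy_corpus)


class TestElim:
    def make_flat(self):
        """All terms directly under the root: no descendants to eliminate."""
        onto = chain_ontology(0, branch=(4,))
        corpus = AnnotationCorpus()
        leaves = sorted(onto.leaves())
        for i in range(12):
            corpus.add_annotation(f"P{i}", leaves[i % len(leaves)], onto)
        study = ProteinSet.from_ids([f"P{i}" for i in range(4)])
        return onto, corpus, study

    def test_flat_ontology_elim_equals_classic(self):
        onto, corpus, study = self.make_flat()
        results = analyze(study, corpus, onto, alpha=0.05)
        for r in results:
            if r.term != onto.root:
                assert r.p_elim == pytest.approx(r.p_classic)

    def test_tiny_alpha_never_eliminates(self):
        onto, corpus, study = self.make_flat()
        results = analyze(study, corpus, onto, alpha=1e-12)
        for r in results:
            assert r.p_elim == pytest.approx(r.p_classic)

    def test_chain_elimination_trace(self):
        """Significant leaf empties its parent's counts: p_elim(parent) = 1."""
        onto = chain_ontology(2)          # root <- t1 <- t2
        leaf, mid = "SYN:0000002", "SYN:0000001"
        corpus = AnnotationCorpus()
        study_ids = [f"S{i}" for i in range(5)]
        for pid in study_ids:
            corpus.add_annotation(pid, leaf, onto)
        # 95 background proteins never reach t1: annotate them to the root
        for i in range(95):
            corpus.add_annotation(f"B{i}", onto.root, onto)
        study = ProteinSet.from_ids(study_ids)
        results = {r.term: r for r in analyze(study, corpus, onto, alpha=0.05)}
        assert results[leaf].significant
        assert results[leaf].p_classic == pytest.approx(
            hypergeom_tail(5, 5, 5, 100), abs=1e-12
        )
        assert results[mid].p_elim == pytest.approx(1.0)
        assert not results[mid].significant
        # root keeps 95 carriers; nt = 0 after elimination of the 5
        assert results[onto.root].p_elim == pytest.approx(1.0)

    def test_no_significant_descendant_keeps_classic(self):
        onto = chain_ontology(2)
        corpus = AnnotationCorpus()
        for i in range(6):
            corpus.add_annotation(f"P{i}", "SYN:0000002" if i < 3 else onto.root, onto)
        study = ProteinSet.from_ids(["P0", "P3"])  # nothing significant here
        results = analyze(study, corpus, onto, alpha=0.05)
        assert all(not r.significant for r in results)
        for r in results:
            assert r.p_elim == pytest.approx(r.p_classic)

    def test_invalid_alpha_rejected(self, toy_ontology, toy_corpus):
        study = ProteinSet.from_ids(["P1", "P2"])
        results = term_for_term(study, toy_corpus)
        with pytest.raises(ValueError):
            elim_adjust(results, study, toy_corpus, toy_ontology, alpha=0.0)
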