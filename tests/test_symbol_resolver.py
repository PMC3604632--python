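"""Symbol/synonym indexing, ambiguity classification and censuses."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genid_audit.annotation_io import Provenance, ValidationError
from genid_audit.symbol_resolver import (
    TermClass,
    ambiguity_census,
    build_index,
    classify_term,
    cross_version_overlap,
    resolve_terms,
)
from genid_audit.synthetic_data import GeneTableSpec, generate_gene_table

from _oracles import brute_force_ambiguity_census

from conftest import SIX_TERM_LIST

PROV = Provenance(database_name="T", version="1", genome_build="Hg19")


class TestBuildIndex:
    def test_dual_role_term_indexed_on_both_sides(self, index1):
        key = "adra1a"
        assert index1.official_of[key] == {148}
        assert index1.synonym_of[key] == {146}

    def test_empty_input(self):
        idx = build_index([], provenance=PROV)
        assert not idx.official_of and not idx.synonym_of

    def test_every_official_symbol_retrievable_exhaustive(self):
        table, _ = generate_gene_table(GeneTableSpec(n_genes=1000, seed=3))
        idx = build_index(table)
        for rec in table:  # brute-force scan over all records
            assert rec.gene_id in idx.official_of[rec.official_symbol.casefold()]

    def test_requires_provenance_for_bare_records(self, table1):
        with pytest.raises(ValidationError):
            build_index(table1.records)


class TestClassifyTerm:
    @pytest.mark.parametrize(
        "term, expected_class, officials, synonyms",
        [
            ("TOSO", TermClass.SYNONYM_UNIQUE, set(), {9214}),
            ("ADRA1A", TermClass.DUAL_ROLE, {148}, {146}),
            ("ADRA1", TermClass.SYNONYM_AMBIGUOUS, set(), {146, 147}),
            ("FAIM3", TermClass.OFFICIAL_UNIQUE, {9214}, set()),
            ("XYZZY", TermClass.UNKNOWN, set(), set()),
        ],
    )
    def test_fixture_classifications(self, index1, term, expected_class, officials, synonyms):
        cl = classify_term(index1, term)
        assert cl.term_class is expected_class
        assert cl.official_candidates == officials
        assert cl.synonym_candidates == synonyms

    def test_case_insensitive_matching(self, index1):
        assert classify_term(index1, "toso").synonym_candidates == {9214}

    def test_empty_term_rejected(self, index1):
        with pytest.raises(ValidationError):
            classify_term(index1, "   ")

    def test_classification_partition(self, index1):
        """Exactly one class holds for every indexed term."""
        all_terms = set(index1.official_of) | set(index1.synonym_of)
        for term in all_terms:
            cl = classify_term(index1, term)
            off, syn = len(cl.official_candidates), len(cl.synonym_candidates)
            expected = {
                (True, True): TermClass.DUAL_ROLE,
                (True, False): TermClass.OFFICIAL_UNIQUE if off == 1 else TermClass.OFFICIAL_MULTIPLE,
                (False, True): TermClass.SYNONYM_UNIQUE if syn == 1 else TermClass.SYNONYM_AMBIGUOUS,
                (False, False): TermClass.UNKNOWN,
            }[(off > 0, syn > 0)]
            assert cl.term_class is expected

    def test_official_multiple_on_malformed_table(self):
        from genid_audit.annotation_io import GeneRecord

        recs = [GeneRecord(1, "DUP", (), "1", "a"), GeneRecord(2, "DUP", (), "1", "b")]
        idx = build_index(recs, provenance=PROV)
        assert classify_term(idx, "DUP").term_class is TermClass.OFFICIAL_MULTIPLE


class TestResolveTerms:
    def test_six_term_list_strict(self, index1):
        rep = resolve_terms(index1, SIX_TERM_LIST, policy="strict")
        assert len(rep.entries) == len(SIX_TERM_LIST)
        assert len(rep.resolved) == 5
        (flagged,) = rep.flagged
        assert flagged.term == "ADRA1A"
        assert flagged.classification.official_candidates == {148}
        assert flagged.classification.synonym_candidates == {146}

    def test_toso_resolves_to_faim3(self, index1):
        rep = resolve_terms(index1, ["TOSO"])
        assert rep.entries[0].gene_id == 9214

    def test_official_first_resolves_dual_role_with_warning(self, index1):
        rep = resolve_terms(index1, ["ADRA1A"], policy="official_first")
        entry = rep.entries[0]
        assert entry.gene_id == 148
        assert not entry.needs_review
        assert "dual-role" in entry.note

    def test_strict_never_resolves_ambiguous(self, index1):
        rep = resolve_terms(index1, ["ADRA1A", "ADRA1"], policy="strict")
        assert all(e.needs_review and e.gene_id is None for e in rep.entries)

    def test_empty_list_gives_empty_report(self, index1):
        assert resolve_terms(index1, []).entries == ()

    def test_unknown_policy_rejected(self, index1):
        with pytest.raises(ValidationError, match="policy"):
            resolve_terms(index1, ["TOSO"], policy="fuzzy")

    def test_no_term_dropped_and_order_preserved(self, index1):
        terms = SIX_TERM_LIST + ["XYZZY", "TOSO"]
        rep = resolve_terms(index1, terms)
        assert [e.term for e in rep.entries] == terms

    def test_determinism(self, index1):
        a = resolve_terms(index1, SIX_TERM_LIST)
        b = resolve_terms(index1, SIX_TERM_LIST)
        assert a == b


class TestAmbiguityCensus:
    def test_fixture_census(self, index1, table1):
        c = ambiguity_census(index1)
        assert c.n_unique_symbols == 6
        assert c.n_dual_role_terms == 1
        assert c.n_multi_gene_synonyms == 1
        oracle = brute_force_ambiguity_census(table1.records)
        assert c.n_unique_symbols == oracle["n_unique_symbols"]
        assert c.n_unique_synonyms == oracle["n_unique_synonyms"]

    def test_empty_index_all_zero(self):
        c = ambiguity_census(build_index([], provenance=PROV))
        assert (c.n_unique_symbols, c.n_unique_synonyms,
                c.n_dual_role_terms, c.n_multi_gene_synonyms) == (0, 0, 0, 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(8, 50),
        d=st.integers(0, 3),
        m=st.integers(0, 3),
        seed=st.integers(0, 10_000),
    )
    def test_oracle_equivalence_small_tables(self, n, d, m, seed):
        """Census equals a brute-force double loop over (term, gene) pairs."""
        if 2 * d + 2 * m > n:
            d = m = 0
        table, _ = generate_gene_table(
            GeneTableSpec(n_genes=n, n_dual_role=d, n_multi_gene_synonyms=m, seed=seed)
        )
        c = ambiguity_census(build_index(table))
        oracle = brute_force_ambiguity_census(table.records)
        assert c.n_unique_symbols == oracle["n_unique_symbols"]
        assert c.n_unique_synonyms == oracle["n_unique_synonyms"]
        assert c.n_dual_role_terms == oracle["n_dual_role_terms"]
        assert c.n_multi_gene_synonyms == oracle["n_multi_gene_synonyms"]

    def test_planted_counts_recovered(self):
        table, truth = generate_gene_table(
            GeneTableSpec(n_genes=100, n_dual_role=5, n_multi_gene_synonyms=7, seed=42)
        )
        c = ambiguity_census(build_index(table))
        assert c.n_dual_role_terms == 5
        assert c.n_multi_gene_synonyms == 7
        assert len(truth.dual_role_terms) == 5


class TestCrossVersionOverlap:
    def test_index_with_itself(self, index1):
        ov = cross_version_overlap(index1, index1)
        assert ov.n_overlap == ov.n_symbols_a == ov.n_symbols_b == 6

    def test_disjoint_indexes(self):
        a, _ = generate_gene_table(GeneTableSpec(n_genes=10, seed=1))
        from genid_audit.annotation_io import GeneRecord

        other = [GeneRecord(100 + i, f"Z{i:03d}", (), "1", "x") for i in range(5)]
        ov = cross_version_overlap(build_index(a), build_index(other, provenance=PROV))
        assert ov.n_overlap == 0

    def test_planted_overlap(self):
        """Two synthetic releases sharing exactly k official symbols."""
        a, _ = generate_gene_table(GeneTableSpec(n_genes=30, seed=5))
        k = 12
        from genid_audit.annotation_io import GeneRecord

        shared = [r for r in a.records[:k]]
        fresh = [GeneRecord(900 + i, f"NEW{i:04d}", (), "1", "x") for i in range(8)]
        b = [GeneRecord(500 + i, r.official_symbol, (), r.chromosome, "copy")
             for i, r in enumerate(shared)] + fresh
        ov = cross_version_overlap(build_index(a), build_index(b, provenance=PROV))
        assert ov.n_overlap == k
        assert ov.n_symbols_b == k + 8
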