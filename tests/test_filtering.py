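"""Literature and database signal filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import adrsub
from adrsub.errors import InvalidArgumentError
from adrsub.filtering import (
    CitationRecord,
    CooccurrenceTable,
    MeshAnnotation,
    chi_square,
    database_filter,
    load_corpus,
    mesh_filter,
    sentence_cooccurrence,
)
from adrsub.synth import SynthParams, generate_corpus

from oracles import chi_square_margin_formula, naive_sentence_counts


def _citation(pmid, mesh, sentences=(), year=2005):
    return CitationRecord(
        pmid=pmid, year=year, publication_types=("Journal Article",),
        mesh_terms=tuple(MeshAnnotation(d, tuple(s)) for d, s in mesh),
        sentences=tuple(sentences),
    )


class TestMeshFilter:
    def test_requires_both_subheading_conditions(self):
        corpus = [
            _citation("1", [("qt", ["chemically induced"]), ("halo", ["adverse effects"])]),
            _citation("2", [("qt", ["chemically induced"])]),
            _citation("3", [("halo", ["adverse effects"])]),
        ]
        rep = mesh_filter(corpus, {"halo"}, set(), {"qt"})
        assert rep.matched_ids == ["1"]

    def test_pharm_action_expansion_member_suffices(self):
        corpus = [
            _citation("1", [("qt", ["chemically induced"]),
                            ("antipsychotics", ["adverse effects"]),
                            ("halo", [])])
        ]
        assert mesh_filter(corpus, {"halo"}, {"antipsychotics"}, {"qt"}).matched_ids == ["1"]
        assert mesh_filter(corpus, {"halo"}, set(), {"qt"}).matched_ids == []

    def test_event_subheading_alone_insufficient(self):
        corpus = [_citation("1", [("qt", ["chemically induced"]), ("halo", [])])]
        assert mesh_filter(corpus, {"halo"}, set(), {"qt"}).matched_ids == []

    def test_groups_by_publication_type_and_year(self, qt_corpus):
        rep = mesh_filter(qt_corpus, {"haloperidol"}, {"antipsychotic agents"},
                          {"long qt syndrome"})
        assert rep.matched_ids == ["11001001", "11001002", "11001003"]
        assert rep.per_year == {2001: 1, 2004: 2}
        assert rep.by_publication_type["Case Reports"] == ["11001001"]

    def test_empty_corpus_gives_empty_report(self):
        assert mesh_filter([], {"d"}, set(), {"e"}).matched_ids == []

    def test_empty_descriptor_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mesh_filter([], set(), set(), {"e"})

    def test_citation_order_irrelevant(self, qt_corpus):
        args = ({"haloperidol"}, {"antipsychotic agents"}, {"long qt syndrome"})
        fwd = mesh_filter(qt_corpus, *args)
        rev = mesh_filter(list(reversed(qt_corpus)), *args)
        assert sorted(fwd.matched_ids) == sorted(rev.matched_ids)
        assert fwd.per_year == rev.per_year


class TestSentenceCooccurrence:
    def test_direct_counts(self):
        sentences = (
            ["drugx caused eventy"] * 2 + ["drugx given"] * 3 + ["eventy seen"] * 1
            + ["nothing here"] * 4
        )
        corpus = [_citation("1", [], sentences)]
        t = sentence_cooccurrence(corpus, {"drugx"}, {"eventy"})
        assert (t.n11, t.n10, t.n01, t.n00) == (2, 3, 1, 4)
        assert t.total == 10

    def test_empty_corpus(self):
        t = sentence_cooccurrence([], {"d"}, {"e"})
        assert (t.n11, t.n10, t.n01, t.n00) == (0, 0, 0, 0)

    def test_whole_token_matching_not_substring(self):
        corpus = [_citation("1", [], ["drugxyz was given", "the drugx dose"])]
        t = sentence_cooccurrence(corpus, {"drugx"}, {"eventy"})
        assert t.n10 == 1  # 'drugxyz' must not match 'drugx'

    def test_multiword_terms_match_contiguously(self):
        corpus = [_citation("1", [], ["qt prolongation after drugx", "prolongation qt drugx"])]
        t = sentence_cooccurrence(corpus, {"drugx"}, {"qt prolongation"})
        assert t.n11 == 1 and t.n10 == 1

    def test_matches_brute_force_scan_on_synthetic_corpus(self):
        citations, truth = generate_corpus(
            SynthParams(corpus_size=1000, cooccurrence_rate_signal=0.08,
                        cooccurrence_rate_null=0.02, seed=11)
        )
        corpus = [
            CitationRecord(
                pmid=c["pmid"], year=c["year"],
                publication_types=tuple(c["publication_types"]),
                sentences=tuple(c["sentences"]),
            )
            for c in citations
        ]
        all_sentences = [s for c in corpus for s in c.sentences]
        for dterm, eterm in [
            (truth.signal_drug_term, truth.signal_event_term),
            (truth.null_drug_term, truth.null_event_term),
        ]:
            t = sentence_cooccurrence(corpus, {dterm}, {eterm})
            assert (t.n11, t.n10, t.n01, t.n00) == naive_sentence_counts(
                all_sentences, {dterm}, {eterm}
            )


class TestChiSquare:
    def test_exact_independence_gives_zero(self):
        res = chi_square(CooccurrenceTable(5, 45, 45, 405))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_spot_value(self):
        res = chi_square(CooccurrenceTable(10, 90, 40, 9860))
        assert res.statistic == pytest.approx(183.2, abs=0.05)

    def test_matches_reference_implementation_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            cells = rng.integers(1, 200, size=4)
            t = CooccurrenceTable(*map(int, cells))
            res = chi_square(t)
            ref_stat, ref_p, _, _ = chi2_contingency(
                [[t.n11, t.n10], [t.n01, t.n00]], correction=False
            )
            assert res.statistic == pytest.approx(ref_stat, abs=1e-8)
            assert res.p_value == pytest.approx(ref_p, abs=1e-8)
            assert res.statistic == pytest.approx(
                chi_square_margin_formula(t.n11, t.n10, t.n01, t.n00), abs=1e-8
            )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_symmetric_under_row_column_swap(self, cells):
        n11, n10, n01, n00 = cells
        a = chi_square(CooccurrenceTable(n11, n10, n01, n00))
        b = chi_square(CooccurrenceTable(n11, n01, n10, n00))  # transpose
        c = chi_square(CooccurrenceTable(n00, n01, n10, n11))  # swap both
        assert a.statistic == pytest.approx(b.statistic)
        assert a.statistic == pytest.approx(c.statistic)

    def test_zero_margin_not_testable(self):
        res = chi_square(CooccurrenceTable(0, 0, 5, 5))
        assert not res.testable and res.statistic is None


class TestDatabaseFilter:
    def test_matching_records_per_source(self, qt_kb):
        ev = qt_kb.resolve_event("QTPROL")
        rep = database_filter(qt_kb, "N05AD01", ev)
        assert rep["DAILYMED"].matched_ids == ["DM-HAL-1", "DM-HAL-2"]
        assert rep["DRUGBANK"].matched_ids == []

    def test_absent_source_reported_na(self, qt_kb):
        from dataclasses import replace

        kb = replace(qt_kb, dailymed=None)
        rep = database_filter(kb, "N05AD01", kb.resolve_event("QTPROL"))
        assert not rep["DAILYMED"].available
        assert rep["DAILYMED"].n_matched is None

    def test_boxed_warning_field_is_indexed(self, qt_kb):
        ev = qt_kb.resolve_event("QTPROL")
        rep = database_filter(qt_kb, "N05AE04", ev)
        assert rep["DAILYMED"].matched_ids == ["DM-ZIP-1"]

    def test_event_mentioned_outside_indexed_fields_not_matched(self, qt_kb):
        ev = qt_kb.resolve_event("QTPROL")
        assert database_filter(qt_kb, "N05AG02", ev)["DAILYMED"].matched_ids == []


def test_corpus_jsonl_round_trip(tmp_path):
    path = tmp_path / "corpus.jsonl"
    citations, truth = generate_corpus(SynthParams(corpus_size=100, seed=3), path)
    loaded = load_corpus(path)
    assert len(loaded) == len(citations)
    assert loaded[0].pmid == citations[0]["pmid"]
    assert [s for c in loaded for s in c.sentences] == [
        s for c in citations for s in c["sentences"]
    ]
    # MeSH annotations survive with their subheadings
    sig = {c.pmid: c for c in loaded}
    for pmid in truth.signal_pmids:
        assert sig[pmid].mesh_terms[0].descriptor == "humans"
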