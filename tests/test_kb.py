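"""Knowledge-base loading, validation and profile construction."""

import random

import pytest

import adrsub
from adrsub.errors import SchemaError, UnknownIdentifierError, UnmappedEventError
from adrsub.kb import ATC_PATTERN, KnowledgeBase, load_knowledge_base
from adrsub.synth import SynthParams, generate_kb

from conftest import make_kb


@pytest.fixture(scope="module")
def synth_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("synthkb")
    generate_kb(SynthParams(seed=7, n_planted_pairs=4, metabolite_only_fraction=0.5), out)
    return out


class TestLoading:
    def test_synthetic_tables_load_with_zero_rejections(self, synth_dir):
        kb = load_knowledge_base(synth_dir / "config.yaml")
        assert kb.rejections == ()
        assert len(kb.compounds) == 20
        assert len(kb.drug_targets) > 0

    def test_loading_is_idempotent(self, synth_dir):
        kb1 = load_knowledge_base(synth_dir / "config.yaml")
        kb2 = load_knowledge_base(synth_dir / "config.yaml")
        assert kb1.drug_targets == kb2.drug_targets
        assert kb1.event_proteins == kb2.event_proteins
        assert kb1.compounds == kb2.compounds
        assert kb1.protein_universe == kb2.protein_universe

    def test_catalog_only_kb_has_empty_profiles_and_catalog_universe(self, tmp_path):
        (tmp_path / "proteins.tsv").write_text(
            "uniprot_acc\tgene_symbol\nP1\tG1\nP2\tG2\nP3\tG3\n"
        )
        (tmp_path / "compounds.tsv").write_text("atc_code\tsmiles\tname\nA01AA01\tCC\ttoy\n")
        (tmp_path / "config.yaml").write_text(
            "tables:\n  proteins: proteins.tsv\n  compounds: compounds.tsv\n"
        )
        kb = load_knowledge_base(tmp_path / "config.yaml")
        assert len(kb.drug_target_profile("A01AA01")) == 0
        assert kb.universe_size == 3

    def test_invalid_evidence_type_is_rejected_not_fatal(self, tmp_path):
        (tmp_path / "proteins.tsv").write_text("uniprot_acc\tgene_symbol\nP1\tG1\n")
        (tmp_path / "compounds.tsv").write_text("atc_code\tsmiles\tname\nA01AA01\tCC\ttoy\n")
        rows = [f"A01AA01\tP1\tpKi\t{5 + i / 10}\tsrc\tOBSERVATIONAL" for i in range(5)]
        rows.append("A01AA01\tP1\tpKi\t6.0\tsrc\tGUESS")
        (tmp_path / "drug_targets.tsv").write_text(
            "compound_id\tuniprot_acc\taffinity_kind\taffinity_value\tevidence_source\tevidence_type\n"
            + "\n".join(rows) + "\n"
        )
        (tmp_path / "config.yaml").write_text(
            "tables:\n  proteins: proteins.tsv\n  compounds: compounds.tsv\n"
            "  drug_targets: drug_targets.tsv\n"
        )
        kb = load_knowledge_base(tmp_path / "config.yaml")
        assert len(kb.drug_targets) == 5
        assert len(kb.rejections) == 1
        assert "GUESS" in kb.rejections[0].reason

    def test_malformed_atc_collected_with_line_number(self, tmp_path):
        (tmp_path / "proteins.tsv").write_text("uniprot_acc\tgene_symbol\nP1\tG1\n")
        (tmp_path / "compounds.tsv").write_text(
            "atc_code\tsmiles\tname\nA01AA01\tCC\tgood\nBADCODE\tCC\tbad\n"
        )
        (tmp_path / "config.yaml").write_text(
            "tables:\n  proteins: proteins.tsv\n  compounds: compounds.tsv\n"
        )
        kb = load_knowledge_base(tmp_path / "config.yaml")
        assert list(kb.compounds) == ["A01AA01"]
        (rej,) = kb.rejections
        assert rej.table == "compounds" and rej.line == 3

    def test_missing_column_is_fatal(self, tmp_path):
        (tmp_path / "proteins.tsv").write_text("uniprot_acc\nP1\n")
        (tmp_path / "config.yaml").write_text("tables:\n  proteins: proteins.tsv\n")
        with pytest.raises(SchemaError, match="gene_symbol"):
            load_knowledge_base(tmp_path / "config.yaml")

    def test_missing_file_is_fatal(self, tmp_path):
        (tmp_path / "config.yaml").write_text("tables:\n  proteins: nowhere.tsv\n")
        with pytest.raises(FileNotFoundError):
            load_knowledge_base(tmp_path / "config.yaml")


class TestEventResolution:
    def test_euadr_codes_resolve_to_canonical_names(self, qt_kb):
        ev = qt_kb.resolve_event("QTPROL")
        assert ev.name == "QT Prolongation"
        assert len(ev.cui_list) == 5

    def test_explicit_cui_list_passes_through(self, qt_kb):
        ev = qt_kb.resolve_event(["C0000001"], name="toy")
        assert ev.cui_list == ("C0000001",)
        assert ev.name == "toy"

    def test_unknown_code_raises(self, qt_kb):
        with pytest.raises(UnmappedEventError):
            qt_kb.resolve_event("XYZ")

    def test_empty_cui_list_raises(self, qt_kb):
        with pytest.raises(UnmappedEventError):
            qt_kb.resolve_event([])


class TestCompoundStructure:
    def test_lookup_returns_stored_smiles_verbatim(self):
        kb = make_kb(compounds=("A01AA01",))
        assert kb.compound_structure("a01aa01") == "C"

    def test_unknown_atc_raises(self, qt_kb):
        with pytest.raises(UnknownIdentifierError):
            qt_kb.compound_structure("Z99ZZ99")

    def test_empty_smiles_raises(self):
        from adrsub.kb import CompoundRecord

        kb = make_kb()
        kb.compounds["A01AA01"] = CompoundRecord("A01AA01", "", "toy")
        with pytest.raises(UnknownIdentifierError, match="unavailable"):
            kb.compound_structure("A01AA01")


class TestTargetProfiles:
    def test_haloperidol_channel_affinities(self, qt_kb):
        tp = qt_kb.drug_target_profile("N05AD01")
        by_gene = {qt_kb.gene_symbol(a): a for a in tp.proteins}
        assert {"KCNH2", "CACNA1C", "KCNH1"} <= set(by_gene)
        assert tp.mean_affinity(by_gene["KCNH2"], "pKi") == pytest.approx(6.99)
        assert tp.mean_affinity(by_gene["KCNH2"], "pIC50") == pytest.approx(6.73)
        assert tp.mean_affinity(by_gene["CACNA1C"], "pKi") == pytest.approx(6.7)
        assert tp.mean_affinity(by_gene["KCNH1"], "pIC50") == pytest.approx(6.2)

    def test_metabolite_only_protein_flagged_and_excludable(self):
        kb = make_kb(
            drug_targets=[("A01AA01", "P1"), ("MET1", "P2")],
            metabolites=[("MET1", "A01AA01", "", "Metabolite 1")],
        )
        with_met = kb.drug_target_profile("A01AA01", include_metabolites=True)
        assert with_met.proteins == {"P1", "P2"}
        assert with_met.via_metabolite == {"P1": False, "P2": True}
        without = kb.drug_target_profile("A01AA01", include_metabolites=False)
        assert without.proteins == {"P1"}

    def test_parent_and_metabolite_evidence_pools_without_flag(self):
        kb = make_kb(
            drug_targets=[("A01AA01", "P1"), ("MET1", "P1")],
            metabolites=[("MET1", "A01AA01", "", "Metabolite 1")],
        )
        tp = kb.drug_target_profile("A01AA01")
        assert tp.via_metabolite["P1"] is False
        assert len(tp.evidence["P1"]) == 2

    def test_drug_without_targets_gives_empty_profile(self):
        kb = make_kb(drug_targets=[], compounds=("A01AA01",))
        assert len(kb.drug_target_profile("A01AA01")) == 0

    def test_unknown_drug_raises(self):
        with pytest.raises(UnknownIdentifierError):
            make_kb().drug_target_profile("Z99ZZ99")

    def test_metabolite_inclusion_never_shrinks_profiles(self, qt_kb):
        for atc in qt_kb.compounds:
            assert len(qt_kb.drug_target_profile(atc, True)) >= len(
                qt_kb.drug_target_profile(atc, False)
            )

    def test_profiles_live_in_protein_universe(self, qt_kb):
        ev = qt_kb.resolve_event("QTPROL")
        universe = qt_kb.protein_universe
        for atc in qt_kb.compounds:
            assert qt_kb.drug_target_profile(atc).proteins <= universe
        assert qt_kb.event_protein_profile(ev).proteins <= universe


class TestEventProfiles:
    def test_union_over_cuis(self):
        rows = [(f"CUI{i}", f"P{i}{j}") for i in (1, 2) for j in (1, 2, 3)]
        kb = make_kb(event_proteins=rows)
        ev = adrsub.EventDefinition("E", "e", ("CUI1", "CUI2"))
        assert len(kb.event_protein_profile(ev)) == 6

    def test_duplicate_rows_collapse_to_one_protein_two_evidences(self):
        kb = make_kb(
            event_proteins=[
                ("CUI1", "P1", "Biomarker", "DisGeNET", "OBSERVATIONAL"),
                ("CUI1", "P1", "GeneticVariation", "OMIM", "OBSERVATIONAL"),
            ]
        )
        ep = kb.event_protein_profile(adrsub.EventDefinition("E", "e", ("CUI1",)))
        assert ep.proteins == {"P1"}
        assert len(ep.evidence["P1"]) == 2

    def test_row_order_never_changes_profiles(self, qt_kb):
        rng = random.Random(3)
        shuffled_dt = list(qt_kb.drug_targets)
        shuffled_ep = list(qt_kb.event_proteins)
        ev = qt_kb.resolve_event("QTPROL")
        for _ in range(5):
            rng.shuffle(shuffled_dt)
            rng.shuffle(shuffled_ep)
            kb2 = KnowledgeBase(
                compounds=qt_kb.compounds,
                metabolites=qt_kb.metabolites,
                proteins=qt_kb.proteins,
                drug_targets=tuple(shuffled_dt),
                event_proteins=tuple(shuffled_ep),
                event_map=qt_kb.event_map,
            )
            for atc in qt_kb.compounds:
                a, b = qt_kb.drug_target_profile(atc), kb2.drug_target_profile(atc)
                assert a.proteins == b.proteins
                for acc in a.proteins:
                    assert sorted(map(repr, a.evidence[acc])) == sorted(map(repr, b.evidence[acc]))
            assert qt_kb.event_protein_profile(ev).proteins == kb2.event_protein_profile(ev).proteins


def test_atc_pattern_accepts_valid_rejects_invalid():
    assert ATC_PATTERN.match("N05AD01")
    for bad in ("N05AD1", "n05ad01", "N05AD011", "12345AA", "N05A D01"):
        assert not ATC_PATTERN.match(bad)
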