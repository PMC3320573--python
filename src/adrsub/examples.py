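"""Bundled worked example: six antipsychotics and QT-interval prolongation.

Antipsychotic drugs differ widely in their risk of prolonging the cardiac
QT interval, a delay of repolarization predisposing to Torsade de Pointes.
The accepted mechanism is blockade of the HERG potassium channel (gene
KCNH2); high-risk drugs additionally bind the L-type calcium channel
Cav1.2 (CACNA1C) and the hEAG1 channel (KCNH1). This module builds a small
knowledge base transcribing the published target affinities of six
antipsychotics (pKi/pIC50, averages over source databases) together with
the event-protein associations of the QTPROL event, cardiac expression
records, bridging pathways, a toy interaction network and a miniature
annotated citation corpus — enough to run every stage of the toolkit end
to end with known expected output:

* sulpiride shares no protein with the event;
* quetiapine, olanzapine and ziprasidone link through KCNH2 only;
* pimozide and haloperidol link through KCNH2, CACNA1C and KCNH1.
"""

from __future__ import annotations

from .filtering import CitationRecord, MeshAnnotation
from .kb import (
    CompoundRecord,
    DatabaseAssociationRecord,
    DrugTargetAssociation,
    EventDefinition,
    EventProteinAssociation,
    ExpressionRecord,
    InteractionEdge,
    KnowledgeBase,
    MetaboliteRecord,
    PathwayAnnotation,
    ProteinRecord,
)

#: ATC codes of the six example drugs, low risk to high risk.
QT_DRUGS = {
    "sulpiride": "N05AL01",
    "quetiapine": "N05AH04",
    "olanzapine": "N05AH03",
    "ziprasidone": "N05AE04",
    "pimozide": "N05AG02",
    "haloperidol": "N05AD01",
}

#: Expected linking-protein gene sets per drug (ground truth of the example).
QT_EXPECTED_LINKING = {
    "N05AL01": frozenset(),
    "N05AH04": frozenset({"KCNH2"}),
    "N05AH03": frozenset({"KCNH2"}),
    "N05AE04": frozenset({"KCNH2"}),
    "N05AG02": frozenset({"KCNH2", "CACNA1C", "KCNH1"}),
    "N05AD01": frozenset({"KCNH2", "CACNA1C", "KCNH1"}),
}

_HEART = ("heart muscle", "cardiomyocytes")

_PROTEINS = [
    ("Q12809", "KCNH2"),
    ("Q13936", "CACNA1C"),
    ("O95259", "KCNH1"),
    ("P35498", "SCN5A"),
    ("P08183", "ABCB1"),
    ("P14416", "DRD2"),
    ("P28223", "HTR2A"),
    ("P35348", "ADRA1A"),
    ("P08588", "ADRB1"),
    ("P63092", "GNAS"),
]

_ACC = {gene: acc for acc, gene in _PROTEINS}

_QT_CUIS = {
    "C0023976": "Long QT Syndrome",
    "C1832916": "Timothy syndrome",
    "C0040479": "Torsades de Pointes",
    "C0035828": "Romano-Ward Syndrome",
    "C0003811": "Cardiac arrhythmia",
}


def _target(compound: str, gene: str, kind: str, value: float, source: str,
            etype: str = "OBSERVATIONAL") -> DrugTargetAssociation:
    return DrugTargetAssociation(compound, _ACC[gene], kind, value, source, etype)


def qt_antipsychotics_kb() -> KnowledgeBase:
    """Knowledge base for the antipsychotics / QT-prolongation example."""
    compounds = {
        "N05AL01": CompoundRecord("N05AL01", "CCN1CCCC1CNC(=O)c1cc(S(N)(=O)=O)ccc1OC", "sulpiride"),
        "N05AH04": CompoundRecord("N05AH04", "OCCOCCN1CCN(CC1)C1=Nc2ccccc2Sc2ccccc12", "quetiapine"),
        "N05AH03": CompoundRecord("N05AH03", "CC1=CC2=C(S1)Nc1ccccc1N=C2N1CCN(C)CC1", "olanzapine"),
        "N05AE04": CompoundRecord("N05AE04", "O=C1Cc2cc(CCN3CCN(CC3)c3nsc4ccccc34)c(Cl)cc2N1", "ziprasidone"),
        "N05AG02": CompoundRecord("N05AG02", "O=C1Nc2ccccc2N1C1CCN(CCCC(c2ccc(F)cc2)c2ccc(F)cc2)CC1", "pimozide"),
        "N05AD01": CompoundRecord("N05AD01", "OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1", "haloperidol"),
    }
    metabolites = {
        "MET-N05AE04-1": MetaboliteRecord("MET-N05AE04-1", "N05AE04", "", "Metabolite 1"),
    }
    proteins = {acc: ProteinRecord(acc, gene) for acc, gene in _PROTEINS}

    drug_targets = (
        # sulpiride: selective D2 antagonist, no channel activity
        _target("N05AL01", "DRD2", "pKi", 7.4, "ChemblDB"),
        # quetiapine
        _target("N05AH04", "KCNH2", "pKi", 5.24, "ChemblDB"),
        _target("N05AH04", "DRD2", "pKi", 6.9, "PDSP"),
        _target("N05AH04", "HTR2A", "pKi", 7.2, "PDSP"),
        # olanzapine
        _target("N05AH03", "KCNH2", "pKi", 4.64, "ChemblDB"),
        _target("N05AH03", "KCNH2", "pIC50", 6.18, "IUPHARdb"),
        _target("N05AH03", "DRD2", "pKi", 7.8, "PDSP"),
        _target("N05AH03", "HTR2A", "pKi", 8.5, "PDSP"),
        # ziprasidone; one metabolite is predicted to bind HERG
        _target("N05AE04", "KCNH2", "pKi", 6.77, "ChemblDB"),
        _target("N05AE04", "KCNH2", "pIC50", 6.36, "BindingDB"),
        _target("N05AE04", "DRD2", "pKi", 8.3, "PDSP"),
        _target("N05AE04", "HTR2A", "pKi", 9.0, "PDSP"),
        _target("MET-N05AE04-1", "KCNH2", "pIC50", 6.4, "in-silico-profiling", "SIMILARITY"),
        # pimozide
        _target("N05AG02", "KCNH2", "pKi", 6.99, "ChemblDB"),
        _target("N05AG02", "KCNH2", "pIC50", 6.73, "BindingDB"),
        _target("N05AG02", "CACNA1C", "pKi", 6.7, "IUPHARdb"),
        _target("N05AG02", "KCNH1", "pIC50", 6.2, "BindingDB"),
        _target("N05AG02", "DRD2", "pKi", 9.2, "PDSP"),
        _target("N05AG02", "ABCB1", "pKi", 6.7, "ChemblDB"),
        # haloperidol
        _target("N05AD01", "KCNH2", "pKi", 6.99, "ChemblDB"),
        _target("N05AD01", "KCNH2", "pIC50", 6.73, "BindingDB"),
        _target("N05AD01", "CACNA1C", "pKi", 6.7, "IUPHARdb"),
        _target("N05AD01", "KCNH1", "pIC50", 6.2, "BindingDB"),
        _target("N05AD01", "DRD2", "pKi", 8.9, "PDSP"),
        _target("N05AD01", "ABCB1", "pKi", 6.7, "ChemblDB"),
        _target("N05AD01", "ADRA1A", "pKi", 7.0, "PDSP"),
    )

    event_proteins = (
        EventProteinAssociation("C0023976", _ACC["KCNH2"], "GeneticVariation",
                                "OMIM", "OBSERVATIONAL", "10973849"),
        EventProteinAssociation("C0040479", _ACC["KCNH2"], "Biomarker",
                                "DisGeNET", "OBSERVATIONAL"),
        EventProteinAssociation("C0035828", _ACC["KCNH2"], "GeneticVariation",
                                "OMIM", "OBSERVATIONAL"),
        EventProteinAssociation("C1832916", _ACC["CACNA1C"], "GeneticVariation",
                                "OMIM", "OBSERVATIONAL", "15454078"),
        EventProteinAssociation(
            "C0003811", _ACC["KCNH1"], "GeneticVariation", "DisGeNET",
            "TEXT-MINING", "17967808",
            "Mutations in the eag channel gene were associated with prolonged "
            "QT interval and cardiac arrhythmia in an animal model.",
        ),
        EventProteinAssociation("C0023976", _ACC["SCN5A"], "GeneticVariation",
                                "OMIM", "OBSERVATIONAL"),
    )

    heart_expressed = ("KCNH2", "CACNA1C", "KCNH1", "SCN5A", "ABCB1", "ADRB1", "GNAS")
    expression = tuple(
        ExpressionRecord(_ACC[g], *_HEART, True) for g in heart_expressed
    ) + (
        ExpressionRecord(_ACC["DRD2"], "brain", "neuronal cells", True),
        ExpressionRecord(_ACC["HTR2A"], "brain", "neuronal cells", True),
        ExpressionRecord(_ACC["ADRA1A"], "brain", "neuronal cells", True),
        # tissue shared with heart proteins but at a different cell type:
        # must NOT satisfy the both-levels co-expression rule
        ExpressionRecord(_ACC["DRD2"], "heart muscle", "fibroblasts", True),
    )

    _pw = [
        ("R-HSA-PW1", "Integration of energy metabolism", ("ABCB1", "GNAS", "SCN5A")),
        ("R-HSA-PW2", "Axon guidance", ("KCNH1", "GNAS")),
        ("R-HSA-PW3", "Synaptic transmission", ("KCNH2", "DRD2", "HTR2A")),
        ("R-HSA-PW4", "Signaling by GPCRs", ("ADRA1A", "ADRB1", "GNAS", "DRD2", "CACNA1C")),
        ("R-HSA-PW5", "Diabetes pathways", ("ABCB1", "KCNH2", "GNAS")),
        ("R-HSA-PW6", "Neuronal System", ("DRD2", "HTR2A", "ADRA1A")),
    ]
    pathways = tuple(
        PathwayAnnotation(pid, name, _ACC[g]) for pid, name, genes in _pw for g in genes
    )

    _edges = [
        ("KCNH2", "SCN5A"), ("KCNH2", "CACNA1C"), ("KCNH2", "KCNH1"),
        ("CACNA1C", "GNAS"), ("GNAS", "ADRB1"), ("ADRB1", "ADRA1A"),
        ("GNAS", "DRD2"), ("DRD2", "HTR2A"), ("ABCB1", "GNAS"),
    ]
    interactions = tuple(InteractionEdge.make(_ACC[a], _ACC[b]) for a, b in _edges)

    event_map = {
        "QTPROL": EventDefinition("QTPROL", "QT Prolongation", tuple(_QT_CUIS)),
    }

    dailymed = (
        DatabaseAssociationRecord("DM-HAL-1", "N05AD01", "C0023976", "adverse_reaction"),
        DatabaseAssociationRecord("DM-HAL-2", "N05AD01", "C0040479", "adverse_reaction"),
        DatabaseAssociationRecord("DM-ZIP-1", "N05AE04", "C0023976", "boxed_warning"),
        DatabaseAssociationRecord("DM-QUE-1", "N05AH04", "C0023976", "adverse_reaction"),
        DatabaseAssociationRecord("DM-OLA-1", "N05AH03", "C0003811", "adverse_reaction"),
        # pimozide's label mentions QT only outside the indexed fields
        DatabaseAssociationRecord("DM-PIM-1", "N05AG02", "C0012236", "adverse_reaction"),
    )
    # drug cards carry no QT-event extraction for any of the six drugs
    drugbank = (
        DatabaseAssociationRecord("DB00502", "N05AD01", "C0013384"),
    )

    return KnowledgeBase(
        compounds=compounds,
        metabolites=metabolites,
        proteins=proteins,
        drug_targets=drug_targets,
        event_proteins=event_proteins,
        expression=expression,
        pathways=pathways,
        interactions=interactions,
        event_map=event_map,
        dailymed=dailymed,
        drugbank=drugbank,
        # The bundled slice carries only the proteins this example touches;
        # a full snapshot would catalogue on the order of 1500 proteins with
        # target or disease annotations, which is the proper Fisher universe.
        universe_size_override=1500,
    )


def qt_example_corpus() -> list[CitationRecord]:
    """Miniature annotated corpus for the haloperidol / QTPROL filters."""
    chem = ("long qt syndrome", ["chemically induced"])
    adv = ("haloperidol", ["adverse effects"])
    adv_class = ("antipsychotic agents", ["adverse effects"])
    return [
        CitationRecord(
            pmid="11001001", year=2001,
            publication_types=("Case Reports",),
            mesh_terms=(MeshAnnotation(*chem), MeshAnnotation(*adv)),
            sentences=(
                "QT prolongation was observed after haloperidol infusion.",
                "The patient recovered after discontinuation.",
            ),
        ),
        CitationRecord(
            pmid="11001002", year=2004,
            publication_types=("Journal Article",),
            # drug lacks the subheading itself; the pharmacological-action
            # expansion member carries it
            mesh_terms=(MeshAnnotation(*chem), MeshAnnotation(*adv_class),
                        MeshAnnotation("haloperidol", ())),
            sentences=(
                "Torsades de pointes occurred during intravenous haloperidol therapy.",
            ),
        ),
        CitationRecord(
            pmid="11001003", year=2004,
            publication_types=("Review",),
            mesh_terms=(MeshAnnotation(*chem), MeshAnnotation(*adv)),
            sentences=(
                "We review antipsychotics and cardiac repolarization.",
                "Haloperidol and QT prolongation are discussed in detail.",
            ),
        ),
        CitationRecord(
            pmid="11001004", year=2007,
            publication_types=("Journal Article",),
            # event subheading alone: conjunction must fail
            mesh_terms=(MeshAnnotation(*chem),),
            sentences=("Drug induced long QT syndrome has many causes.",),
        ),
        CitationRecord(
            pmid="11001005", year=2009,
            publication_types=("Clinical Trial",),
            mesh_terms=(MeshAnnotation("haloperidol", ["therapeutic use"]),),
            sentences=(
                "Haloperidol improved agitation scores.",
                "No QT prolongation was recorded in the treatment arm "
                "receiving haloperidol.",
            ),
        ),
        CitationRecord(
            pmid="11001006", year=2011,
            publication_types=("Journal Article",),
            mesh_terms=(MeshAnnotation("olanzapine", ["adverse effects"]),),
            sentences=("Olanzapine was associated with weight gain.",),
        ),
    ]
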