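import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from adrsub.examples import qt_antipsychotics_kb, qt_example_corpus
from adrsub.kb import (
    CompoundRecord,
    EventDefinition,
    EventProteinAssociation,
    DrugTargetAssociation,
    KnowledgeBase,
    MetaboliteRecord,
    ProteinRecord,
)


@pytest.fixture(scope="session")
def qt_kb():
    return qt_antipsychotics_kb()


@pytest.fixture(scope="session")
def qt_corpus():
    return qt_example_corpus()


def make_kb(
    drug_targets=(),
    event_proteins=(),
    metabolites=(),
    compounds=("A01AA01",),
    universe_size_override=None,
):
    """Minimal in-memory KB builder for targeted unit tests.

    ``drug_targets`` rows are (compound_id, acc) or full tuples; proteins are
    catalogued automatically with gene symbol = accession.
    """
    dt = [
        r if isinstance(r, DrugTargetAssociation) else DrugTargetAssociation(*r)
        for r in drug_targets
    ]
    ep = [
        r if isinstance(r, EventProteinAssociation) else EventProteinAssociation(*r)
        for r in event_proteins
    ]
    mets = {
        m.metabolite_id: m
        for m in (
            r if isinstance(r, MetaboliteRecord) else MetaboliteRecord(*r)
            for r in metabolites
        )
    }
    accs = sorted({r.uniprot_acc for r in dt} | {r.uniprot_acc for r in ep})
    return KnowledgeBase(
        compounds={c: CompoundRecord(c, "C", c.lower()) for c in compounds},
        metabolites=mets,
        proteins={a: ProteinRecord(a, a) for a in accs},
        drug_targets=tuple(dt),
        event_proteins=tuple(ep),
        event_map={
            "EV1": EventDefinition("EV1", "toy event", tuple(sorted({r.cui for r in ep})) or ("CUI1",))
        },
        universe_size_override=universe_size_override,
    )
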