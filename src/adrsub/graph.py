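"""Typed evidence multigraph of a substantiation run and its serializers.

The graph has drug, event and protein nodes (metabolite nodes carry
nodeType ``Drug`` with an ``is_metabolite`` marker) and **one edge per
evidence record**, so parallel edges between two nodes represent different
evidences for the same association. Node attributes are
``{ID, SMILE, styleName, nodeType}`` and edge attributes
``{ID, bindingValue, evidenceLink, evidenceSource, evidenceType,
relationshipType}``; drug-protein and metabolite-protein edges carry
relationshipType ``BINDS``, event-protein edges carry the gene-disease
association type. The primary serialization is XGMML 1.0 for Cytoscape; a
GraphML writer is provided as a convenience.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import networkx as nx
from lxml import etree

from .kb import EventProfile, KnowledgeBase, TargetProfile

XGMML_NS = "http://www.cs.rpi.edu/XGMML"

NODE_ATTRIBUTES = ("ID", "SMILE", "styleName", "nodeType")
EDGE_ATTRIBUTES = (
    "ID",
    "bindingValue",
    "evidenceLink",
    "evidenceSource",
    "evidenceType",
    "relationshipType",
)


def _binding_value(row) -> str:
    if row.affinity_value is None:
        return ""
    return f"{row.affinity_kind} {row.affinity_value:g}"


def build_result_graph(
    kb: KnowledgeBase,
    tp: TargetProfile,
    ep: EventProfile,
    label: Optional[str] = None,
) -> nx.MultiGraph:
    """Assemble the evidence multigraph for one substantiation run.

    Node keys are the domain identifiers (ATC code, metabolite id, concept
    identifier, UniProt accession); each node also receives a sequential
    integer ``id`` in insertion order, emitted separately from the domain
    ``ID`` attribute. An empty run still yields the drug and event nodes.
    """
    g = nx.MultiGraph(label=label or f"{tp.compound_id}-{ep.event.code}")
    counter = 0

    def add_node(key: str, **attrs) -> None:
        nonlocal counter
        if key in g:
            return
        counter += 1
        g.add_node(key, id=counter, **attrs)

    drug = kb.compounds.get(tp.compound_id)
    add_node(
        tp.compound_id,
        ID=tp.compound_id,
        SMILE=drug.smiles if drug else "",
        styleName=drug.name if drug else tp.compound_id,
        nodeType="Drug",
        is_metabolite="false",
    )
    # metabolite nodes, only those contributing evidence rows to the profile
    used_metabolites = sorted(
        {
            row.compound_id
            for rows in tp.evidence.values()
            for row in rows
            if row.compound_id != tp.compound_id
        }
    )
    for mid in used_metabolites:
        met = kb.metabolites.get(mid)
        add_node(
            mid,
            ID=mid,
            SMILE=met.smiles if met else "",
            styleName=met.label if met else mid,
            nodeType="Drug",
            is_metabolite="true",
        )
    for cui in ep.event.cui_list:
        add_node(
            cui,
            ID=cui,
            SMILE="",
            styleName=ep.event.name,
            nodeType="Event",
            is_metabolite="false",
        )
    for acc in sorted(tp.proteins | ep.proteins):
        add_node(
            acc,
            ID=acc,
            SMILE="",
            styleName=kb.gene_symbol(acc) or acc,
            nodeType="Protein",
            is_metabolite="false",
        )

    # one edge per evidence record, deterministic order
    for acc in sorted(tp.proteins):
        for row in tp.evidence[acc]:
            g.add_edge(
                row.compound_id,
                acc,
                ID=f"{row.compound_id}-{acc}",
                bindingValue=_binding_value(row),
                evidenceLink="",
                evidenceSource=row.evidence_source,
                evidenceType=row.evidence_type,
                relationshipType="BINDS",
            )
    for acc in sorted(ep.proteins):
        for row in ep.evidence[acc]:
            g.add_edge(
                row.cui,
                acc,
                ID=f"{row.cui}-{acc}",
                bindingValue="",
                evidenceLink=row.pmid,
                evidenceSource=row.evidence_source,
                evidenceType=row.evidence_type,
                relationshipType=row.association_type,
            )
    return g


# ---------------------------------------------------------------------------
# XGMML
# ---------------------------------------------------------------------------

def write_xgmml(graph: nx.MultiGraph, path: str | Path) -> None:
    """Serialize to a well-formed XGMML 1.0 document with stable ordering:
    identical inputs produce byte-identical files."""
    root = etree.Element(
        "{%s}graph" % XGMML_NS,
        nsmap={None: XGMML_NS},
        label=str(graph.graph.get("label", "result")),
        directed="0",
    )
    node_ids: dict[str, str] = {}
    for key, attrs in sorted(graph.nodes(data=True), key=lambda kv: kv[1]["id"]):
        internal = str(attrs["id"])
        node_ids[key] = internal
        el = etree.SubElement(
            root, "{%s}node" % XGMML_NS, id=internal, label=str(attrs.get("styleName", key))
        )
        for name in NODE_ATTRIBUTES:
            etree.SubElement(
                el,
                "{%s}att" % XGMML_NS,
                name=name,
                value=str(attrs.get(name, "")),
                type="string",
            )
        etree.SubElement(
            el,
            "{%s}att" % XGMML_NS,
            name="is_metabolite",
            value=str(attrs.get("is_metabolite", "false")),
            type="string",
        )
    for i, (u, v, attrs) in enumerate(graph.edges(data=True), start=1):
        el = etree.SubElement(
            root,
            "{%s}edge" % XGMML_NS,
            id=str(i),
            label=str(attrs.get("ID", "")),
            source=node_ids[u],
            target=node_ids[v],
        )
        for name in EDGE_ATTRIBUTES:
            etree.SubElement(
                el,
                "{%s}att" % XGMML_NS,
                name=name,
                value=str(attrs.get(name, "")),
                type="string",
            )
    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_xgmml(path: str | Path) -> nx.MultiGraph:
    """Parse an XGMML file written by :func:`write_xgmml` back into a
    multigraph with the same node keys and attribute multisets."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    g = nx.MultiGraph(label=root.get("label"))
    by_internal: dict[str, str] = {}
    for el in root.findall("{%s}node" % XGMML_NS):
        atts = {
            a.get("name"): a.get("value") for a in el.findall("{%s}att" % XGMML_NS)
        }
        key = atts["ID"]
        by_internal[el.get("id")] = key
        g.add_node(key, id=int(el.get("id")), **atts)
    for el in root.findall("{%s}edge" % XGMML_NS):
        atts = {
            a.get("name"): a.get("value") for a in el.findall("{%s}att" % XGMML_NS)
        }
        g.add_edge(by_internal[el.get("source")], by_internal[el.get("target")], **atts)
    return g


def write_graphml(graph: nx.MultiGraph, path: str | Path) -> None:
    """Convenience GraphML export; attribute names are kept identical to the
    XGMML attribute names."""
    h = nx.MultiGraph()
    for key, attrs in graph.nodes(data=True):
        h.add_node(key, **{k: str(v) for k, v in attrs.items()})
    for u, v, attrs in graph.edges(data=True):
        h.add_edge(u, v, **{k: str(v) for k, v in attrs.items()})
    nx.write_graphml(h, str(path))
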