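"""Synthetic knowledge bases and citation corpora with planted or null structure.

Every analysis stage in this package is exercised against generated data
whose ground truth is known exactly:

* **null mode** — drug-target and event-protein profiles are independent
  uniform draws from the protein universe, the regime in which overlap
  p-values must be (conservatively) calibrated;
* **planted mode** — designated drug-event pairs share exactly
  ``planted_overlap`` reserved proteins; a configurable fraction of planted
  pairs is connected *only* through metabolite rows; planted pathway
  bridges and hub adjacency in the interaction network are wired in on
  request. Reserved-protein construction guarantees the planted linking
  sets exactly (no rejection sampling), and non-reserved drug-side and
  event-side proteins come from disjoint pools so no accidental overlap can
  occur in planted mode.

Generation is fully deterministic given the seed: the same parameters
produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import InvalidArgumentError
from .kb import (
    CompoundRecord,
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

import networkx as nx


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration; defaults give a small but non-trivial KB."""

    n_drugs: int = 20
    n_events: int = 10
    n_proteins: int = 200
    n_pathways: int = 30
    n_tissues: int = 5
    n_celltypes: int = 4
    target_profile_size_range: tuple[int, int] = (4, 8)
    event_profile_size_range: tuple[int, int] = (4, 8)
    n_planted_pairs: int = 10
    planted_overlap: int = 3
    metabolite_only_fraction: float = 0.0
    planted_pathway_bridges: int = 2
    pathway_size: int = 6
    expression_sites_per_protein: int = 2
    corpus_size: int = 1000  # total sentences
    sentences_per_citation: int = 5
    cooccurrence_rate_signal: float = 0.1
    cooccurrence_rate_null: float = 0.0
    mesh_annotation_rate: float = 0.8
    ppi_model: str = "erdos_renyi"  # or "planted_hub"
    ppi_edge_prob: float = 0.05
    null_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_drugs, self.n_events, self.n_proteins) < 1:
            raise InvalidArgumentError("counts must be positive")
        if not (0.0 <= self.metabolite_only_fraction <= 1.0):
            raise InvalidArgumentError("metabolite_only_fraction must be in [0, 1]")
        for rate in (self.cooccurrence_rate_signal, self.cooccurrence_rate_null,
                     self.mesh_annotation_rate):
            if not (0.0 <= rate <= 1.0):
                raise InvalidArgumentError("rates must be in [0, 1]")
        if not self.null_mode:
            if self.n_planted_pairs > min(self.n_drugs, self.n_events):
                raise InvalidArgumentError("more planted pairs than drugs or events")
            lo_t, lo_e = self.target_profile_size_range[0], self.event_profile_size_range[0]
            if self.planted_overlap > min(lo_t, lo_e):
                raise InvalidArgumentError(
                    "planted_overlap exceeds a profile-size minimum"
                )
            reserve = self.n_planted_pairs * self.planted_overlap
            need = reserve + self.target_profile_size_range[1] + self.event_profile_size_range[1]
            if need > self.n_proteins:
                raise InvalidArgumentError(
                    f"universe of {self.n_proteins} proteins too small for the "
                    f"requested planted structure (needs >= {need})"
                )
        if self.ppi_model not in {"erdos_renyi", "planted_hub"}:
            raise InvalidArgumentError(f"unknown ppi_model {self.ppi_model!r}")


@dataclass(frozen=True)
class PairTruth:
    drug_atc: str
    event_code: str
    is_planted: bool
    planted_linking: tuple[str, ...] = ()
    planted_metabolite_only: bool = False
    planted_pathway_ids: tuple[str, ...] = ()
    hub_protein: str = ""


@dataclass
class PlantedTruth:
    pairs: list[PairTruth] = field(default_factory=list)

    def planted(self) -> list[PairTruth]:
        return [p for p in self.pairs if p.is_planted]


def _atc_code(i: int) -> str:
    block, num = divmod(i, 99)
    letter = chr(ord("A") + block % 26)
    return f"{letter}{num + 1:02d}AA{block // 26 + 1:02d}"


def _protein_acc(i: int) -> str:
    return f"SP{i + 1:05d}"


@dataclass
class SynthKB:
    """In-memory synthetic knowledge base plus its planted truth."""

    params: SynthParams
    kb: KnowledgeBase
    truth: PlantedTruth


def generate_kb(params: SynthParams, out_dir: Optional[str | Path] = None) -> SynthKB:
    """Build a synthetic knowledge base; optionally emit it as TSV files.

    When ``out_dir`` is given, the seven association tables, the interaction
    edge list, the event mapping, a ready-to-load ``config.yaml`` and the
    planted-truth TSV are written there, deterministically.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    accs = [_protein_acc(i) for i in range(params.n_proteins)]
    proteins = {a: ProteinRecord(a, f"G{i + 1}") for i, a in enumerate(accs)}

    drugs = [_atc_code(i) for i in range(params.n_drugs)]
    compounds = {
        atc: CompoundRecord(atc, f"C{i + 1}C(=O)O", f"drugname{i + 1}")
        for i, atc in enumerate(drugs)
    }
    events = [f"EV{j + 1:03d}" for j in range(params.n_events)]
    event_map = {
        code: EventDefinition(code, f"eventterm{j + 1}", (f"C{j + 1:07d}",))
        for j, code in enumerate(events)
    }

    lo_t, hi_t = params.target_profile_size_range
    lo_e, hi_e = params.event_profile_size_range

    drug_profiles: dict[str, list[str]] = {}
    event_profiles: dict[str, list[str]] = {}
    truth = PlantedTruth()
    reserved_by_pair: dict[int, list[str]] = {}

    if params.null_mode:
        for atc in drugs:
            size = int(rng.integers(lo_t, hi_t + 1))
            drug_profiles[atc] = sorted(rng.choice(accs, size=size, replace=False))
        for code in events:
            size = int(rng.integers(lo_e, hi_e + 1))
            event_profiles[code] = sorted(rng.choice(accs, size=size, replace=False))
        for atc in drugs:
            for code in events:
                truth.pairs.append(PairTruth(atc, code, is_planted=False))
    else:
        n_reserved = params.n_planted_pairs * params.planted_overlap
        reserve = accs[:n_reserved]
        rest = accs[n_reserved:]
        half = len(rest) // 2
        drug_pool, event_pool = rest[:half], rest[half:]
        for i in range(params.n_planted_pairs):
            reserved_by_pair[i] = reserve[
                i * params.planted_overlap : (i + 1) * params.planted_overlap
            ]
        n_met_only = round(params.metabolite_only_fraction * params.n_planted_pairs)
        for i, atc in enumerate(drugs):
            size = int(rng.integers(lo_t, hi_t + 1))
            if i < params.n_planted_pairs:
                extra = size - params.planted_overlap
                picks = sorted(rng.choice(drug_pool, size=extra, replace=False))
                drug_profiles[atc] = sorted(reserved_by_pair[i] + picks)
            else:
                drug_profiles[atc] = sorted(rng.choice(drug_pool, size=size, replace=False))
        for j, code in enumerate(events):
            size = int(rng.integers(lo_e, hi_e + 1))
            if j < params.n_planted_pairs:
                extra = size - params.planted_overlap
                picks = sorted(rng.choice(event_pool, size=extra, replace=False))
                event_profiles[code] = sorted(reserved_by_pair[j] + picks)
            else:
                event_profiles[code] = sorted(rng.choice(event_pool, size=size, replace=False))
        for i, atc in enumerate(drugs):
            for j, code in enumerate(events):
                if i == j and i < params.n_planted_pairs:
                    truth.pairs.append(
                        PairTruth(
                            atc,
                            code,
                            is_planted=True,
                            planted_linking=tuple(sorted(reserved_by_pair[i])),
                            planted_metabolite_only=i < n_met_only,
                        )
                    )
                else:
                    truth.pairs.append(PairTruth(atc, code, is_planted=False))

    # --- drug-target rows (parent or metabolite-mediated) ------------------
    metabolites: dict[str, MetaboliteRecord] = {}
    drug_targets: list[DrugTargetAssociation] = []
    sources = ("ChemblDB", "DrugBank", "BindingDB", "IUPHARdb")
    met_only_accs: dict[str, set[str]] = {}
    for t in truth.planted():
        if t.planted_metabolite_only:
            met_only_accs[t.drug_atc] = set(t.planted_linking)
    for atc in drugs:
        via_met = met_only_accs.get(atc, set())
        if via_met:
            mid = f"MET-{atc}-1"
            metabolites[mid] = MetaboliteRecord(mid, atc, "", "Metabolite 1")
        for acc in drug_profiles[atc]:
            value = round(float(rng.uniform(4.5, 8.5)), 2)
            source = sources[int(rng.integers(0, len(sources)))]
            if acc in via_met:
                drug_targets.append(
                    DrugTargetAssociation(
                        f"MET-{atc}-1", acc, "pKi", value, source, "SIMILARITY"
                    )
                )
            else:
                drug_targets.append(
                    DrugTargetAssociation(atc, acc, "pKi", value, source, "OBSERVATIONAL")
                )

    # --- event-protein rows ------------------------------------------------
    event_proteins: list[EventProteinAssociation] = []
    for j, code in enumerate(events):
        cui = event_map[code].cui_list[0]
        for acc in event_profiles[code]:
            if rng.random() < 0.3:
                event_proteins.append(
                    EventProteinAssociation(
                        cui, acc, "GeneticVariation", "DisGeNET", "TEXT-MINING",
                        pmid=str(10_000_000 + int(rng.integers(0, 9_000_000))),
                        sentence=f"{proteins[acc].gene_symbol} variants were associated "
                        f"with eventterm{j + 1}.",
                    )
                )
            else:
                event_proteins.append(
                    EventProteinAssociation(
                        cui, acc, "Biomarker", "DisGeNET", "OBSERVATIONAL"
                    )
                )

    # --- expression and pathways -------------------------------------------
    tissues = [f"tissue{t + 1}" for t in range(params.n_tissues)]
    cells = [f"celltype{c + 1}" for c in range(params.n_celltypes)]
    sites = [(t, c) for t in tissues for c in cells]
    expression_keys: set[tuple[str, str, str]] = set()
    expression: list[ExpressionRecord] = []

    def express(acc: str, tissue: str, cell: str) -> None:
        key = (acc, tissue, cell)
        if key not in expression_keys:
            expression_keys.add(key)
            expression.append(ExpressionRecord(acc, tissue, cell, True))

    pathway_rows: list[PathwayAnnotation] = []
    pathway_members: dict[str, set[str]] = {}

    def annotate(pid: str, name: str, acc: str) -> None:
        members = pathway_members.setdefault(pid, set())
        if acc not in members:
            members.add(acc)
            pathway_rows.append(PathwayAnnotation(pid, name, acc))

    if not params.null_mode:
        for i, t in enumerate(truth.planted()):
            tissue, cell = sites[i % len(sites)]
            d_only = [a for a in drug_profiles[t.drug_atc] if a not in t.planted_linking]
            e_only = [a for a in event_profiles[t.event_code] if a not in t.planted_linking]
            pids = []
            for b in range(params.planted_pathway_bridges):
                if not d_only or not e_only:
                    break
                pid = f"PW-PLANT-{i + 1:02d}-{b + 1}"
                dp = d_only[b % len(d_only)]
                ep = e_only[b % len(e_only)]
                annotate(pid, f"Planted bridge pathway {i + 1}.{b + 1}", dp)
                annotate(pid, f"Planted bridge pathway {i + 1}.{b + 1}", ep)
                express(dp, tissue, cell)
                express(ep, tissue, cell)
                pids.append(pid)
            truth.pairs[truth.pairs.index(t)] = replace(t, planted_pathway_ids=tuple(pids))

    for p in range(params.n_pathways):
        pid = f"PW{p + 1:04d}"
        size = min(params.pathway_size, params.n_proteins)
        for acc in sorted(rng.choice(accs, size=size, replace=False)):
            annotate(pid, f"Background pathway {p + 1}", acc)
    if params.expression_sites_per_protein > 0:
        for acc in accs:
            k = min(params.expression_sites_per_protein, len(sites))
            for idx in rng.choice(len(sites), size=k, replace=False):
                express(acc, *sites[int(idx)])

    # --- interaction network -----------------------------------------------
    net_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.gnp_random_graph(params.n_proteins, params.ppi_edge_prob, seed=net_seed)
    edges = {
        InteractionEdge.make(accs[a], accs[b]) for a, b in g.edges if a != b
    }
    if params.ppi_model == "planted_hub" and not params.null_mode:
        for i, t in enumerate(truth.planted()):
            hub = f"HUB{i + 1:03d}"
            proteins[hub] = ProteinRecord(hub, f"HUBG{i + 1}")
            for acc in set(drug_profiles[t.drug_atc]) | set(event_profiles[t.event_code]):
                edges.add(InteractionEdge.make(hub, acc))
            truth.pairs[truth.pairs.index(t)] = replace(
                truth.pairs[truth.pairs.index(t)], hub_protein=hub
            )

    kb = KnowledgeBase(
        compounds=compounds,
        metabolites=metabolites,
        proteins=proteins,
        drug_targets=tuple(drug_targets),
        event_proteins=tuple(event_proteins),
        expression=tuple(expression),
        pathways=tuple(pathway_rows),
        interactions=tuple(sorted(edges, key=lambda e: (e.uniprot_a, e.uniprot_b))),
        event_map=event_map,
    )
    result = SynthKB(params=params, kb=kb, truth=truth)
    if out_dir is not None:
        write_kb_tables(result, Path(out_dir))
    return result


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def write_kb_tables(synth: SynthKB, out_dir: Path) -> dict[str, Path]:
    """Emit all knowledge-base tables, a config.yaml and the truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kb = synth.kb
    paths: dict[str, Path] = {}

    def emit(role: str, header, rows) -> None:
        paths[role] = out_dir / f"{role}.tsv"
        _write_tsv(paths[role], header, rows)

    emit("compounds", ("atc_code", "smiles", "name"),
         [(c.atc_code, c.smiles, c.name) for c in kb.compounds.values()])
    emit("metabolites", ("metabolite_id", "parent_atc", "smiles", "label"),
         [(m.metabolite_id, m.parent_atc, m.smiles, m.label) for m in kb.metabolites.values()])
    emit("proteins", ("uniprot_acc", "gene_symbol"),
         [(p.uniprot_acc, p.gene_symbol) for p in kb.proteins.values()])
    emit("drug_targets",
         ("compound_id", "uniprot_acc", "affinity_kind", "affinity_value",
          "evidence_source", "evidence_type"),
         [(r.compound_id, r.uniprot_acc, r.affinity_kind,
           "" if r.affinity_value is None else f"{r.affinity_value:.2f}",
           r.evidence_source, r.evidence_type) for r in kb.drug_targets])
    emit("event_proteins",
         ("cui", "uniprot_acc", "association_type", "evidence_source",
          "evidence_type", "pmid", "sentence"),
         [(r.cui, r.uniprot_acc, r.association_type, r.evidence_source,
           r.evidence_type, r.pmid, r.sentence) for r in kb.event_proteins])
    emit("expression", ("uniprot_acc", "tissue", "cell_type", "expressed"),
         [(r.uniprot_acc, r.tissue, r.cell_type, str(r.expressed).lower())
          for r in kb.expression])
    emit("pathways", ("pathway_id", "pathway_name", "uniprot_acc"),
         [(r.pathway_id, r.pathway_name, r.uniprot_acc) for r in kb.pathways])
    emit("interactions", ("uniprot_a", "uniprot_b"),
         [(e.uniprot_a, e.uniprot_b) for e in kb.interactions])
    emit("event_map", ("code", "name", "cui"),
         [(ev.code, ev.name, cui) for ev in kb.event_map.values() for cui in ev.cui_list])

    truth_path = out_dir / "truth.tsv"
    _write_tsv(
        truth_path,
        ("drug_atc", "event_code", "is_planted", "planted_linking",
         "planted_metabolite_only", "planted_pathway_ids", "hub_protein"),
        [(t.drug_atc, t.event_code, str(t.is_planted).lower(),
          "|".join(t.planted_linking), str(t.planted_metabolite_only).lower(),
          "|".join(t.planted_pathway_ids), t.hub_protein)
         for t in synth.truth.pairs],
    )
    config = {
        "tables": {role: p.name for role, p in paths.items()},
        "options": {"include_metabolites": True},
    }
    with open(out_dir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    paths["config"] = out_dir / "config.yaml"
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

_FILLER = ("patients", "were", "treated", "and", "observed", "during", "the", "study")


@dataclass(frozen=True)
class CorpusTruth:
    signal_drug_term: str
    signal_event_term: str
    null_drug_term: str
    null_event_term: str
    n_signal_cooccurrences: int
    n_null_cooccurrences: int
    signal_pmids: tuple[str, ...]


def generate_corpus(
    params: SynthParams, out_path: Optional[str | Path] = None
) -> tuple[list[dict], CorpusTruth]:
    """Generate a JSON-lines citation corpus emulating sentence-level
    drug-event co-occurrence and MeSH subheading annotation.

    The signal pair (drug 1, event 1) co-occurs per sentence at
    ``cooccurrence_rate_signal``; the null pair (drug 2, event 2) at
    ``cooccurrence_rate_null``. Citations containing a signal co-occurrence
    also receive the *chemically induced* / *adverse effects* MeSH
    annotations at ``mesh_annotation_rate``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed + 1)
    d_sig, e_sig = "drugname1", "eventterm1"
    d_null, e_null = "drugname2", "eventterm2"
    pub_types = ("Journal Article", "Review", "Case Reports", "Clinical Trial")

    n_cit = max(1, -(-params.corpus_size // params.sentences_per_citation))
    citations: list[dict] = []
    n_sig = n_null = 0
    signal_pmids: list[str] = []
    sentence_budget = params.corpus_size
    for c in range(n_cit):
        n_sent = min(params.sentences_per_citation, sentence_budget)
        sentence_budget -= n_sent
        sentences = []
        has_signal = False
        for _ in range(n_sent):
            words = list(rng.choice(_FILLER, size=4))
            if rng.random() < params.cooccurrence_rate_signal:
                words += [d_sig, "induced", e_sig]
                n_sig += 1
                has_signal = True
            else:
                if rng.random() < 0.05:
                    words.append(d_sig)
                if rng.random() < 0.05:
                    words.append(e_sig)
            if rng.random() < params.cooccurrence_rate_null:
                words += [d_null, "induced", e_null]
                n_null += 1
            sentences.append(" ".join(words) + ".")
        mesh: list[tuple[str, list[str]]] = [("humans", [])]
        if has_signal and rng.random() < params.mesh_annotation_rate:
            mesh.append((e_sig, ["chemically induced"]))
            mesh.append((d_sig, ["adverse effects"]))
        pmid = str(20_000_000 + c)
        if has_signal:
            signal_pmids.append(pmid)
        citations.append(
            {
                "pmid": pmid,
                "year": int(rng.integers(1995, 2013)),
                "publication_types": [pub_types[int(rng.integers(0, len(pub_types)))]],
                "mesh_terms": mesh,
                "sentences": sentences,
            }
        )
    truth = CorpusTruth(
        signal_drug_term=d_sig,
        signal_event_term=e_sig,
        null_drug_term=d_null,
        null_event_term=e_null,
        n_signal_cooccurrences=n_sig,
        n_null_cooccurrences=n_null,
        signal_pmids=tuple(signal_pmids),
    )
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
            for obj in citations:
                fh.write(json.dumps(obj, sort_keys=True) + "\n")
    return citations, truth


# ---------------------------------------------------------------------------
# proximity-study instances
# ---------------------------------------------------------------------------

def sample_proximity_instance(
    n_nodes: int,
    edge_prob: float,
    size_a: int,
    size_b: int,
    planted: bool,
    seed: int,
):
    """One random-graph instance for a network-proximity simulation study.

    Returns (network, set_a, set_b). Under ``planted=True`` both sets are
    wired to a common hub node, so every cross distance is at most 2; under
    ``planted=False`` the sets are uniform random draws (the null).
    """
    from .network import ProteinNetwork

    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(rng.integers(0, 2**31 - 1)))
    names = [f"SP{i + 1:05d}" for i in range(n_nodes)]
    edges = [(names[a], names[b]) for a, b in g.edges]
    draw = rng.choice(names, size=size_a + size_b, replace=False)
    set_a, set_b = set(draw[:size_a]), set(draw[size_a:])
    if planted:
        hub = "HUB0001"
        edges += [(hub, x) for x in sorted(set_a | set_b)]
    # an ER graph can leave a drawn node isolated; the analysis drops it
    net = ProteinNetwork(edges)
    return net, set_a, set_b
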