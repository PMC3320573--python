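"""Knowledge-base data model: typed association tables and protein profiles.

The toolkit operates on a local snapshot of heterogeneous pharmacology
knowledge: a compound catalogue (ATC code, SMILES, name), drug-target
associations with binding affinities, drug metabolites, event-protein
associations (DisGeNET-style, with literature provenance), protein
expression by tissue and cell type (Human-Protein-Atlas-style), pathway
membership (Reactome-style), and an undirected protein-protein interaction
edge list. All tables are plain TSV with a header row; ``#`` comment lines
are ignored.

Two derived objects drive every downstream analysis:

* :class:`TargetProfile` — the set of proteins a drug (and optionally its
  metabolites) binds, with every supporting evidence row retained.
* :class:`EventProfile` — the set of proteins associated with a clinical
  event, defined as a list of concept identifiers (UMLS-CUI-style strings).

Loading is strict about structure (missing columns or unparseable numbers
are fatal) but tolerant about content: rows with malformed ATC codes,
unknown evidence types or dangling protein/compound references are
collected into a rejection report rather than aborting the load, mirroring
how heterogeneous database exports are handled in practice.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import SchemaError, UnknownIdentifierError, UnmappedEventError

logger = logging.getLogger(__name__)

#: 7-character Anatomical Therapeutic Chemical pattern: letter, 2 digits,
#: 2 letters, 2 digits (e.g. N05AD01).
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: EU-ADR project event codes and display names.
EUADR_EVENT_NAMES: Mapping[str, str] = {
    "BE": "Bullous Eruptions",
    "AS": "Anaphylactic Shock",
    "ARF": "Acute Renal Failure",
    "AMI": "Acute Myocardial Infarction",
    "ALI": "Acute Liver Injury",
    "CARDFIB": "Cardiac Valve Fibrosis",
    "UGIB": "Upper gastrointestinal bleeding",
    "RHABD": "Rhabdomyolysis",
    "PANCYTOP": "Aplastic anemia/Pancytopenia",
    "NEUTROP": "Neutropenia/Agranulocytosis",
    "QTPROL": "QT Prolongation",
}

DRUG_EVIDENCE_TYPES = frozenset({"OBSERVATIONAL", "SIMILARITY"})
EVENT_EVIDENCE_TYPES = frozenset({"OBSERVATIONAL", "TEXT-MINING"})
AFFINITY_KINDS = frozenset({"pKi", "pIC50", "none"})


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    atc_code: str
    smiles: str
    name: str


@dataclass(frozen=True)
class MetaboliteRecord:
    metabolite_id: str
    parent_atc: str
    smiles: str
    label: str


@dataclass(frozen=True)
class ProteinRecord:
    uniprot_acc: str
    gene_symbol: str


@dataclass(frozen=True)
class DrugTargetAssociation:
    """One drug-target (or metabolite-target) evidence row.

    ``affinity_value`` is a -log10 molar binding measure (pKi or pIC50);
    ``evidence_type`` distinguishes database-curated rows (OBSERVATIONAL)
    from in-silico target-profiling predictions (SIMILARITY).
    """

    compound_id: str  # ATC code of the parent drug, or a metabolite_id
    uniprot_acc: str
    affinity_kind: str = "none"
    affinity_value: Optional[float] = None
    evidence_source: str = ""
    evidence_type: str = "OBSERVATIONAL"


@dataclass(frozen=True)
class EventProteinAssociation:
    """One event-protein evidence row (gene-disease association style)."""

    cui: str
    uniprot_acc: str
    association_type: str = ""
    evidence_source: str = ""
    evidence_type: str = "OBSERVATIONAL"
    pmid: str = ""
    sentence: str = ""


@dataclass(frozen=True)
class ExpressionRecord:
    uniprot_acc: str
    tissue: str
    cell_type: str
    expressed: bool


@dataclass(frozen=True)
class PathwayAnnotation:
    pathway_id: str
    pathway_name: str
    uniprot_acc: str


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected, unweighted interaction; stored canonically with a < b."""

    uniprot_a: str
    uniprot_b: str

    @staticmethod
    def make(a: str, b: str) -> "InteractionEdge":
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        return InteractionEdge(*sorted((a, b)))


@dataclass(frozen=True)
class EventDefinition:
    """A clinical event: a code/token, display name and its concept identifiers."""

    code: str
    name: str
    cui_list: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.cui_list:
            raise ValueError(f"event {self.code!r} has an empty concept-identifier list")


@dataclass(frozen=True)
class DatabaseAssociationRecord:
    """Pre-extracted drug-label / drug-database association (DailyMed or
    DrugBank style): a record id, the drug's ATC code, the label field the
    event was found in, and the event concept identifier."""

    record_id: str
    atc_code: str
    cui: str
    field: str = ""  # e.g. adverse_reaction / boxed_warning; empty for card-level


@dataclass(frozen=True)
class Rejection:
    """One rejected input row with its provenance."""

    table: str
    line: int
    reason: str


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetProfile:
    """Proteins bound by a drug and (optionally) its metabolites.

    ``via_metabolite[acc]`` is True exactly when no parent-drug row supports
    the protein, i.e. it is reachable only through a metabolite.
    """

    compound_id: str
    proteins: frozenset[str]
    evidence: Mapping[str, tuple[DrugTargetAssociation, ...]]
    via_metabolite: Mapping[str, bool]

    def __len__(self) -> int:
        return len(self.proteins)

    def mean_affinity(self, uniprot_acc: str, affinity_kind: str) -> Optional[float]:
        """Arithmetic mean of the stored affinity values of one kind, a
        derived display value; the raw rows remain the unit of evidence."""
        values = [
            r.affinity_value
            for r in self.evidence.get(uniprot_acc, ())
            if r.affinity_kind == affinity_kind and r.affinity_value is not None
        ]
        return sum(values) / len(values) if values else None


@dataclass(frozen=True)
class EventProfile:
    event: EventDefinition
    proteins: frozenset[str]
    evidence: Mapping[str, tuple[EventProteinAssociation, ...]]

    def __len__(self) -> int:
        return len(self.proteins)


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _read_tsv(path: Path, columns: Sequence[str]) -> Iterable[tuple[int, dict]]:
    """Yield (physical line number, row dict) from a headered TSV.

    Blank lines and '#' comments are skipped. A missing column is a fatal
    :class:`SchemaError`; extra columns are carried through untouched.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        header: Optional[list[str]] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = next(csv.reader(io.StringIO(line), delimiter="\t"))
            if header is None:
                header = fields
                missing = [c for c in columns if c not in header]
                if missing:
                    raise SchemaError(
                        f"{path}: missing required column(s) {missing} in header"
                    )
                continue
            if len(fields) < len(header):
                fields = fields + [""] * (len(header) - len(fields))
            yield lineno, dict(zip(header, fields))
        if header is None:
            raise SchemaError(f"{path}: empty file (no header row)")


def _parse_float(value: str, path: Path, lineno: int, col: str) -> Optional[float]:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise SchemaError(f"{path}:{lineno}: column {col!r}: not a number: {value!r}") from exc


def _parse_bool(value: str, path: Path, lineno: int, col: str) -> bool:
    v = value.strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise SchemaError(f"{path}:{lineno}: column {col!r}: not a boolean: {value!r}")


# ---------------------------------------------------------------------------
# the knowledge base
# ---------------------------------------------------------------------------

@dataclass
class KnowledgeBase:
    """Immutable-by-convention container of all loaded association tables.

    The ``protein_universe`` (the Fisher-test universe N) defaults to the
    union of proteins appearing in the drug-target and event-protein tables;
    ``universe_size_override`` substitutes a fixed integer (for instance a
    human-proteome size) without changing the profiles themselves.
    """

    compounds: Mapping[str, CompoundRecord] = field(default_factory=dict)
    metabolites: Mapping[str, MetaboliteRecord] = field(default_factory=dict)
    proteins: Mapping[str, ProteinRecord] = field(default_factory=dict)
    drug_targets: tuple[DrugTargetAssociation, ...] = ()
    event_proteins: tuple[EventProteinAssociation, ...] = ()
    expression: tuple[ExpressionRecord, ...] = ()
    pathways: tuple[PathwayAnnotation, ...] = ()
    interactions: tuple[InteractionEdge, ...] = ()
    event_map: Mapping[str, EventDefinition] = field(default_factory=dict)
    dailymed: Optional[tuple[DatabaseAssociationRecord, ...]] = None
    drugbank: Optional[tuple[DatabaseAssociationRecord, ...]] = None
    corpus_path: Optional[str] = None
    universe_size_override: Optional[int] = None
    include_metabolites_default: bool = True
    missing_expression: str = "drop"  # or "retain"
    rejections: tuple[Rejection, ...] = ()

    # -- derived ----------------------------------------------------------

    @property
    def protein_universe(self) -> frozenset[str]:
        universe = frozenset(
            [r.uniprot_acc for r in self.drug_targets]
            + [r.uniprot_acc for r in self.event_proteins]
        )
        # with no association rows at all, the catalogue is the universe
        return universe if universe else frozenset(self.proteins)

    @property
    def universe_size(self) -> int:
        if self.universe_size_override is not None:
            return self.universe_size_override
        return len(self.protein_universe)

    def gene_symbol(self, uniprot_acc: str) -> str:
        rec = self.proteins.get(uniprot_acc)
        return rec.gene_symbol if rec else ""

    def _targets_by_compound(self) -> Mapping[str, list[DrugTargetAssociation]]:
        idx: dict[str, list[DrugTargetAssociation]] = {}
        for row in self.drug_targets:
            idx.setdefault(row.compound_id, []).append(row)
        return idx

    def _metabolites_of(self, atc: str) -> list[MetaboliteRecord]:
        return sorted(
            (m for m in self.metabolites.values() if m.parent_atc == atc),
            key=lambda m: m.metabolite_id,
        )

    # -- operations -------------------------------------------------------

    def compound_structure(self, atc: str) -> str:
        """SMILES for an ATC code, verbatim as stored (no canonicalization)."""
        atc = atc.upper()
        rec = self.compounds.get(atc)
        if rec is None:
            raise UnknownIdentifierError(f"unknown ATC code {atc!r}")
        if not rec.smiles:
            raise UnknownIdentifierError(f"structure unavailable for ATC {atc!r}")
        return rec.smiles

    def resolve_event(
        self,
        code_or_cuis: str | Sequence[str],
        name: Optional[str] = None,
    ) -> EventDefinition:
        """Resolve an event token to its concept-identifier list.

        Known event codes resolve through the mapping table (EU-ADR codes
        keep their canonical display names); an explicit identifier list
        passes through unchanged with the user-supplied name.
        """
        if not isinstance(code_or_cuis, str):
            cuis = tuple(code_or_cuis)
            if not cuis:
                raise UnmappedEventError("empty concept-identifier list")
            return EventDefinition(
                code=name or "+".join(cuis), name=name or "+".join(cuis), cui_list=cuis
            )
        code = code_or_cuis
        mapped = self.event_map.get(code)
        if mapped is None:
            raise UnmappedEventError(f"unmapped event {code!r}")
        display = EUADR_EVENT_NAMES.get(code, name or mapped.name or code)
        return EventDefinition(code=code, name=display, cui_list=mapped.cui_list)

    def drug_target_profile(
        self, atc: str, include_metabolites: Optional[bool] = None
    ) -> TargetProfile:
        """Union of parent-drug target rows and, if enabled, all rows of the
        drug's metabolites. A drug with no target rows yields an empty
        profile; an unknown ATC is an error."""
        atc = atc.upper()
        if atc not in self.compounds:
            raise UnknownIdentifierError(f"unknown ATC code {atc!r}")
        if include_metabolites is None:
            include_metabolites = self.include_metabolites_default
        idx = self._targets_by_compound()
        evidence: dict[str, list[DrugTargetAssociation]] = {}
        parent_hit: dict[str, bool] = {}
        for row in idx.get(atc, []):
            evidence.setdefault(row.uniprot_acc, []).append(row)
            parent_hit[row.uniprot_acc] = True
        if include_metabolites:
            for met in self._metabolites_of(atc):
                for row in idx.get(met.metabolite_id, []):
                    evidence.setdefault(row.uniprot_acc, []).append(row)
                    parent_hit.setdefault(row.uniprot_acc, False)
        return TargetProfile(
            compound_id=atc,
            proteins=frozenset(evidence),
            evidence={acc: tuple(rows) for acc, rows in evidence.items()},
            via_metabolite={acc: not hit for acc, hit in parent_hit.items()},
        )

    def event_protein_profile(self, event: EventDefinition) -> EventProfile:
        """Union over the event's concept identifiers of all event-protein
        rows; duplicate rows collapse at the protein level while every
        evidence record is retained."""
        wanted = set(event.cui_list)
        evidence: dict[str, list[EventProteinAssociation]] = {}
        for row in self.event_proteins:
            if row.cui in wanted:
                evidence.setdefault(row.uniprot_acc, []).append(row)
        return EventProfile(
            event=event,
            proteins=frozenset(evidence),
            evidence={acc: tuple(rows) for acc, rows in evidence.items()},
        )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = {
    "compounds": ("atc_code", "smiles", "name"),
    "metabolites": ("metabolite_id", "parent_atc", "smiles", "label"),
    "proteins": ("uniprot_acc", "gene_symbol"),
    "drug_targets": (
        "compound_id",
        "uniprot_acc",
        "affinity_kind",
        "affinity_value",
        "evidence_source",
        "evidence_type",
    ),
    "event_proteins": (
        "cui",
        "uniprot_acc",
        "association_type",
        "evidence_source",
        "evidence_type",
        "pmid",
        "sentence",
    ),
    "expression": ("uniprot_acc", "tissue", "cell_type", "expressed"),
    "pathways": ("pathway_id", "pathway_name", "uniprot_acc"),
    "interactions": ("uniprot_a", "uniprot_b"),
    "event_map": ("code", "name", "cui"),
    "dailymed": ("label_id", "atc_code", "field", "cui"),
    "drugbank": ("card_id", "atc_code", "cui"),
}

#: Tables a knowledge base cannot be built without.
_REQUIRED_TABLES = ("proteins",)


def load_knowledge_base(config: str | Path | Mapping) -> KnowledgeBase:
    """Load and validate a knowledge base from a YAML config or config dict.

    The config maps table roles to file paths under ``tables:`` and carries
    options (``include_metabolites``, ``universe_size_override``,
    ``missing_expression``) under ``options:``. Any configured path that does
    not exist is fatal; rows failing referential or value checks are
    collected into ``kb.rejections`` and logged.
    """
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        with open(cfg_path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        base = cfg_path.parent
    else:
        cfg = dict(config)
        base = Path(cfg.get("base_dir", "."))

    tables_cfg: Mapping[str, str] = cfg.get("tables", {}) or {}
    options: Mapping = cfg.get("options", {}) or {}

    paths: dict[str, Path] = {}
    for role, rel in tables_cfg.items():
        if role not in _TABLE_COLUMNS:
            raise SchemaError(f"unknown table role {role!r} in config")
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"table {role!r}: no such file: {p}")
        paths[role] = p
    for role in _REQUIRED_TABLES:
        if role not in paths:
            raise SchemaError(f"config is missing the required table {role!r}")

    rejections: list[Rejection] = []

    def reject(table: str, line: int, reason: str) -> None:
        rejections.append(Rejection(table, line, reason))

    # protein catalogue first: everything else references it
    proteins: dict[str, ProteinRecord] = {}
    for lineno, row in _read_tsv(paths["proteins"], _TABLE_COLUMNS["proteins"]):
        acc = row["uniprot_acc"].strip()
        if not acc:
            reject("proteins", lineno, "empty uniprot_acc")
            continue
        if acc in proteins:
            reject("proteins", lineno, f"duplicate uniprot_acc {acc!r}")
            continue
        proteins[acc] = ProteinRecord(acc, row["gene_symbol"].strip())

    compounds: dict[str, CompoundRecord] = {}
    if "compounds" in paths:
        for lineno, row in _read_tsv(paths["compounds"], _TABLE_COLUMNS["compounds"]):
            atc = row["atc_code"].strip().upper()
            if not ATC_PATTERN.match(atc):
                reject("compounds", lineno, f"malformed ATC code {row['atc_code']!r}")
                continue
            compounds[atc] = CompoundRecord(atc, row["smiles"].strip(), row["name"].strip())

    metabolites: dict[str, MetaboliteRecord] = {}
    if "metabolites" in paths:
        for lineno, row in _read_tsv(paths["metabolites"], _TABLE_COLUMNS["metabolites"]):
            parent = row["parent_atc"].strip().upper()
            if parent not in compounds:
                reject("metabolites", lineno, f"unknown parent ATC {parent!r}")
                continue
            mid = row["metabolite_id"].strip()
            metabolites[mid] = MetaboliteRecord(mid, parent, row["smiles"].strip(), row["label"].strip())

    drug_targets: list[DrugTargetAssociation] = []
    if "drug_targets" in paths:
        for lineno, row in _read_tsv(paths["drug_targets"], _TABLE_COLUMNS["drug_targets"]):
            cid = row["compound_id"].strip()
            if ATC_PATTERN.match(cid.upper()):
                cid = cid.upper()
                known = cid in compounds
            else:
                known = cid in metabolites
            if not known:
                reject("drug_targets", lineno, f"unknown compound {row['compound_id']!r}")
                continue
            acc = row["uniprot_acc"].strip()
            if acc not in proteins:
                reject("drug_targets", lineno, f"unknown protein {acc!r}")
                continue
            etype = row["evidence_type"].strip()
            if etype not in DRUG_EVIDENCE_TYPES:
                reject("drug_targets", lineno, f"invalid evidence_type {etype!r}")
                continue
            kind = row["affinity_kind"].strip() or "none"
            if kind not in AFFINITY_KINDS:
                reject("drug_targets", lineno, f"invalid affinity_kind {kind!r}")
                continue
            value = _parse_float(row["affinity_value"].strip(), paths["drug_targets"], lineno, "affinity_value")
            if value is not None and kind == "none":
                reject("drug_targets", lineno, "affinity_value given without affinity_kind")
                continue
            if value is not None and not (0.0 < value < 15.0):
                reject("drug_targets", lineno, f"affinity_value {value} outside (0, 15)")
                continue
            drug_targets.append(
                DrugTargetAssociation(cid, acc, kind, value, row["evidence_source"].strip(), etype)
            )

    event_proteins: list[EventProteinAssociation] = []
    if "event_proteins" in paths:
        for lineno, row in _read_tsv(paths["event_proteins"], _TABLE_COLUMNS["event_proteins"]):
            acc = row["uniprot_acc"].strip()
            if acc not in proteins:
                reject("event_proteins", lineno, f"unknown protein {acc!r}")
                continue
            etype = row["evidence_type"].strip()
            if etype not in EVENT_EVIDENCE_TYPES:
                reject("event_proteins", lineno, f"invalid evidence_type {etype!r}")
                continue
            event_proteins.append(
                EventProteinAssociation(
                    row["cui"].strip(),
                    acc,
                    row["association_type"].strip(),
                    row["evidence_source"].strip(),
                    etype,
                    row["pmid"].strip(),
                    row["sentence"],
                )
            )

    expression: list[ExpressionRecord] = []
    if "expression" in paths:
        seen: set[tuple[str, str, str]] = set()
        for lineno, row in _read_tsv(paths["expression"], _TABLE_COLUMNS["expression"]):
            acc = row["uniprot_acc"].strip()
            if acc not in proteins:
                reject("expression", lineno, f"unknown protein {acc!r}")
                continue
            key = (acc, row["tissue"].strip(), row["cell_type"].strip())
            if key in seen:
                reject("expression", lineno, f"duplicate expression key {key!r}")
                continue
            seen.add(key)
            expression.append(
                ExpressionRecord(*key, _parse_bool(row["expressed"], paths["expression"], lineno, "expressed"))
            )

    pathway_rows: list[PathwayAnnotation] = []
    if "pathways" in paths:
        seen_pw: set[tuple[str, str]] = set()
        for lineno, row in _read_tsv(paths["pathways"], _TABLE_COLUMNS["pathways"]):
            acc = row["uniprot_acc"].strip()
            if acc not in proteins:
                reject("pathways", lineno, f"unknown protein {acc!r}")
                continue
            key = (row["pathway_id"].strip(), acc)
            if key in seen_pw:
                reject("pathways", lineno, f"duplicate pathway membership {key!r}")
                continue
            seen_pw.add(key)
            pathway_rows.append(PathwayAnnotation(key[0], row["pathway_name"].strip(), acc))

    interactions: list[InteractionEdge] = []
    if "interactions" in paths:
        seen_edges: set[tuple[str, str]] = set()
        for lineno, row in _read_tsv(paths["interactions"], _TABLE_COLUMNS["interactions"]):
            a, b = row["uniprot_a"].strip(), row["uniprot_b"].strip()
            if a == b:
                reject("interactions", lineno, f"self-loop on {a!r}")
                continue
            edge = InteractionEdge.make(a, b)
            key = (edge.uniprot_a, edge.uniprot_b)
            if key in seen_edges:
                continue  # duplicate undirected edge: silently collapse
            seen_edges.add(key)
            interactions.append(edge)

    event_map: dict[str, EventDefinition] = {}
    if "event_map" in paths:
        cuis_by_code: dict[str, list[str]] = {}
        name_by_code: dict[str, str] = {}
        for lineno, row in _read_tsv(paths["event_map"], _TABLE_COLUMNS["event_map"]):
            code = row["code"].strip()
            cui = row["cui"].strip()
            if not code or not cui:
                reject("event_map", lineno, "empty code or cui")
                continue
            cuis_by_code.setdefault(code, [])
            if cui not in cuis_by_code[code]:
                cuis_by_code[code].append(cui)
            if row["name"].strip():
                name_by_code.setdefault(code, row["name"].strip())
        for code, cuis in cuis_by_code.items():
            name = EUADR_EVENT_NAMES.get(code, name_by_code.get(code, code))
            event_map[code] = EventDefinition(code, name, tuple(cuis))

    def _load_db(role: str, id_col: str, has_field: bool) -> Optional[tuple[DatabaseAssociationRecord, ...]]:
        if role not in paths:
            return None
        out = []
        for lineno, row in _read_tsv(paths[role], _TABLE_COLUMNS[role]):
            atc = row["atc_code"].strip().upper()
            if not ATC_PATTERN.match(atc):
                reject(role, lineno, f"malformed ATC code {row['atc_code']!r}")
                continue
            out.append(
                DatabaseAssociationRecord(
                    row[id_col].strip(), atc, row["cui"].strip(),
                    row["field"].strip() if has_field else "",
                )
            )
        return tuple(out)

    kb = KnowledgeBase(
        compounds=compounds,
        metabolites=metabolites,
        proteins=proteins,
        drug_targets=tuple(drug_targets),
        event_proteins=tuple(event_proteins),
        expression=tuple(expression),
        pathways=tuple(pathway_rows),
        interactions=tuple(interactions),
        event_map=event_map,
        dailymed=_load_db("dailymed", "label_id", True),
        drugbank=_load_db("drugbank", "card_id", False),
        corpus_path=str(cfg["corpus"]) if cfg.get("corpus") else None,
        universe_size_override=options.get("universe_size_override"),
        include_metabolites_default=bool(options.get("include_metabolites", True)),
        missing_expression=options.get("missing_expression", "drop"),
        rejections=tuple(rejections),
    )
    for role in sorted(paths):
        n = {
            "compounds": len(compounds), "metabolites": len(metabolites),
            "proteins": len(proteins), "drug_targets": len(drug_targets),
            "event_proteins": len(event_proteins), "expression": len(expression),
            "pathways": len(pathway_rows), "interactions": len(interactions),
            "event_map": len(event_map),
            "dailymed": len(kb.dailymed or ()), "drugbank": len(kb.drugbank or ()),
        }.get(role, 0)
        logger.info("loaded %s: %d rows", role, n)
    if rejections:
        logger.warning("rejected %d rows during load", len(rejections))
        for r in rejections:
            logger.warning("  %s line %d: %s", r.table, r.line, r.reason)
    return kb
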