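"""Signal filtering: has a drug-event pair already been reported?

Two complementary literature routes plus two database routes are provided
over a local, pre-annotated citation corpus and pre-extracted association
tables:

* **MeSH route** — a citation supports the pair iff some event descriptor
  carries the subheading *chemically induced* AND some drug descriptor (the
  drug itself or any member of its pharmacological-action expansion) carries
  the subheading *adverse effects*. Concept recognition happened upstream;
  here matching is plain descriptor/subheading lookup.
* **Sentence route** — abstracts were split into sentences upstream; we
  count sentence-level co-occurrence of drug and event terms into a 2x2
  table and test independence with a 1-df chi-square (no continuity
  correction).
* **Database routes** — DailyMed-style label extractions (adverse-reaction
  and boxed-warning fields) and DrugBank-style card extractions are scanned
  for records linking the ATC code to any of the event's concept
  identifiers. An absent source table is reported as not available (NA)
  rather than as zero matches.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .errors import InvalidArgumentError
from .kb import DatabaseAssociationRecord, EventDefinition, KnowledgeBase

MESH_CHEM_INDUCED = "chemically induced"
MESH_ADVERSE_EFFECTS = "adverse effects"


@dataclass(frozen=True)
class MeshAnnotation:
    descriptor: str
    subheadings: tuple[str, ...] = ()


@dataclass(frozen=True)
class CitationRecord:
    pmid: str
    year: int
    publication_types: tuple[str, ...] = ()
    mesh_terms: tuple[MeshAnnotation, ...] = ()
    sentences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (1800 <= self.year <= 2100):
            raise ValueError(f"citation {self.pmid}: implausible year {self.year}")


def load_corpus(path: str | Path) -> list[CitationRecord]:
    """Read a JSON-lines corpus, one citation object per line."""
    out: list[CitationRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            obj = json.loads(line)
            pmid = str(obj["pmid"])
            if pmid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pmid {pmid}")
            seen.add(pmid)
            out.append(
                CitationRecord(
                    pmid=pmid,
                    year=int(obj["year"]),
                    publication_types=tuple(obj.get("publication_types", ())),
                    mesh_terms=tuple(
                        MeshAnnotation(d, tuple(subs))
                        for d, subs in obj.get("mesh_terms", ())
                    ),
                    sentences=tuple(obj.get("sentences", ())),
                )
            )
    return out


@dataclass(frozen=True)
class CooccurrenceTable:
    """Sentence-level 2x2 contingency counts for one drug-event pair."""

    n11: int  # sentences mentioning both drug and event
    n10: int  # drug only
    n01: int  # event only
    n00: int  # neither

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: Optional[float]
    p_value: Optional[float]
    testable: bool

    NOT_TESTABLE_REASON = "a table margin is zero"


@dataclass
class FilterReport:
    """Outcome of one filtering source for one drug-event pair."""

    source: str  # MESH, MEDLINE-SENTENCE, DAILYMED or DRUGBANK
    available: bool = True
    matched_ids: list[str] = field(default_factory=list)
    per_year: Counter = field(default_factory=Counter)
    by_publication_type: dict[str, list[str]] = field(default_factory=dict)
    cooccurrence: Optional[CooccurrenceTable] = None
    statistic: Optional[float] = None
    p_value: Optional[float] = None

    @property
    def n_matched(self) -> Optional[int]:
        return len(self.matched_ids) if self.available else None

    @classmethod
    def not_available(cls, source: str) -> "FilterReport":
        return cls(source=source, available=False)


# ---------------------------------------------------------------------------
# MeSH route
# ---------------------------------------------------------------------------

def mesh_filter(
    corpus: Iterable[CitationRecord],
    drug_descriptors: set[str],
    pharm_action_expansion: set[str],
    event_descriptors: set[str],
) -> FilterReport:
    """Subheading-based retrieval of citations discussing the pair.

    Both conditions must hold in the same citation (conjunction): the event
    descriptor annotated with *chemically induced*, and the drug descriptor
    or a pharmacological-action sibling annotated with *adverse effects*.
    """
    if not drug_descriptors or not event_descriptors:
        raise InvalidArgumentError("descriptor sets must be non-empty")
    drug_side = {d.lower() for d in drug_descriptors | pharm_action_expansion}
    event_side = {d.lower() for d in event_descriptors}

    report = FilterReport(source="MESH")
    for cit in corpus:
        event_ok = drug_ok = False
        for ann in cit.mesh_terms:
            desc = ann.descriptor.lower()
            subs = {s.lower() for s in ann.subheadings}
            if desc in event_side and MESH_CHEM_INDUCED in subs:
                event_ok = True
            if desc in drug_side and MESH_ADVERSE_EFFECTS in subs:
                drug_ok = True
        if event_ok and drug_ok:
            report.matched_ids.append(cit.pmid)
            report.per_year[cit.year] += 1
            for pt in cit.publication_types or ("Unclassified",):
                report.by_publication_type.setdefault(pt, []).append(cit.pmid)
    return report


# ---------------------------------------------------------------------------
# sentence route
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _tokens(text: str) -> tuple[str, ...]:
    return tuple(_TOKEN_RE.findall(text.lower()))


def _contains_term(sentence_tokens: tuple[str, ...], term_tokens: tuple[str, ...]) -> bool:
    """Whole-token (possibly multi-token) containment."""
    k = len(term_tokens)
    if k == 0 or k > len(sentence_tokens):
        return False
    return any(
        sentence_tokens[i : i + k] == term_tokens
        for i in range(len(sentence_tokens) - k + 1)
    )


def sentence_cooccurrence(
    corpus: Iterable[CitationRecord],
    drug_terms: set[str],
    event_terms: set[str],
) -> CooccurrenceTable:
    """Count every sentence in the corpus into exactly one 2x2 cell.

    Matching is case-insensitive whole-token matching; multi-word terms must
    appear as a contiguous token run.
    """
    if not drug_terms or not event_terms:
        raise InvalidArgumentError("term sets must be non-empty")
    dterms = [_tokens(t) for t in drug_terms]
    eterms = [_tokens(t) for t in event_terms]
    n11 = n10 = n01 = n00 = 0
    for cit in corpus:
        for sentence in cit.sentences:
            toks = _tokens(sentence)
            d = any(_contains_term(toks, t) for t in dterms)
            e = any(_contains_term(toks, t) for t in eterms)
            if d and e:
                n11 += 1
            elif d:
                n10 += 1
            elif e:
                n01 += 1
            else:
                n00 += 1
    return CooccurrenceTable(n11, n10, n01, n00)


def chi_square(table: CooccurrenceTable) -> ChiSquareResult:
    """1-df chi-square of independence, closed margin form, no continuity
    correction; two-sided p from the chi-square distribution.

    With a zero row or column margin the statistic is undefined and a
    not-testable result is returned.
    """
    n11, n10, n01, n00 = table.n11, table.n10, table.n01, table.n00
    if min(n11, n10, n01, n00) < 0:
        raise InvalidArgumentError("negative cell count")
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    if min(r1, r0, c1, c0) == 0:
        return ChiSquareResult(None, None, testable=False)
    n = table.total
    stat = n * (n11 * n00 - n10 * n01) ** 2 / (r1 * r0 * c1 * c0)
    p = float(stats.chi2.sf(stat, df=1))
    return ChiSquareResult(float(stat), p, testable=True)


def sentence_filter(
    corpus: Iterable[CitationRecord],
    drug_terms: set[str],
    event_terms: set[str],
) -> FilterReport:
    """Sentence-co-occurrence report: matched citations (those with at least
    one co-occurring sentence), counts table and chi-square."""
    corpus = list(corpus)
    table = sentence_cooccurrence(corpus, drug_terms, event_terms)
    chi = chi_square(table)
    report = FilterReport(
        source="MEDLINE-SENTENCE",
        cooccurrence=table,
        statistic=chi.statistic,
        p_value=chi.p_value,
    )
    dterms = [_tokens(t) for t in drug_terms]
    eterms = [_tokens(t) for t in event_terms]
    for cit in corpus:
        hit = False
        for sentence in cit.sentences:
            toks = _tokens(sentence)
            if any(_contains_term(toks, t) for t in dterms) and any(
                _contains_term(toks, t) for t in eterms
            ):
                hit = True
                break
        if hit:
            report.matched_ids.append(cit.pmid)
            report.per_year[cit.year] += 1
            for pt in cit.publication_types or ("Unclassified",):
                report.by_publication_type.setdefault(pt, []).append(cit.pmid)
    return report


# ---------------------------------------------------------------------------
# database routes
# ---------------------------------------------------------------------------

def _db_report(
    source: str,
    records: Optional[Sequence[DatabaseAssociationRecord]],
    atc: str,
    cuis: set[str],
) -> FilterReport:
    if records is None:
        return FilterReport.not_available(source)
    report = FilterReport(source=source)
    for rec in records:
        if rec.atc_code == atc and rec.cui in cuis:
            report.matched_ids.append(rec.record_id)
    return report


def database_filter(
    kb: KnowledgeBase, drug_atc: str, event: EventDefinition
) -> Mapping[str, FilterReport]:
    """Scan the pre-extracted label/database tables for records linking the
    ATC code to any of the event's concept identifiers. Both the
    adverse-reaction and boxed-warning label fields are indexed; a source
    whose table is absent is reported NA."""
    atc = drug_atc.upper()
    cuis = set(event.cui_list)
    return {
        "DAILYMED": _db_report("DAILYMED", kb.dailymed, atc, cuis),
        "DRUGBANK": _db_report("DRUGBANK", kb.drugbank, atc, cuis),
    }
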