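"""Substantiation through pathways.

A drug and a clinical event can be connected indirectly: a protein targeted
by the drug and a protein associated with the event may participate in the
same biological pathway. Because canonical pathway annotations are
context-free, profiles are first restricted to proteins co-expressed with a
partner from the opposite profile in at least one shared (tissue, cell type)
combination — expression must agree at both levels, tissue alone is not
enough. Pathways containing at least one retained drug protein and one
retained event protein then count as connecting pathways.

The batch significance of a connecting-pathway count is assessed by a
permutation test: random protein sets of the same sizes are drawn from the
knowledge-base universe and pushed through the identical filter-and-bridge
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError
from .kb import EventProfile, KnowledgeBase, TargetProfile

#: A co-expression witness: the (tissue, cell_type) shared with a partner
#: protein from the opposite profile.
Witness = tuple[str, str, str]  # (tissue, cell_type, partner accession)


@dataclass(frozen=True)
class CoexpressionSet:
    """Profiles after the tissue/cell-type co-expression filter.

    Every retained protein carries at least one witness triple, except
    proteins retained under the ``missing_expression='retain'`` policy,
    which have no expression rows at all and hence no witness.
    """

    retained_drug_proteins: frozenset[str]
    retained_event_proteins: frozenset[str]
    witnesses: Mapping[str, tuple[Witness, ...]]


@dataclass(frozen=True)
class ConnectingPathway:
    """A pathway bridging the two retained profiles."""

    pathway_id: str
    pathway_name: str
    drug_proteins: frozenset[str]
    event_proteins: frozenset[str]

    def __post_init__(self) -> None:
        if not self.drug_proteins or not self.event_proteins:
            raise ValueError(f"{self.pathway_id}: both member sets must be non-empty")


def _expression_index(kb: KnowledgeBase) -> Mapping[str, frozenset[tuple[str, str]]]:
    idx: dict[str, set[tuple[str, str]]] = {}
    for row in kb.expression:
        if row.expressed:
            idx.setdefault(row.uniprot_acc, set()).add((row.tissue, row.cell_type))
    return {acc: frozenset(sites) for acc, sites in idx.items()}


def _has_expression_rows(kb: KnowledgeBase) -> frozenset[str]:
    return frozenset(row.uniprot_acc for row in kb.expression)


def coexpression_filter(
    tp: TargetProfile | frozenset[str] | set[str],
    ep: EventProfile | frozenset[str] | set[str],
    kb: KnowledgeBase,
    missing_expression: Optional[str] = None,
) -> CoexpressionSet:
    """Keep proteins that share expression at both levels (tissue AND cell
    type) with at least one protein from the opposite profile.

    ``missing_expression`` policy for proteins with no expression rows:
    ``'drop'`` (default) treats them as not expressed; ``'retain'`` keeps
    them without a witness, for knowledge bases with patchy expression
    coverage.
    """
    drug_set = tp.proteins if isinstance(tp, TargetProfile) else frozenset(tp)
    event_set = ep.proteins if isinstance(ep, EventProfile) else frozenset(ep)
    policy = missing_expression or kb.missing_expression
    if policy not in {"drop", "retain"}:
        raise InvalidArgumentError(f"unknown missing_expression policy {policy!r}")

    expr = _expression_index(kb)
    covered = _has_expression_rows(kb)

    witnesses: dict[str, list[Witness]] = {}
    retained_drug: set[str] = set()
    retained_event: set[str] = set()

    for d in sorted(drug_set):
        d_sites = expr.get(d, frozenset())
        for e in sorted(event_set):
            # a protein sitting in both profiles trivially co-expresses with itself
            shared = d_sites if e == d else d_sites & expr.get(e, frozenset())
            for tissue, cell in sorted(shared):
                retained_drug.add(d)
                retained_event.add(e)
                witnesses.setdefault(d, []).append((tissue, cell, e))
                witnesses.setdefault(e, []).append((tissue, cell, d))

    if policy == "retain":
        for d in drug_set:
            if d not in covered:
                retained_drug.add(d)
        for e in event_set:
            if e not in covered:
                retained_event.add(e)

    return CoexpressionSet(
        retained_drug_proteins=frozenset(retained_drug),
        retained_event_proteins=frozenset(retained_event),
        witnesses={acc: tuple(dict.fromkeys(w)) for acc, w in witnesses.items()},
    )


def connecting_pathways(
    coexp: CoexpressionSet, kb: KnowledgeBase
) -> list[ConnectingPathway]:
    """Pathways whose membership intersects both retained sets, ordered by
    pathway id. A protein present in both profiles may serve both roles."""
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in kb.pathways:
        members.setdefault(row.pathway_id, set()).add(row.uniprot_acc)
        names.setdefault(row.pathway_id, row.pathway_name)
    out: list[ConnectingPathway] = []
    for pid in sorted(members):
        dp = members[pid] & coexp.retained_drug_proteins
        epr = members[pid] & coexp.retained_event_proteins
        if dp and epr:
            out.append(
                ConnectingPathway(
                    pathway_id=pid,
                    pathway_name=names[pid],
                    drug_proteins=frozenset(dp),
                    event_proteins=frozenset(epr),
                )
            )
    return out


@dataclass(frozen=True)
class PathwayPermutationResult:
    observed_count: int
    p_value: float
    n_replicates: int
    null_counts: tuple[int, ...]


def pathway_connection_pvalue(
    kb: KnowledgeBase,
    observed_count: int,
    tp_size: int,
    ep_size: int,
    n_replicates: int = 1000,
    seed: Optional[int] = None,
    missing_expression: Optional[str] = None,
) -> PathwayPermutationResult:
    """Permutation p-value for a connecting-pathway count.

    Each replicate draws uniform random protein sets of the two profile
    sizes from the knowledge-base universe and reruns the co-expression
    filter and pathway bridging; p = (1 + #{replicate count >= observed})
    / (R + 1). Seeded and reproducible.
    """
    if n_replicates < 100:
        raise InvalidArgumentError("need at least 100 permutation replicates")
    universe = sorted(kb.protein_universe)
    if tp_size > len(universe) or ep_size > len(universe):
        raise InvalidArgumentError(
            f"universe of {len(universe)} proteins cannot supply profile sizes "
            f"{tp_size} and {ep_size}"
        )
    rng = np.random.default_rng(seed)
    null_counts: list[int] = []
    for _ in range(n_replicates):
        fake_tp = frozenset(rng.choice(universe, size=tp_size, replace=False))
        fake_ep = frozenset(rng.choice(universe, size=ep_size, replace=False))
        coexp = coexpression_filter(fake_tp, fake_ep, kb, missing_expression)
        null_counts.append(len(connecting_pathways(coexp, kb)))
    exceed = sum(c >= observed_count for c in null_counts)
    return PathwayPermutationResult(
        observed_count=observed_count,
        p_value=(1 + exceed) / (n_replicates + 1),
        n_replicates=n_replicates,
        null_counts=tuple(null_counts),
    )
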