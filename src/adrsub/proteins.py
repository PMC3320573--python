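"""Substantiation through proteins.

The mechanistic question: do the drug's target profile and the event's
protein profile share more proteins than expected by chance? The overlap is
scored with a one-sided Fisher exact test — equivalently the hypergeometric
tail P(X >= k) for k shared proteins when m drug proteins are drawn from a
universe of N containing the n event proteins — and batches of drug-event
pairs are corrected with Benjamini-Hochberg step-up FDR.

Shared proteins reachable only through a drug metabolite are flagged
``via_metabolite``; metabolite targets are pooled into the drug profile
before testing, so altered-metabolism mechanisms contribute to the same
overlap statistic while remaining attributable per protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import AdrError, InvalidArgumentError
from .kb import (
    DrugTargetAssociation,
    EventDefinition,
    EventProfile,
    EventProteinAssociation,
    KnowledgeBase,
    TargetProfile,
)


@dataclass(frozen=True)
class LinkingProtein:
    """A protein present in both profiles, carrying both evidence lists."""

    uniprot_acc: str
    gene_symbol: str
    drug_evidence: tuple[DrugTargetAssociation, ...]
    event_evidence: tuple[EventProteinAssociation, ...]
    via_metabolite: bool

    def __post_init__(self) -> None:
        if not self.drug_evidence or not self.event_evidence:
            raise ValueError(f"{self.uniprot_acc}: a linking protein needs evidence on both sides")


@dataclass(frozen=True)
class SubstantiationResult:
    """Overlap result for one drug-event pair.

    ``q_value`` is None until the pair is adjusted within a batch.
    ``metabolite_only`` is True iff every linking protein is reachable only
    via a metabolite (and there is at least one linking protein).
    """

    drug_atc: str
    event: EventDefinition
    linking: tuple[LinkingProtein, ...]
    k: int
    m: int
    n: int
    N: int
    p_value: float
    q_value: Optional[float] = None

    @property
    def metabolite_only(self) -> bool:
        return bool(self.linking) and all(lp.via_metabolite for lp in self.linking)

    @property
    def metabolite_involved(self) -> bool:
        return any(lp.via_metabolite for lp in self.linking)


def overlap_pvalue(k: int, m: int, n: int, N: int) -> float:
    """One-sided (enrichment) Fisher exact p-value for an overlap of k
    between set sizes m and n drawn from a universe of N.

    Exact hypergeometric tail P(X >= k), computed in log space; no normal
    approximation. Symmetric in (m, n); p = 1 when k = 0 or when the
    overlap is forced (m = N or n = N with k at its minimum).
    """
    for name, v in (("k", k), ("m", m), ("n", n), ("N", N)):
        if int(v) != v:
            raise InvalidArgumentError(f"{name} must be an integer, got {v!r}")
    k, m, n, N = int(k), int(m), int(n), int(N)
    if N < 1:
        raise InvalidArgumentError("universe size N must be >= 1")
    if not (0 <= k <= min(m, n) <= N) or m > N or n > N:
        raise InvalidArgumentError(f"invalid overlap arguments k={k} m={m} n={n} N={N}")
    if k == 0:
        return 1.0
    # X ~ Hypergeometric(N, n, m): number of event proteins among m draws
    return float(stats.hypergeom.sf(k - 1, N, n, m))


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1, returned
    in input order. Guarantees q >= p element-wise and monotonicity along
    the sorted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    mtot = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * mtot / np.arange(1, mtot + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(mtot)
    q[order] = q_sorted
    return q.tolist()


def linking_proteins(tp: TargetProfile, ep: EventProfile, kb: KnowledgeBase) -> list[LinkingProtein]:
    """Intersection of the two profiles, each protein carrying both evidence
    lists, ordered deterministically by accession."""
    return [
        LinkingProtein(
            uniprot_acc=acc,
            gene_symbol=kb.gene_symbol(acc),
            drug_evidence=tp.evidence[acc],
            event_evidence=ep.evidence[acc],
            via_metabolite=tp.via_metabolite.get(acc, False),
        )
        for acc in sorted(tp.proteins & ep.proteins)
    ]


def substantiate_pair(
    kb: KnowledgeBase,
    drug_atc: str,
    event: EventDefinition | str,
    include_metabolites: Optional[bool] = None,
) -> SubstantiationResult:
    """Profile both sides, intersect, and score the overlap against the
    knowledge base's protein universe. The q-value is left unadjusted; use
    :func:`substantiate_batch` for FDR across many pairs."""
    if isinstance(event, str):
        event = kb.resolve_event(event)
    tp = kb.drug_target_profile(drug_atc, include_metabolites)
    ep = kb.event_protein_profile(event)
    N = kb.universe_size
    if N < 1:
        raise AdrError("empty protein universe: no associations loaded")
    linking = linking_proteins(tp, ep, kb)
    k, m, n = len(linking), len(tp), len(ep)
    if max(m, n) > N:
        raise AdrError(
            f"universe override N={N} smaller than a profile (m={m}, n={n})"
        )
    return SubstantiationResult(
        drug_atc=tp.compound_id,
        event=event,
        linking=tuple(linking),
        k=k,
        m=m,
        n=n,
        N=N,
        p_value=overlap_pvalue(k, m, n, N),
    )


@dataclass(frozen=True)
class BatchSummary:
    n_pairs: int
    n_connected: int  # >= 1 linking protein
    n_p_le_alpha: int
    n_q_le_alpha: int
    n_metabolite_only: int
    alpha: float

    @property
    def metabolite_only_fraction(self) -> Optional[float]:
        """Among connected pairs, the fraction linked only through metabolites."""
        return self.n_metabolite_only / self.n_connected if self.n_connected else None


@dataclass(frozen=True)
class BatchResult:
    results: tuple[SubstantiationResult, ...]
    summary: BatchSummary


def substantiate_batch(
    kb: KnowledgeBase,
    pairs: Sequence[tuple[str, EventDefinition | str]],
    alpha: float = 0.01,
    include_metabolites: Optional[bool] = None,
) -> BatchResult:
    """Score every pair and apply BH-FDR across the whole batch."""
    if not pairs:
        raise InvalidArgumentError("empty batch")
    raw = [substantiate_pair(kb, d, e, include_metabolites) for d, e in pairs]
    qvals = fdr_adjust([r.p_value for r in raw])
    results = tuple(
        SubstantiationResult(
            r.drug_atc, r.event, r.linking, r.k, r.m, r.n, r.N, r.p_value, q
        )
        for r, q in zip(raw, qvals)
    )
    connected = [r for r in results if r.k > 0]
    summary = BatchSummary(
        n_pairs=len(results),
        n_connected=len(connected),
        n_p_le_alpha=sum(r.p_value <= alpha for r in results),
        n_q_le_alpha=sum(r.q_value <= alpha for r in results),
        n_metabolite_only=sum(r.metabolite_only for r in connected),
        alpha=alpha,
    )
    return BatchResult(results=results, summary=summary)
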