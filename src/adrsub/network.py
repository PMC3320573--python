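"""Network proximity between drug-target and event-protein sets.

If a drug elicits an event mechanistically, its targets should sit close to
the event-associated proteins in a protein-protein interaction network. We
measure the average shortest-path length (in hops) over all cross pairs of
the two sets and compare it against the averages obtained for randomly
chosen protein-set pairs of the same sizes: a one-sample, one-sided t-test
asks whether the random ensemble mean exceeds the observed mean, and an
empirical permutation p-value is reported alongside.

The interaction network is undirected and unweighted, so shortest paths
reduce to breadth-first search; the interface accepts per-edge weights
should a weighted snapshot ever be supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .errors import AdrError, InvalidArgumentError
from .kb import InteractionEdge, KnowledgeBase

logger = logging.getLogger(__name__)


class ProteinNetwork:
    """Simple undirected protein interaction graph (no self-loops, no
    parallel edges)."""

    def __init__(self, edges: Iterable[InteractionEdge | tuple[str, str]]):
        g = nx.Graph()
        for e in edges:
            a, b = (e.uniprot_a, e.uniprot_b) if isinstance(e, InteractionEdge) else e
            if a == b:
                raise InvalidArgumentError(f"self-loop on {a!r}")
            g.add_edge(a, b)
        self.graph = g

    @classmethod
    def from_kb(cls, kb: KnowledgeBase) -> "ProteinNetwork":
        return cls(kb.interactions)

    @classmethod
    def from_tsv(cls, path) -> "ProteinNetwork":
        """Read a 2-column TSV edge list (header ``uniprot_a<TAB>uniprot_b``)."""
        from .kb import _read_tsv  # shared parser, same comment/header rules

        edges = [
            (row["uniprot_a"].strip(), row["uniprot_b"].strip())
            for _, row in _read_tsv(path, ("uniprot_a", "uniprot_b"))
        ]
        return cls(edges)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class DistanceTable:
    """Cross-pair hop distances; ``math.inf`` marks unreachable pairs."""

    distances: Mapping[tuple[str, str], float]
    dropped_sources: int
    dropped_targets: int


def shortest_path_lengths(
    net: ProteinNetwork, sources: set[str], targets: set[str]
) -> DistanceTable:
    """Unweighted shortest-path hop counts for every cross pair (s, t),
    s != t. Proteins absent from the network are dropped with a warning
    count; if either set empties, there is no network coverage to test."""
    if not sources or not targets:
        raise InvalidArgumentError("source and target sets must be non-empty")
    present = set(net.graph.nodes)
    src = sorted(sources & present)
    tgt = sorted(targets & present)
    dropped_s = len(sources) - len(src)
    dropped_t = len(targets) - len(tgt)
    if dropped_s or dropped_t:
        logger.warning(
            "dropped %d source and %d target proteins absent from the network",
            dropped_s,
            dropped_t,
        )
    if not src or not tgt:
        raise AdrError("no network coverage: a profile has no proteins in the network")
    distances: dict[tuple[str, str], float] = {}
    for s in src:
        reach = nx.single_source_shortest_path_length(net.graph, s)
        for t in tgt:
            if t == s:
                continue
            distances[(s, t)] = float(reach.get(t, math.inf))
    return DistanceTable(distances, dropped_s, dropped_t)


@dataclass(frozen=True)
class MeanDistance:
    mean: Optional[float]  # None when no pair has a finite distance
    n_used: int
    n_unreachable: int

    @property
    def defined(self) -> bool:
        return self.mean is not None


def mean_cross_distance(table: DistanceTable) -> MeanDistance:
    """Arithmetic mean over finite cross-pair distances; identical-protein
    pairs were never formed and unreachable pairs are excluded but counted."""
    finite = [d for d in table.distances.values() if math.isfinite(d)]
    unreachable = len(table.distances) - len(finite)
    if not finite:
        return MeanDistance(mean=None, n_used=0, n_unreachable=unreachable)
    return MeanDistance(
        mean=sum(finite) / len(finite), n_used=len(finite), n_unreachable=unreachable
    )


def null_mean_distribution(
    net: ProteinNetwork,
    size_a: int,
    size_b: int,
    n_replicates: int = 1000,
    seed: Optional[int] = None,
) -> list[float]:
    """Mean cross distances for R random disjoint node-set pairs of the
    given sizes, drawn uniformly (no degree matching). Replicates in which
    every cross pair is unreachable are dropped with a warning."""
    if n_replicates < 100:
        raise InvalidArgumentError("need at least 100 null replicates")
    nodes = net.nodes
    if size_a + size_b > len(nodes):
        raise AdrError(
            f"graph of {len(nodes)} nodes cannot supply disjoint sets of "
            f"sizes {size_a} and {size_b}"
        )
    if size_a < 1 or size_b < 1:
        raise InvalidArgumentError("set sizes must be positive")
    rng = np.random.default_rng(seed)
    means: list[float] = []
    dropped = 0
    for _ in range(n_replicates):
        draw = rng.choice(nodes, size=size_a + size_b, replace=False)
        a, b = set(draw[:size_a]), set(draw[size_a:])
        md = mean_cross_distance(shortest_path_lengths(net, a, b))
        if md.defined:
            means.append(md.mean)
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d null replicates with no finite cross pair", dropped)
    return means


@dataclass(frozen=True)
class PathTestResult:
    observed_mean: float
    null_means: tuple[float, ...]
    t_statistic: Optional[float]
    p_value: float  # one-sided t-test p; falls back to empirical p on zero variance
    empirical_p: float
    n_pairs_used: int
    n_pairs_unreachable: int
    zero_variance: bool = False

    @property
    def null_mean(self) -> float:
        return sum(self.null_means) / len(self.null_means)


def path_proximity_test(
    observed: MeanDistance, null_means: Sequence[float]
) -> PathTestResult:
    """Test whether the observed mean cross distance is shorter than random.

    One-sample t-test of the null replicate means against the observed
    value, alternative 'the null mean is greater'; the empirical permutation
    p-value (1 + #{null <= observed}) / (R + 1) is reported alongside. With
    a zero-variance null the t statistic is undefined and the empirical p
    is used, flagged.
    """
    if not observed.defined:
        raise AdrError("observed mean distance undefined: no finite cross pair")
    if len(null_means) < 2:
        raise InvalidArgumentError("need at least 2 null means")
    nulls = np.asarray(null_means, dtype=float)
    obs = observed.mean
    empirical = (1 + int(np.sum(nulls <= obs))) / (len(nulls) + 1)
    if np.ptp(nulls) == 0.0:
        return PathTestResult(
            observed_mean=obs,
            null_means=tuple(nulls.tolist()),
            t_statistic=None,
            p_value=empirical,
            empirical_p=empirical,
            n_pairs_used=observed.n_used,
            n_pairs_unreachable=observed.n_unreachable,
            zero_variance=True,
        )
    t = stats.ttest_1samp(nulls, popmean=obs, alternative="greater")
    return PathTestResult(
        observed_mean=obs,
        null_means=tuple(nulls.tolist()),
        t_statistic=float(t.statistic),
        p_value=float(t.pvalue),
        empirical_p=empirical,
        n_pairs_used=observed.n_used,
        n_pairs_unreachable=observed.n_unreachable,
    )


def network_proximity(
    net: ProteinNetwork,
    drug_proteins: set[str],
    event_proteins: set[str],
    n_replicates: int = 1000,
    seed: Optional[int] = None,
) -> PathTestResult:
    """Full proximity pipeline: observed mean cross distance, null ensemble
    of random set pairs of the same (network-covered) sizes, and the test."""
    table = shortest_path_lengths(net, drug_proteins, event_proteins)
    observed = mean_cross_distance(table)
    if not observed.defined:
        raise AdrError("observed mean distance undefined: no finite cross pair")
    present = set(net.graph.nodes)
    size_a = len(drug_proteins & present)
    size_b = len(event_proteins & present)
    nulls = null_mean_distribution(net, size_a, size_b, n_replicates, seed)
    return path_proximity_test(observed, nulls)
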