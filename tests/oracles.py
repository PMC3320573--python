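"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths (and where practical the libraries)
used by the package: exact rational arithmetic for hypergeometric tails,
exhaustive enumeration of draws, a hand-coded breadth-first search, naive
double-loop scans for sentence counts and pathway bridging.
"""

from __future__ import annotations

import itertools
import math
import re
from collections import deque
from fractions import Fraction


def hypergeom_tail_exact(k: int, m: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, n, m), exact rational value
    computed from factorial point masses."""
    total = math.comb(N, m)
    acc = Fraction(0)
    for j in range(k, min(m, n) + 1):
        if m - j > N - n:
            continue
        acc += Fraction(math.comb(n, j) * math.comb(N - n, m - j), total)
    return acc


def overlap_pvalue_by_enumeration(k: int, m: int, n: int, N: int) -> Fraction:
    """P(overlap >= k) by exhaustively enumerating all C(N, m) draws of the
    drug profile against a fixed event profile of size n. Small N only."""
    universe = range(N)
    event = set(range(n))
    hits = total = 0
    for draw in itertools.combinations(universe, m):
        total += 1
        if len(event.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up by the textbook recipe: sort, scale by
    m/rank, take running minima from the largest rank down."""
    m = len(pvalues)
    indexed = sorted(enumerate(pvalues), key=lambda t: t[1])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx, p = indexed[rank - 1]
        running = min(running, p * m / rank)
        q[idx] = min(running, 1.0)
    return q


def chi_square_margin_formula(n11, n10, n01, n00):
    """Closed-form 1-df chi-square statistic from the 2x2 margins."""
    n = n11 + n10 + n01 + n00
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    return n * (n11 * n00 - n10 * n01) ** 2 / (r1 * r0 * c1 * c0)


def bfs_distances(adjacency: dict, source):
    """Hop distances from source over an adjacency-set mapping."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


_WORD = re.compile(r"[a-z0-9]+")


def naive_sentence_counts(sentences, drug_terms, event_terms):
    """Per-sentence double loop over all terms; whole-token containment."""

    def mentions(sentence: str, term: str) -> bool:
        toks = _WORD.findall(sentence.lower())
        needle = _WORD.findall(term.lower())
        for start in range(len(toks) - len(needle) + 1):
            if toks[start : start + len(needle)] == needle:
                return True
        return False

    n11 = n10 = n01 = n00 = 0
    for s in sentences:
        d = any(mentions(s, t) for t in drug_terms)
        e = any(mentions(s, t) for t in event_terms)
        if d and e:
            n11 += 1
        elif d:
            n10 += 1
        elif e:
            n01 += 1
        else:
            n00 += 1
    return n11, n10, n01, n00


def brute_force_connecting_pathways(pathway_rows, retained_drug, retained_event):
    """Triple scan over (pathway, drug protein, event protein)."""
    hits = set()
    members = {}
    for row in pathway_rows:
        members.setdefault(row.pathway_id, set()).add(row.uniprot_acc)
    for pid, accs in members.items():
        for d in retained_drug:
            for e in retained_event:
                if d in accs and e in accs:
                    hits.add(pid)
    return sorted(hits)
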