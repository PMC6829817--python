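"""Shared fixtures and independent oracles.

The oracles here are deliberately naive — exhaustive enumeration and
brute-force breadth-first search — so they stay independent of the code
paths they check.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from itertools import combinations

import pandas as pd
import pytest

from mitena.interaction_db import CANONICAL_COLUMNS, InteractionDB


# -- oracle: exhaustive hypergeometric tail --------------------------------

def overlap_distribution(M: int, K: int, N: int) -> dict[int, Fraction]:
    """Exact P(overlap = x) by enumerating every size-N draw from M items,
    the first K of which are marked."""
    universe = range(M)
    marked = set(range(K))
    counts: dict[int, int] = {}
    total = 0
    for draw in combinations(universe, N):
        x = len(marked.intersection(draw))
        counts[x] = counts.get(x, 0) + 1
        total += 1
    return {x: Fraction(c, total) for x, c in counts.items()}


def exact_upper_tail(M: int, K: int, N: int, X: int) -> Fraction:
    """Exact P(overlap >= X) from the enumerated distribution."""
    dist = overlap_distribution(M, K, N)
    return sum((p for x, p in dist.items() if x >= X), Fraction(0))


# -- oracle: min-over-suffix BH adjustment ---------------------------------

def bh_oracle(pvals) -> list[float]:
    """q_(i) = min_{j >= i} p_(j) * m / j, computed directly from the
    step-up definition and mapped back to input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    for pos, i in enumerate(order):
        q = min(pvals[order[j]] * m / (j + 1) for j in range(pos, m))
        adjusted[i] = min(q, 1.0)
    return adjusted


# -- oracle: brute-force BFS topology --------------------------------------

def bfs_dist_sigma(adj: dict, s) -> tuple[dict, dict]:
    """Distances and shortest-path counts from s by plain BFS."""
    dist = {s: 0}
    sigma = {s: 1}
    q = deque([s])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def brute_force_topology(adj: dict) -> dict:
    """Degree, betweenness (unnormalized), closeness, average shortest path
    and eccentricity for every node, all from pairwise BFS only."""
    nodes = list(adj)
    dists = {}
    sigmas = {}
    for s in nodes:
        dists[s], sigmas[s] = bfs_dist_sigma(adj, s)
    out = {}
    for v in nodes:
        reach = {u: d for u, d in dists[v].items() if u != v}
        total = sum(reach.values())
        n_others = len(reach)
        betw = 0.0
        for i, s in enumerate(nodes):
            for t in nodes[i + 1:]:
                if s == v or t == v or t not in dists[s]:
                    continue
                if v in dists[s] and v in dists[t] and dists[s][v] + dists[t][v] == dists[s][t]:
                    betw += sigmas[s][v] * sigmas[t][v] / sigmas[s][t]
        out[v] = {
            "degree": len(adj[v]),
            "betweenness": betw,
            "closeness": (n_others / total) if total > 0 else 0.0,
            "avg_shortest_path": (total / n_others) if n_others > 0 else 0.0,
            "eccentricity": max(reach.values()) if reach else 0,
        }
    return out


# -- fixtures --------------------------------------------------------------

def make_db(pairs, source: str = "predicted", scores=None, evidence=None,
            species: str = "hsa") -> InteractionDB:
    """Build an InteractionDB directly from (mirna, gene) pairs."""
    rows = []
    for i, (m, g) in enumerate(pairs):
        rows.append({
            "mirna_id": m,
            "gene_symbol": g.upper(),
            "species": species,
            "source": source,
            "evidence": ("none" if source == "predicted"
                         else (evidence[i] if evidence else "strong")),
            "score": (scores[i] if scores else (-1.0 if source == "predicted" else float("nan"))),
            "family": "",
            "n_support": 1,
        })
    records = (pd.DataFrame(rows, columns=CANONICAL_COLUMNS + ["n_support"])
               .sort_values(["mirna_id", "gene_symbol"], kind="mergesort")
               .reset_index(drop=True))
    return InteractionDB(records=records, source=source, species=species)


@pytest.fixture
def toy_db() -> InteractionDB:
    """miR-A -> {G1, G2, G3}; miR-B -> {G4, G5} (predicted, scored)."""
    pairs = [("miR-A", "G1"), ("miR-A", "G2"), ("miR-A", "G3"),
             ("miR-B", "G4"), ("miR-B", "G5")]
    return make_db(pairs, scores=[-0.9, -0.5, -0.1, -0.7, -0.2])


@pytest.fixture
def validated_db() -> InteractionDB:
    """5 strong + 3 weak validated interactions."""
    pairs = [("miR-A", f"G{i}") for i in range(1, 6)] + [("miR-B", f"H{i}") for i in range(1, 4)]
    evidence = ["strong"] * 5 + ["weak"] * 3
    return make_db(pairs, source="validated", evidence=evidence)
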