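"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written from scratch (plain dicts,
recursion, Floyd-Warshall) so they share no code path with the library
implementations they check.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from psflow import Pathway, PathwayEdge, PathwayNode


def build_pathway(pid: str, node_fcs: dict, edges: list[tuple]) -> Pathway:
    """Tiny pathway builder: ``node_fcs`` maps id -> fold change, each edge
    is ``(source, target)`` or ``(source, target, impact)`` or
    ``(source, target, impact, weight)``."""
    p = Pathway(pid)
    for nid, fc in node_fcs.items():
        p.nodes[nid] = PathwayNode(
            id=nid, label=nid, kind="gene", gene_ids=[f"gene_{nid}"],
            fold_change=fc, provenance="original",
        )
    for e in edges:
        s, t = e[0], e[1]
        impact = e[2] if len(e) > 2 else 1
        weight = e[3] if len(e) > 3 else 1.0
        p.edges.append(
            PathwayEdge(
                source=s, target=t, impact=impact, weight=weight,
                subtype="activation" if impact == 1 else "inhibition",
                provenance="original",
            )
        )
    return p


@pytest.fixture
def chain_abc() -> Pathway:
    return build_pathway("chain", {"A": 2.0, "B": 1.0, "C": 1.0},
                         [("A", "B"), ("B", "C")])


def recursive_oracle(node_fc: dict, edges: list[tuple]) -> dict:
    """Memoized recursive evaluation of the signal recurrence (DAGs only).

    ``edges`` are ``(source, target, weight, impact)`` tuples.  Completely
    independent of the engine: plain dict recursion, no numpy.
    """
    incoming = defaultdict(list)
    for s, t, w, k in edges:
        incoming[t].append((s, w, k))
    memo: dict = {}

    def signal(j):
        if j in memo:
            return memo[j]
        inc = incoming[j]
        if not inc:
            memo[j] = node_fc[j]
        else:
            denom = sum(signal(i) for i, _, _ in inc)
            memo[j] = node_fc[j] * sum(
                (signal(i) / denom) * w * (signal(i) ** k) for i, w, k in inc
            )
        return memo[j]

    return {j: signal(j) for j in node_fc}


def floyd_warshall_oracle(nodes: list, arcs: set) -> dict:
    """Brute-force topology metrics for a directed graph.

    Returns the same quantities as ``topology_report`` computed from a
    hand-rolled Floyd-Warshall plus shortest-path counting DP, so any
    agreement with the library is meaningful.
    """
    inf = float("inf")
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = [[inf] * n for _ in range(n)]
    for v in nodes:
        d[idx[v]][idx[v]] = 0
    for s, t in arcs:
        if s != t:
            d[idx[s]][idx[t]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]

    # sigma[s][t]: number of distinct shortest s->t paths
    sigma = [[0] * n for _ in range(n)]
    for s in range(n):
        sigma[s][s] = 1
        order = sorted(
            (t for t in range(n) if d[s][t] < inf), key=lambda t: d[s][t]
        )
        for t in order:
            if t == s:
                continue
            sigma[s][t] = sum(
                sigma[s][u]
                for u, t2 in ((idx[a], idx[b]) for a, b in arcs)
                if t2 == t and d[s][u] == d[s][t] - 1
            )

    betweenness = {}
    for v in range(n):
        total = 0.0
        for s in range(n):
            for t in range(n):
                if s == t or s == v or t == v or d[s][t] == inf or sigma[s][t] == 0:
                    continue
                if d[s][v] + d[v][t] == d[s][t]:
                    total += sigma[s][v] * sigma[v][t] / sigma[s][t]
        betweenness[nodes[v]] = total

    pairs = sum(
        1 for s in range(n) for t in range(n) if s != t and d[s][t] < inf
    )
    ecc, clo = [], []
    diameter = 0
    for s in range(n):
        dists = [d[s][t] for t in range(n) if t != s and d[s][t] < inf]
        if dists:
            ecc.append(max(dists))
            clo.append(len(dists) / sum(dists))
            diameter = max(diameter, max(dists))
    touched = {v for a in arcs for v in a}
    return {
        "shortest_path_pairs": pairs,
        "betweenness_median": float(np.median(list(betweenness.values()))),
        "closeness_median": float(np.median(clo)) if clo else 0.0,
        "eccentricity_median": float(np.median(ecc)) if ecc else 0.0,
        "diameter": diameter,
        "disconnected_count": sum(1 for v in nodes if v not in touched),
        "sink_count": sum(1 for v in nodes if all(s != v for s, _ in arcs)),
    }


def reachability_closure(nodes: list, arcs: set) -> dict:
    """Transitive closure by repeated squaring-free iteration (oracle for
    SCC detection)."""
    reach = {v: {t for s, t in arcs if s == v} for v in nodes}
    changed = True
    while changed:
        changed = False
        for v in nodes:
            new = set(reach[v])
            for u in reach[v]:
                new |= reach[u]
            if new != reach[v]:
                reach[v] = new
                changed = True
    return reach
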