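"""Independent brute-force oracles used to check the scoring and clustering code.

Everything here is deliberately written by a different route than the
implementation: frequency classes via exact integer comparisons, modularity
as the literal double sum over ordered node pairs, and optimal partitions by
exhaustive enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from litnex._canon import NEGATIVE, POSITIVE
from litnex.reading_io import EntityRef, EventRecord


def brute_frequency_class(f: int, f_max: int) -> int:
    """Largest k >= 0 with 2^(2k) <= 2 * (f_max/f)^2, integer-exact.

    Equivalent to floor(0.5 - log2(f/f_max)): the class k is the unique
    integer with 2^(k-1/2) <= f_max/f < 2^(k+1/2); squaring both sides gives
    an all-integer test.
    """
    k = 0
    while f * f * (4 ** (k + 1)) <= 2 * f_max * f_max:
        k += 1
    return k


def brute_if_pa(f_ij: int, f_i: int, f_j: int, n: int) -> float:
    return f_ij * (math.log(n / f_i) + math.log(n / f_j))


def brute_modularity(weights: dict, nodes: list, assignment: dict) -> float:
    """Literal double sum over ordered node pairs.

    ``weights`` maps an unordered edge (u, v) to its weight.
    """
    w = {}
    for (u, v), x in weights.items():
        w[(u, v)] = w.get((u, v), 0.0) + x
        w[(v, u)] = w.get((v, u), 0.0) + x
    m = sum(weights.values())
    sigma = {n: sum(x for (a, _), x in w.items() if a == n) for n in nodes}
    q = 0.0
    for u in nodes:
        for v in nodes:
            if assignment[u] != assignment[v]:
                continue
            q += w.get((u, v), 0.0) - sigma[u] * sigma[v] / (2.0 * m)
    return q / (2.0 * m)


def all_partitions(items: list):
    """Yield every set partition of ``items`` as a list of lists."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_q(graph, weight_attr: str = "if_pa") -> float:
    """Exhaustive-search maximum modularity over all partitions."""
    weights = {(u, v): d[weight_attr] for u, v, d in graph.edges(data=True)}
    nodes = sorted(graph.nodes)
    best = -np.inf
    for part in all_partitions(nodes):
        assignment = {n: i for i, grp in enumerate(part) for n in grp}
        best = max(best, brute_modularity(weights, nodes, assignment))
    return best


def random_records(rng: np.random.Generator, max_events: int = 30
                   ) -> list[EventRecord]:
    """Random reading records over a small entity/paper alphabet."""
    n_entities = int(rng.integers(3, 9))
    entities = [f"E{i}" for i in range(n_entities)]
    papers = [f"P{i}" for i in range(int(rng.integers(2, 7)))]
    n_distinct = int(rng.integers(1, max_events + 1))
    records = []
    for _ in range(n_distinct):
        i, j = rng.choice(n_entities, size=2, replace=False)
        sign = POSITIVE if rng.random() < 0.5 else NEGATIVE
        for _ in range(int(rng.integers(1, 5))):
            records.append(EventRecord(
                regulator=EntityRef(entities[i]),
                regulated=EntityRef(entities[j]),
                sign=sign,
                paper_id=papers[int(rng.integers(len(papers)))],
                evidence="synthetic sentence",
            ))
    return records
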