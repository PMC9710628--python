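"""Event collaboration graph (ECLG) construction, scoring and filtering.

The ECLG is a weighted undirected graph whose nodes are the distinct events
of an extracted event set and whose edges join events that co-occur in at
least one common paper. Literature support is scored with:

* ``fc_ia(f_i, f_max) = floor(0.5 - log2(f_i / f_max))`` — the frequency class
  of a single event, borrowed from corpus linguistics (Häufigkeitsklasse):
  0 for the most frequent event, 1 for an event half as frequent, and so on.
* ``fc_pa(f_ij, f_max_pair)`` — the same construction applied to pair
  co-occurrence counts (number of distinct shared papers).
* ``if_pa(f_ij, f_i, f_j, N) = f_ij * (ln(N/f_i) + ln(N/f_j))`` — pair
  co-occurrence weighted by summed log inverse relative frequencies, which
  boosts rare-but-co-occurring events.

Filtering removes the least frequent events (frequency class above a
threshold, by default the rounded mean class), optionally keeping only
neighbors of the most frequent (class-0) events. The surviving graph is the
*candidate* ECLG handed to clustering; pair metrics are recomputed on it
because the maximal pair count may drop with the filtered edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from ._canon import EventKey
from .reading_io import EES

__all__ = [
    "ECLG",
    "FilterReport",
    "DomainError",
    "fc_ia",
    "fc_pa",
    "if_pa",
    "build_eclg",
    "filter_eclg",
    "write_eclg_graphml",
    "write_edge_list",
    "write_node_table",
]


class DomainError(ValueError):
    """An argument outside the domain of a scoring formula."""


def _frequency_class(f: int, f_max: int) -> int:
    if f_max <= 0 or f <= 0:
        raise DomainError(f"counts must be positive (got f={f}, f_max={f_max})")
    if f > f_max:
        raise DomainError(f"f={f} exceeds f_max={f_max}")
    return math.floor(0.5 - math.log2(f / f_max))


def fc_ia(f_i: int, f_max: int) -> int:
    """Frequency class of one event: floor(0.5 - log2(f_i/f_max)), >= 0.

    0 for the most frequent event(s); an event half as frequent as the most
    frequent one gets class 1.
    """
    return _frequency_class(f_i, f_max)


def fc_pa(f_ij: int, f_max_pair: int) -> int:
    """Frequency class of a co-occurring event pair (same algebra as fc_ia)."""
    return _frequency_class(f_ij, f_max_pair)


def if_pa(f_ij: int, f_i: int, f_j: int, N: int) -> float:
    """Inverse-frequency pair weight: f_ij * (ln(N/f_i) + ln(N/f_j))."""
    if f_ij <= 0 or f_i <= 0 or f_j <= 0:
        raise DomainError("counts must be positive")
    if N < max(f_i, f_j):
        raise DomainError(f"N={N} smaller than an event frequency")
    return f_ij * (math.log(N / f_i) + math.log(N / f_j))


@dataclass
class ECLG:
    """Weighted undirected graph over distinct events.

    Node attributes: ``f_i`` (occurrences), ``fc_ia``.
    Edge attributes: ``f_ij`` (shared papers), ``fc_pa``, ``if_pa``.
    """

    graph: nx.Graph
    N: int
    f_max: int
    f_max_pair: int

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


@dataclass
class FilterReport:
    threshold_used: int = 0
    removed_by_threshold: int = 0
    removed_by_neighbor_rule: int = 0
    removed_isolated: int = 0
    f_max_pair_before: int = 0
    f_max_pair_after: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _score_pairs(graph: nx.Graph, N: int) -> int:
    """(Re)compute fc_pa / if_pa edge attributes; returns f_max_pair."""
    if graph.number_of_edges() == 0:
        return 0
    f_max_pair = max(d["f_ij"] for _, _, d in graph.edges(data=True))
    for u, v, d in graph.edges(data=True):
        d["fc_pa"] = fc_pa(d["f_ij"], f_max_pair)
        d["if_pa"] = if_pa(d["f_ij"], graph.nodes[u]["f_i"], graph.nodes[v]["f_i"], N)
    return f_max_pair


def build_eclg(ees: EES) -> ECLG:
    """Build the original ECLG from an extracted event set.

    One node per distinct event; an edge joins two events iff they share at
    least one paper, weighted by the number of distinct shared papers.
    """
    if ees.M == 0:
        raise ValueError("nothing to build: the extracted event set is empty")
    g = nx.Graph()
    f_max = ees.f_max
    for key, ev in ees.events.items():
        g.add_node(key, f_i=ev.f_i, fc_ia=fc_ia(ev.f_i, f_max))
    by_paper: dict[str, list[EventKey]] = {}
    for key, ev in ees.events.items():
        for p in ev.papers:
            by_paper.setdefault(p, []).append(key)
    for keys in by_paper.values():
        for a, b in combinations(sorted(keys), 2):
            if g.has_edge(a, b):
                g[a][b]["f_ij"] += 1
            else:
                g.add_edge(a, b, f_ij=1)
    f_max_pair = _score_pairs(g, ees.N)
    return ECLG(graph=g, N=ees.N, f_max=f_max, f_max_pair=f_max_pair)


def auto_threshold(g: ECLG) -> int:
    """Default class threshold: mean fc_ia over nodes, rounded half-up."""
    values = [d["fc_ia"] for _, d in g.graph.nodes(data=True)]
    return math.floor(sum(values) / len(values) + 0.5)


def filter_eclg(
    g: ECLG,
    fc_threshold: int | str = "auto",
    require_neighbor_of_most_frequent: bool = False,
    drop_isolated: bool = False,
) -> tuple[ECLG, FilterReport]:
    """Reduce the ECLG to the candidate graph of well-supported events.

    Removes nodes with ``fc_ia`` above the threshold ("auto" = rounded mean
    class); optionally also nodes not adjacent to any class-0 node; optionally
    nodes left isolated. Pair metrics are recomputed on the survivors.
    """
    if g.graph.number_of_nodes() == 0:
        raise ValueError("cannot filter an empty graph")
    if fc_threshold == "auto":
        threshold = auto_threshold(g)
    else:
        threshold = int(fc_threshold)
        if threshold < 0:
            raise DomainError(f"fc_threshold must be >= 0, got {threshold}")

    report = FilterReport(threshold_used=threshold, f_max_pair_before=g.f_max_pair)
    sub = g.graph.copy()
    doomed = [n for n, d in sub.nodes(data=True) if d["fc_ia"] > threshold]
    report.removed_by_threshold = len(doomed)
    sub.remove_nodes_from(doomed)

    if require_neighbor_of_most_frequent:
        anchors = {n for n, d in sub.nodes(data=True) if d["fc_ia"] == 0}
        keep = set(anchors)
        for a in anchors:
            keep.update(sub.neighbors(a))
        doomed = [n for n in sub.nodes if n not in keep]
        report.removed_by_neighbor_rule = len(doomed)
        sub.remove_nodes_from(doomed)

    if drop_isolated:
        doomed = [n for n in sub.nodes if sub.degree(n) == 0]
        report.removed_isolated = len(doomed)
        sub.remove_nodes_from(doomed)

    if sub.number_of_nodes() == 0:
        raise ValueError("empty candidate ECLG: filtering removed every node")

    f_max_pair = _score_pairs(sub, g.N)
    report.f_max_pair_after = f_max_pair
    return ECLG(graph=sub, N=g.N, f_max=g.f_max, f_max_pair=f_max_pair), report


# -- exports ------------------------------------------------------------------

def _flat(key: EventKey) -> str:
    return "|".join(key)


def write_eclg_graphml(g: ECLG, path: str | Path) -> None:
    out = nx.relabel_nodes(g.graph, _flat, copy=True)
    nx.write_graphml(out, str(path))


def write_edge_list(g: ECLG, path: str | Path, weight: str = "if_pa") -> None:
    rows = [{"event_a": _flat(u), "event_b": _flat(v), weight: d[weight]}
            for u, v, d in g.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["event_a", "event_b", weight]).to_csv(
        path, sep="\t", index=False)


def write_node_table(g: ECLG, path: str | Path) -> None:
    rows = [{"event": _flat(n), "f_i": d["f_i"], "fc_ia": d["fc_ia"]}
            for n, d in sorted(g.graph.nodes(data=True))]
    pd.DataFrame(rows, columns=["event", "f_i", "fc_ia"]).to_csv(
        path, sep="\t", index=False)
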