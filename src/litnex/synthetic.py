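"""Synthetic reading tables and model pairs with planted structure.

Real extracted event sets have a characteristic shape: the same interaction
is re-extracted across papers (a heavy-tailed per-event frequency), and
events from one line of investigation co-occur inside the same small set of
papers, forming tight co-occurrence communities with only occasional
cross-community mentions. The generator reproduces exactly that: events are
grouped into communities, each community owns a pool of papers, an event's
occurrences are placed in its community's papers, and a small
``cross_paper_rate`` plants the rare cross-community co-occurrence.

For end-to-end benchmarks a gold model is generated as a random directed
signed graph, a baseline is derived by truncation (removing regulators,
breaking paths between node pairs, or deleting random edges), and the removed
edges are planted back into the synthetic event set as its best-supported
community — the recoverable target a selection pipeline should retrieve.

What the generator does not emulate: reader grounding errors, synonymous
entity labels, and event-subtype ambiguity. Tests passing on this fixture
show the pipeline machinery is correct, not that a particular reader's noise
profile is handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from ._canon import NEGATIVE, POSITIVE, EventKey, canonical_key
from .model_io import ModelGraph, model_from_edges
from .reading_io import EES, EntityRef, EventRecord, build_ees, write_ees

__all__ = [
    "SynthConfig",
    "generate_ees",
    "generate_model_pair",
    "generate_benchmark",
    "write_reading_table",
]


@dataclass
class SynthConfig:
    """Knobs of the planted-community event generator.

    Defaults are the standard desk-scale fixture: three communities of 15
    events, five papers per community, a 2% chance of a stray
    cross-community occurrence, and per-event frequencies uniform on [1, 6].
    """

    n_communities: int = 3
    events_per_community: int = 15
    papers_per_community: int = 5
    cross_paper_rate: float = 0.02
    frequency_law: tuple = ("uniform", 1, 6)
    model_overlap_fraction: float = 0.0
    entities_per_community: int | None = None  # default: half the events + 2
    seed: int = 0
    # model-pair generation
    gold_nodes: int = 20
    gold_edges: int = 40

    def validate(self) -> None:
        for name in ("n_communities", "events_per_community",
                     "papers_per_community", "gold_nodes", "gold_edges"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("cross_paper_rate", "model_overlap_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _draw_frequency(rng: np.random.Generator, law: tuple) -> int:
    kind = law[0]
    if kind == "uniform":
        lo, hi = int(law[1]), int(law[2])
        return int(rng.integers(lo, hi + 1))
    if kind == "zipf":
        return int(min(rng.zipf(float(law[1])), 50))
    raise ValueError(f"unknown frequency law {law!r}")


def _community_events(
    rng: np.random.Generator,
    cfg: SynthConfig,
    community: int,
    entity_pool: list[str],
) -> list[EventKey]:
    """Distinct signed event keys over the community's entity pool."""
    n_pairs = len(entity_pool) * (len(entity_pool) - 1)
    if cfg.events_per_community > 2 * n_pairs:
        raise ValueError(
            "infeasible config: more distinct events requested than the "
            "entity name space supports")
    events: set[EventKey] = set()
    guard = 0
    while len(events) < cfg.events_per_community:
        guard += 1
        if guard > 100 * cfg.events_per_community:
            raise ValueError("infeasible config: cannot draw enough distinct events")
        i, j = rng.choice(len(entity_pool), size=2, replace=False)
        sign = POSITIVE if rng.random() < 0.7 else NEGATIVE
        events.add((entity_pool[i], entity_pool[j], sign))
    return sorted(events)


def generate_ees(
    cfg: SynthConfig,
    model: ModelGraph | None = None,
    planted_events: dict[int, list[EventKey]] | None = None,
) -> tuple[list[EventRecord], dict[EventKey, int]]:
    """Generate reading records with planted co-occurrence communities.

    Returns the records (one per occurrence) and the ground-truth map from
    event key to community label. ``planted_events`` can force specific event
    keys into given communities (used by the end-to-end benchmark to inject
    recoverable gold edges); forced events are drawn at the top of the
    frequency law so they are the well-supported ones.

    Deterministic for a fixed config: same seed, byte-identical table.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    planted_events = planted_events or {}

    model_names: list[str] = []
    if model is not None and cfg.model_overlap_fraction > 0:
        model_names = sorted(model.elements[k].name for k in model.elements)

    records: list[EventRecord] = []
    truth: dict[EventKey, int] = {}
    used_keys: set[EventKey] = set()

    for c in range(cfg.n_communities):
        papers = [f"PMID{c + 1:02d}{j + 1:03d}" for j in range(cfg.papers_per_community)]
        if c in planted_events:
            events = list(planted_events[c])
        else:
            pool_size = cfg.entities_per_community or max(
                4, cfg.events_per_community // 2 + 2)
            pool = [f"C{c + 1}E{k + 1:02d}" for k in range(pool_size)]
            if model_names:
                n_swap = int(round(cfg.model_overlap_fraction * len(pool)))
                picks = rng.choice(len(model_names), size=min(n_swap, len(model_names)),
                                   replace=False)
                for slot, pick in enumerate(sorted(int(p) for p in picks)):
                    pool[slot] = model_names[pick]
            events = _community_events(rng, cfg, c, pool)
        lo_hi = cfg.frequency_law
        for key in events:
            if key in used_keys:
                continue
            used_keys.add(key)
            src, dst, sign = key
            truth[(canonical_key(src), canonical_key(dst), sign)] = c
            if c in planted_events and lo_hi[0] == "uniform":
                # forced (recoverable) events sit at the top of the law
                f = int(lo_hi[2])
            else:
                f = _draw_frequency(rng, cfg.frequency_law)
            for occ in range(f):
                paper = papers[int(rng.integers(len(papers)))]
                records.append(_record(src, dst, sign, paper))
            if rng.random() < cfg.cross_paper_rate and cfg.n_communities > 1:
                other = (c + 1 + int(rng.integers(cfg.n_communities - 1))) \
                    % cfg.n_communities
                stray = f"PMID{other + 1:02d}{int(rng.integers(cfg.papers_per_community)) + 1:03d}"
                records.append(_record(src, dst, sign, stray))
    return records, truth


def _record(src: str, dst: str, sign: str, paper: str) -> EventRecord:
    verb = "activates" if sign == POSITIVE else "inhibits"
    return EventRecord(
        regulator=EntityRef(src, "protein", ""),
        regulated=EntityRef(dst, "protein", ""),
        sign=sign,
        paper_id=paper,
        evidence=f"We find that {src} {verb} {dst}.",
    )


def write_reading_table(records: Iterable[EventRecord], path: str | Path) -> None:
    """Serialize generated records in the reading-table dialect."""
    write_ees(build_ees(records), path)


# -- model pairs --------------------------------------------------------------

def _random_gold(rng: np.random.Generator, cfg: SynthConfig
                 ) -> list[tuple[str, str, str]]:
    names = [f"GEN{i + 1:02d}" for i in range(cfg.gold_nodes)]
    edges: set[tuple[str, str, str]] = set()
    # backbone ring keeps the graph weakly connected
    for i in range(cfg.gold_nodes):
        edges.add((names[i], names[(i + 1) % cfg.gold_nodes], POSITIVE))
    guard = 0
    while len(edges) < cfg.gold_edges:
        guard += 1
        if guard > 100 * cfg.gold_edges:
            break
        i, j = rng.choice(cfg.gold_nodes, size=2, replace=False)
        sign = POSITIVE if rng.random() < 0.7 else NEGATIVE
        if not any(e[0] == names[i] and e[1] == names[j] for e in edges):
            edges.add((names[i], names[j], sign))
    return sorted(edges)


def generate_model_pair(
    cfg: SynthConfig,
    truncation: str = "remove_random_edges",
    amount: float = 0.25,
) -> tuple[ModelGraph, ModelGraph, list[tuple[str, str, str]]]:
    """Random gold model plus a truncated baseline.

    ``truncation`` mirrors the three benchmark constructions: removing all
    in-edges of randomly chosen key players (``remove_regulators``), breaking
    every directed path between chosen node pairs (``remove_paths``), or
    deleting random edges (``remove_random_edges``). Returns (gold, baseline,
    removed name-triples) — the removed content is the recoverable target.
    """
    cfg.validate()
    if not 0.0 < amount < 1.0:
        raise ValueError("amount must be in (0, 1)")
    rng = np.random.default_rng(cfg.seed + 1)
    gold_edges = _random_gold(rng, cfg)
    n_remove = max(1, round(amount * len(gold_edges)))

    removed: list[tuple[str, str, str]] = []
    if truncation == "remove_random_edges":
        idx = rng.choice(len(gold_edges), size=n_remove, replace=False)
        removed = [gold_edges[i] for i in sorted(int(i) for i in idx)]
    elif truncation == "remove_regulators":
        nodes = sorted({e[1] for e in gold_edges})
        order = rng.permutation(len(nodes))
        for i in order:
            key_player = nodes[int(i)]
            removed.extend(e for e in gold_edges
                           if e[1] == key_player and e not in removed)
            if len(removed) >= n_remove:
                break
    elif truncation == "remove_paths":
        import networkx as nx
        g = nx.DiGraph((s, d) for s, d, _ in gold_edges)
        nodes = sorted(g.nodes)
        order = [int(i) for i in rng.permutation(len(nodes))]
        for a in order:
            for b in order:
                if a == b or len(removed) >= n_remove:
                    continue
                s, t = nodes[a], nodes[b]
                if nx.has_path(g, s, t):
                    cut = nx.minimum_edge_cut(g, s, t)
                    for u, v in sorted(cut):
                        for e in gold_edges:
                            if e[0] == u and e[1] == v and e not in removed:
                                removed.append(e)
                        g.remove_edge(u, v)
            if len(removed) >= n_remove:
                break
    else:
        raise ValueError(f"unknown truncation scheme {truncation!r}")

    baseline_edges = [e for e in gold_edges if e not in removed]
    if not baseline_edges:
        raise ValueError("truncation emptied the model")
    gold = model_from_edges(gold_edges)
    baseline = model_from_edges(baseline_edges)
    # keep every gold node in the baseline (truncation removes edges, not nodes)
    for key, el in gold.elements.items():
        if key not in baseline.elements:
            from dataclasses import replace
            baseline.add_element(replace(el, pos_expr="", neg_expr=""), key=key)
    return gold, baseline, removed


def generate_benchmark(
    cfg: SynthConfig,
    truncation: str = "remove_random_edges",
    amount: float = 0.25,
) -> tuple[list[EventRecord], ModelGraph, ModelGraph, dict[EventKey, int]]:
    """End-to-end fixture: gold/baseline pair plus an EES whose community 0
    is exactly the set of recoverable (truncated-away) gold edges.

    Noise communities use synthetic entities at lower frequencies, so the
    recoverable community is the best literature-supported one — the
    situation a frequency-based selection pipeline is designed for.
    """
    gold, baseline, removed = generate_model_pair(cfg, truncation, amount)
    injected = {0: list(removed)}
    records, truth = generate_ees(cfg, model=baseline, planted_events=injected)
    return records, gold, baseline, truth
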