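"""Community detection on the candidate ECLG by weighted modularity.

Partitions the event collaboration graph with the two-phase greedy
modularity-maximization scheme of Blondel et al. (Louvain): phase one moves
each node to the neighboring community with the largest positive modularity
gain until no move helps; phase two contracts communities into super-nodes
(intra-community weight becomes a self-loop) and repeats. The implementation
is written for determinism: the node sweep order is the canonical sorted
order shuffled by a fixed seed, equal-gain ties go to the lowest community
label, and a gain must exceed a small tolerance to count as an improvement.

Modularity of a partition (Kronecker delta over community labels)::

    Q = (1/2m) * sum_{u,v} [ w_uv - s_u s_v / (2m) ] * delta(c_u, c_v)

with w_uv the edge weight, s_u the weighted degree of u and m the total edge
weight. Edge weights default to ``if_pa``. ``fc_pa`` ranks *low* values as
strong support while modularity treats high weight as a strong tie, so when
clustering on ``fc_pa`` the weight used is ``fc_pa_max - fc_pa + 1``
(recorded on the partition).

Each resulting community is summarized as a generated cluster with its
intra-cluster edge count ``P_l`` and the arithmetic means of ``fc_pa`` and
``if_pa`` over those edges — the literature-support scores used by cluster
selection downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "Partition",
    "GeneratedCluster",
    "modularity",
    "delta_q",
    "louvain",
    "cluster_averages",
    "clustering_weight",
]

#: Minimum modularity gain that counts as an improvement.
DEFAULT_TOL = 1e-12


@dataclass
class Partition:
    assignment: dict[Hashable, int]
    Q: float
    m: float
    weight_key: str


@dataclass
class GeneratedCluster:
    """A community of ECLG event-nodes with its literature-support scores."""

    label: int
    events: frozenset
    P_l: int
    fc_pa_avg: float | None
    if_pa_avg: float | None


def _as_graph(g) -> nx.Graph:
    return g.graph if hasattr(g, "graph") and isinstance(g.graph, nx.Graph) else g


def clustering_weight(g, weight_key: str) -> dict[tuple, float]:
    """Edge -> weight used for clustering under the chosen metric.

    ``if_pa`` and ``f_ij`` are used as-is; ``fc_pa`` is inverted
    (``fc_pa_max - fc_pa + 1``) so that strongly supported pairs get the
    heavier ties.
    """
    graph = _as_graph(g)
    if weight_key in ("if_pa", "f_ij"):
        return {(u, v): float(d[weight_key]) for u, v, d in graph.edges(data=True)}
    if weight_key == "fc_pa":
        if graph.number_of_edges() == 0:
            return {}
        fc_max = max(d["fc_pa"] for _, _, d in graph.edges(data=True))
        return {(u, v): float(fc_max - d["fc_pa"] + 1)
                for u, v, d in graph.edges(data=True)}
    raise ValueError(f"unknown weight_key {weight_key!r}")


def modularity(g, assignment: Mapping[Hashable, int], weight_key: str = "if_pa") -> float:
    """Evaluate Q for an arbitrary assignment on an (edge-weighted) ECLG."""
    graph = _as_graph(g)
    weights = clustering_weight(g, weight_key)
    m = sum(weights.values())
    if m <= 0:
        raise ValueError("graph has no weighted edges; modularity undefined")
    sigma: dict[Hashable, float] = {n: 0.0 for n in graph.nodes}
    for (u, v), w in weights.items():
        sigma[u] += w
        sigma[v] += w
    intra = sum(w for (u, v), w in weights.items()
                if assignment[u] == assignment[v])
    comm_sigma: dict[int, float] = {}
    for n in graph.nodes:
        comm_sigma[assignment[n]] = comm_sigma.get(assignment[n], 0.0) + sigma[n]
    return intra / m - sum((s / (2.0 * m)) ** 2 for s in comm_sigma.values())


def delta_q(g, u: Hashable, target_community: int,
            assignment: Mapping[Hashable, int], weight_key: str = "if_pa") -> float:
    """Gain in Q from moving a currently-singleton node into a community.

    Equals ``modularity(after move) - modularity(before move)`` when ``u``
    is alone in its community: the intra-weight it brings, minus the
    degree-product penalty against the target's total incident weight.
    """
    if assignment[u] == target_community:
        return 0.0
    graph = _as_graph(g)
    weights = clustering_weight(g, weight_key)
    m = sum(weights.values())
    if m <= 0:
        raise ValueError("graph has no weighted edges")
    sigma: dict[Hashable, float] = {n: 0.0 for n in graph.nodes}
    for (a, b), w in weights.items():
        sigma[a] += w
        sigma[b] += w
    members = [n for n in graph.nodes if assignment[n] == target_community]
    k_u_target = sum(weights.get((u, v), weights.get((v, u), 0.0)) for v in members)
    sigma_tot = sum(sigma[v] for v in members)
    return k_u_target / m - sigma[u] * sigma_tot / (2.0 * m * m)


# -- Louvain ------------------------------------------------------------------

def _one_level(adj: dict, selfw: dict, m: float, order: list, tol: float
               ) -> tuple[dict, bool]:
    """Phase one: greedy local moves until a full sweep makes no move.

    ``adj`` maps node -> {neighbor: weight} (no self entries); ``selfw``
    carries contracted self-loop weight. Returns (community map, any_moved).
    """
    comm = {n: i for i, n in enumerate(sorted(adj))}
    sigma = {n: sum(adj[n].values()) + 2.0 * selfw.get(n, 0.0) for n in adj}
    sigma_tot = {comm[n]: sigma[n] for n in adj}
    improved = False
    moved = True
    while moved:
        moved = False
        for u in order:
            c0 = comm[u]
            sigma_tot[c0] -= sigma[u]
            # weight from u into each neighboring community
            k_uc: dict[int, float] = {}
            for v, w in adj[u].items():
                k_uc[comm[v]] = k_uc.get(comm[v], 0.0) + w
            k_uc.setdefault(c0, 0.0)
            best_c, best_gain = None, -np.inf
            for c in sorted(k_uc):
                gain = k_uc[c] / m - sigma[u] * sigma_tot.get(c, 0.0) / (2.0 * m * m)
                if gain > best_gain + tol:
                    best_c, best_gain = c, gain
            stay_gain = k_uc[c0] / m - sigma[u] * sigma_tot.get(c0, 0.0) / (2.0 * m * m)
            if best_c != c0 and best_gain - stay_gain > tol:
                comm[u] = best_c
                sigma_tot[best_c] = sigma_tot.get(best_c, 0.0) + sigma[u]
                moved = improved = True
            else:
                comm[u] = c0
                sigma_tot[c0] += sigma[u]
    return comm, improved


def louvain(g, weight_key: str = "if_pa", node_order_seed: int = 0,
            tol: float = DEFAULT_TOL) -> tuple[Partition, list[GeneratedCluster]]:
    """Two-phase modularity maximization on the candidate ECLG.

    Returns the flat assignment over original nodes (labels renumbered
    contiguously, ordered by each community's smallest member) plus the
    generated clusters with intra-edge counts and literature-score averages
    computed on the *input* graph.
    """
    graph = _as_graph(g)
    nodes = sorted(graph.nodes)
    weights = clustering_weight(g, weight_key)
    m = sum(weights.values())
    if m <= 0:
        warnings.warn("graph has no weighted edges: every node is its own cluster")
        assignment = {n: i for i, n in enumerate(nodes)}
        part = Partition(assignment=assignment, Q=0.0, m=0.0, weight_key=weight_key)
        return part, _make_clusters(g, assignment)

    # level-0 state
    adj: dict = {n: {} for n in nodes}
    for (u, v), w in weights.items():
        if u == v:
            continue
        adj[u][v] = adj[u].get(v, 0.0) + w
        adj[v][u] = adj[v].get(u, 0.0) + w
    selfw: dict = {}
    node_to_current = {n: n for n in nodes}

    rng = np.random.default_rng(node_order_seed)
    q_prev = modularity(g, {n: i for i, n in enumerate(nodes)}, weight_key)

    while True:
        order = sorted(adj)
        idx = rng.permutation(len(order))
        order = [order[i] for i in idx]
        comm, improved = _one_level(adj, selfw, m, order, tol)
        if not improved:
            break
        # flatten assignment to original nodes
        node_to_current = {n: comm[cur] for n, cur in node_to_current.items()}
        q_now = modularity(g, node_to_current, weight_key)
        # contract communities into super-nodes
        new_adj: dict = {c: {} for c in set(comm.values())}
        new_selfw: dict = {c: 0.0 for c in new_adj}
        for n, c in comm.items():
            new_selfw[c] += selfw.get(n, 0.0)
        for u in adj:
            for v, w in adj[u].items():
                if u >= v:  # nodes at one level are same-typed; visit pairs once
                    continue
                cu, cv = comm[u], comm[v]
                if cu == cv:
                    new_selfw[cu] += w
                else:
                    new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
                    new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
        adj, selfw = new_adj, new_selfw
        if q_now - q_prev <= tol:
            q_prev = max(q_prev, q_now)
            break
        q_prev = q_now

    # renumber labels contiguously, by smallest member node
    groups: dict[int, list] = {}
    for n, c in node_to_current.items():
        groups.setdefault(c, []).append(n)
    ordered = sorted(groups.values(), key=lambda ns: min(ns))
    assignment = {n: i for i, ns in enumerate(ordered) for n in ns}
    q_final = modularity(g, assignment, weight_key)
    part = Partition(assignment=assignment, Q=q_final, m=m, weight_key=weight_key)
    return part, _make_clusters(g, assignment)


def cluster_averages(g, events: frozenset | set) -> tuple[float | None, float | None, int]:
    """Mean fc_pa and if_pa over intra-cluster edges; None when edgeless."""
    graph = _as_graph(g)
    fc_vals, if_vals = [], []
    p_l = 0
    for u, v, d in graph.edges(data=True):
        if u in events and v in events:
            p_l += 1
            if "fc_pa" in d:
                fc_vals.append(d["fc_pa"])
            if "if_pa" in d:
                if_vals.append(d["if_pa"])
    if p_l == 0:
        return None, None, 0
    fc_avg = float(np.mean(fc_vals)) if fc_vals else None
    if_avg = float(np.mean(if_vals)) if if_vals else None
    return fc_avg, if_avg, p_l


def _make_clusters(g, assignment: Mapping[Hashable, int]) -> list[GeneratedCluster]:
    groups: dict[int, set] = {}
    for n, c in assignment.items():
        groups.setdefault(c, set()).add(n)
    clusters = []
    for label in sorted(groups):
        events = frozenset(groups[label])
        fc_avg, if_avg, p_l = cluster_averages(g, events)
        clusters.append(GeneratedCluster(
            label=label, events=events, P_l=p_l,
            fc_pa_avg=fc_avg, if_pa_avg=if_avg))
    return clusters
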