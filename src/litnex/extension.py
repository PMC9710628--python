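"""Turn generated clusters into model extensions.

A generated cluster lives in event space (nodes are events). To connect it to
a model it is *interpreted*: every event (regulator, regulated, sign) becomes
a directed signed edge between entities, giving a small influence graph per
cluster. Two model-support quantities are computed on interpreted clusters:

* node overlap ``NO = |V_cluster ∩ V_model| / |V_cluster| * 100`` — how much
  of the cluster is already in the baseline model;
* *return paths* — directed paths built exclusively from cluster edges whose
  first and last nodes are baseline-model elements. A cluster on a return
  path feeds the model and is fed by it, so adding it yields testable
  feedback rather than hanging inputs.

The selection rule admits a cluster if it wins both literature-support
rankings (lowest mean pair frequency class AND highest mean inverse-frequency
weight) or both model-support checks (node overlap above the threshold,
default 50%, AND membership in at least one return path). Clusters that share
a return path with a selected cluster are merged into the same extension set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from ._canon import EventKey, fold_name
from .clustering import GeneratedCluster
from .model_io import ModelElement, ModelGraph
from .reading_io import EES

__all__ = [
    "InterpretedCluster",
    "ReturnPath",
    "ExtensionResult",
    "interpret_cluster",
    "node_overlap",
    "find_return_paths",
    "select_clusters",
    "extend_model",
    "write_selection_report",
]


@dataclass
class InterpretedCluster:
    """Directed signed entity graph induced by one generated cluster."""

    label: int
    edges: set[EventKey]
    nodes: set[str]
    overlap_nodes: set[str]
    new_nodes: set[str]
    no: float  # node overlap, percent

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for src, dst, sign in self.edges:
            g.add_edge(src, dst, sign=sign)
        return g


@dataclass
class ReturnPath:
    """Directed path of cluster edges starting and ending at model nodes."""

    nodes: tuple[str, ...]
    edges: tuple[EventKey, ...]
    clusters: frozenset[int]


@dataclass
class ExtensionResult:
    selected: list[int]
    reasons: dict[int, list[str]]
    merged_events: set[EventKey]
    interpreted: dict[int, InterpretedCluster]
    paths: list[ReturnPath]
    report: dict = field(default_factory=dict)


def node_overlap(cluster_nodes: set[str], model_nodes: set[str]) -> float:
    """Percentage of cluster entities already present in the model."""
    if not cluster_nodes:
        raise ValueError("node overlap undefined for an empty cluster")
    return len(cluster_nodes & model_nodes) / len(cluster_nodes) * 100.0


def interpret_cluster(cluster: GeneratedCluster, ees: EES,
                      model: ModelGraph) -> InterpretedCluster:
    """Convert an event-space cluster into its entity influence graph."""
    edges: set[EventKey] = set(cluster.events)
    nodes: set[str] = set()
    for src, dst, _sign in edges:
        nodes.add(src)
        nodes.add(dst)
    overlap = nodes & model.V_BM
    return InterpretedCluster(
        label=cluster.label,
        edges=edges,
        nodes=nodes,
        overlap_nodes=overlap,
        new_nodes=nodes - overlap,
        no=node_overlap(nodes, model.V_BM),
    )


def find_return_paths(clusters: list[InterpretedCluster], model: ModelGraph,
                      max_len: int = 6, max_paths: int = 10000) -> list[ReturnPath]:
    """Enumerate simple directed paths of cluster edges between model nodes.

    Interior nodes may be model or new nodes; a path is emitted at every
    model node it reaches (and the walk continues through it). ``max_len``
    bounds the number of edges; ``max_paths`` caps the enumeration.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    union = nx.DiGraph()
    for ic in clusters:
        for src, dst, sign in ic.edges:
            if union.has_edge(src, dst):
                union[src][dst]["clusters"].add(ic.label)
            else:
                union.add_edge(src, dst, clusters={ic.label})
    model_nodes = model.V_BM
    paths: list[ReturnPath] = []

    def dfs(node: str, node_path: list[str], edge_path: list[EventKey]) -> None:
        if len(paths) >= max_paths:
            return
        if edge_path and node in model_nodes:
            clusters_touched = frozenset(
                c for s, d, _ in edge_path for c in union[s][d]["clusters"])
            paths.append(ReturnPath(nodes=tuple(node_path),
                                    edges=tuple(edge_path),
                                    clusters=clusters_touched))
        if len(edge_path) >= max_len:
            return
        if node not in union:
            return
        for nxt in sorted(union.successors(node)):
            if nxt in node_path:
                continue
            # a directed cluster edge may carry either sign; record + and -
            for src, dst, sign in sorted(k for k in _edge_keys(clusters, node, nxt)):
                dfs(nxt, node_path + [nxt], edge_path + [(src, dst, sign)])
                break  # one representative signed edge per hop

    for start in sorted(model_nodes & set(union.nodes)):
        dfs(start, [start], [])
    return paths


def _edge_keys(clusters: list[InterpretedCluster], src: str, dst: str) -> set[EventKey]:
    out = set()
    for ic in clusters:
        for s, d, sign in ic.edges:
            if s == src and d == dst:
                out.add((s, d, sign))
    return out


def select_clusters(
    clusters: list[GeneratedCluster],
    interpreted: dict[int, InterpretedCluster],
    paths: list[ReturnPath],
    no_threshold: float = 50.0,
    element_of_interest: str | None = None,
    ees: EES | None = None,
) -> ExtensionResult:
    """Apply the two-disjunct selection rule and merge path-linked clusters.

    Literature disjunct: a cluster with both the minimum mean pair frequency
    class and the maximum mean inverse-frequency weight over all clusters
    with defined averages (ties all qualify). Model disjunct: node overlap
    strictly above ``no_threshold`` and membership in at least one return
    path. With ``element_of_interest``, clusters regulating and regulated by
    that entity that share a return path are additionally selected.
    """
    scored = [c for c in clusters if c.fc_pa_avg is not None]
    reasons: dict[int, list[str]] = {}

    if scored:
        fc_min = min(c.fc_pa_avg for c in scored)
        if_max = max(c.if_pa_avg for c in scored)
        for c in scored:
            if c.fc_pa_avg == fc_min and c.if_pa_avg == if_max:
                reasons.setdefault(c.label, []).append("literature")

    on_path: dict[int, bool] = {c.label: False for c in clusters}
    for p in paths:
        for label in p.clusters:
            on_path[label] = True
    for c in clusters:
        ic = interpreted.get(c.label)
        if ic is not None and ic.no > no_threshold and on_path.get(c.label):
            reasons.setdefault(c.label, []).append("model-support")

    if element_of_interest:
        eoi = fold_name(element_of_interest)
        upstream = {ic.label for ic in interpreted.values()
                    if any(dst == eoi for _, dst, _ in ic.edges)}
        downstream = {ic.label for ic in interpreted.values()
                      if any(src == eoi for src, _, _ in ic.edges)}
        for p in paths:
            if p.clusters & upstream and p.clusters & downstream:
                for label in p.clusters & (upstream | downstream):
                    reasons.setdefault(label, []).append("element-of-interest")

    selected = set(reasons)
    # merge: clusters sharing a return path with a selected cluster join it
    changed = True
    while changed:
        changed = False
        for p in paths:
            if p.clusters & selected and not p.clusters <= selected:
                for label in p.clusters - selected:
                    selected.add(label)
                    reasons.setdefault(label, []).append("return-path merge")
                changed = True

    merged_events: set[EventKey] = set()
    for c in clusters:
        if c.label in selected:
            merged_events.update(c.events)

    report = {
        "ranking_fc_pa_avg": [
            {"cluster": c.label, "fc_pa_avg": c.fc_pa_avg}
            for c in sorted(scored, key=lambda c: c.fc_pa_avg)],
        "ranking_if_pa_avg": [
            {"cluster": c.label, "if_pa_avg": c.if_pa_avg}
            for c in sorted(scored, key=lambda c: -c.if_pa_avg)],
        "node_overlap": {ic.label: ic.no for ic in interpreted.values()},
        "return_paths": [list(p.nodes) for p in paths],
        "no_threshold": no_threshold,
    }
    if not selected:
        diag = {}
        if scored:
            diag["best_fc_pa_avg"] = min(scored, key=lambda c: c.fc_pa_avg).label
            diag["best_if_pa_avg"] = max(scored, key=lambda c: c.if_pa_avg).label
        if interpreted:
            diag["best_no"] = max(interpreted.values(), key=lambda ic: ic.no).label
        report["diagnostic"] = diag

    return ExtensionResult(
        selected=sorted(selected),
        reasons=reasons,
        merged_events=merged_events,
        interpreted=interpreted,
        paths=paths,
        report=report,
    )


def extend_model(model: ModelGraph, result: ExtensionResult,
                 ees: EES | None = None) -> ModelGraph:
    """Add the merged extension events to a copy of the baseline model.

    Entities absent from the baseline are appended as new elements with the
    suffix "_ext" on their name (database id carried over); each event's
    regulator is appended to the target element's positive or negative
    influence expression. Baseline content is never removed; re-applying the
    same result is a no-op.
    """
    if not result.selected:
        return model.copy()
    extended = model.copy()
    for src, dst, sign in sorted(result.merged_events):
        for key in (src, dst):
            if key not in extended.elements:
                base_name = ees.entity_name(key) if ees else key
                ent_type = ees.entity_type(key) if ees else "other"
                db_id = key if key != fold_name(base_name) else ""
                extended.add_element(ModelElement(
                    name=f"{base_name}_ext", type=ent_type, db_id=db_id,
                    variable=f"{base_name}_ext"), key=key)
        extended.add_edge(src, dst, sign)
    return extended


def write_selection_report(result: ExtensionResult, path: str | Path) -> None:
    payload = dict(result.report)
    payload["selected"] = result.selected
    payload["reasons"] = {str(k): v for k, v in result.reasons.items()}
    payload["merged_events"] = [list(k) for k in sorted(result.merged_events)]
    Path(path).write_text(json.dumps(payload, indent=2))
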