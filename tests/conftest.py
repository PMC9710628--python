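import networkx as nx
import pytest

from litnex._canon import NEGATIVE, POSITIVE
from litnex.model_io import ModelGraph, model_from_edges
from litnex.reading_io import EES, EntityRef, EventRecord, build_ees


def rec(src: str, dst: str, sign: str = POSITIVE, paper: str = "P1",
        evidence: str = "", src_id: str = "", dst_id: str = "") -> EventRecord:
    return EventRecord(
        regulator=EntityRef(src, "protein", src_id),
        regulated=EntityRef(dst, "protein", dst_id),
        sign=sign,
        paper_id=paper,
        evidence=evidence,
    )


@pytest.fixture
def small_ees() -> EES:
    """Three distinct events over two papers: N=5, M=3, f_max=3."""
    return build_ees([
        rec("A", "B", POSITIVE, "P1"),
        rec("A", "B", POSITIVE, "P1"),
        rec("A", "B", POSITIVE, "P2"),
        rec("B", "C", NEGATIVE, "P1"),
        rec("C", "D", POSITIVE, "P2"),
    ])


@pytest.fixture
def tiny_model() -> ModelGraph:
    return model_from_edges([
        ("X", "Y", POSITIVE),
        ("Y", "Z", NEGATIVE),
    ])


def weighted_graph(edges, attr: str = "if_pa") -> nx.Graph:
    """nx.Graph with a single clustering-weight attribute on each edge."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, **{attr: float(w)})
    return g


def two_cliques_graph() -> nx.Graph:
    """Two 4-cliques joined by one unit edge; the canonical community fixture."""
    g = nx.Graph()
    for base in (0, 4):
        for i in range(base, base + 4):
            for j in range(i + 1, base + 4):
                g.add_edge(i, j, if_pa=1.0)
    g.add_edge(3, 4, if_pa=1.0)
    return g
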