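"""Cluster interpretation, node overlap, return paths and the selection rule."""

import pytest

from conftest import rec
from litnex._canon import NEGATIVE, POSITIVE
from litnex.clustering import GeneratedCluster
from litnex.extension import (ExtensionResult, InterpretedCluster, extend_model,
                              find_return_paths, interpret_cluster, node_overlap,
                              select_clusters)
from litnex.model_io import model_from_edges
from litnex.reading_io import build_ees


def _cluster(label, events, fc=1.0, ifv=1.0, p_l=1):
    return GeneratedCluster(label=label, events=frozenset(events),
                            P_l=p_l, fc_pa_avg=fc, if_pa_avg=ifv)


def _interp(clusters, model, records):
    ees = build_ees(records)
    return {c.label: interpret_cluster(c, ees, model) for c in clusters}


class TestInterpret:
    def test_events_become_directed_signed_edges(self, tiny_model):
        c = _cluster(0, [("a", "b", POSITIVE), ("b", "c", NEGATIVE)])
        ees = build_ees([rec("A", "B", POSITIVE), rec("B", "C", NEGATIVE)])
        ic = interpret_cluster(c, ees, tiny_model)
        assert ic.nodes == {"a", "b", "c"}
        dg = ic.to_digraph()
        assert dg["a"]["b"]["sign"] == POSITIVE
        assert dg["b"]["c"]["sign"] == NEGATIVE

    def test_all_entities_in_model_gives_full_overlap(self, tiny_model):
        c = _cluster(0, [("x", "y", POSITIVE)])
        ees = build_ees([rec("X", "Y", POSITIVE)])
        ic = interpret_cluster(c, ees, tiny_model)
        assert ic.no == 100.0 and not ic.new_nodes

    def test_half_overlap(self, tiny_model):
        c = _cluster(0, [("x", "n1", POSITIVE), ("n2", "y", POSITIVE)])
        ees = build_ees([rec("X", "N1", POSITIVE), rec("N2", "Y", POSITIVE)])
        ic = interpret_cluster(c, ees, tiny_model)
        assert ic.no == 50.0
        assert ic.overlap_nodes == {"x", "y"} and ic.new_nodes == {"n1", "n2"}


class TestNodeOverlap:
    def test_disjoint(self):
        assert node_overlap({"a", "b"}, {"x"}) == 0.0

    def test_subset(self):
        assert node_overlap({"a", "b"}, {"a", "b", "c"}) == 100.0

    def test_three_of_five(self):
        assert node_overlap(set("abcde"), set("abcxy")) == 60.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            node_overlap(set(), {"a"})


class TestReturnPaths:
    def test_single_bridge_path(self):
        model = model_from_edges([("X", "Y", POSITIVE)])
        ic = InterpretedCluster(
            label=0, edges={("x", "n1", POSITIVE), ("n1", "y", POSITIVE)},
            nodes={"x", "n1", "y"}, overlap_nodes={"x", "y"},
            new_nodes={"n1"}, no=66.7)
        paths = find_return_paths([ic], model, max_len=4)
        assert any(p.nodes == ("x", "n1", "y") for p in paths)

    def test_no_model_contact_gives_no_paths(self, tiny_model):
        ic = InterpretedCluster(
            label=0, edges={("n1", "n2", POSITIVE)}, nodes={"n1", "n2"},
            overlap_nodes=set(), new_nodes={"n1", "n2"}, no=0.0)
        assert find_return_paths([ic], tiny_model) == []

    def test_path_spanning_two_clusters(self):
        model = model_from_edges([("X", "Y", POSITIVE)])
        ca = InterpretedCluster(label=0, edges={("x", "n1", POSITIVE)},
                                nodes={"x", "n1"}, overlap_nodes={"x"},
                                new_nodes={"n1"}, no=50.0)
        cb = InterpretedCluster(label=1, edges={("n1", "y", NEGATIVE)},
                                nodes={"n1", "y"}, overlap_nodes={"y"},
                                new_nodes={"n1"}, no=50.0)
        paths = find_return_paths([ca, cb], model)
        spanning = [p for p in paths if p.clusters == frozenset({0, 1})]
        assert spanning and spanning[0].nodes == ("x", "n1", "y")

    def test_interior_model_nodes_allowed(self):
        # a path may pass through a model node and continue beyond it
        model = model_from_edges([("M1", "M2", POSITIVE), ("M3", "M1", POSITIVE)])
        ic = InterpretedCluster(
            label=0,
            edges={("m1", "n1", POSITIVE), ("n1", "m2", POSITIVE),
                   ("m2", "n2", NEGATIVE), ("n2", "m3", POSITIVE)},
            nodes={"m1", "m2", "m3", "n1", "n2"},
            overlap_nodes={"m1", "m2", "m3"}, new_nodes={"n1", "n2"}, no=60.0)
        paths = find_return_paths([ic], model, max_len=6)
        assert any(p.nodes == ("m1", "n1", "m2", "n2", "m3") for p in paths)

    def test_every_path_satisfies_invariants(self, tiny_model):
        ic = InterpretedCluster(
            label=0,
            edges={("x", "n1", POSITIVE), ("n1", "y", POSITIVE),
                   ("y", "n2", NEGATIVE), ("n2", "x", POSITIVE)},
            nodes={"x", "y", "n1", "n2"}, overlap_nodes={"x", "y"},
            new_nodes={"n1", "n2"}, no=50.0)
        paths = find_return_paths([ic], tiny_model, max_len=5)
        assert paths
        for p in paths:
            assert p.nodes[0] in tiny_model.V_BM
            assert p.nodes[-1] in tiny_model.V_BM
            assert len(p.edges) == len(p.nodes) - 1
            for (s, d, _), a, b in zip(p.edges, p.nodes, p.nodes[1:]):
                assert (s, d) == (a, b)
            assert len(set(p.nodes)) == len(p.nodes)

    def test_max_len_bounds_path_length(self, tiny_model):
        ic = InterpretedCluster(
            label=0,
            edges={("x", "n1", POSITIVE), ("n1", "n2", POSITIVE),
                   ("n2", "n3", POSITIVE), ("n3", "y", POSITIVE)},
            nodes={"x", "n1", "n2", "n3", "y"}, overlap_nodes={"x", "y"},
            new_nodes={"n1", "n2", "n3"}, no=40.0)
        assert find_return_paths([ic], tiny_model, max_len=3) == []
        assert find_return_paths([ic], tiny_model, max_len=4) != []


class TestSelectionRule:
    def _records(self):
        return [rec("X", "N1", POSITIVE), rec("N2", "Y", POSITIVE),
                rec("N3", "N4", POSITIVE)]

    def test_literature_disjunct_selects_double_winner(self, tiny_model):
        clusters = [_cluster(0, [("x", "n1", POSITIVE)], fc=0.5, ifv=9.0),
                    _cluster(1, [("n3", "n4", POSITIVE)], fc=2.0, ifv=1.0)]
        interp = _interp(clusters, tiny_model, self._records())
        result = select_clusters(clusters, interp, paths=[])
        assert result.selected == [0]
        assert result.reasons[0] == ["literature"]

    def test_model_support_disjunct(self, tiny_model):
        # mediocre literature scores, but high overlap and on a return path
        clusters = [_cluster(0, [("x", "n1", POSITIVE), ("n1", "y", POSITIVE)],
                             fc=2.0, ifv=1.0),
                    _cluster(1, [("n3", "n4", POSITIVE)], fc=1.0, ifv=5.0)]
        ees = build_ees([rec("X", "N1", POSITIVE), rec("N1", "Y", POSITIVE),
                         rec("N3", "N4", POSITIVE)])
        interp = {c.label: interpret_cluster(c, ees, tiny_model) for c in clusters}
        paths = find_return_paths(list(interp.values()), tiny_model)
        result = select_clusters(clusters, interp, paths)
        assert 0 in result.selected
        assert "model-support" in result.reasons[0]

    def test_split_criteria_select_nothing(self, tiny_model):
        # cluster 0 wins fc but loses if; cluster 1 the reverse; no paths
        clusters = [_cluster(0, [("n3", "n4", POSITIVE)], fc=0.5, ifv=1.0),
                    _cluster(1, [("n1", "n2", POSITIVE)], fc=2.0, ifv=5.0)]
        records = [rec("N3", "N4", POSITIVE), rec("N1", "N2", POSITIVE)]
        interp = _interp(clusters, tiny_model, records)
        result = select_clusters(clusters, interp, paths=[])
        assert result.selected == []
        assert "diagnostic" in result.report
        assert result.report["diagnostic"]["best_fc_pa_avg"] == 0
        assert result.report["diagnostic"]["best_if_pa_avg"] == 1

    def test_high_overlap_without_path_not_selected(self, tiny_model):
        clusters = [_cluster(0, [("x", "y", POSITIVE)], fc=2.0, ifv=1.0),
                    _cluster(1, [("n1", "n2", POSITIVE)], fc=1.0, ifv=1.0)]
        records = [rec("X", "Y", POSITIVE), rec("N1", "N2", POSITIVE)]
        interp = _interp(clusters, tiny_model, records)
        # cluster 0: NO=100 but no return path provided; literature split
        result = select_clusters(clusters, interp, paths=[])
        assert 0 not in result.selected

    def test_path_sharing_clusters_are_merged(self, tiny_model):
        clusters = [_cluster(0, [("x", "n1", POSITIVE)], fc=0.5, ifv=9.0),
                    _cluster(1, [("n1", "y", POSITIVE)], fc=2.0, ifv=1.0)]
        ees = build_ees([rec("X", "N1", POSITIVE), rec("N1", "Y", POSITIVE)])
        interp = {c.label: interpret_cluster(c, ees, tiny_model) for c in clusters}
        paths = find_return_paths(list(interp.values()), tiny_model)
        result = select_clusters(clusters, interp, paths)
        assert result.selected == [0, 1]
        assert "return-path merge" in result.reasons[1]

    def test_single_scored_cluster_trivially_selected(self, tiny_model):
        clusters = [_cluster(0, [("n1", "n2", POSITIVE)], fc=1.5, ifv=2.5)]
        interp = _interp(clusters, tiny_model, [rec("N1", "N2", POSITIVE)])
        result = select_clusters(clusters, interp, paths=[])
        assert result.selected == [0]

    def test_selection_invariant_under_cluster_order(self, tiny_model):
        clusters = [_cluster(0, [("x", "n1", POSITIVE)], fc=0.5, ifv=9.0),
                    _cluster(1, [("n3", "n4", POSITIVE)], fc=2.0, ifv=1.0),
                    _cluster(2, [("n1", "n2", POSITIVE)], fc=1.0, ifv=3.0)]
        records = self._records() + [rec("N1", "N2", POSITIVE)]
        interp = _interp(clusters, tiny_model, records)
        a = select_clusters(clusters, interp, paths=[])
        b = select_clusters(list(reversed(clusters)), interp, paths=[])
        assert a.selected == b.selected

    def test_undefined_averages_only_qualify_via_model_support(self, tiny_model):
        lone = GeneratedCluster(label=0, events=frozenset([("x", "y", POSITIVE)]),
                                P_l=0, fc_pa_avg=None, if_pa_avg=None)
        interp = _interp([lone], tiny_model, [rec("X", "Y", POSITIVE)])
        no_paths = select_clusters([lone], interp, paths=[])
        assert no_paths.selected == []
        paths = find_return_paths(list(interp.values()), tiny_model)
        with_paths = select_clusters([lone], interp, paths)
        assert with_paths.selected == [0]


class TestExtendModel:
    def _setup(self, tiny_model):
        records = [rec("X", "N1", POSITIVE, "P1"), rec("N1", "Y", NEGATIVE, "P1")]
        ees = build_ees(records)
        clusters = [_cluster(0, list(ees.events), fc=0.5, ifv=2.0)]
        interp = {0: interpret_cluster(clusters[0], ees, tiny_model)}
        paths = find_return_paths(list(interp.values()), tiny_model)
        result = select_clusters(clusters, interp, paths)
        return ees, result

    def test_new_entities_added_with_ext_suffix(self, tiny_model):
        ees, result = self._setup(tiny_model)
        extended = extend_model(tiny_model, result, ees=ees)
        assert "n1" in extended.V_BM
        assert extended.elements["n1"].name == "N1_ext"
        assert ("x", "n1", POSITIVE) in extended.E_BM
        assert ("n1", "y", NEGATIVE) in extended.E_BM

    def test_baseline_edges_untouched(self, tiny_model):
        ees, result = self._setup(tiny_model)
        extended = extend_model(tiny_model, result, ees=ees)
        assert tiny_model.E_BM <= extended.E_BM

    def test_idempotent(self, tiny_model):
        ees, result = self._setup(tiny_model)
        once = extend_model(tiny_model, result, ees=ees)
        twice = extend_model(once, result, ees=ees)
        assert once.E_BM == twice.E_BM
        assert {k: el.pos_expr for k, el in once.elements.items()} == \
               {k: el.pos_expr for k, el in twice.elements.items()}

    def test_cluster_inside_model_adds_only_missing_edges(self, tiny_model):
        records = [rec("X", "Y", POSITIVE, "P1"), rec("Y", "X", POSITIVE, "P1")]
        ees = build_ees(records)
        clusters = [_cluster(0, list(ees.events), fc=0.5, ifv=2.0)]
        interp = {0: interpret_cluster(clusters[0], ees, tiny_model)}
        result = select_clusters(clusters, interp, paths=[])
        extended = extend_model(tiny_model, result, ees=ees)
        assert extended.V_BM == tiny_model.V_BM
        assert extended.E_BM == tiny_model.E_BM | {("y", "x", POSITIVE)}

    def test_empty_selection_returns_model_unchanged(self, tiny_model):
        result = ExtensionResult(selected=[], reasons={}, merged_events=set(),
                                 interpreted={}, paths=[])
        extended = extend_model(tiny_model, result)
        assert extended.E_BM == tiny_model.E_BM
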