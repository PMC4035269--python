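"""Graph construction, restriction, components, and composition summaries."""

import warnings

import pytest
from hypothesis import given, settings, strategies as st

from proteaseweb import (
    CLEAVAGE,
    INHIBITION,
    CleavageRecord,
    InhibitionRecord,
    build_graph,
    class_interaction_matrix,
    composition_stats,
    largest_connected_component,
    network_overlap,
    restrict_to_protease_web,
)

from conftest import inhibitor, protease, substrate, web_from_arcs


class TestBuildGraph:
    def test_duplicate_rows_collapse_with_multiplicity(self):
        web = build_graph(
            [protease("P1"), substrate("S1")],
            [CleavageRecord(protease_acc="P1", substrate_acc="S1"),
             CleavageRecord(protease_acc="P1", substrate_acc="S1")],
            [])
        assert web.n_edges == 1
        assert web.g["P1"]["S1"][CLEAVAGE]["multiplicity"] == 2

    def test_reciprocal_cleavage_and_inhibition(self):
        """A protease can cleave the very inhibitor that inhibits it:
        two stored edges, opposite directions, different kinds."""
        web = build_graph(
            [protease("P1", cat="S"), inhibitor("I1")],
            [CleavageRecord(protease_acc="P1", substrate_acc="I1")],
            [InhibitionRecord(inhibitor_acc="I1", protease_acc="P1")])
        assert set(web.edges()) == {("P1", "I1", CLEAVAGE),
                                    ("I1", "P1", INHIBITION)}

    def test_nodes_require_edge_participation(self):
        web = build_graph(
            [protease("P1"), substrate("S1"), substrate("S2")],
            [CleavageRecord(protease_acc="P1", substrate_acc="S1")], [])
        assert set(web.nodes()) == {"P1", "S1"}

    def test_empty_edge_set_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            web = build_graph([protease("P1")], [], [])
        assert web.n_nodes == 0

    def test_synthetic_totals_match_report(self, default_web):
        prot, clv, inh, report = (*default_web["tables"],
                                  default_web["report"])
        web = default_web["web"]
        assert web.n_edges == (report.table_row_counts["cleavages"]
                               + report.table_row_counts["inhibitions"])
        assert sum(report.realized_out_degrees.values()) == web.n_edges


class TestRestrictToProteaseWeb:
    def make_web(self):
        return build_graph(
            [protease("P1"), protease("P2"), inhibitor("I1"),
             substrate("S1"), substrate("S2"), substrate("S3")],
            [CleavageRecord(protease_acc="P1", substrate_acc="S1"),
             CleavageRecord(protease_acc="P1", substrate_acc="P2"),
             CleavageRecord(protease_acc="P2", substrate_acc="S2"),
             CleavageRecord(protease_acc="P2", substrate_acc="S3")],
            [InhibitionRecord(inhibitor_acc="I1", protease_acc="P1")])

    def test_keeps_merops_nodes_only(self):
        pw = restrict_to_protease_web(self.make_web())
        assert set(pw.nodes()) == {"P1", "P2", "I1"}
        assert set(pw.edges()) == {("P1", "P2", CLEAVAGE),
                                   ("I1", "P1", INHIBITION)}

    def test_no_merops_nodes_gives_empty_graph(self):
        web = build_graph(
            [protease("P1"), substrate("S1")],
            [CleavageRecord(protease_acc="P1", substrate_acc="S1")], [])
        web.g.nodes["P1"]["merops_id"] = ""  # strip annotation
        assert restrict_to_protease_web(web).n_nodes == 0

    def test_idempotent_and_monotone(self, default_web):
        once = restrict_to_protease_web(default_web["web"])
        twice = restrict_to_protease_web(once)
        assert twice == once
        assert once.n_nodes <= default_web["web"].n_nodes
        assert once.n_edges <= default_web["web"].n_edges

    def test_synthetic_retains_proteases_and_inhibitors(self, default_web):
        pw = restrict_to_protease_web(default_web["web"])
        assert all(acc[0] in "PI" for acc in pw.nodes())


class TestLargestConnectedComponent:
    def test_two_disjoint_chains(self):
        web = web_from_arcs([("A", "B"), ("B", "C"), ("X", "Y")])
        lcc = largest_connected_component(web)
        assert set(lcc.nodes()) == {"A", "B", "C"}

    def test_strong_mode_on_cycle(self):
        web = web_from_arcs([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        lcc = largest_connected_component(web, mode="strong")
        assert lcc.n_nodes == 4

    def test_weak_mode_invariant_under_reversal(self):
        arcs = [("A", "B"), ("C", "B"), ("D", "E")]
        size = largest_connected_component(web_from_arcs(arcs)).n_nodes
        rev = largest_connected_component(
            web_from_arcs([(v, u) for u, v in arcs])).n_nodes
        assert size == rev == 3

    def test_empty_graph_raises(self):
        from proteaseweb import ProteaseWebGraph
        with pytest.raises(ValueError):
            largest_connected_component(ProteaseWebGraph())

    def test_tie_breaks_lexicographically(self):
        web = web_from_arcs([("B", "C"), ("X", "Y")])
        lcc = largest_connected_component(web)
        assert set(lcc.nodes()) == {"B", "C"}

    def test_contains_planted_core(self, default_web):
        lcc = default_web["lcc"]
        assert set(default_web["report"].core_members) <= set(lcc.nodes())


class TestCompositionStats:
    def test_single_cleavage_edge(self):
        web = build_graph(
            [protease("P1"), substrate("S1")],
            [CleavageRecord(protease_acc="P1", substrate_acc="S1")], [])
        stats = composition_stats(web)
        assert stats.n_proteases_with_substrates == 1
        assert stats.n_inhibitors_with_targets == 0
        assert stats.substrate_role_fractions == (0.0, 0.0, 1.0)

    def test_all_targets_proteases(self):
        web = build_graph(
            [protease("P1"), protease("P2")],
            [CleavageRecord(protease_acc="P1", substrate_acc="P2")], [])
        assert composition_stats(web).substrate_role_fractions == (1.0, 0, 0)

    def test_fractions_sum_to_one_and_lcc_bound(self, default_web):
        stats = composition_stats(default_web["web"])
        assert abs(sum(stats.substrate_role_fractions) - 1.0) < 1e-12
        assert stats.lcc_size <= stats.n_nodes

    def test_invariant_under_relabeling(self, default_web):
        import networkx as nx
        web = default_web["web"]
        mapping = {n: f"Z{i:05d}" for i, n in enumerate(sorted(web.nodes()))}
        relabeled = web.copy()
        relabeled.g = nx.relabel_nodes(relabeled.g, mapping)
        a, b = composition_stats(web), composition_stats(relabeled)
        assert (a.n_nodes, a.n_edges, a.n_proteases_with_substrates,
                a.n_inhibitors_with_targets, a.lcc_size,
                a.substrate_role_fractions) == (
            b.n_nodes, b.n_edges, b.n_proteases_with_substrates,
            b.n_inhibitors_with_targets, b.lcc_size,
            b.substrate_role_fractions)


class TestClassInteractionMatrix:
    def test_single_cross_class_cleavage(self):
        web = build_graph(
            [protease("P1", cat="M"), protease("P2", cat="S")],
            [CleavageRecord(protease_acc="P1", substrate_acc="P2")], [])
        summary = class_interaction_matrix(web)
        assert summary.matrix == {("M", "S", CLEAVAGE): 1}

    def test_unclassed_edges_fall_in_remainder(self):
        web = build_graph(
            [protease("P1", cat="M"), substrate("S1")],
            [CleavageRecord(protease_acc="P1", substrate_acc="S1")], [])
        summary = class_interaction_matrix(web)
        assert summary.matrix == {}
        assert summary.remainder == {CLEAVAGE: 1}

    def test_cell_sums_match_brute_force(self, default_web):
        """Matrix totals equal a direct tally over classed edges."""
        web = default_web["lcc"]
        summary = class_interaction_matrix(web)
        g = web.g
        classed = 0
        for u, v, k in g.edges(keys=True):
            from proteaseweb.graph import _source_class, _target_class
            if (_source_class(g.nodes[u], k) is not None
                    and _target_class(g.nodes[v]) is not None):
                classed += 1
        assert sum(summary.matrix.values()) == classed
        assert classed + sum(summary.remainder.values()) == web.n_edges


class TestNetworkOverlap:
    def test_identity(self, default_web):
        web = default_web["lcc"]
        identity = [(n, n) for n in web.nodes()]
        res = network_overlap(web, web, identity)
        assert res["fraction_a"] == res["fraction_b"] == 1.0

    def test_disjoint(self):
        """No mapped pair of b's single edge lands on an edge of a."""
        a = web_from_arcs([("A", "B")])
        b = web_from_arcs([("C", "D")])
        res = network_overlap(a, b, [("B", "C"), ("A", "D")])
        assert res["shared_in_a"] == res["shared_in_b"] == 0

    def test_empty_map_warns_zero(self):
        a = web_from_arcs([("A", "B")])
        with pytest.warns(UserWarning):
            res = network_overlap(a, a, [])
        assert res["shared_in_a"] == 0

    def test_many_to_one_matches_pair_expansion(self):
        """2-to-1 ortholog mapping counted by explicit pair enumeration."""
        a = web_from_arcs([("A1", "A2"), ("A2", "A3")])
        b = web_from_arcs([("B1", "B2"), ("B2", "B3"), ("B3", "B1")])
        # B1 and B3 both map to A1; B2 -> A2
        omap = [("A1", "B1"), ("A1", "B3"), ("A2", "B2")]
        res = network_overlap(a, b, omap)
        # expansion: (B1,B2)->(A1,A2) hit; (B2,B3)->(A2,A1) miss;
        # (B3,B1)->(A1,A1) miss
        assert res["shared_in_b"] == 1
        assert res["shared_in_a"] == 1
        assert res["fraction_b"] == pytest.approx(1 / 3)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 7), st.integers(0, 7)),
                min_size=1, max_size=25))
def test_build_is_idempotent_on_edge_set(pairs):
    """Rebuilding from the built edge set reproduces it exactly."""
    arcs = [(f"P{u}", f"P{v}") for u, v in pairs]
    web = web_from_arcs(arcs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        web2 = web_from_arcs([(u, v) for u, v, _ in web.edges()],
                             nodes=web.nodes())
    assert set(web2.edges()) == set(web.edges())
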