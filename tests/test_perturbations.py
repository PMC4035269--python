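"""Perturbation-robustness suite: filters, knockouts, connector search,
and random edge-deletion sweeps."""

import numpy as np
import pytest

from proteaseweb import (
    CLEAVAGE,
    CleavageRecord,
    InhibitionRecord,
    PerturbationConfig,
    build_graph,
    combinatorial_knockout,
    high_confidence_filter,
    iterative_connector_search,
    random_edge_removal,
    reachability,
    reachability_bimodality,
    remove_inhibitor_cleavages,
    single_node_knockouts,
)

from conftest import inhibitor, protease, web_from_arcs


def two_cascade_bridge_web():
    """Two protease chains joined only through a serpin bridge: the chains'
    tails cleave the serpin, the serpin inhibits both chain heads."""
    proteins = [protease(f"A{i}", cat="S") for i in range(3)]
    proteins += [protease(f"B{i}", cat="S") for i in range(3)]
    proteins.append(inhibitor("BR"))
    cleavages = [CleavageRecord(protease_acc=f"{c}{i}",
                                substrate_acc=f"{c}{i + 1}",
                                physiological_relevance="yes")
                 for c in "AB" for i in range(2)]
    cleavages += [CleavageRecord(protease_acc="A2", substrate_acc="BR",
                                 physiological_relevance="yes"),
                  CleavageRecord(protease_acc="B2", substrate_acc="BR",
                                 physiological_relevance="yes")]
    inhibitions = [InhibitionRecord(inhibitor_acc="BR", protease_acc="A0"),
                   InhibitionRecord(inhibitor_acc="BR", protease_acc="B0")]
    return build_graph(proteins, cleavages, inhibitions)


class TestHighConfidenceFilter:
    def test_all_relevant_with_inhibitions_is_identity(self):
        web = two_cascade_bridge_web()
        # promote every cleavage to relevance yes
        for u, v, k, d in web.g.edges(keys=True, data=True):
            if k == CLEAVAGE:
                d["physiological_relevance"] = "yes"
        res = high_confidence_filter(web, keep_inhibitions=True)
        assert res.auc_ratio == pytest.approx(1.0)
        assert res.removed_edge_count == 0

    def test_removed_count_matches_tally(self):
        web = two_cascade_bridge_web()
        res = high_confidence_filter(web, keep_inhibitions=False)
        non_yes = sum(1 for *_, d in web.g.edges(keys=True, data=True)
                      if d.get("physiological_relevance") not in (None, "yes"))
        n_inh = len(web.edges(kind="inhibition"))
        assert res.removed_edge_count == non_yes + n_inh

    def test_bridging_inhibitor_drives_connectivity(self):
        """Dropping inhibitions disconnects the two cascades: the plain
        high-confidence network is far less reachable than hc+i."""
        web = two_cascade_bridge_web()
        hc = high_confidence_filter(web, keep_inhibitions=False)
        hci = high_confidence_filter(web, keep_inhibitions=True)
        assert hc.auc_ratio < 0.5 * hci.auc_ratio

    def test_node_set_frozen(self):
        web = two_cascade_bridge_web()
        res = high_confidence_filter(web, keep_inhibitions=False)
        assert set(res.web.nodes()) == set(web.nodes())


class TestRemoveInhibitorCleavages:
    @pytest.mark.parametrize("p_class,removed", [
        ("S", True),   # serine protease cleaving a serpin: trapped
        ("C", True),   # cysteine protease: also trapped
        ("M", False),  # metalloprotease inactivates the serpin instead
        ("A", False),
    ])
    def test_serpin_cleavage_rule(self, p_class, removed):
        web = build_graph(
            [protease("P1", cat=p_class), inhibitor("SER", classes=("S",))],
            [CleavageRecord(protease_acc="P1", substrate_acc="SER")], [])
        res = remove_inhibitor_cleavages(web)
        assert (res.removed_edge_count == 1) is removed

    @pytest.mark.parametrize("p_class", ["S", "C", "M", "A", "T"])
    def test_trap_inhibitor_cleavage_always_removed(self, p_class):
        web = build_graph(
            [protease("P1", cat=p_class),
             inhibitor("A2M", classes=("broad",), trap=True)],
            [CleavageRecord(protease_acc="P1", substrate_acc="A2M")], [])
        assert remove_inhibitor_cleavages(web).removed_edge_count == 1

    def test_inhibition_edges_untouched(self):
        web = two_cascade_bridge_web()
        res = remove_inhibitor_cleavages(web)
        assert (len(res.web.edges(kind="inhibition"))
                == len(web.edges(kind="inhibition")))


class TestSingleNodeKnockouts:
    def test_edgeless_graph_all_equal(self):
        web = web_from_arcs([], nodes=list("ABCD"))
        results = single_node_knockouts(web)
        assert len({r.auc for r in results}) == 1

    def test_bridge_removal_costs_most(self):
        web = two_cascade_bridge_web()
        results = {r.label.split()[-1]: r for r in single_node_knockouts(web)}
        worst = min(results, key=lambda n: results[n].auc)
        assert worst == "BR"

    def test_normalized_against_frozen_reference(self):
        web = two_cascade_bridge_web()
        n = web.n_nodes
        for r in single_node_knockouts(web):
            assert r.auc == pytest.approx(
                sum(r.profile.counts.values()) / n ** 2)


class TestIterativeConnectorSearch:
    def test_chain_removes_middle_first(self):
        web = web_from_arcs([("A", "B"), ("B", "C")])
        order, _ = iterative_connector_search(web, 1)
        assert order == ["B"]

    def test_k1_is_global_argmax(self, default_web):
        from proteaseweb import betweenness
        web = default_web["lcc"]
        btw = betweenness(web)
        best = max(btw.values())
        expected = min(n for n, b in btw.items() if b == best)
        order, _ = iterative_connector_search(web, 1)
        assert order == [expected]

    def test_full_dismantling(self):
        web = web_from_arcs([("A", "B"), ("B", "C")])
        order, steps = iterative_connector_search(web, 3)
        assert sorted(order) == ["A", "B", "C"]
        assert steps[-1].auc == 0.0

    def test_recovers_both_planted_bridges(self):
        """Four protease chains joined in parallel through two serpin
        bridges: the bridges carry every inter-chain shortest path and
        are removed first."""
        chains = "ABCD"
        web = build_graph(
            [protease(f"{c}{i}", cat="S") for c in chains for i in range(3)]
            + [inhibitor("BR"), inhibitor("BS")],
            [CleavageRecord(protease_acc=f"{c}{i}",
                            substrate_acc=f"{c}{i + 1}")
             for c in chains for i in range(2)]
            + [CleavageRecord(protease_acc=f"{c}2", substrate_acc=b)
               for c in chains for b in ("BR", "BS")],
            [InhibitionRecord(inhibitor_acc=b, protease_acc=f"{c}0")
             for c in chains for b in ("BR", "BS")])
        order, _ = iterative_connector_search(web, 2)
        assert set(order) == {"BR", "BS"}


class TestCombinatorialKnockout:
    def test_single_member_leave_one_in_is_identity(self):
        web = two_cascade_bridge_web()
        results = combinatorial_knockout(web, ["BR"])
        keep = results[1]
        assert keep.auc_ratio == pytest.approx(1.0)
        assert keep.removed_node_count == 0

    def test_all_removed_not_better_than_any_leave_one_in(self, default_web):
        web = default_web["lcc"]
        bridges = default_web["report"].bridge_nodes
        results = combinatorial_knockout(web, bridges)
        all_removed = results[0]
        assert all(all_removed.auc <= r.auc + 1e-12 for r in results[1:])

    def test_unknown_accession(self):
        with pytest.raises(KeyError):
            combinatorial_knockout(two_cascade_bridge_web(), ["NOPE"])

    def test_planted_bridges_carry_bimodality(self, default_web):
        """Removing every planted bridge destroys the bimodal reachability
        signature; keeping any single bridge preserves it."""
        web = default_web["lcc"]
        bridges = default_web["report"].bridge_nodes
        results = combinatorial_knockout(web, bridges)
        assert reachability_bimodality(results[0].profile)[0] is False
        for r in results[1:]:
            assert reachability_bimodality(r.profile)[0] is True


class TestRandomEdgeRemoval:
    def test_exact_removal_counts(self, default_web):
        web = default_web["lcc"]
        cfg = PerturbationConfig(edge_removal_fractions=(0.25,), reps=3,
                                 seed=1)
        sweep = random_edge_removal(web, cfg)
        assert sweep[0.25]["removed_per_draw"] == int(0.25 * web.n_edges)

    def test_worst_not_above_mean_not_above_original(self, default_web):
        web = default_web["lcc"]
        from proteaseweb import frozen_auc
        auc0 = frozen_auc(reachability(web))
        cfg = PerturbationConfig(reps=5, seed=0)
        sweep = random_edge_removal(web, cfg)
        for f, res in sweep.items():
            assert res["worst_auc"] <= res["mean_auc"] + 1e-12
            assert res["mean_auc"] <= auc0 + 1e-12

    def test_deterministic_under_seed(self, default_web):
        web = default_web["lcc"]
        cfg = PerturbationConfig(edge_removal_fractions=(0.2,), reps=4, seed=9)
        a = random_edge_removal(web, cfg)
        b = random_edge_removal(web, cfg)
        assert a[0.2]["aucs"] == b[0.2]["aucs"]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            PerturbationConfig(edge_removal_fractions=(1.0,))


def test_no_perturbation_increases_reachability(default_web):
    """Every suite member only deletes, so per-node reachability is
    non-increasing versus the original network."""
    web = default_web["lcc"]
    before = reachability(web).counts
    variants = [
        high_confidence_filter(web, keep_inhibitions=True),
        high_confidence_filter(web, keep_inhibitions=False),
        remove_inhibitor_cleavages(web),
    ]
    variants += combinatorial_knockout(
        web, default_web["report"].bridge_nodes[:3])
    for res in variants:
        for node, r in res.profile.counts.items():
            assert r <= before[node]
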