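"""Shared fixtures: hand-built toy webs, random-graph helpers, and the
independent brute-force oracles the metric tests compare against."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from proteaseweb import (
    CleavageRecord,
    InhibitionRecord,
    ProteaseWebGraph,
    ProteinRecord,
    SyntheticWebParams,
    build_graph,
    generate_web,
    largest_connected_component,
    records_from_frames,
    restrict_to_protease_web,
)


def protease(acc, cat="M", **kw):
    return ProteinRecord(accession=acc, gene_name=f"GN_{acc}",
                         merops_id=f"{cat}1.{acc}", roles=frozenset({"protease"}),
                         catalytic_class=cat, **kw)


def inhibitor(acc, classes=("S",), trap=False):
    return ProteinRecord(accession=acc, gene_name=f"GN_{acc}",
                         merops_id=f"I1.{acc}",
                         roles=frozenset({"inhibitor"}),
                         inhibitor_classes=frozenset(classes),
                         trap_inhibitor=trap)


def substrate(acc):
    return ProteinRecord(accession=acc, gene_name=f"GN_{acc}",
                         roles=frozenset({"substrate_only"}))


def web_from_arcs(arcs, kind="cleavage", nodes=()):
    """Minimal web whose nodes are generic proteases, for metric tests.

    ``nodes`` adds isolated proteases that take part in no edge.
    """
    accs = sorted(set(nodes) | {x for arc in arcs for x in arc})
    proteins = {a: protease(a) for a in accs}
    if kind != "cleavage":
        raise ValueError(kind)
    cl = [CleavageRecord(protease_acc=u, substrate_acc=v) for u, v in arcs]
    import warnings as _warnings
    with _warnings.catch_warnings():
        if not cl:
            _warnings.simplefilter("ignore")
        web = build_graph(list(proteins.values()), cl, [])
    for a in accs:
        if a not in web.g:
            web.g.add_node(a, **proteins[a].to_node_attrs())
    return web


def arcs_graph(arcs, n=None):
    g = nx.DiGraph()
    if n is not None:
        g.add_nodes_from(range(n))
    g.add_edges_from(arcs)
    return g


def random_digraph(rng, n_max=12, p=None):
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.05, 0.5)) if p is None else p
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g


# -- independent oracles -------------------------------------------------

def closure_reachability(g: nx.DiGraph) -> dict:
    """Transitive-closure row sums via boolean Floyd-Warshall."""
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in g.edges():
        if u != v:
            reach[idx[u], idx[v]] = True
    for k in range(n):
        reach |= np.outer(reach[:, k], reach[k, :])
    return {node: int(reach[idx[node]].sum()) for node in nodes}


def brute_betweenness(g: nx.DiGraph) -> dict:
    """Endpoint-excluded directed betweenness by explicit enumeration of
    every shortest path (BFS distances + recursive path expansion)."""
    nodes = list(g.nodes)
    score = {n: 0.0 for n in nodes}
    for s in nodes:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.successors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt

        def all_paths(t):
            if t == s:
                return [[s]]
            out = []
            for p in g.predecessors(t):
                if p in dist and dist[p] == dist[t] - 1:
                    out.extend(path + [t] for path in all_paths(p))
            return out

        for t in nodes:
            if t == s or t not in dist:
                continue
            paths = all_paths(t)
            w = 1.0 / len(paths)
            for path in paths:
                for inner in path[1:-1]:
                    score[inner] += w
    return score


# -- session-scoped synthetic dataset ------------------------------------

@pytest.fixture(scope="session")
def default_web():
    """Default-parameter synthetic dataset, built once per session."""
    params = SyntheticWebParams(seed=0)
    tables = generate_web(params)
    prot, clv, inh, report = tables
    web = build_graph(*records_from_frames(prot, clv, inh))
    lcc = largest_connected_component(restrict_to_protease_web(web))
    return {"params": params, "tables": (prot, clv, inh), "report": report,
            "web": web, "lcc": lcc}
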