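"""The directed protease-web graph and its construction.

Nodes are proteins; edges are directed regulatory influences, either a
cleavage (protease -> substrate) or an inhibition (inhibitor -> target
protease).  A cleavage and an inhibition between the same ordered pair are
stored as two distinct edges, but all connectivity computations collapse
them to a single arc: reachability depends on direction, not on the
biochemical kind of the influence.  Self-loops (autolysis) are stored but
never contribute to paths; reachability already counts the node itself.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .records import (
    CleavageRecord,
    InhibitionRecord,
    ProteinRecord,
    validate_records,
)

__all__ = [
    "CLEAVAGE",
    "INHIBITION",
    "ProteaseWebGraph",
    "CompositionStats",
    "ClassInteractionSummary",
    "build_graph",
    "restrict_to_protease_web",
    "largest_connected_component",
    "composition_stats",
    "class_interaction_matrix",
    "network_overlap",
]

logger = logging.getLogger(__name__)

CLEAVAGE = "cleavage"
INHIBITION = "inhibition"

#: How cleavage-relevance labels are merged when duplicate rows disagree;
#: the most confident label wins.
_RELEVANCE_RANK = {"yes": 2, "unknown": 1, "no": 0}


class ProteaseWebGraph:
    """Directed multigraph of cleavage and inhibition edges.

    Thin wrapper around :class:`networkx.MultiDiGraph` whose edge keys are
    the edge kinds, so at most one edge is stored per
    ``(source, target, kind)`` triple.  ``provenance`` labels how the graph
    was derived (full network, protease web, LCC, a perturbation label...).
    """

    def __init__(self, g: nx.MultiDiGraph | None = None,
                 provenance: str = "full network"):
        self.g = g if g is not None else nx.MultiDiGraph()
        self.provenance = provenance

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Stored edge count; parallel cleavage+inhibition count as two."""
        return self.g.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.g.nodes)

    def edges(self, kind: str | None = None) -> list[tuple[str, str, str]]:
        out = [(u, v, k) for u, v, k in self.g.edges(keys=True)]
        if kind is not None:
            out = [e for e in out if e[2] == kind]
        return out

    def has_node(self, acc: str) -> bool:
        return acc in self.g

    def record(self, acc: str) -> ProteinRecord:
        return ProteinRecord.from_node_attrs(acc, self.g.nodes[acc])

    def copy(self, provenance: str | None = None) -> "ProteaseWebGraph":
        return ProteaseWebGraph(
            self.g.copy(), provenance if provenance is not None
            else self.provenance)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProteaseWebGraph):
            return NotImplemented
        return (set(self.g.nodes) == set(other.g.nodes)
                and set(self.g.edges(keys=True)) == set(other.g.edges(keys=True)))

    # -- derived views ---------------------------------------------------

    def arc_view(self) -> nx.DiGraph:
        """Simple digraph of unique arcs, self-loops dropped.

        This is the graph all path, reachability, and betweenness
        computations run on: kind-collapsed and loop-free.
        """
        h = nx.DiGraph()
        h.add_nodes_from(self.g.nodes)
        h.add_edges_from(
            (u, v) for u, v in self.g.edges() if u != v)
        return h

    def induced_subgraph(self, nodes, provenance: str) -> "ProteaseWebGraph":
        sub = self.g.subgraph(nodes).copy()
        return ProteaseWebGraph(sub, provenance)


@dataclass(frozen=True)
class CompositionStats:
    """Headline composition counts of a built network.

    ``substrate_role_fractions`` splits cleavage *targets* (with
    multiplicity over cleavage edges) into proteases / inhibitors / other
    substrates; the three fractions sum to 1 whenever cleavages exist.
    """

    n_nodes: int
    n_edges: int
    n_proteases_with_substrates: int
    n_inhibitors_with_targets: int
    lcc_size: int
    substrate_role_fractions: tuple[float, float, float]


@dataclass(frozen=True)
class ClassInteractionSummary:
    """Interaction counts aggregated by (source class, target class, kind).

    Keys of ``matrix`` are ``(source_class, target_class, kind)``.  For
    cleavages the source class is the protease catalytic class and the
    target class is the target's catalytic class or inhibitor class; for
    inhibitions the source class is the inhibitor class.  Edges with an
    unclassed endpoint land in ``remainder`` per kind.
    """

    matrix: dict[tuple[str, str, str], int]
    class_member_counts: dict[str, int]
    remainder: dict[str, int] = field(default_factory=dict)


def build_graph(
    proteins: list[ProteinRecord],
    cleavages: list[CleavageRecord],
    inhibitions: list[InhibitionRecord],
    provenance: str = "full network",
) -> ProteaseWebGraph:
    """Assemble the directed network from validated records.

    Only proteins taking part in at least one cleavage or inhibition (as
    source or target) become nodes.  Duplicate input rows collapse to a
    single stored edge; the multiplicity is kept as an edge attribute and
    logged.  Relevance labels of duplicate cleavage rows are merged
    optimistically (yes > unknown > no).
    """
    validate_records(proteins, cleavages, inhibitions)
    by_acc = {p.accession: p for p in proteins}

    g = nx.MultiDiGraph()
    dup = 0
    for clv in cleavages:
        u, v = clv.protease_acc, clv.substrate_acc
        _ensure_node(g, by_acc[u])
        _ensure_node(g, by_acc[v])
        if g.has_edge(u, v, key=CLEAVAGE):
            dup += 1
            data = g[u][v][CLEAVAGE]
            data["multiplicity"] += 1
            if (_RELEVANCE_RANK[clv.physiological_relevance]
                    > _RELEVANCE_RANK[data["physiological_relevance"]]):
                data["physiological_relevance"] = clv.physiological_relevance
        else:
            g.add_edge(u, v, key=CLEAVAGE, kind=CLEAVAGE,
                       physiological_relevance=clv.physiological_relevance,
                       source=clv.source, multiplicity=1)
    for inh in inhibitions:
        u, v = inh.inhibitor_acc, inh.protease_acc
        _ensure_node(g, by_acc[u])
        _ensure_node(g, by_acc[v])
        if g.has_edge(u, v, key=INHIBITION):
            dup += 1
            g[u][v][INHIBITION]["multiplicity"] += 1
        else:
            g.add_edge(u, v, key=INHIBITION, kind=INHIBITION, multiplicity=1)

    if dup:
        logger.info("collapsed %d duplicate interaction rows", dup)
    if g.number_of_edges() == 0:
        warnings.warn("built an empty protease-web graph (no edges)",
                      stacklevel=2)
    return ProteaseWebGraph(g, provenance)


def _ensure_node(g: nx.MultiDiGraph, rec: ProteinRecord) -> None:
    if rec.accession not in g:
        g.add_node(rec.accession, **rec.to_node_attrs())


def restrict_to_protease_web(web: ProteaseWebGraph) -> ProteaseWebGraph:
    """Drop plain substrates: keep only MEROPS-identified proteins.

    The protease web proper contains only proteases and inhibitors (nodes
    carrying a MEROPS-style ID) that take part in an edge; substrate-only
    nodes, whose reachability is 1 by definition, are removed and the edge
    set is induced.  Idempotent.
    """
    keep = [n for n, d in web.g.nodes(data=True) if d.get("merops_id")]
    return web.induced_subgraph(keep, "protease web")


def largest_connected_component(
    web: ProteaseWebGraph, mode: str = "weak"
) -> ProteaseWebGraph:
    """Induced subgraph on the largest weak (default) or strong component.

    Size ties break on the smallest lexicographic member accession.
    """
    if web.n_nodes == 0:
        raise ValueError("largest_connected_component of an empty graph")
    if mode == "weak":
        comps = nx.weakly_connected_components(web.g)
    elif mode == "strong":
        comps = nx.strongly_connected_components(web.g)
    else:
        raise ValueError(f"mode must be 'weak' or 'strong', got {mode!r}")
    comps = list(comps)
    biggest = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == biggest), key=min)
    return web.induced_subgraph(best, f"LCC ({mode}) of {web.provenance}")


def composition_stats(web: ProteaseWebGraph) -> CompositionStats:
    """Table-1-style composition counts.

    A protease "with substrates" has at least one outgoing cleavage edge;
    an inhibitor "with target proteases" has at least one outgoing
    inhibition edge.
    """
    g = web.g
    prot_with_sub = set()
    inh_with_tgt = set()
    target_roles = Counter()
    for u, v, k in g.edges(keys=True):
        if k == CLEAVAGE:
            prot_with_sub.add(u)
            roles = set(str(g.nodes[v].get("roles", "")).split(";"))
            if "protease" in roles:
                target_roles["protease"] += 1
            elif "inhibitor" in roles:
                target_roles["inhibitor"] += 1
            else:
                target_roles["other"] += 1
        else:
            inh_with_tgt.add(u)
    n_clv = sum(target_roles.values())
    if n_clv:
        fractions = (target_roles["protease"] / n_clv,
                     target_roles["inhibitor"] / n_clv,
                     target_roles["other"] / n_clv)
    else:
        fractions = (0.0, 0.0, 0.0)
    lcc = 0
    if web.n_nodes:
        lcc = max(len(c) for c in nx.weakly_connected_components(g))
    return CompositionStats(
        n_nodes=web.n_nodes,
        n_edges=web.n_edges,
        n_proteases_with_substrates=len(prot_with_sub),
        n_inhibitors_with_targets=len(inh_with_tgt),
        lcc_size=lcc,
        substrate_role_fractions=fractions,
    )


def _source_class(attrs: dict, kind: str) -> str | None:
    if kind == CLEAVAGE:
        c = attrs.get("catalytic_class", "none")
        return None if c in ("none", "", None) else c
    classes = [c for c in str(attrs.get("inhibitor_classes", "")).split(";") if c]
    if not classes:
        return None
    return "broad" if len(classes) > 1 or "broad" in classes else classes[0]


def _target_class(attrs: dict) -> str | None:
    c = attrs.get("catalytic_class", "none")
    if c not in ("none", "", None):
        return c
    classes = [c for c in str(attrs.get("inhibitor_classes", "")).split(";") if c]
    if not classes:
        return None
    return "broad" if len(classes) > 1 or "broad" in classes else classes[0]


def class_interaction_matrix(web: ProteaseWebGraph) -> ClassInteractionSummary:
    """Count interactions between catalytic / inhibitor classes per kind.

    Edges with an endpoint lacking any class annotation are excluded from
    the matrix and tallied in a per-kind remainder bucket.
    """
    g = web.g
    matrix: Counter = Counter()
    remainder: Counter = Counter()
    for u, v, k in g.edges(keys=True):
        sc = _source_class(g.nodes[u], k)
        tc = _target_class(g.nodes[v])
        if sc is None or tc is None:
            remainder[k] += 1
        else:
            matrix[(sc, tc, k)] += 1
    member_counts: Counter = Counter()
    for n, d in g.nodes(data=True):
        c = _target_class(d)
        if c is not None:
            member_counts[c] += 1
    return ClassInteractionSummary(
        matrix=dict(matrix),
        class_member_counts=dict(member_counts),
        remainder=dict(remainder),
    )


def network_overlap(
    web_a: ProteaseWebGraph,
    web_b: ProteaseWebGraph,
    ortholog_map: list[tuple[str, str]],
    match_kind: bool = False,
) -> dict:
    """Count edges of ``web_b`` reflected in ``web_a`` under an ortholog map.

    ``ortholog_map`` rows are ``(a_accession, b_accession)`` pairs, possibly
    many-to-many.  An edge (u, v) of b is shared if any mapped pair
    (u', v') is an edge of a; kind-insensitive unless ``match_kind``.
    Returned dict has shared counts, totals, and fractions per graph.
    """
    if not ortholog_map:
        warnings.warn("empty ortholog map: zero overlap by construction",
                      stacklevel=2)
    b_to_a: dict[str, set[str]] = {}
    for a_acc, b_acc in ortholog_map:
        b_to_a.setdefault(b_acc, set()).add(a_acc)

    def edge_keys(web, kinds):
        if kinds:
            return {(u, v, k) for u, v, k in web.g.edges(keys=True)}
        return {(u, v) for u, v in web.g.edges()}

    a_edges = edge_keys(web_a, match_kind)
    shared_b = set()
    shared_a = set()
    for u, v, k in web_b.g.edges(keys=True):
        for u2 in b_to_a.get(u, ()):
            for v2 in b_to_a.get(v, ()):
                key_a = (u2, v2, k) if match_kind else (u2, v2)
                if key_a in a_edges:
                    shared_b.add((u, v, k) if match_kind else (u, v))
                    shared_a.add(key_a)
    total_a = len(edge_keys(web_a, match_kind))
    total_b = len(edge_keys(web_b, match_kind))
    return {
        "shared_in_a": len(shared_a),
        "shared_in_b": len(shared_b),
        "total_a": total_a,
        "total_b": total_b,
        "fraction_a": len(shared_a) / total_a if total_a else 0.0,
        "fraction_b": len(shared_b) / total_b if total_b else 0.0,
    }
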