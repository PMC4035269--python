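"""Connectivity metrics: reachability, its inverse cumulative curve and
AUC, betweenness, the strongly connected core, and explicit paths.

Reachability of a node X is the number of nodes Y — including X itself —
with a finite directed path X -> Y.  The self-inclusive convention makes an
isolated node's reachability 1 and every member of an n-cycle's
reachability n, matching the model networks the measure is calibrated to.
The network-level summary is the inverse cumulative curve (fraction of
nodes with reachability >= r) and its area normalized by a reference node
count; under the step convention used here the normalized AUC is exactly
mean(reachability) / reference_n.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import ProteaseWebGraph

__all__ = [
    "ReachabilityProfile",
    "TierSummary",
    "PathQueryResult",
    "reachability",
    "inverse_cumulative",
    "auc",
    "frozen_auc",
    "betweenness",
    "strongly_connected_core",
    "path_length_histogram",
    "all_shortest_paths",
    "reachability_bimodality",
    "write_metrics_report",
]


@dataclass(frozen=True)
class ReachabilityProfile:
    """Per-node reachability counts with a normalization reference.

    ``reference_n`` is the node count used to normalize the AUC.  It
    defaults to the profiled graph's own size but is deliberately kept
    separate so a perturbation series can freeze it to the unperturbed
    network's size and report comparable AUC ratios.
    """

    counts: dict[str, int]
    reference_n: int

    def __post_init__(self) -> None:
        if self.reference_n <= 0:
            raise ValueError("reference_n must be positive")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(sorted(self.counts.values()), dtype=int)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.counts.values())))

    @property
    def auc(self) -> float:
        """Normalized area under the inverse cumulative curve.

        Exact rectangle sum; identically mean(reachability)/reference_n.
        """
        return self.mean / self.reference_n


@dataclass(frozen=True)
class TierSummary:
    """Reachability tiers around the strongly connected core.

    All members of the largest strongly connected component share one
    reachability value ``r_core``.  Nodes with strictly greater
    reachability sit upstream (they reach the core but are not reached
    from it); everything else outside the core is downstream.
    """

    r_core: int
    n_core: int
    n_upstream: int
    n_downstream: int

    @property
    def total(self) -> int:
        return self.n_core + self.n_upstream + self.n_downstream


@dataclass(frozen=True)
class PathQueryResult:
    """All minimal-length directed paths between one ordered node pair.

    Each path is a node sequence plus, per step, the tuple of edge kinds
    stored on that arc (a step can carry both a cleavage and an
    inhibition).  ``length`` is None when the target is unreachable.
    """

    source: str
    target: str
    paths: list[tuple[list[str], list[tuple[str, ...]]]] = field(
        default_factory=list)
    length: int | None = None


def _reach_counts(arcs: nx.DiGraph) -> dict[str, int]:
    """Self-inclusive reachability via condensation + bitset DP.

    Condense to the DAG of strongly connected components, then propagate
    reachable-node bitsets in reverse topological order; every member of
    an SCC shares its component's count.
    """
    cond = nx.condensation(arcs)
    index = {n: i for i, n in enumerate(arcs.nodes)}
    bits: dict[int, int] = {}
    for scc in reversed(list(nx.topological_sort(cond))):
        b = 0
        for member in cond.nodes[scc]["members"]:
            b |= 1 << index[member]
        for succ in cond.successors(scc):
            b |= bits[succ]
        bits[scc] = b
    counts: dict[str, int] = {}
    for scc, b in bits.items():
        c = b.bit_count()
        for member in cond.nodes[scc]["members"]:
            counts[member] = c
    return counts


def reachability(
    web: ProteaseWebGraph, reference_n: int | None = None
) -> ReachabilityProfile:
    """Per-node reachability profile of a web (or any directed graph).

    Self-loops never contribute: the node itself is already counted.
    """
    arcs = web.arc_view() if isinstance(web, ProteaseWebGraph) else web
    counts = _reach_counts(arcs)
    n = reference_n if reference_n is not None else arcs.number_of_nodes()
    return ReachabilityProfile(counts=counts, reference_n=n)


def inverse_cumulative(profile: ReachabilityProfile) -> list[tuple[int, float]]:
    """Step points (r, fraction of nodes with reachability >= r).

    One point per observed value, non-increasing in r; the curve is the
    left-closed step function through these points.
    """
    if not profile.counts:
        raise ValueError("empty reachability profile")
    values = profile.values
    n = len(values)
    points = []
    for r in sorted(set(values.tolist())):
        points.append((r, float(np.sum(values >= r)) / n))
    return points


def auc(profile: ReachabilityProfile) -> float:
    """Normalized AUC of the inverse cumulative reachability curve."""
    return profile.auc


def frozen_auc(profile: ReachabilityProfile) -> float:
    """AUC against a frozen reference node count.

    Nodes removed from the graph (absent from ``counts``) contribute zero,
    so a perturbation series normalized to the original network size stays
    comparable: auc = sum(counts) / reference_n**2.
    """
    return sum(profile.counts.values()) / profile.reference_n ** 2


def betweenness(web: ProteaseWebGraph) -> dict[str, float]:
    """Directed shortest-path betweenness, endpoints excluded.

    Freeman/Brandes contract: tied shortest paths between a pair split
    the pair's unit weight equally.  Unnormalized counts.
    """
    arcs = web.arc_view() if isinstance(web, ProteaseWebGraph) else web
    return nx.betweenness_centrality(arcs, normalized=False)


def strongly_connected_core(
    web: ProteaseWebGraph,
) -> tuple[set[str], TierSummary]:
    """Largest strongly connected component and the tier split around it.

    Ties on component size break on the smallest lexicographic member.
    A size-1 core is degenerate (the graph has no mutually reachable
    subgroup); tiers are still defined and a warning is emitted.
    """
    arcs = web.arc_view() if isinstance(web, ProteaseWebGraph) else web
    if arcs.number_of_nodes() == 0:
        raise ValueError("strongly_connected_core of an empty graph")
    sccs = list(nx.strongly_connected_components(arcs))
    biggest = max(len(c) for c in sccs)
    core = min((c for c in sccs if len(c) == biggest), key=min)
    if len(core) == 1:
        warnings.warn("largest strongly connected component has size 1; "
                      "the network has no regulatory core", stacklevel=2)
    counts = _reach_counts(arcs)
    core_values = {counts[n] for n in core}
    assert len(core_values) == 1, "SCC members must share one reachability"
    r_core = core_values.pop()
    upstream = sum(1 for n, c in counts.items() if n not in core and c > r_core)
    downstream = arcs.number_of_nodes() - len(core) - upstream
    return set(core), TierSummary(
        r_core=r_core, n_core=len(core),
        n_upstream=upstream, n_downstream=downstream)


def path_length_histogram(
    web: ProteaseWebGraph,
) -> tuple[dict[int, int], int]:
    """Shortest-path length histogram over reachable ordered pairs.

    Counts d(X, Y) over all ordered pairs X != Y with a finite directed
    distance; returns (histogram, reachable_pair_count).  The maximum
    possible pair count is n(n-1).
    """
    arcs = web.arc_view() if isinstance(web, ProteaseWebGraph) else web
    hist: Counter = Counter()
    for _, dists in nx.all_pairs_shortest_path_length(arcs):
        for d in dists.values():
            if d > 0:
                hist[d] += 1
    return dict(hist), sum(hist.values())


def all_shortest_paths(
    web: ProteaseWebGraph, source: str, target: str
) -> PathQueryResult:
    """Enumerate every minimal-length directed path source -> target.

    Each step is annotated with the kinds of the stored edges realizing
    that arc.  Unreachable pairs yield an empty result with length None.
    """
    arcs = web.arc_view()
    for acc in (source, target):
        if acc not in arcs:
            raise KeyError(f"unknown accession {acc!r}")
    try:
        node_paths = list(nx.all_shortest_paths(arcs, source, target))
    except nx.NetworkXNoPath:
        return PathQueryResult(source=source, target=target)
    paths = []
    for nodes in node_paths:
        kinds = [tuple(sorted(web.g[u][v].keys()))
                 for u, v in zip(nodes, nodes[1:])]
        paths.append((nodes, kinds))
    length = len(node_paths[0]) - 1
    return PathQueryResult(source=source, target=target,
                           paths=paths, length=length)


def reachability_bimodality(
    profile: ReachabilityProfile,
    min_gap: float = 0.25,
    min_mass: float = 0.10,
) -> tuple[bool, float]:
    """Gap test for a bimodal reachability distribution.

    Splits the nodes at the largest gap between consecutive observed
    reachability values (normalized by ``reference_n``).  The distribution
    is called bimodal when that gap spans at least ``min_gap`` of the
    reference size and each side holds at least ``min_mass`` of the nodes —
    a high-reachability mode (the core and its upstream feeders) cleanly
    separated from a low mode.  Returns (is_bimodal, normalized gap).
    """
    values = profile.values
    uniq = np.unique(values)
    if len(uniq) < 2:
        return False, 0.0
    gaps = np.diff(uniq) / profile.reference_n
    i = int(np.argmax(gaps))
    gap = float(gaps[i])
    split = uniq[i]
    low_mass = float(np.sum(values <= split)) / len(values)
    high_mass = 1.0 - low_mass
    ok = gap >= min_gap and low_mass >= min_mass and high_mass >= min_mass
    return ok, gap


def write_metrics_report(web: ProteaseWebGraph, tsv_path, json_path=None):
    """Per-node metrics TSV (accession, reachability, betweenness, tier)
    plus an optional JSON summary (auc, r_core, tier counts, histogram)."""
    profile = reachability(web)
    btw = betweenness(web)
    core, tiers = strongly_connected_core(web)

    def tier_of(acc):
        if acc in core:
            return "core"
        return "upstream" if profile.counts[acc] > tiers.r_core else "downstream"

    lines = ["accession\treachability\tbetweenness\ttier"]
    for acc in sorted(profile.counts):
        lines.append(f"{acc}\t{profile.counts[acc]}\t{btw[acc]:.6g}"
                     f"\t{tier_of(acc)}")
    with open(tsv_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if json_path is not None:
        hist, pairs = path_length_histogram(web)
        summary = {
            "auc": profile.auc,
            "r_core": tiers.r_core,
            "tiers": {"core": tiers.n_core, "upstream": tiers.n_upstream,
                      "downstream": tiers.n_downstream},
            "reachable_pair_count": pairs,
            "path_length_histogram": {str(k): v for k, v in sorted(hist.items())},
        }
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2)
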