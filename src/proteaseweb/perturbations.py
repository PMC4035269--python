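"""Robustness suite: annotation-error perturbations of the protease web.

Every perturbation only removes edges or nodes, so no node's reachability
can increase.  The AUC of each perturbed network is normalized against the
frozen node count of the unperturbed network (removed nodes contribute
zero), making the reported ``auc_ratio`` values comparable across a series.

Perturbations
-------------
hc / hc+i      keep only physiologically relevant cleavages, without /
               with the inhibition edges
inh rm         drop cleavages that mechanistically encode an inhibition
               (serpin cleaved by a serine/cysteine protease; any cleavage
               of a trap inhibitor)
1 rm           every single-node knockout
connector search   iterative removal of the highest-betweenness node
k rm / k-1 rm  combinatorial knockout of a connector set and each
               leave-one-in variant
random sweep   seeded random edge deletions at fixed fractions
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ReachabilityProfile, frozen_auc, reachability
from .connectivity import betweenness as _betweenness
from .graph import CLEAVAGE, INHIBITION, ProteaseWebGraph

__all__ = [
    "PerturbationConfig",
    "PerturbationResult",
    "high_confidence_filter",
    "remove_inhibitor_cleavages",
    "single_node_knockouts",
    "iterative_connector_search",
    "combinatorial_knockout",
    "random_edge_removal",
    "write_perturbation_report",
]


@dataclass(frozen=True)
class PerturbationConfig:
    edge_removal_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    reps: int = 200
    seed: int = 0
    connector_count: int = 6

    def __post_init__(self) -> None:
        for f in self.edge_removal_fractions:
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must be strictly between 0 and 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.connector_count < 1:
            raise ValueError("connector_count must be >= 1")


@dataclass(frozen=True)
class PerturbationResult:
    """One labeled network variant with its connectivity summary."""

    label: str
    auc: float
    auc_ratio: float
    removed_edge_count: int
    removed_node_count: int
    profile: ReachabilityProfile = field(repr=False, default=None)
    web: ProteaseWebGraph = field(repr=False, default=None)


def _result(web: ProteaseWebGraph, label: str, reference_n: int,
            auc_original: float, removed_edges: int,
            removed_nodes: int) -> PerturbationResult:
    profile = reachability(web, reference_n=reference_n)
    a = frozen_auc(profile) if profile.counts else 0.0
    return PerturbationResult(
        label=label, auc=a,
        auc_ratio=a / auc_original if auc_original else 0.0,
        removed_edge_count=removed_edges,
        removed_node_count=removed_nodes,
        profile=profile, web=web)


def _baseline(web: ProteaseWebGraph) -> tuple[int, float]:
    n = web.n_nodes
    return n, frozen_auc(reachability(web, reference_n=n))


def high_confidence_filter(
    web: ProteaseWebGraph, keep_inhibitions: bool
) -> PerturbationResult:
    """«hc» / «hc+i»: drop cleavages not annotated physiologically relevant.

    Cleavage edges whose relevance label is anything but "yes" are removed.
    Inhibition edges are removed as well unless ``keep_inhibitions`` (the
    curated databases leave inhibition relevance unannotated, so the plain
    high-confidence filter strips every inhibitor connection).  The node
    set is frozen.
    """
    ref_n, auc0 = _baseline(web)
    out = web.copy("hc+i" if keep_inhibitions else "hc")
    drop = []
    for u, v, k, data in out.g.edges(keys=True, data=True):
        if k == CLEAVAGE and data.get("physiological_relevance") != "yes":
            drop.append((u, v, k))
        elif k == INHIBITION and not keep_inhibitions:
            drop.append((u, v, k))
    out.g.remove_edges_from(drop)
    return _result(out, out.provenance, ref_n, auc0, len(drop), 0)


def remove_inhibitor_cleavages(web: ProteaseWebGraph) -> PerturbationResult:
    """«inh rm»: drop cleavages that encode inhibition, not inactivation.

    A cleavage edge P -> I is removed iff the target I is a serpin-class
    (inhibitor class S) inhibitor and the protease P is of serine or
    cysteine catalytic class — those cleavages trap the protease rather
    than inactivating the inhibitor — or I is a physical trap inhibitor
    (A2M/PZP style), which cages proteases of any class.  Metallo- and
    aspartic-protease cleavages of serpins inactivate the serpin and are
    retained.  Inhibition edges are untouched.
    """
    ref_n, auc0 = _baseline(web)
    out = web.copy("inh rm")
    g = out.g
    drop = []
    for u, v, k in g.edges(keys=True):
        if k != CLEAVAGE:
            continue
        tgt = g.nodes[v]
        trap = bool(int(tgt.get("trap_inhibitor", 0)))
        serpin = "S" in str(tgt.get("inhibitor_classes", "")).split(";")
        p_class = g.nodes[u].get("catalytic_class", "none")
        if trap or (serpin and p_class in ("S", "C")):
            drop.append((u, v, k))
    g.remove_edges_from(drop)
    return _result(out, "inh rm", ref_n, auc0, len(drop), 0)


def single_node_knockouts(web: ProteaseWebGraph) -> list[PerturbationResult]:
    """«1 rm»: remove each node (with incident edges) individually.

    AUCs are normalized against the original node count, the removed node
    contributing zero reachability.
    """
    ref_n, auc0 = _baseline(web)
    results = []
    for node in sorted(web.g.nodes):
        out = web.copy(f"1 rm {node}")
        removed_edges = out.g.degree(node)
        out.g.remove_node(node)
        results.append(_result(out, out.provenance, ref_n, auc0,
                               removed_edges, 1))
    return results


def iterative_connector_search(
    web: ProteaseWebGraph, k: int
) -> tuple[list[str], list[PerturbationResult]]:
    """Identify the k key connector nodes by iterated betweenness removal.

    Repeat k times: compute directed betweenness, remove the arg-max node
    (ties broken by lexicographically smallest accession), record the AUC
    of the remainder against the frozen original reference.
    """
    if k > web.n_nodes:
        raise ValueError("k exceeds node count")
    ref_n, auc0 = _baseline(web)
    out = web.copy("connector search")
    order: list[str] = []
    steps: list[PerturbationResult] = []
    removed_edges = 0
    for step in range(k):
        btw = _betweenness(out)
        best = max(btw.values())
        node = min(n for n, b in btw.items() if b == best)
        removed_edges += out.g.degree(node)
        out.g.remove_node(node)
        order.append(node)
        steps.append(_result(out.copy(f"connector rm {step + 1}"),
                             f"connector rm {step + 1}", ref_n, auc0,
                             removed_edges, step + 1))
    return order, steps


def combinatorial_knockout(
    web: ProteaseWebGraph, node_set: list[str]
) -> list[PerturbationResult]:
    """«k rm» plus every «k-1 rm» leave-one-in variant.

    First result removes the whole ``node_set``; then one result per
    member kept while the other members are removed.
    """
    nodes = list(dict.fromkeys(node_set))
    unknown = [n for n in nodes if not web.has_node(n)]
    if unknown:
        raise KeyError(f"unknown accession(s) {unknown}")
    ref_n, auc0 = _baseline(web)

    def knock(remove: list[str], label: str) -> PerturbationResult:
        out = web.copy(label)
        removed_edges = sum(out.g.degree(n) for n in remove)
        # degree double-counts edges within the removed set once per endpoint
        internal = sum(1 for u, v in web.g.edges()
                       if u in remove and v in remove)
        out.g.remove_nodes_from(remove)
        return _result(out, label, ref_n, auc0,
                       removed_edges - internal, len(remove))

    results = [knock(nodes, f"{len(nodes)} rm")]
    for keep in nodes:
        rest = [n for n in nodes if n != keep]
        results.append(knock(rest, f"{len(rest)} rm (keep {keep})"))
    return results


def random_edge_removal(
    web: ProteaseWebGraph, config: PerturbationConfig
) -> dict[float, dict]:
    """Random edge-deletion sweep: per fraction, seeded AUC distribution.

    For each fraction f, ``config.reps`` independent draws remove
    ``floor(f * |E|)`` stored edges (cleavages and inhibitions alike)
    uniformly without replacement from the frozen node set.  Reports the
    per-draw AUCs, their minimum ("worst case", the quantity the paper
    plots) and mean.
    """
    ref_n, auc0 = _baseline(web)
    edges = sorted(web.g.edges(keys=True))
    m = len(edges)
    sweep: dict[float, dict] = {}
    for fi, f in enumerate(config.edge_removal_fractions):
        n_remove = int(np.floor(f * m))
        aucs = []
        for rep in range(config.reps):
            rng = np.random.default_rng([config.seed, fi, rep])
            idx = rng.choice(m, size=n_remove, replace=False)
            out = web.copy(f"random rm {f:g} rep {rep}")
            out.g.remove_edges_from([edges[i] for i in idx])
            profile = reachability(out, reference_n=ref_n)
            aucs.append(frozen_auc(profile))
        arr = np.asarray(aucs)
        sweep[f] = {
            "aucs": aucs,
            "worst_auc": float(arr.min()),
            "mean_auc": float(arr.mean()),
            "auc_ratio_worst": float(arr.min() / auc0),
            "removed_per_draw": n_remove,
        }
    return sweep


def write_perturbation_report(results: list[PerturbationResult], tsv_path,
                              manifest_path=None, config=None) -> None:
    """Perturbation TSV (label, removed counts, auc, auc_ratio) and an
    optional JSON manifest of the sweep configuration."""
    lines = ["label\tremoved_edges\tremoved_nodes\tauc\tauc_ratio"]
    for r in results:
        lines.append(f"{r.label}\t{r.removed_edge_count}\t"
                     f"{r.removed_node_count}\t{r.auc:.6f}\t{r.auc_ratio:.6f}")
    with open(tsv_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if manifest_path is not None and config is not None:
        payload = {
            "edge_removal_fractions": list(config.edge_removal_fractions),
            "reps": config.reps,
            "seed": config.seed,
            "connector_count": config.connector_count,
        }
        with open(manifest_path, "w") as fh:
            json.dump(payload, fh, indent=2)
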