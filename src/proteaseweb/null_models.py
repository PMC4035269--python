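"""Matched random-network ensembles for the protease web.

Four null models, each matched to a property of the observed network:

ER
    Erdős–Rényi-like: same node and arc counts, arcs uniform without
    replacement, no self-loops.
BA
    Preferential-attachment-like: nodes arrive in random order and emit
    their assigned out-degrees toward already-present nodes with
    probability proportional to (in-degree + 1).
Shuffled
    Directed double-edge swaps preserving every node's joint
    (in, out) degree exactly.
Shuffled2
    The in- and out-degree sequences are each permuted independently
    across nodes, decoupling any in/out correlation, then realized by
    stub matching.

``null_experiment`` runs a seeded ensemble of replicates and places the
observed network's mean reachability within the replicate distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import reachability
from .graph import ProteaseWebGraph

__all__ = [
    "NullModelConfig",
    "NullModelSummary",
    "er_like",
    "ba_like",
    "degree_preserving_shuffle",
    "degree_sequence_shuffle",
    "null_experiment",
    "write_ensemble_report",
]

logger = logging.getLogger(__name__)

MODELS = ("ER", "BA", "Shuffled", "Shuffled2")

#: Edge kind attached to generated/rewired arcs, which carry no
#: biochemical identity.
ARC = "arc"


@dataclass(frozen=True)
class NullModelConfig:
    model: str
    replicates: int = 500
    seed: int = 0
    swap_multiplier: int = 10  # Shuffled only

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.swap_multiplier < 1:
            raise ValueError("swap_multiplier must be >= 1")


@dataclass(frozen=True)
class NullModelSummary:
    """Ensemble of per-replicate mean reachabilities vs the observed mean.

    ``quantile`` places the observed mean within the replicate
    distribution with the mid-rank tie rule
    (strictly below + half of equal) / replicates.
    """

    model: str
    replicate_means: list[float]
    ensemble_mean: float
    observed_mean: float
    quantile: float
    n_exceeding_observed: int
    config: NullModelConfig = field(repr=False, default=None)


def _wrap(arcs: nx.DiGraph, source: ProteaseWebGraph | None,
          provenance: str) -> ProteaseWebGraph:
    g = nx.MultiDiGraph()
    if source is not None:
        g.add_nodes_from(source.g.nodes(data=True))
    g.add_nodes_from(arcs.nodes)
    g.add_edges_from((u, v, ARC, {"kind": ARC}) for u, v in arcs.edges())
    return ProteaseWebGraph(g, provenance)


def er_like(n_nodes: int, n_edges: int, seed: int) -> ProteaseWebGraph:
    """Uniform directed simple graph with exactly ``n_edges`` arcs."""
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError(
            f"cannot place {n_edges} arcs on {n_nodes} nodes "
            f"(max {n_nodes * (n_nodes - 1)})")
    rng = np.random.default_rng(seed)
    # sample arc indices without replacement from the n(n-1) off-diagonal slots
    total = n_nodes * (n_nodes - 1)
    idx = rng.choice(total, size=n_edges, replace=False)
    arcs = nx.DiGraph()
    arcs.add_nodes_from(range(n_nodes))
    for a in idx:
        u, r = divmod(int(a), n_nodes - 1)
        v = r if r < u else r + 1
        arcs.add_edge(u, v)
    return _wrap(arcs, None, f"ER n={n_nodes} m={n_edges} seed={seed}")


def ba_like(out_degree_sequence: list[int], seed: int) -> ProteaseWebGraph:
    """Sequential attachment forcing a given out-degree sequence.

    Nodes are added in random order; node i emits its assigned out-degree
    as arcs from the new node to already-present nodes, each target drawn
    with probability proportional to (in-degree + 1) without replacement.
    The +1 offset keeps zero-in-degree nodes eligible as targets.  A node
    arriving before enough targets exist has its out-degree capped at the
    number of prior nodes; the shortfall is logged.
    """
    if len(out_degree_sequence) == 0:
        raise ValueError("out-degree sequence must be nonempty")
    rng = np.random.default_rng(seed)
    n = len(out_degree_sequence)
    order = rng.permutation(n)
    arcs = nx.DiGraph()
    arcs.add_nodes_from(range(n))
    present: list[int] = []
    indeg = np.zeros(n, dtype=float)
    shortfall = 0
    for pos, node in enumerate(order):
        want = int(out_degree_sequence[node])
        d = min(want, pos)
        shortfall += want - d
        if d > 0:
            weights = indeg[present] + 1.0
            targets = rng.choice(present, size=d, replace=False,
                                 p=weights / weights.sum())
            for t in np.atleast_1d(targets):
                arcs.add_edge(int(node), int(t))
                indeg[int(t)] += 1
        present.append(int(node))
    if shortfall:
        logger.info("BA generator: out-degree shortfall of %d arcs", shortfall)
    return _wrap(arcs, None, f"BA n={n} seed={seed}")


def degree_preserving_shuffle(
    web: ProteaseWebGraph, seed: int, swap_multiplier: int = 10
) -> ProteaseWebGraph:
    """«Shuffled»: directed double-edge swaps with rejection.

    ``swap_multiplier * |E|`` swap attempts; a swap replacing
    (a->b, c->d) with (a->d, c->b) is rejected when it would create a
    self-loop or duplicate arc.  Every node's in- and out-degree is
    preserved exactly.  Operates on the unique-arc view.
    """
    arcs = web.arc_view()
    edges = list(arcs.edges())
    if len(edges) < 2:
        return _wrap(arcs, web, f"Shuffled of {web.provenance} seed={seed}")
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    attempts = swap_multiplier * len(edges)
    for _ in range(attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue  # would create a self-loop
        if (a, d) in edge_set or (c, b) in edge_set:
            continue  # would create a duplicate arc
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
    out = nx.DiGraph()
    out.add_nodes_from(arcs.nodes)
    out.add_edges_from(edge_set)
    return _wrap(out, web, f"Shuffled of {web.provenance} seed={seed}")


def degree_sequence_shuffle(
    web: ProteaseWebGraph, seed: int, max_rounds: int = 200
) -> ProteaseWebGraph:
    """«Shuffled2»: permute degree sequences, then realize by stub matching.

    The in-degree sequence and the out-degree sequence are each permuted
    independently across nodes, then a simple directed graph realizing
    both sequences is built by matching out-stubs to in-stubs, rejecting
    self-loops and duplicate arcs.  Residual stubs are re-matched for up
    to ``max_rounds`` rounds, then repaired by constrained swaps with
    existing arcs; if stubs still remain the sequences are unrealizable
    within budget and an error reports them.
    """
    arcs = web.arc_view()
    if arcs.number_of_edges() == 0:
        return _wrap(arcs, web, f"Shuffled2 of {web.provenance} seed={seed}")
    rng = np.random.default_rng(seed)
    nodes = list(arcs.nodes)
    out_deg = np.array([arcs.out_degree(n) for n in nodes])
    in_deg = np.array([arcs.in_degree(n) for n in nodes])
    out_deg = out_deg[rng.permutation(len(nodes))]
    in_deg = in_deg[rng.permutation(len(nodes))]

    out_stubs = [n for n, d in zip(nodes, out_deg) for _ in range(d)]
    in_stubs = [n for n, d in zip(nodes, in_deg) for _ in range(d)]
    edge_set: set[tuple[str, str]] = set()
    for _ in range(max_rounds):
        if not out_stubs:
            break
        rng.shuffle(out_stubs)
        rng.shuffle(in_stubs)
        rest_out, rest_in = [], []
        for u, v in zip(out_stubs, in_stubs):
            if u == v or (u, v) in edge_set:
                rest_out.append(u)
                rest_in.append(v)
            else:
                edge_set.add((u, v))
        out_stubs, in_stubs = rest_out, rest_in
    if out_stubs:
        # constrained repair: splice each residual stub pair into an
        # existing arc (x, y) with (u, y) and (x, v) both fresh
        still = []
        for u, v in zip(out_stubs, in_stubs):
            done = False
            pool = list(edge_set)
            rng.shuffle(pool)
            for x, y in pool:
                if (u != y and x != v and (u, y) not in edge_set
                        and (x, v) not in edge_set):
                    edge_set.discard((x, y))
                    edge_set.add((u, y))
                    edge_set.add((x, v))
                    done = True
                    break
            if not done:
                still.append((u, v))
        if still:
            raise RuntimeError(
                f"degree sequences unrealizable within budget; "
                f"{len(still)} residual stub pair(s): {still[:5]}")
    out = nx.DiGraph()
    out.add_nodes_from(nodes)
    out.add_edges_from(edge_set)
    return _wrap(out, web, f"Shuffled2 of {web.provenance} seed={seed}")


def _replicate(web: ProteaseWebGraph, config: NullModelConfig,
               rep_seed: int) -> ProteaseWebGraph:
    arcs = web.arc_view()
    if config.model == "ER":
        return er_like(arcs.number_of_nodes(), arcs.number_of_edges(), rep_seed)
    if config.model == "BA":
        seq = [arcs.out_degree(n) for n in sorted(arcs.nodes)]
        return ba_like(seq, rep_seed)
    if config.model == "Shuffled":
        return degree_preserving_shuffle(web, rep_seed, config.swap_multiplier)
    return degree_sequence_shuffle(web, rep_seed)


def null_experiment(
    web: ProteaseWebGraph, config: NullModelConfig
) -> NullModelSummary:
    """Seeded null ensemble with the observed mean reachability located
    inside it.

    Replicate i is generated from seed ``config.seed + i``, so
    (config, seed) fully determines the ensemble.
    """
    observed = reachability(web).mean
    means: list[float] = []
    for i in range(config.replicates):
        try:
            rep = _replicate(web, config, config.seed + i)
        except Exception as exc:
            raise RuntimeError(
                f"{config.model} replicate {i} failed: {exc}") from exc
        means.append(reachability(rep).mean)
    arr = np.asarray(means)
    below = int(np.sum(arr < observed))
    equal = int(np.sum(arr == observed))
    quantile = (below + 0.5 * equal) / config.replicates
    return NullModelSummary(
        model=config.model,
        replicate_means=means,
        ensemble_mean=float(arr.mean()),
        observed_mean=float(observed),
        quantile=float(quantile),
        n_exceeding_observed=int(np.sum(arr > observed)),
        config=config,
    )


def write_ensemble_report(summaries: list[NullModelSummary], tsv_path,
                          json_path=None) -> None:
    """Per-replicate TSV (replicate, model, mean_reachability) and an
    optional JSON summary per model."""
    lines = ["replicate\tmodel\tmean_reachability"]
    for s in summaries:
        for i, m in enumerate(s.replicate_means):
            lines.append(f"{i}\t{s.model}\t{m:.6f}")
    with open(tsv_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if json_path is not None:
        import json

        payload = {
            s.model: {
                "ensemble_mean": s.ensemble_mean,
                "observed_mean": s.observed_mean,
                "quantile": s.quantile,
                "n_exceeding_observed": s.n_exceeding_observed,
                "replicates": len(s.replicate_means),
            }
            for s in summaries
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
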