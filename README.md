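# proteaseweb

Network analysis of the **protease web** — the universe of cleavage and
inhibition interactions among proteases and their inhibitors. Proteolysis is
not a set of isolated linear cascades: proteases activate and inactivate
each other and each other's inhibitors, so the system behaves as a directed
regulatory network. This package is for computational and systems biologists
who want to quantify that structure from curated interaction tables: how far
a protease's influence reaches, whether the network has a mutually reachable
regulatory core, which proteins tether it together, how robust the
connectivity is to annotation errors, and which parts of the web are active
in a given tissue.

## Model and measures

Proteins are nodes. A cleavage is a directed edge protease → substrate; an
inhibition is a directed edge inhibitor → target protease. Both kinds encode
a direct regulatory influence, so connectivity is computed on the
kind-collapsed arc graph.

- **Reachability** R(X) = |{Y : a directed path X → Y exists}|, counting X
  itself; an isolated node scores 1, every node of an n-cycle scores n.
- The network summary is the **inverse cumulative curve**
  F(r) = fraction of nodes with R ≥ r and its normalized area
  **AUC** = mean(R)/n_ref — 1/n for an edgeless network, 1 for a complete
  digraph. Perturbation series freeze n_ref at the original network size so
  AUC ratios are comparable.
- The **regulatory core** is the largest strongly connected component; all
  of its members share one reachability value r_core, splitting the network
  into core / upstream (R > r_core) / downstream tiers.
- **Key connectors** are found by iteratively removing the node with the
  highest directed betweenness (recomputed after every removal).
- Observed connectivity is located within four matched null ensembles
  (Erdős–Rényi, preferential attachment, exact degree-preserving shuffle,
  independent degree-sequence shuffle) and stress-tested by a perturbation
  suite (confidence filtering, mechanistic removal of inhibitor cleavages,
  single/combinatorial knockouts, random edge-deletion sweeps).
- Tissue-specific webs are induced on proteins whose expression A-value
  exceeds a negative-control-derived nearest-rank 95% threshold.

A planted-structure synthetic generator (`SyntheticWebParams`,
`generate_web`) emits the same table dialects with known ground truth —
a strongly connected core closed through parallel serpin "bridge"
inhibitors, upstream zymogen cascades, downstream targets, heavy-tailed
hub out-degrees — so the whole pipeline is testable end to end without
any database download. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import proteaseweb as pw

params = pw.SyntheticWebParams(seed=0)          # or load_tables(...) for real TSVs
proteins, cleavages, inhibitions, truth = pw.generate_web(params)
web  = pw.build_graph(*pw.records_from_frames(proteins, cleavages, inhibitions))
lcc  = pw.largest_connected_component(pw.restrict_to_protease_web(web))

profile      = pw.reachability(lcc)
core, tiers  = pw.strongly_connected_core(lcc)
order, steps = pw.iterative_connector_search(lcc, 6)
knock        = pw.combinatorial_knockout(lcc, order)
shuf  = pw.null_experiment(lcc, pw.NullModelConfig(model="Shuffled",  replicates=50, seed=1))
shuf2 = pw.null_experiment(lcc, pw.NullModelConfig(model="Shuffled2", replicates=50, seed=1))
```

Output for this dataset:

```text
full network: 161 nodes, 377 edges
protease web LCC: 102 nodes, 249 edges
AUC = 0.591; core = 54 nodes at r_core = 80; 22 upstream, 26 downstream
reachable ordered pairs: 6050 of 10302
connectors: ['I000', 'I001', 'I002', 'I003', 'I004', 'I005']
all-6 knockout AUC ratio = 0.07; leave-one-in ratios 0.88-0.88
mean reachability: observed 60.3, Shuffled 60.3, Shuffled2 43.6
```

Reading it: 102 proteases and inhibitors form one connected web whose
54-member core can mutually reach itself plus everything downstream
(r_core = 80 of 102 nodes), a strongly bimodal reachability distribution.
The six connectors recovered by betweenness search are exactly the six
planted bridge inhibitors; removing all six collapses connectivity to 7%
of the original AUC while sparing any one of them preserves 88% — the
connectivity rests on a redundant set of inhibitor switches, not on any
single protein. Degree-preserving shuffles reproduce the observed mean
reachability, while decoupling each node's in- and out-degrees
(Shuffled2) loses a third of it: high reachability is a property of which
proteins are simultaneously cleaved and cleaving, not of the degree
distributions alone.

Regulatory paths between specific proteins come from
`pw.all_shortest_paths(lcc, "P0048", "I000")`, which enumerates every
minimal-length path with per-step edge kinds — the query used to explain
indirect knockout effects (e.g. a metalloprotease enabling elastase
activity by destroying its serpin inhibitor).

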