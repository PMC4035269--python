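# Methods

## The model

A protease web is a directed graph over proteins. A cleavage is an edge
from a protease to its substrate; an inhibition is an edge from an
inhibitor to its target protease. Both edge kinds encode the same thing
for the graph model — a direct regulatory influence from source to
target — so although a cleavage and an inhibition between the same
ordered pair are stored as two distinct edges (the edge totals count
them separately), every path, reachability, and betweenness computation
runs on the *arc view*: the kind-collapsed simple digraph with
self-loops removed. Self-loops (autolysis) are stored for completeness
but never contribute to connectivity; the node itself is already
counted. Edges are unsigned: an influence may raise, lower, or merely
alter the target's activity, and the model deliberately does not
propagate signs.

The *full network* contains every protein participating in at least one
annotated interaction. The *protease web* proper restricts to proteins
carrying a MEROPS-style identifier (proteases and inhibitors); plain
substrates, whose reachability is 1 by definition, are dropped and the
edge set induced. Most structural analyses run on the largest (weakly)
connected component of the protease web.

## Reachability and its AUC

Reachability of node X is the number of nodes Y — **including X
itself** — with a finite directed path X → Y. Self-inclusion is forced
by the calibration networks: every node of an edgeless network has
reachability 1, and every node of an n-cycle has reachability n.
Internally the computation condenses the graph to its DAG of strongly
connected components and propagates reachable-set bitsets in reverse
topological order, so all members of an SCC share one value by
construction; a brute-force transitive-closure oracle checks this
against random graphs in the tests.

The network-level summary is the inverse cumulative curve: for each
observed value r, the fraction of nodes with reachability ≥ r,
evaluated as a left-closed step function. Its area over [0,
reference_n], normalized by reference_n, is computed as an exact
rectangle sum and is identically mean(reachability)/reference_n; the
tests assert this identity to 1e-9. `reference_n` is kept explicit
because a perturbation series freezes it to the unperturbed network's
node count (a removed node contributes zero), which makes AUC ratios
across the series comparable and independent of the normalization
constant.

Tiers: the largest SCC is the regulatory core, and all its members
share one reachability value r_core. Nodes with reachability strictly
above r_core are upstream (they reach the core but are not reached
from it); the remaining nodes are downstream. The tier boundary is
defined relative to r_core only, not to any fixed cutoff. Betweenness
is directed, endpoint-excluding Freeman/Brandes betweenness with equal
splitting over tied shortest paths (unnormalized counts).

Bimodality of a reachability distribution is judged by a gap statistic:
normalize values by reference_n, find the largest gap between
consecutive observed values, and call the distribution bimodal when the
gap spans ≥ 0.25 of the reference size with ≥ 10% of the nodes on each
side. This captures the signature of interest — a large block of nodes
with near-identical high reachability (core plus upstream) cleanly
separated from a low mode — while a shattered network with graded
values fails the gap condition.

## Null models

Four matched ensembles, all generated on the arc view and fully
determined by (config, seed); replicate i uses seed + i.

- **ER**: exactly m arcs sampled uniformly without replacement from the
  n(n−1) off-diagonal slots.
- **BA**: nodes arrive in random order; each emits its assigned
  out-degree (the observed out-degree sequence) toward already-present
  nodes with probability ∝ (in-degree + 1), without replacement. The +1
  offset keeps zero-in-degree nodes eligible; arcs run from new to old
  nodes. Early arrivals are capped at the number of prior nodes and the
  shortfall logged.
- **Shuffled**: double-edge swaps, swap_multiplier × |E| attempts
  (default 10×), rejecting any swap that would create a self-loop or
  duplicate arc. Preserves every node's joint (in, out) degree exactly.
  The mixing budget is configurable; 10× is a common heuristic, not a
  proven mixing time.
- **Shuffled2**: the in-degree sequence and the out-degree sequence are
  each permuted *independently* across nodes — decoupling any in/out
  correlation, which is precisely the contrast with Shuffled — then
  realized by stub matching with rejection, bounded re-matching rounds,
  and a constrained-swap repair pass; unrealizable residues raise.

The experiment summary reports per-replicate mean reachability, the
ensemble mean, and the observed mean's empirical quantile with the
mid-rank tie rule (below + ½·equal)/replicates.

## Perturbation suite

All perturbations only delete, so per-node reachability is
non-increasing (property-tested). AUCs use the frozen original
reference.

- **hc / hc+i**: remove cleavage edges whose physiological-relevance
  label is not "yes"; remove inhibitions too (hc) or keep them (hc+i).
- **inh rm**: remove a cleavage P → I iff I is a serpin-class inhibitor
  and P is a serine or cysteine protease (the cleavage traps the
  protease — it encodes inhibition, not inactivation), or I is a
  physical trap inhibitor (A2M/PZP style), for any protease class.
  Serpin identification uses the inhibitor-class field (contains S)
  rather than a curated family list; traps use the explicit flag. The
  broader reading — any serine-protease inhibitor regardless of
  mechanism — would be a superset rule; the implemented rule is the
  conservative mechanistic one.
- **Single-node knockouts** and **combinatorial knockouts** (all-of-k
  removed plus each leave-one-in variant).
- **Iterative connector search**: k rounds of removing the
  highest-betweenness node, recomputing betweenness after each
  removal; ties break on the lexicographically smallest accession.
- **Random edge removal**: for each fraction f, reps seeded draws
  remove ⌊f·|E|⌋ stored edges uniformly without replacement; the worst
  case is the minimum AUC (unambiguous, since deletions only lower it).
  Draw r of fraction index i uses the seed stream (seed, i, r).

## Tissue-specific webs

The expression cutoff is the nearest-rank (inverse empirical CDF)
q-quantile of the negative-control A-values, default q = 0.95: the
⌈qn⌉-th order statistic. A tissue subnetwork is the induced subgraph on
nodes with A-value strictly above the cutoff in that tissue; proteins
absent from the matrix count as not expressed (logged). The survey
takes each tissue subnetwork's largest weak component and reports its
reachability AUC — normalized to the tissue LCC size by default
(per-tissue curves), with a global-reference flag for cross-tissue
ratio comparisons — plus the number of a supplied connector set present
among the expressed nodes. Filtering happens first, then the LCC is
taken.

## Synthetic data generator

The generator is scenario-based: it plants known structure rather than
fitting any real degree sequence, because recovery tests need ground
truth. Layout (defaults in parentheses):

- A **core** of `core_size` (54) members: protease *segments* — short
  zymogen-activation chains of four — plus `n_bridges` (6) serpin
  **bridge** inhibitors wired in parallel: every segment tail cleaves
  every bridge (reactive-loop bait cleavage) and every bridge inhibits
  every segment head. Any single bridge closes feedback across all
  segments, so the core is one SCC whose strong connectivity runs
  exclusively through the bridges; removing all bridges shatters it,
  removing all but one does not. Protease-to-protease cross-links
  (`cross_link_rate`, 0.08 per node) run forward-only between
  consecutive segments, keeping the protease-only subgraph acyclic.
  This wiring is a deliberate design choice: a core that is strongly
  connected through proteases alone could not exhibit the
  connector-dependence the perturbation suite measures.
- **Upstream**: `n_cascades` (4) chains of `cascade_length` (4)
  proteases whose tails cleave distinct segment tails, plus half of the
  non-bridge inhibitors targeting 1–4 core proteases
  (`inhibition_rate` = 0.25 controls extra targets).
- **Downstream**: leftover proteases (20 by default) cleaved by core
  proteases but cleaving only substrate sinks, plus the other half of
  the non-bridge inhibitors, which are cleaved by core proteases and
  have no outgoing edges; `trap_count` (2) of these are A2M/PZP-style
  traps.
- **Substrate sinks** (`n_substrates` = 60) attached with out-degrees
  drawn from a zeta(`outdegree_tail_exponent` = 2.5) distribution
  shifted to start at 0 and truncated at `n_substrates`, reproducing
  the strong annotation skew of curated degradomics data (few hub
  proteases hold most cleavages).
- Labels: catalytic classes from `class_mix`; bridges are always
  serpins; `serpin_fraction` (0.5) of other inhibitors are class S;
  cleavage relevance is "yes" with `relevance_yes_fraction` (0.6), the
  remainder mostly "unknown".

The default sizes give a web of ~100 protease/inhibitor nodes — large
enough that tiers, bimodality, and connector recovery are
non-degenerate, small enough that the complete suite of seeded
replicate analyses runs in seconds. All randomness flows from one seed
through named substreams (topology, labels, expression), so tables are
byte-identical per (params, seed).

By construction the planted expectations are exact: r_core =
core_size + #downstream, the upstream tier is the cascades plus
upstream inhibitors, and tier counts follow from the partition — the
recovery check compares pipeline output against these parameter-derived
numbers, not against quantities recomputed from the emitted tables.

The expression generator draws negative controls from Normal(5, 1) and
places expressed proteins strictly above, unexpressed strictly below,
the derived 95% cutoff, so threshold recovery is exact and forced
on/off subsets are respected verbatim.

**What the generator does not emulate**: real annotation bias is not a
clean planted partition — curated databases mix study-driven target
bias with incomplete coverage; degree sequences are not fit to MEROPS;
there is no kinetics, no concentration, no signed
activation/inactivation semantics, and tissue expression is i.i.d.
per protein rather than co-regulated. Passing recovery tests therefore
shows the pipeline's machinery is correct on known ground truth, not
that any real snapshot has a particular structure.

## Numerical and degenerate-input choices

- Component and betweenness ties break on the lexicographically
  smallest accession; deterministic and documented.
- Duplicate interaction rows collapse to one edge with multiplicity
  logged; conflicting relevance labels merge optimistically
  (yes > unknown > no).
- A size-1 largest SCC is degenerate: a warning is emitted and tiers
  are still defined.
- Empty graphs: building with no edges warns and returns a valid empty
  graph; component extraction on an empty graph raises.
- Removal counts round down (⌊f·|E|⌋); strict inequality at the
  expression threshold (ties are "not expressed").
- Referential integrity is strict by default; a lenient flag drops
  offending rows with a logged count.
- Ortholog-overlap counting is kind-insensitive by default (a cleavage
  in one species may be reflected by any connection in the other);
  a strict kind-matching switch exists.

## Known limitations

- Headline quantities of any real curated snapshot (node/edge totals,
  tier sizes, named connectors, ensemble means) depend on the snapshot
  and are not asserted anywhere; the package tests mechanics and
  qualitative orderings (ER above the observed mean, BA far below,
  Shuffled near it, Shuffled2 below it; hc ≪ hc+i; bridge knockouts
  destroying bimodality).
- The Shuffled sampler is an MCMC walk with a fixed attempt budget, not
  an exact uniform sampler over the degree-fixed family.
- Betweenness-based connector search is greedy; it is the defined
  procedure, not a globally optimal dismantling.
- The bitset reachability computation is exact but quadratic in memory
  over SCC-condensed components; it is sized for webs of up to a few
  thousand nodes, not genome-scale interactomes.
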