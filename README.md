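# bioretro

Retro-biosynthesis route planning for natural products: decompose a
target metabolite backwards into simple biogenic building blocks by
best-first AND-OR tree search over single-step precursor proposals.

Most natural products have no fully characterised biosynthetic pathway,
yet nearly all of them are reachable from a few dozen building blocks
(amino acids, acetyl/malonyl-CoA, isoprenoid diphosphates, shikimate-path
acids, central-carbon metabolites).  `bioretro` is a toolkit for people
who want to propose such pathways computationally — metabolic engineers
redesigning a heterologous route, and method developers who need a
rigorously testable planning core.  It provides:

* **chemistry layer** (`bioretro.chem`) — canonical-SMILES molecules,
  reaction-record parsing (`precursor1.precursor2>>product`), coenzyme A
  masking to a `*` attachment point and restoration, stereo stripping;
* **curation** (`bioretro.curation`) — building precursor→metabolite pair
  datasets from raw reaction records: multi-product decomposition,
  cofactor removal, maximum-common-substructure (MCS) pair derivation,
  natural-product similarity screening, stereo audit, seeded splits;
* **proposer** (`bioretro.proposer`) — the single-step retro-prediction
  contract: ranked candidate precursor sets with probabilities and
  negative-log-likelihood costs, a deterministic table-backed
  implementation, and an ensemble combiner;
* **planner** (`bioretro.planner`) — the multi-step search itself;
* **evaluation** (`bioretro.evaluation`) — pathway-recovery benchmark
  metrics (success rate, hit rate of pathways, hit rate of building
  blocks, average solutions, longest route);
* **netgen** (`bioretro.netgen`) — a synthetic reaction-network generator
  with planted ground-truth routes and an exact dynamic-programming
  oracle, so every search property can be verified at desk scale.

## The search

The search state is an AND-OR tree *T* rooted at the target *t*:
molecule nodes are OR nodes (solved if **any** producing reaction is
solved, or if the molecule is a building block), reaction nodes are AND
nodes (solved only if **all** precursors are solved).  Each single step
carries a cost, the negative log-likelihood −ln *p* of the proposal, and
a route's total cost is the sum of its step costs.

Each iteration selects the open frontier molecule *m* minimising the
value of its best enclosing partial route,

&nbsp;&nbsp;&nbsp;&nbsp;*V*(*m* | *T*) = Σ committed step costs + Σ *h*(open leaves) − bonus(*m*),

and expands it with one AND-OR stump of top-*k* proposals.  With the
default *h* ≡ 0 and nonnegative costs, *V* is an admissible lower bound,
so complete routes are discovered in nondecreasing cost order and the
first one is optimal; the planner verifies this against an exact
dynamic-programming oracle on hundreds of random synthetic networks in
its test suite.  An optional bonus credits nodes on each completed route,
biasing later selection toward neighbourhoods of successful pathways.

Defaults mirror common practice for this class of planner: 10 expansions
per step, 100 iterations, maximum depth 10, top-5 routes returned.

## Worked example

Generate a small synthetic network with planted routes, plan a target,
and score the benchmark:

```bash
bioretro --seed 7 netgen --layers 3 --per-layer 4 --out demo
bioretro plan --target "CON" \
    --building-blocks demo/building_blocks.smi \
    --proposer table:demo/reactions.tsv --out routes.json
bioretro evaluate --benchmark demo/benchmark.json \
    --building-blocks demo/building_blocks.smi \
    --proposer table:demo/reactions.tsv --out eval_out
```

The plan step prints `3 route(s) written to routes.json`; the routes,
cheapest first, are

```
cost=1.987 length=2 leaves=['CCN']
    CNS >> CON (0.619)
    CCN >> CNS (1.368)
cost=2.794 length=1 leaves=['CCS']
    CCS >> CON (2.794)
cost=3.008 length=2 leaves=['CCO', 'CCS']
    CNS >> CON (0.619)
    CCO.CCS >> CNS (2.389)
```

i.e. the best route reaches the building block `CCN` in two steps at
total cost 1.987 (= 0.619 + 1.368), and two costlier alternatives
terminate in other blocks.  The evaluate step prints

```
success 100.0%  pathway hit 100.0%  block hit 100.0%  avg solutions 3.00  longest 2
```

— with the full network as the proposal table, every planted target is
solved, every planted reference pathway and block set is recovered, and
the longest returned route has two steps.

The same machinery runs on real data: feed `curate` a reaction file
(`substrates>>products`, one per line) to build a pair dataset, build a
table proposer from any scored reaction file, or adapt a learned
single-step model to the `Proposer` protocol.  The shipped core library
(`bioretro.io.core_library`) holds 40 canonical building blocks; pass
`--building-blocks` for the extended or a user-defined set.

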