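# Methods

## Problem and model

The package plans retro-biosynthesis: given a target natural product, it
recursively proposes single-step precursor sets until every open branch
terminates in a building-block metabolite.  Pathway space is modelled as
an AND-OR tree.  A molecule (OR) node is solved when the molecule is in
the building-block library or when at least one of its child reaction
nodes is solved; a reaction (AND) node is solved only when all of its
precursor children are solved.  Single-step proposals carry a
probability *p* ∈ (0, 1]; the step cost is the negative log-likelihood
−ln *p*, and the cost of a route is the sum of its step costs, so
maximising route probability and minimising additive cost coincide.

The single-step model is abstracted behind a `Proposer` protocol
(`propose(target, k) → ranked candidate precursor sets`).  The shipped
implementation is a deterministic table proposer that replays a stored
reaction set; a learned sequence model can be adapted to the same
contract.  An ensemble combiner merges ranked lists from several models
by arithmetic-mean probability, imputing 0 for models that did not
propose a candidate.  The mean rule was chosen because it is the
simplest combination that is invariant to model order and reduces to the
identity on identical lists; it sits behind one function so rank-sum or
max rules can replace it without touching callers.  Lists are merged in
full and truncated to *k* afterwards, so a candidate ranked below *k* by
every individual model can still enter the ensemble top-*k*.

## Search

Selection follows a best-first value function.  For every open frontier
molecule *m*, let rn(*x*) be the cheapest known completion of node *x*:
0 for library molecules, *h*(*x*) for unexpanded molecules, step cost
plus the sum of child rn for reaction nodes, and the child minimum for
expanded molecules.  The value of *m* is the total of its best enclosing
partial route — computed top-down as V(root) = rn(root), V(reaction) =
V(parent) − rn(parent) + rn(reaction), V(molecule child) = V(its
reaction) — minus any bonus credit on *m*.  Ties break toward the
earliest-inserted node, which makes the search fully deterministic.

With the default *h* ≡ 0 and nonnegative costs this value is an
admissible lower bound on any route through *m*, so complete routes
appear in nondecreasing cost order.  One consequence shaped the stopping
rule: a route completes the moment its last leaf closes, which can
happen while a cheaper partial route is still open, so "k routes found"
alone does not prove they are the k best.  The planner therefore stops
early only when it holds `route_top_k` distinct routes **and** the k-th
cheapest of them does not exceed the cheapest open partial-route bound;
otherwise it runs until the frontier is exhausted or the iteration
budget ends.  The test suite pins the resulting guarantee — top-1 cost
equal to an exact dynamic-programming optimum to 1e−9 — on hundreds of
random networks.

Expansion adds at most *k* reaction stumps per iteration.  A per-branch
cycle guard discards proposals that re-introduce any molecule on the
path back to the root; the tree (rather than graph) formulation costs
shared intermediates once per occurrence, which matches the route-cost
semantics of both the oracle and the metrics.  Molecules at the depth
cap that are not blocks are dead on creation; a molecule with no valid
proposals is dead, and death propagates through the AND/OR logic as
rn = ∞.  Routes are extracted by enumerating solved subtrees (top
`4·route_top_k` per node, cost-sorted), deduplicated by step multiset,
and returned in ascending total cost.  The solution bonus defaults to 0
(pure best-first); when positive it is subtracted from the selection
value of nodes on already-completed routes, trading the optimality
guarantee for exploration bias around successful pathways.

## Curation rules

Raw reactions are curated into mono-product precursor→metabolite pairs
in a fixed order: multi-product decomposition (each product keeps the
full substrate set) → cofactor removal (a side emptied by removal
rejects the reaction) → MCS pair derivation → CoA masking →
deduplication by (sorted precursors, product).

The MCS rule keeps a pair when at least one substrate's maximum common
substructure with the product covers **strictly more** than 40% of the
product's heavy atoms.  Heavy atoms only, because hydrogens are implicit
in SMILES; the denominator is always the product (metabolite).  Matching
compares atoms by element and bonds by connectivity irrespective of bond
order, with ring bonds restricted to ring bonds, under a 10 s per-pair
timeout that falls back to the best bound found (logged).  The rule is
applied per substrate with an any-substrate keep rule; `require_all`
switches to the stricter joint reading.  Note a boundary consequence of
the strict inequality: at threshold 1.0 nothing survives, since the
fraction cannot exceed 1 and a substrate identical to the product is
excluded as a self-loop.

Coenzyme A handling: the shipped pattern (`data/coa_fragment.smi`) is
the full CoA scaffold rooted at its thiol sulfur — 48 heavy atoms — so
masking collapses S-CoA to a single `*` and acetyl-CoA becomes
`CC(=O)*`.  Matching ignores stereo annotation (databases annotate the
carrier inconsistently); unmasking restores the natural stereochemistry,
so mask/unmask round-trips are canonical for naturally annotated inputs.
Free CoA would mask to a bare `*` and is returned unchanged instead; as
a cofactor it is removed earlier in the pipeline anyway.  Masking runs
before canonicalization ordering decisions, i.e. the masked form is
itself canonicalized.

The similarity screen keeps reactions whose best component ECFP4-class
(Morgan radius-2, 2048-bit) Tanimoto similarity to a reference molecule
set is ≥ 0.8 (inclusive).  The stereo audit counts molecules with ≥1
potential stereo element (tetrahedral or double-bond), and of those the
fully and at-least-half annotated.  Splits are uniform seeded draws into
train/validation/test, deterministic under the seed.

The cofactor list (`data/cofactors.smi`) covers NAD(P)+/NAD(P)H,
ATP/ADP/AMP, free CoA, water, phosphate, diphosphate, CO2, O2 and the
proton; it is a plain editable data file because no canonical list
exists across databases.

## Evaluation metrics

For each benchmark case the planner is run and only solution routes
(every leaf in the library) are scored.  Success rate is the fraction of
cases with ≥1 solution route.  Pathway hit rate requires some returned
route to equal the reference pathway as a multiset of (precursor-set,
product) pairs after canonicalization (optionally stereo-stripped).
Block hit rate in `exact` mode requires some route's leaf set to equal
the blocks **consumed by the reference pathway** — not the possibly
larger allowable library a case may carry — which makes "pathway hit ⇒
block hit" a structural invariant rather than an empirical one; `any`
mode (the external-style criterion) requires one shared block with the
case's reference set.  Average solutions counts returned solution routes
per case (bounded by `route_top_k`, so it is a top-k-limited count);
longest length is the maximum root-to-leaf step count over all solution
routes.  UDB (user-defined building blocks) mode replaces the
termination library per case by the case's own reference blocks, which
lowers success but raises recovery rates, since the search may no longer
stop at unrelated blocks.

## Synthetic networks

`generate_network` emulates the combinatorial shape of a biosynthetic
reaction network — layered precursor structure, branching alternatives,
occasional two-precursor (convergent) steps — while staying small enough
for exhaustive verification.  Defaults: 4 layers, 6 molecules per layer,
up to 2 producing reactions per molecule, two-precursor probability 0.3,
costs −ln(U(0.05, 1)); these sizes keep brute-force enumeration trivial
while exercising multi-branch AND nodes.  Molecules are real parseable
SMILES (unique unbranched C/N/O/S chains), so canonicalization and
matching run unmodified.  What the generator does **not** emulate:
chemical plausibility of transformations, proposal noise (the table
proposer replays the true network, so benchmark hit rates of 1.0 mean
the search and metrics are correct, not that any predictive model is
accurate), shortcut reactions through by-products, and the heavy-tailed
depth of real pathways.  Passing tests therefore certify the planning
and measurement machinery, not prediction quality on real metabolism.

The oracle computes cost(m) = 0 for blocks and min over producing
reactions of [step cost + Σ cost(precursors)] bottom-up by layer —
exact because the network is layer-acyclic — and reconstructs one argmin
route.  Benchmark cases take the top-layer molecules as targets with the
oracle route as reference pathway and its leaves as reference blocks.

## Numerical choices and degenerate inputs

Probability↔cost conversions use the natural logarithm; proposal cost
consistency is enforced to 1e−9 and planner/oracle agreement asserted to
1e−9.  Duplicate proposals for one product collapse to the cheaper cost
with a warning.  Unparseable candidate SMILES from a proposer are
dropped, not fatal; an invalid planning target is an error.  A target
already in the library returns one zero-step route of cost 0.  Empty
proposal lists kill nodes; exhausted frontiers end the search quietly
with whatever routes exist.  Reaction records must have exactly one
`>>`, nonempty sides and a single product component.  The `*` dummy of
masked molecules is excluded from heavy-atom counts (a bookkeeping
token, not an atom).

## Scale of shipped experiments

Test-suite and acceptance-script problem sizes — 100 networks of ≤5
layers and ≤8 molecules per layer, ≤2 targets each, 1000 fuzz trials in
batches of 25 — were chosen so exhaustive oracles stay exact and the
whole verification runs in seconds while covering every generator
regime (mono/multi-precursor, branching 1–3, 2–5 layers).

## Known limitations

The planner is a tree search: cross-branch sharing of an intermediate is
re-derived per branch (cost per occurrence), which is the stated route
semantics but can repeat work on highly convergent networks.  The bonus
mechanism is exposed but unmeasured (no trained search bias ships with
the package).  Atom-mapping and mass balance are out of scope, so
nothing prevents a proposal table from containing mass-inconsistent
steps.  The MCS fraction uses one fixed matching policy; alternative
chemistries (e.g. bond-order-sensitive matching) would need a parameter,
not a code change.  Hit rates are computed over the returned top-k
routes; raising `route_top_k` can only raise them.
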