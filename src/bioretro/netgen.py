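"""Synthetic layered reaction networks with planted ground-truth routes.

The generator builds an acyclic, layered retro-network: layer 0 holds the
building blocks and every molecule of a higher layer is the product of at
least one reaction whose precursors all lie in strictly lower layers.
Molecules are real, parseable SMILES (unbranched heteroatom-decorated
carbon chains, unique after canonicalization) so the chemistry layer
operates on fixtures unmodified.  Step costs are drawn as −ln(p) with
p ~ Uniform(0.05, 1), matching the scale of proposer confidence scores.

A bottom-up dynamic program over the layers provides the exact optimal
route, used as the independent oracle for the best-first planner.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem import Molecule, ReactionStep, canonicalize
from .evaluation import BenchmarkCase
from .planner import Route

__all__ = [
    "SyntheticNetwork",
    "UnreachableTarget",
    "generate_network",
    "bruteforce_optimum",
    "to_benchmark_cases",
    "molecule_stream",
]

_ALPHABET = "CNOS"
_MIN_STEP_PROBABILITY = 0.05


class UnreachableTarget(Exception):
    """The dynamic program found no route from the target to the blocks."""


@dataclass(frozen=True)
class SyntheticNetwork:
    """A layered acyclic reaction network; layer 0 = building blocks."""

    layers: tuple[frozenset[Molecule], ...]
    reactions: tuple[ReactionStep, ...]
    seed: int

    @property
    def building_blocks(self) -> frozenset[Molecule]:
        return self.layers[0]

    @property
    def molecules(self) -> frozenset[Molecule]:
        return frozenset().union(*self.layers)

    def validate(self) -> None:
        """Assert layer-acyclicity and full coverage of non-block molecules."""
        layer_of = {m: i for i, layer in enumerate(self.layers) for m in layer}
        produced = set()
        for step in self.reactions:
            prod_layer = layer_of[step.product]
            for pre in step.precursors:
                if layer_of[pre] >= prod_layer:
                    raise AssertionError(
                        f"precursor {pre.smiles} not strictly below product "
                        f"{step.product.smiles}"
                    )
            produced.add(step.product)
        missing = self.molecules - self.building_blocks - produced
        if missing:
            raise AssertionError(
                f"orphan molecules without producing reactions: "
                f"{sorted(m.smiles for m in missing)}"
            )


def molecule_stream():
    """Yield an endless stream of unique canonical chain-molecule SMILES."""
    seen: set[str] = set()
    for length in itertools.count(3):
        for combo in itertools.product(_ALPHABET, repeat=length):
            raw = "".join(combo)
            mol = Chem.MolFromSmiles(raw)
            if mol is None:
                continue
            can = Chem.MolToSmiles(mol)
            if can in seen:
                continue
            seen.add(can)
            yield canonicalize(can)


def generate_network(
    n_layers: int = 4,
    mols_per_layer: int = 6,
    branching: int = 2,
    multi_precursor_prob: float = 0.3,
    seed: int = 0,
) -> SyntheticNetwork:
    """Generate a layered retro-network, deterministic under ``seed``.

    Each non-block molecule receives 1..``branching`` producing reactions;
    each reaction has one precursor, or two with probability
    ``multi_precursor_prob``, sampled from strictly lower layers.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers (blocks + one product layer)")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    rng = np.random.default_rng(seed)
    stream = molecule_stream()
    layers = [
        frozenset(next(stream) for _ in range(mols_per_layer))
        for _ in range(n_layers)
    ]
    below: list[list[Molecule]] = []
    acc: list[Molecule] = []
    for layer in layers:
        below.append(list(acc))
        acc.extend(sorted(layer))

    reactions: list[ReactionStep] = []
    seen_keys: set[tuple] = set()
    for li in range(1, n_layers):
        pool = below[li]
        for product in sorted(layers[li]):
            n_rxn = int(rng.integers(1, branching + 1))
            made = 0
            for _ in range(20 * n_rxn):  # bounded retries against duplicates
                if made >= n_rxn:
                    break
                n_pre = 2 if (rng.random() < multi_precursor_prob and len(pool) > 1) else 1
                idx = rng.choice(len(pool), size=n_pre, replace=False)
                precursors = frozenset(pool[i] for i in idx)
                prob = rng.uniform(_MIN_STEP_PROBABILITY, 1.0)
                step = ReactionStep(
                    precursors=precursors, product=product,
                    cost=-math.log(prob), provenance="synthetic",
                )
                if step.key in seen_keys:
                    continue
                seen_keys.add(step.key)
                reactions.append(step)
                made += 1
            if made == 0:
                raise RuntimeError(
                    f"could not place a producing reaction for {product.smiles}"
                )
    net = SyntheticNetwork(
        layers=tuple(layers), reactions=tuple(reactions), seed=seed
    )
    net.validate()
    return net


def bruteforce_optimum(
    network: SyntheticNetwork, target: Molecule
) -> tuple[float, Route]:
    """Exact minimum-cost route by bottom-up dynamic programming.

    cost(block) = 0; cost(m) = min over reactions producing m of
    [step cost + Σ cost(precursors)].  Shared precursors are costed per
    occurrence, matching the tree semantics of the planner.

    Raises
    ------
    UnreachableTarget
        If no route from ``target`` terminates entirely in blocks.
    """
    by_product: dict[Molecule, list[ReactionStep]] = {}
    for step in network.reactions:
        by_product.setdefault(step.product, []).append(step)

    cost: dict[Molecule, float] = {m: 0.0 for m in network.building_blocks}
    best_step: dict[Molecule, ReactionStep | None] = {
        m: None for m in network.building_blocks
    }
    for layer in network.layers[1:]:
        for m in sorted(layer):
            best = math.inf
            argmin = None
            for step in by_product.get(m, []):
                c = step.cost + sum(cost.get(p, math.inf) for p in step.precursors)
                if c < best:
                    best = c
                    argmin = step
            cost[m] = best
            best_step[m] = argmin

    if cost.get(target, math.inf) == math.inf:
        raise UnreachableTarget(target.smiles)

    steps: list[ReactionStep] = []
    leaves: list[Molecule] = []

    def build(m: Molecule) -> int:
        step = best_step.get(m)
        if step is None:
            leaves.append(m)
            return 0
        steps.append(step)
        return 1 + max(build(p) for p in step.precursors)

    length = build(target)
    route = Route(
        target=target, steps=tuple(steps), leaves=frozenset(leaves),
        total_cost=cost[target], length=length,
    )
    return cost[target], route


def to_benchmark_cases(
    network: SyntheticNetwork, n_targets: int, seed: int = 0
) -> list[BenchmarkCase]:
    """Sample top-layer targets with their planted optimal reference routes."""
    top = sorted(network.layers[-1])
    rng = np.random.default_rng(seed)
    n_targets = min(n_targets, len(top))
    idx = rng.choice(len(top), size=n_targets, replace=False)
    cases = []
    for i in sorted(idx):
        target = top[i]
        _, route = bruteforce_optimum(network, target)
        cases.append(
            BenchmarkCase(
                target=target,
                reference_pathway=route.steps,
                reference_blocks=route.leaves,
                category="Other",
            )
        )
    return cases
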