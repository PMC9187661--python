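"""Single-step retro-proposal backends.

A proposer maps a target molecule to a ranked list of candidate precursor
sets.  Each candidate carries a probability and the equivalent additive
cost, the negative log-likelihood, so that a pathway's total cost is the
sum of its step costs.  The interface is backend-agnostic: the table
proposer here replays stored reactions deterministically; a sequence-model
adapter can satisfy the same contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Protocol

from .chem import Molecule, ReactionStep

logger = logging.getLogger(__name__)

__all__ = [
    "Proposal",
    "ProposalList",
    "Proposer",
    "TableProposer",
    "build_table_proposer",
    "ensemble_combine",
    "cost_of",
    "probability_of",
]

_COST_PROB_TOL = 1e-9


def cost_of(probability: float) -> float:
    """Negative log-likelihood cost of a proposal probability.

    Monotone decreasing on (0, 1]; ``cost_of(1) == 0``.
    """
    if not 0.0 < probability <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {probability}")
    return -math.log(probability)


def probability_of(cost: float) -> float:
    """Inverse of :func:`cost_of`."""
    if cost < 0:
        raise ValueError(f"cost must be nonnegative, got {cost}")
    return math.exp(-cost)


@dataclass(frozen=True)
class Proposal:
    """One ranked candidate precursor set for a target molecule."""

    precursors: frozenset[Molecule]
    probability: float
    cost: float
    rank: int

    def __post_init__(self) -> None:
        if abs(self.cost - cost_of(self.probability)) > _COST_PROB_TOL:
            raise ValueError(
                f"cost {self.cost} inconsistent with probability {self.probability}"
            )
        if self.rank < 1:
            raise ValueError("ranks start at 1")

    def as_step(self, target: Molecule, provenance: str = "proposed") -> ReactionStep:
        return ReactionStep(
            precursors=self.precursors, product=target,
            cost=self.cost, provenance=provenance,
        )


@dataclass(frozen=True)
class ProposalList:
    """Ranked proposals for one target; at most ``k_requested`` entries."""

    target: Molecule
    proposals: tuple[Proposal, ...]
    k_requested: int

    def __post_init__(self) -> None:
        if len(self.proposals) > self.k_requested:
            raise ValueError("more proposals than requested")
        seen = set()
        prev_cost = -math.inf
        for i, p in enumerate(self.proposals, start=1):
            if p.rank != i:
                raise ValueError("ranks must be contiguous from 1")
            if p.cost < prev_cost - _COST_PROB_TOL:
                raise ValueError("costs must be nondecreasing with rank")
            prev_cost = p.cost
            if p.precursors in seen:
                raise ValueError("duplicate precursor set in proposal list")
            seen.add(p.precursors)
            if self.target in p.precursors:
                raise ValueError("target may not appear among its own precursors")

    def __len__(self) -> int:
        return len(self.proposals)

    def __iter__(self):
        return iter(self.proposals)


class Proposer(Protocol):
    """Contract for single-step retro prediction backends."""

    def propose(self, target: Molecule, k: int) -> ProposalList:
        """Return up to ``k`` ranked, deduplicated, self-loop-free candidates."""
        ...


def _ranked_list(
    target: Molecule, cands: Iterable[tuple[frozenset[Molecule], float]], k: int
) -> ProposalList:
    """Assemble a ProposalList from (precursors, probability) candidates."""
    best: dict[frozenset[Molecule], float] = {}
    for precursors, prob in cands:
        if target in precursors:
            continue
        if precursors not in best or prob > best[precursors]:
            best[precursors] = prob
    ordered = sorted(
        best.items(),
        key=lambda item: (-item[1], tuple(sorted(m.smiles for m in item[0]))),
    )[:k]
    proposals = tuple(
        Proposal(precursors=pre, probability=prob, cost=cost_of(prob), rank=i)
        for i, (pre, prob) in enumerate(ordered, start=1)
    )
    return ProposalList(target=target, proposals=proposals, k_requested=k)


class TableProposer:
    """Deterministic proposer replaying a fixed reaction table.

    ``propose(product, k)`` returns exactly the stored precursor sets for
    that product, ranked by probability (descending) with SMILES order as
    the tie-break.  Duplicate entries for the same (product, precursor set)
    collapse to the cheaper cost with a warning.
    """

    def __init__(self) -> None:
        self._table: dict[Molecule, dict[frozenset[Molecule], float]] = {}

    def add(self, step: ReactionStep, probability: float | None = None) -> None:
        prob = probability if probability is not None else probability_of(step.cost)
        if not 0.0 < prob <= 1.0:
            raise ValueError(f"probability must be in (0, 1], got {prob}")
        entry = self._table.setdefault(step.product, {})
        if step.precursors in entry and entry[step.precursors] != prob:
            logger.warning(
                "conflicting costs for duplicate step %s; keeping the cheaper",
                step.key,
            )
            prob = max(prob, entry[step.precursors])
        entry[step.precursors] = prob

    def propose(self, target: Molecule, k: int) -> ProposalList:
        if k < 1:
            raise ValueError("k must be >= 1")
        entry = self._table.get(target, {})
        return _ranked_list(target, entry.items(), k)

    def __len__(self) -> int:
        return sum(len(v) for v in self._table.values())


def build_table_proposer(
    steps: Iterable[ReactionStep],
    default_probability_rule: Callable[[ReactionStep], float] | None = None,
) -> TableProposer:
    """Build a table proposer from reaction steps.

    Probabilities come from each step's cost (``exp(-cost)``) unless a
    ``default_probability_rule`` overrides them, e.g. to assign a constant
    probability to unscored database records.
    """
    proposer = TableProposer()
    for step in steps:
        prob = default_probability_rule(step) if default_probability_rule else None
        proposer.add(step, probability=prob)
    return proposer


def ensemble_combine(lists: list[ProposalList], k: int) -> ProposalList:
    """Merge ranked candidate lists from several models for one target.

    Candidates are identified by their precursor set; the merged
    probability is the arithmetic mean over models, counting 0 for models
    that did not propose the candidate.  The merge is invariant to the
    order of the input lists, and combining n copies of one list is the
    identity.
    """
    if not lists:
        raise ValueError("ensemble_combine needs at least one proposal list")
    target = lists[0].target
    for pl in lists[1:]:
        if pl.target != target:
            raise ValueError("all proposal lists must share the same target")
    n_models = len(lists)
    sums: dict[frozenset[Molecule], float] = {}
    for pl in lists:
        for p in pl:
            sums[p.precursors] = sums.get(p.precursors, 0.0) + p.probability
    means = ((pre, s / n_models) for pre, s in sums.items())
    return _ranked_list(target, means, k)
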