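"""Pathway-level benchmark metrics.

For a set of benchmark cases (target, reference pathway, reference
building blocks) the report measures:

* **success rate** — fraction of targets with at least one route that
  terminates entirely in allowable building blocks;
* **hit rate of pathways** — fraction whose returned routes contain the
  reference pathway exactly, as a step multiset;
* **hit rate of building blocks** — fraction whose returned routes recover
  the reference blocks (exact leaf-set equality, or ≥1 shared block in
  ``any`` mode);
* **average solutions** and the **longest route length** over all cases.

An exact pathway hit implies an exact block hit, so
``pathway_hit_rate <= block_hit_rate`` always holds in exact mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .chem import Molecule, ReactionStep, strip_stereo
from .planner import BuildingBlockLibrary, PlannerConfig, Route, plan
from .proposer import Proposer

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkCase",
    "MetricsReport",
    "route_is_solution",
    "match_pathway",
    "match_building_blocks",
    "evaluate_benchmark",
]

CATEGORIES = ("AA/MA", "MVA/MEP", "CA/SA", "AAs", "Other")


@dataclass(frozen=True)
class BenchmarkCase:
    """One evaluation target with its reference pathway and blocks."""

    target: Molecule
    reference_pathway: tuple[ReactionStep, ...]
    reference_blocks: frozenset[Molecule]
    category: str = "Other"

    def __post_init__(self) -> None:
        if self.reference_pathway:
            products = {s.product for s in self.reference_pathway}
            leaves = {
                p for s in self.reference_pathway for p in s.precursors
            } - products
            if not leaves <= self.reference_blocks:
                raise ValueError(
                    "reference pathway leaves must lie in reference_blocks"
                )

    @property
    def pathway_blocks(self) -> frozenset[Molecule]:
        """The blocks actually consumed by the reference pathway.

        ``reference_blocks`` may be a superset (a whole allowable library);
        exact block recovery is judged against the blocks the reference
        pathway uses, so that an exact pathway hit is always a block hit.
        """
        if not self.reference_pathway:
            return self.reference_blocks
        products = {s.product for s in self.reference_pathway}
        leaves = frozenset(
            p for s in self.reference_pathway for p in s.precursors
        ) - products
        return frozenset(leaves) if leaves else self.reference_blocks


@dataclass
class MetricsReport:
    """Aggregate benchmark metrics; rates are fractions in [0, 1]."""

    n_cases: int
    success_rate: float
    pathway_hit_rate: float
    block_hit_rate: float
    avg_solutions: float
    longest_length: int
    per_category: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in (self.success_rate, self.pathway_hit_rate, self.block_hit_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.pathway_hit_rate > self.block_hit_rate + 1e-12:
            raise ValueError(
                "an exact pathway hit implies an exact block hit; "
                f"{self.pathway_hit_rate} > {self.block_hit_rate}"
            )

    def as_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "success_rate": self.success_rate,
            "pathway_hit_rate": self.pathway_hit_rate,
            "block_hit_rate": self.block_hit_rate,
            "avg_solutions": self.avg_solutions,
            "longest_length": self.longest_length,
            "per_category": self.per_category,
        }


def route_is_solution(route: Route, library: BuildingBlockLibrary) -> bool:
    """True iff every leaf of the route is a library building block."""
    return all(leaf in library for leaf in route.leaves)


def _step_multiset(steps, ignore_stereo: bool):
    def norm(m: Molecule) -> str:
        return strip_stereo(m).smiles if ignore_stereo else m.smiles

    return sorted(
        (tuple(sorted(norm(p) for p in s.precursors)), norm(s.product))
        for s in steps
    )


def match_pathway(
    route: Route, reference: tuple[ReactionStep, ...] | list[ReactionStep],
    ignore_stereo: bool = False,
) -> bool:
    """Exact pathway match: identical (precursor-set, product) multisets."""
    if not route.steps or not reference:
        return False
    return _step_multiset(route.steps, ignore_stereo) == _step_multiset(
        reference, ignore_stereo
    )


def match_building_blocks(
    routes: list[Route], reference_blocks: frozenset[Molecule],
    mode: str = "exact",
) -> bool:
    """Block recovery over a case's returned routes.

    ``exact``: some route's leaf set equals the reference blocks.
    ``any``: some route shares at least one leaf with them.
    """
    if mode not in ("exact", "any"):
        raise ValueError(f"unknown block-matching mode {mode!r}")
    for route in routes:
        if mode == "exact" and route.leaves == reference_blocks:
            return True
        if mode == "any" and route.leaves & reference_blocks:
            return True
    return False


def evaluate_benchmark(
    cases: list[BenchmarkCase],
    proposer: Proposer,
    library: BuildingBlockLibrary,
    cfg: PlannerConfig | None = None,
    block_mode: str = "exact",
    ignore_stereo: bool = False,
    udb: bool = False,
) -> MetricsReport:
    """Plan every case and aggregate the pathway-recovery metrics.

    With ``udb`` (user-defined building blocks) the termination library is
    replaced per case by the case's own reference blocks, so the search
    may stop only at those.  A planner failure on a case is logged and the
    case counted as unsolved.
    """
    if not cases:
        raise ValueError("need at least one benchmark case")
    cfg = cfg or PlannerConfig()
    n = len(cases)
    n_success = n_pathway = n_block = 0
    total_routes = 0
    longest = 0
    cat_counts: dict[str, dict[str, float]] = {}
    for case in cases:
        lib = (
            BuildingBlockLibrary(name="udb", members=case.reference_blocks)
            if udb else library
        )
        try:
            routes = plan(case.target, proposer, lib, cfg)
        except Exception:
            logger.exception("planner failed on %s; counted unsolved",
                             case.target.smiles)
            routes = []
        solutions = [r for r in routes if route_is_solution(r, lib)]
        total_routes += len(solutions)
        solved = bool(solutions)
        pathway_hit = any(
            match_pathway(r, case.reference_pathway, ignore_stereo)
            for r in solutions
        )
        block_reference = (
            case.pathway_blocks if block_mode == "exact" else case.reference_blocks
        )
        block_hit = match_building_blocks(
            solutions, block_reference, mode=block_mode
        )
        if solutions:
            longest = max(longest, max(r.length for r in solutions))
        n_success += solved
        n_pathway += pathway_hit
        n_block += block_hit
        bucket = cat_counts.setdefault(
            case.category,
            {"n": 0, "success": 0, "pathway_hit": 0, "block_hit": 0},
        )
        bucket["n"] += 1
        bucket["success"] += solved
        bucket["pathway_hit"] += pathway_hit
        bucket["block_hit"] += block_hit

    per_category = {
        cat: {
            "n_cases": int(c["n"]),
            "success_rate": c["success"] / c["n"],
            "pathway_hit_rate": c["pathway_hit"] / c["n"],
            "block_hit_rate": c["block_hit"] / c["n"],
        }
        for cat, c in cat_counts.items()
    }
    return MetricsReport(
        n_cases=n,
        success_rate=n_success / n,
        pathway_hit_rate=n_pathway / n,
        block_hit_rate=n_block / n,
        avg_solutions=total_routes / n,
        longest_length=longest,
        per_category=per_category,
    )
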