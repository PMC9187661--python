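"""Best-first AND-OR tree search for retro-biosynthesis planning.

The search tree alternates molecule (OR) nodes and reaction (AND) nodes:
a molecule is solved when it is a building block or when any one of its
producing reactions is solved; a reaction is solved only when all of its
precursor molecules are solved.  Each iteration selects the open frontier
molecule whose best enclosing partial route is cheapest — the partial
route's value combines the reaction costs already committed along the
route with a heuristic estimate (zero by default) for every unexpanded
leaf — and expands it with one AND-OR stump of single-step proposals.
With a nonnegative cost model and the zero heuristic this value is an
admissible lower bound on any completion, so routes are discovered in
nondecreasing order of total cost and the first complete route is optimal.

Each time a route completes, an optional bonus is credited to the nodes on
it, biasing later selection toward neighbourhoods of successful pathways.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

from .chem import Molecule, ReactionStep, canonicalize
from .proposer import Proposer

__all__ = [
    "BuildingBlockLibrary",
    "PlannerConfig",
    "Route",
    "AndOrTree",
    "MoleculeNode",
    "ReactionNode",
    "SearchExhausted",
    "plan",
    "extract_routes",
    "route_cost",
    "select_expansion_node",
    "expand_node",
]

_INF = math.inf


class SearchExhausted(Exception):
    """Raised when selection is requested from an empty or dead frontier."""


@dataclass(frozen=True)
class BuildingBlockLibrary:
    """A named set of terminal precursor metabolites.

    Membership is exact string equality of canonical SMILES; the backward
    search stops the moment it reaches any member.
    """

    name: str
    members: frozenset[Molecule]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("building-block library must be nonempty")

    def __contains__(self, m: Molecule) -> bool:
        return m in self.members

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_smiles(cls, smiles: Iterable[str], name: str = "user") -> "BuildingBlockLibrary":
        return cls(name=name, members=frozenset(canonicalize(s) for s in smiles))


@dataclass(frozen=True)
class PlannerConfig:
    """Search budget and shape parameters.

    ``iterations`` select/expand cycles, ``expansions`` proposals requested
    per expansion (the single-step top-N), ``max_depth`` reaction steps
    from the target, ``route_top_k`` distinct routes after which the search
    stops early, and ``bonus`` the credit granted to nodes on each newly
    completed route (0 disables the bias).  ``heuristic`` estimates the
    remaining cost below an unexpanded molecule; the default 0 keeps the
    search admissible.
    """

    iterations: int = 100
    expansions: int = 10
    max_depth: int = 10
    route_top_k: int = 5
    bonus: float = 0.0
    heuristic: Callable[[Molecule], float] | None = None

    def __post_init__(self) -> None:
        if min(self.iterations, self.expansions, self.max_depth, self.route_top_k) < 1:
            raise ValueError("iterations, expansions, max_depth, route_top_k must be >= 1")
        if self.bonus < 0:
            raise ValueError("bonus must be >= 0")

    def h(self, m: Molecule) -> float:
        return self.heuristic(m) if self.heuristic is not None else 0.0


@dataclass(frozen=True)
class Route:
    """A solved pathway: a tree of reaction steps from target to blocks."""

    target: Molecule
    steps: tuple[ReactionStep, ...]
    leaves: frozenset[Molecule]
    total_cost: float
    length: int

    @property
    def key(self) -> tuple:
        """Step-multiset identity used for route distinctness."""
        return tuple(sorted(s.key for s in self.steps))


def route_cost(route: Route) -> float:
    """Total route cost: the sum of its step costs."""
    return sum(s.cost for s in route.steps)


class MoleculeNode:
    """OR node: one molecule to be decomposed (or recognised as a block)."""

    __slots__ = (
        "molecule", "depth", "parent", "children", "in_library",
        "expanded", "dead", "bonus_credit", "rn", "order",
    )

    def __init__(self, molecule: Molecule, depth: int, parent: "ReactionNode | None",
                 in_library: bool, h: float, order: int) -> None:
        self.molecule = molecule
        self.depth = depth
        self.parent = parent
        self.children: list[ReactionNode] = []
        self.in_library = in_library
        self.expanded = False
        self.dead = False
        self.bonus_credit = 0.0
        self.rn = 0.0 if in_library else h
        self.order = order

    @property
    def solved(self) -> bool:
        return self.in_library or any(c.solved for c in self.children)

    @property
    def open(self) -> bool:
        return not (self.in_library or self.expanded or self.dead)

    @property
    def status(self) -> str:
        if self.solved:
            return "solved"
        if self.dead:
            return "dead"
        return "open"

    def ancestors(self) -> set[Molecule]:
        """Molecules on the path from the root down to (and including) self."""
        out = {self.molecule}
        node = self.parent
        while node is not None:
            out.add(node.parent.molecule)
            node = node.parent.parent
        return out


class ReactionNode:
    """AND node: one proposed step; solved only when every precursor is."""

    __slots__ = ("step", "parent", "children", "rn")

    def __init__(self, step: ReactionStep, parent: MoleculeNode) -> None:
        self.step = step
        self.parent = parent
        self.children: list[MoleculeNode] = []
        self.rn = step.cost

    @property
    def solved(self) -> bool:
        return all(c.solved for c in self.children)

    @property
    def dead(self) -> bool:
        return any(c.dead for c in self.children)


class AndOrTree:
    """The search state rooted at one target molecule."""

    def __init__(self, target: Molecule, library: BuildingBlockLibrary,
                 cfg: PlannerConfig) -> None:
        self.library = library
        self.cfg = cfg
        self._counter = itertools.count()
        self.root = MoleculeNode(
            target, depth=0, parent=None, in_library=target in library,
            h=cfg.h(target), order=next(self._counter),
        )
        self.molecule_nodes: list[MoleculeNode] = [self.root]
        self.iterations_used = 0

    # ---- value bookkeeping -------------------------------------------------

    def _update_rn_upward(self, node: MoleculeNode) -> None:
        """Refresh best-completion estimates from ``node`` to the root."""
        current: MoleculeNode | None = node
        while current is not None:
            if current.in_library:
                current.rn = 0.0
            elif current.dead:
                current.rn = _INF
            elif current.expanded:
                child_rns = []
                for r in current.children:
                    r.rn = r.step.cost + sum(c.rn for c in r.children)
                    child_rns.append(r.rn)
                current.rn = min(child_rns) if child_rns else _INF
            parent_rxn = current.parent
            if parent_rxn is None:
                break
            parent_rxn.rn = parent_rxn.step.cost + sum(c.rn for c in parent_rxn.children)
            current = parent_rxn.parent

    def _frontier_values(self) -> list[tuple[float, int, MoleculeNode]]:
        """Partial-route value of every open frontier molecule, top-down.

        V(root) = rn(root); stepping into reaction r of molecule m adds
        rn(r) − rn(m); every molecule child of r inherits V(r), because r's
        value already accounts for all of its precursor subtrees.
        """
        out: list[tuple[float, int, MoleculeNode]] = []

        def walk(m: MoleculeNode, v: float) -> None:
            if m.open:
                if v < _INF:
                    out.append((v - m.bonus_credit, m.order, m))
                return
            for r in m.children:
                vr = v - m.rn + r.rn
                for c in r.children:
                    walk(c, vr)

        walk(self.root, self.root.rn)
        return out

    # ---- search steps ------------------------------------------------------

    def select_expansion_node(self) -> MoleculeNode:
        """The open frontier molecule with minimal value V = g + h − bonus.

        Ties break toward the earliest-inserted node.
        """
        frontier = self._frontier_values()
        if not frontier:
            raise SearchExhausted("no open frontier node remains")
        return min(frontier, key=lambda t: (t[0], t[1]))[2]

    def expand_node(self, node: MoleculeNode, proposer: Proposer,
                    k: int | None = None) -> None:
        """Grow one AND-OR stump of single-step proposals under ``node``.

        Proposals re-introducing any molecule on the branch back to the
        root are discarded (cycle guard); an empty valid set kills the
        node.  Precursors already in the library are solved on creation;
        precursors at the depth cap are dead on creation.
        """
        if not node.open:
            raise ValueError("only open frontier nodes can be expanded")
        if node.depth >= self.cfg.max_depth:
            node.dead = True
            self._update_rn_upward(node)
            return
        k = k if k is not None else self.cfg.expansions
        ancestors = node.ancestors()
        for prop in proposer.propose(node.molecule, k):
            if prop.precursors & ancestors:
                continue
            rxn = ReactionNode(prop.as_step(node.molecule), parent=node)
            for pre in sorted(prop.precursors):
                child = MoleculeNode(
                    pre, depth=node.depth + 1, parent=rxn,
                    in_library=pre in self.library, h=self.cfg.h(pre),
                    order=next(self._counter),
                )
                if not child.in_library and child.depth >= self.cfg.max_depth:
                    child.dead = True
                    child.rn = _INF
                rxn.children.append(child)
                self.molecule_nodes.append(child)
            node.children.append(rxn)
        node.expanded = True
        if not node.children:
            node.dead = True
        self._update_rn_upward(node)

    # ---- route extraction --------------------------------------------------

    def enumerate_routes(self, cap: int) -> list[Route]:
        """All distinct solved routes (up to ``cap`` per node), cost-sorted."""
        memo: dict[int, list[tuple[float, int, tuple[ReactionStep, ...], frozenset[Molecule]]]] = {}

        def routes_of(m: MoleculeNode):
            if id(m) in memo:
                return memo[id(m)]
            if m.in_library:
                result = [(0.0, 0, (), frozenset([m.molecule]))]
            else:
                result = []
                for r in m.children:
                    if not r.solved:
                        continue
                    parts = [routes_of(c) for c in r.children]
                    for combo in itertools.product(*parts):
                        cost = r.step.cost + sum(p[0] for p in combo)
                        length = 1 + max((p[1] for p in combo), default=0)
                        steps = (r.step,) + tuple(
                            s for p in combo for s in p[2]
                        )
                        leaves = frozenset().union(*(p[3] for p in combo))
                        result.append((cost, length, steps, leaves))
                result.sort(key=lambda t: t[0])
                del result[cap:]
            memo[id(m)] = result
            return result

        if not self.root.solved:
            return []
        seen: set[tuple] = set()
        routes = []
        for cost, length, steps, leaves in routes_of(self.root):
            route = Route(
                target=self.root.molecule, steps=steps, leaves=leaves,
                total_cost=cost, length=length,
            )
            if route.key in seen:
                continue
            seen.add(route.key)
            routes.append(route)
        routes.sort(key=lambda r: r.total_cost)
        return routes

    def _credit_bonus(self, route: Route) -> None:
        """Grant the solution bonus to every molecule node on ``route``."""
        step_keys = {s.key for s in route.steps}

        def walk(m: MoleculeNode) -> None:
            m.bonus_credit += self.cfg.bonus
            for r in m.children:
                if r.step.key in step_keys:
                    for c in r.children:
                        walk(c)

        walk(self.root)


def select_expansion_node(tree: AndOrTree) -> MoleculeNode:
    """Functional wrapper over :meth:`AndOrTree.select_expansion_node`."""
    return tree.select_expansion_node()


def expand_node(tree: AndOrTree, node: MoleculeNode, proposer: Proposer,
                k: int | None = None) -> AndOrTree:
    """Functional wrapper over :meth:`AndOrTree.expand_node`."""
    tree.expand_node(node, proposer, k)
    return tree


def extract_routes(tree: AndOrTree, top_k: int) -> list[Route]:
    """Up to ``top_k`` distinct solved routes, cheapest first.

    Distinctness is by step multiset; ties in cost keep enumeration order.
    """
    cap = max(top_k * 4, 64)
    return tree.enumerate_routes(cap)[:top_k]


def plan(
    target: Molecule | str,
    proposer: Proposer,
    library: BuildingBlockLibrary,
    cfg: PlannerConfig | None = None,
) -> list[Route]:
    """Search for routes from ``target`` down to the building-block library.

    Runs at most ``cfg.iterations`` select/expand cycles, stopping early
    once ``cfg.route_top_k`` distinct routes exist or the frontier is
    exhausted.  Returns routes sorted by nondecreasing total cost (empty
    when no route terminates entirely in building blocks).
    """
    cfg = cfg or PlannerConfig()
    if isinstance(target, str):
        target = canonicalize(target)
    tree = AndOrTree(target, library, cfg)
    if tree.root.in_library:
        return [Route(target=target, steps=(), leaves=frozenset([target]),
                      total_cost=0.0, length=0)]
    known_routes: set[tuple] = set()
    for _ in range(cfg.iterations):
        try:
            node = tree.select_expansion_node()
        except SearchExhausted:
            break
        tree.expand_node(node, proposer)
        tree.iterations_used += 1
        if tree.root.solved:
            routes = tree.enumerate_routes(cap=max(cfg.route_top_k * 4, 64))
            for route in routes:
                if route.key not in known_routes:
                    known_routes.add(route.key)
                    if cfg.bonus > 0:
                        tree._credit_bonus(route)
            if len(known_routes) >= cfg.route_top_k:
                # the top-k set is final only once no open partial route
                # can still undercut its most expensive member: a route
                # completes the moment its last leaf closes, so the k-th
                # found route is not yet proven k-th best
                kth_cost = routes[min(cfg.route_top_k, len(routes)) - 1].total_cost
                frontier = tree._frontier_values()
                if not frontier or min(v for v, _, _ in frontier) >= kth_cost - 1e-12:
                    break
    return extract_routes(tree, cfg.route_top_k)
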