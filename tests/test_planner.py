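"""AND-OR best-first search: selection, expansion, routes, optimality."""

import pytest

from bioretro.chem import canonicalize, parse_reaction_record
from bioretro.planner import (
    AndOrTree,
    BuildingBlockLibrary,
    PlannerConfig,
    Route,
    SearchExhausted,
    extract_routes,
    plan,
    route_cost,
)
from bioretro.proposer import build_table_proposer

from .oracles import enumerate_all_routes


def cfg(**kw):
    base = dict(iterations=200, expansions=10, max_depth=10, route_top_k=5)
    base.update(kw)
    return PlannerConfig(**base)


class TestSelection:
    def test_min_value_frontier_node_selected(self, toy_network, toy_proposer):
        tree = AndOrTree(toy_network["target"], toy_network["library"], cfg())
        tree.expand_node(tree.root, toy_proposer)
        # frontier now holds M1 under R3 (partial value 0.1+0) only:
        # R4's children are library blocks and never enter the frontier
        node = tree.select_expansion_node()
        assert node.molecule == canonicalize("CCCO")

    def test_tie_breaks_by_insertion_order(self):
        steps = [
            parse_reaction_record("CCCO>>CCCCO", cost=0.3),
            parse_reaction_record("CCCN>>CCCCO", cost=0.3),
        ]
        proposer = build_table_proposer(steps)
        lib = BuildingBlockLibrary.from_smiles(["CCO"], name="t")
        tree = AndOrTree(canonicalize("CCCCO"), lib, cfg())
        tree.expand_node(tree.root, proposer)
        first = tree.select_expansion_node()
        others = [
            c for r in tree.root.children for c in r.children if c is not first
        ]
        assert others and first.order < min(o.order for o in others)

    def test_exhausted_frontier_raises(self, toy_network):
        proposer = build_table_proposer([])
        tree = AndOrTree(toy_network["target"], toy_network["library"], cfg())
        tree.expand_node(tree.root, proposer)  # no proposals: root dead
        with pytest.raises(SearchExhausted):
            tree.select_expansion_node()


class TestExpansion:
    def test_cycle_guard_discards_ancestor_proposals(self):
        # A>>B and B>>A: expanding B under A must not re-propose A
        steps = [
            parse_reaction_record("CCCO>>CCCCO", cost=0.1),
            parse_reaction_record("CCCCO>>CCCO", cost=0.1),
        ]
        proposer = build_table_proposer(steps)
        lib = BuildingBlockLibrary.from_smiles(["CCO"], name="t")
        tree = AndOrTree(canonicalize("CCCCO"), lib, cfg())
        tree.expand_node(tree.root, proposer)
        child = tree.select_expansion_node()
        tree.expand_node(child, proposer)
        assert child.dead  # its only proposal was the root molecule

    def test_all_library_precursors_solve_immediately(self, toy_network,
                                                     toy_proposer):
        tree = AndOrTree(toy_network["target"], toy_network["library"], cfg())
        tree.expand_node(tree.root, toy_proposer)
        # R4 = B1.B2>>T has both precursors in the library
        assert tree.root.solved

    def test_depth_cap_kills_node(self, toy_network, toy_proposer):
        shallow = cfg(max_depth=1)
        tree = AndOrTree(toy_network["target"], toy_network["library"], shallow)
        tree.expand_node(tree.root, toy_proposer)
        m1 = [c for r in tree.root.children for c in r.children
              if not c.in_library]
        assert m1 and all(c.dead for c in m1)


class TestPlan:
    def test_toy_network_routes_match_enumeration(self, toy_network,
                                                  toy_proposer):
        routes = plan(toy_network["target"], toy_proposer,
                      toy_network["library"], cfg())
        expected = enumerate_all_routes(
            toy_network["steps"], toy_network["blocks"], toy_network["target"]
        )
        assert [r.total_cost for r in routes] == pytest.approx(
            [c for c, _ in expected]
        )  # 0.3, 0.6, 0.9
        assert routes[0].length == 2 and routes[2].length == 1

    def test_target_in_library_is_a_zero_step_route(self, toy_network,
                                                    toy_proposer):
        target = canonicalize("CCO")
        routes = plan(target, toy_proposer, toy_network["library"], cfg())
        assert len(routes) == 1
        assert routes[0].steps == () and routes[0].total_cost == 0.0
        assert routes[0].leaves == frozenset([target])

    def test_no_proposals_means_no_routes(self, toy_network):
        routes = plan(toy_network["target"], build_table_proposer([]),
                      toy_network["library"], cfg())
        assert routes == []

    def test_route_validity_invariants(self, toy_network, toy_proposer):
        routes = plan(toy_network["target"], toy_proposer,
                      toy_network["library"], cfg())
        for r in routes:
            assert r.leaves <= toy_network["library"].members
            assert r.length <= cfg().max_depth
            assert route_cost(r) == pytest.approx(r.total_cost)
            products = [s.product for s in r.steps]
            assert len(products) == len(set(products))  # acyclic tree

    def test_determinism(self, toy_network, toy_proposer):
        a = plan(toy_network["target"], toy_proposer, toy_network["library"], cfg())
        b = plan(toy_network["target"], toy_proposer, toy_network["library"], cfg())
        assert [r.key for r in a] == [r.key for r in b]

    def test_bonus_biases_selection_not_correctness(self, toy_network,
                                                    toy_proposer):
        routes = plan(toy_network["target"], toy_proposer,
                      toy_network["library"], cfg(bonus=0.5))
        assert routes[0].total_cost == pytest.approx(0.3)


class TestExtractRoutes:
    def test_unsolved_tree_yields_nothing(self, toy_network):
        tree = AndOrTree(toy_network["target"], toy_network["library"], cfg())
        assert extract_routes(tree, top_k=5) == []

    def test_top_k_truncation(self, toy_network, toy_proposer):
        r1 = plan(toy_network["target"], toy_proposer, toy_network["library"],
                  cfg(route_top_k=1))
        assert len(r1) == 1 and r1[0].total_cost == pytest.approx(0.3)
        r2 = plan(toy_network["target"], toy_proposer, toy_network["library"],
                  cfg(route_top_k=2))
        assert [r.total_cost for r in r2] == pytest.approx([0.3, 0.6])


class TestRouteCost:
    def test_empty_route_costs_zero(self):
        target = canonicalize("CCO")
        r = Route(target=target, steps=(), leaves=frozenset([target]),
                  total_cost=0.0, length=0)
        assert route_cost(r) == 0.0

    def test_cost_is_sum_of_steps(self):
        s1 = parse_reaction_record("CCO>>CCCO", cost=0.1)
        s2 = parse_reaction_record("CCCO>>CCCCO", cost=0.2)
        r = Route(target=canonicalize("CCCCO"), steps=(s2, s1),
                  leaves=frozenset([canonicalize("CCO")]),
                  total_cost=0.3, length=2)
        assert route_cost(r) == pytest.approx(0.3)
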