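"""Independent brute-force oracles used only by the test suite.

The maximum-common-substructure oracle enumerates every connected
edge-subgraph of the smaller molecule and checks embeddability into the
other via subgraph monomorphism, with the same matching rules the
implementation configures (elements must match, bond order ignored, ring
bonds/atoms only match ring bonds/atoms).  Exponential, therefore only
for molecules of a dozen heavy atoms or fewer.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
from networkx.algorithms import isomorphism
from rdkit import Chem


def mol_graph(smiles: str) -> nx.Graph:
    mol = Chem.MolFromSmiles(smiles)
    g = nx.Graph()
    for a in mol.GetAtoms():
        if a.GetAtomicNum() > 1:
            g.add_node(a.GetIdx(), element=a.GetSymbol(), ring=a.IsInRing())
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if g.has_node(i) and g.has_node(j):
            g.add_edge(i, j, ring=b.IsInRing())
    return g


def _node_match(a: dict, b: dict) -> bool:
    return a["element"] == b["element"] and a["ring"] == b["ring"]


def _edge_match(a: dict, b: dict) -> bool:
    return a["ring"] == b["ring"]


def max_common_subgraph_atoms(smiles_a: str, smiles_b: str) -> int:
    """Heavy-atom count of the largest connected common subgraph."""
    ga, gb = mol_graph(smiles_a), mol_graph(smiles_b)
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga
    best = 0
    host_nodes = list(gb.nodes(data=True))
    for _, attrs in ga.nodes(data=True):
        if any(_node_match(h, attrs) for _, h in host_nodes):
            best = 1
            break
    edges = list(ga.edges)
    for r in range(1, len(edges) + 1):
        for subset in combinations(edges, r):
            sg = nx.Graph()
            for u, v in subset:
                sg.add_node(u, **ga.nodes[u])
                sg.add_node(v, **ga.nodes[v])
                sg.add_edge(u, v, **ga.edges[u, v])
            if sg.number_of_nodes() <= best or not nx.is_connected(sg):
                continue
            gm = isomorphism.GraphMatcher(
                gb, sg, node_match=_node_match, edge_match=_edge_match
            )
            if gm.subgraph_is_monomorphic():
                best = sg.number_of_nodes()
    return best


def enumerate_all_routes(reactions, blocks, target, max_depth=20):
    """Every route from target to blocks in a reaction table, by recursion.

    Routes are (total_cost, step_list) tuples; shared precursors are
    costed per occurrence (tree semantics).  Only for tiny networks.
    """
    by_product = {}
    for step in reactions:
        by_product.setdefault(step.product, []).append(step)

    def routes_of(mol, depth, visited):
        if mol in blocks:
            return [(0.0, [])]
        if depth >= max_depth:
            return []
        out = []
        for step in by_product.get(mol, []):
            if any(p in visited for p in step.precursors):
                continue
            partials = [(step.cost, [step])]
            for pre in sorted(step.precursors):
                sub = routes_of(pre, depth + 1, visited | {mol})
                partials = [
                    (c + sc, s + ss) for c, s in partials for sc, ss in sub
                ]
            out.extend(partials)
        return out

    return sorted(routes_of(target, 0, set()), key=lambda t: t[0])
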