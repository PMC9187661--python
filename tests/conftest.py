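"""Shared fixtures: toy networks, planted benchmarks, CoA examples."""

from __future__ import annotations

import pytest

from bioretro.chem import canonicalize, default_coa_fragment, parse_reaction_record
from bioretro.evaluation import BenchmarkCase
from bioretro.planner import BuildingBlockLibrary
from bioretro.proposer import build_table_proposer

B1, B2 = "CCO", "CCN"
M1, T = "CCCO", "CCCCO"


@pytest.fixture(scope="session")
def toy_network():
    """Four-reaction network with three enumerable routes to the target.

    R1: B1>>M1 (0.2);  R2: B2>>M1 (0.5);  R3: M1>>T (0.1);  R4: B1.B2>>T (0.9)
    Routes to T: (R3,R1)=0.3 < (R3,R2)=0.6 < (R4)=0.9.
    """
    steps = [
        parse_reaction_record(f"{B1}>>{M1}", cost=0.2, provenance="R1"),
        parse_reaction_record(f"{B2}>>{M1}", cost=0.5, provenance="R2"),
        parse_reaction_record(f"{M1}>>{T}", cost=0.1, provenance="R3"),
        parse_reaction_record(f"{B1}.{B2}>>{T}", cost=0.9, provenance="R4"),
    ]
    return {
        "steps": steps,
        "target": canonicalize(T),
        "library": BuildingBlockLibrary.from_smiles([B1, B2], name="toy"),
        "blocks": {canonicalize(B1), canonicalize(B2)},
    }


@pytest.fixture(scope="session")
def toy_proposer(toy_network):
    return build_table_proposer(toy_network["steps"])


@pytest.fixture(scope="session")
def planted_benchmark():
    """Three hand-planted cases: pathway hit / block hit only / unsolved.

    * T1: the table reproduces the reference step exactly.
    * T2: the table reaches the reference blocks via a different pathway.
    * T3: no reaction produces it.
    """
    t1, t2, t3 = "CCCO", "CCCN", "CCCS"
    mid = "CCNC"
    table = [
        parse_reaction_record(f"{B1}>>{t1}", cost=0.1),
        parse_reaction_record(f"{B2}>>{mid}", cost=0.2),
        parse_reaction_record(f"{mid}>>{t2}", cost=0.3),
    ]
    cases = [
        BenchmarkCase(
            target=canonicalize(t1),
            reference_pathway=(parse_reaction_record(f"{B1}>>{t1}"),),
            reference_blocks=frozenset([canonicalize(B1)]),
        ),
        BenchmarkCase(
            target=canonicalize(t2),
            reference_pathway=(parse_reaction_record(f"{B2}>>{t2}"),),
            reference_blocks=frozenset([canonicalize(B2)]),
        ),
        BenchmarkCase(
            target=canonicalize(t3),
            reference_pathway=(parse_reaction_record(f"{B1}>>{t3}"),),
            reference_blocks=frozenset([canonicalize(B1)]),
        ),
    ]
    return {
        "cases": cases,
        "proposer": build_table_proposer(table),
        "library": BuildingBlockLibrary.from_smiles([B1, B2], name="toy"),
    }


@pytest.fixture(scope="session")
def acetyl_coa_smiles():
    return "CC(=O)" + default_coa_fragment()


@pytest.fixture(scope="session")
def malonyl_coa_smiles():
    return "O=C(O)CC(=O)" + default_coa_fragment()
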