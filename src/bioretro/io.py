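"""File formats: reaction tables, molecule lists, benchmark and route JSON.

Reaction files are UTF-8 text, one reaction SMILES per line with optional
tab-separated trailing columns (id/probability/source).  Molecule lists
are one SMILES per line with ``#`` comments.  Benchmarks and routes are
JSON, checked against small structural schemas before use.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

from .chem import (
    Molecule,
    ReactionStep,
    canonicalize,
    format_reaction,
    parse_reaction_record,
    read_molecule_list,
)
from .evaluation import BenchmarkCase
from .planner import BuildingBlockLibrary, Route
from .proposer import cost_of

__all__ = [
    "read_reaction_file",
    "write_reaction_file",
    "read_building_blocks",
    "core_library",
    "read_benchmark",
    "write_benchmark",
    "routes_to_json",
    "validate_routes_json",
]


def read_reaction_file(path: str | Path) -> list[ReactionStep]:
    """Read a reaction table; a numeric third field is a probability.

    Line layout: ``reaction_smiles[<TAB>id_or_prob[<TAB>source]]``.  A
    parseable float in the second column is taken as the step probability
    and converted to a cost; otherwise the column is kept as provenance.
    """
    steps = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        fields = body.split("\t")
        cost = 0.0
        provenance = ""
        for extra in fields[1:]:
            try:
                cost = cost_of(float(extra))
            except ValueError:
                provenance = extra
        try:
            steps.append(parse_reaction_record(fields[0], cost=cost,
                                               provenance=provenance))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return steps


def write_reaction_file(path: str | Path, steps: Iterable[ReactionStep]) -> None:
    lines = []
    for step in steps:
        prob = math.exp(-step.cost)
        lines.append(f"{format_reaction(step)}\t{prob:.6g}\t{step.provenance}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_building_blocks(path: str | Path, name: str = "user") -> BuildingBlockLibrary:
    mols = read_molecule_list(Path(path).read_text(encoding="utf-8").splitlines())
    return BuildingBlockLibrary(name=name, members=frozenset(mols))


def core_library() -> BuildingBlockLibrary:
    """The default core building-block library shipped with the package."""
    import importlib.resources

    text = (
        importlib.resources.files("bioretro.data")
        .joinpath("building_blocks_core.smi")
        .read_text(encoding="utf-8")
    )
    mols = read_molecule_list(text.splitlines())
    return BuildingBlockLibrary(name="core", members=frozenset(mols))


# ---- benchmark JSON --------------------------------------------------------

def read_benchmark(path: str | Path) -> list[BenchmarkCase]:
    """Load a benchmark: JSON list of {target, pathway, blocks, category}."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, list):
        raise ValueError("benchmark file must contain a JSON list of cases")
    cases = []
    for i, entry in enumerate(data):
        for key in ("target", "pathway", "blocks"):
            if key not in entry:
                raise ValueError(f"case {i}: missing required key {key!r}")
        cases.append(
            BenchmarkCase(
                target=canonicalize(entry["target"]),
                reference_pathway=tuple(
                    parse_reaction_record(r) for r in entry["pathway"]
                ),
                reference_blocks=frozenset(
                    canonicalize(s) for s in entry["blocks"]
                ),
                category=entry.get("category", "Other"),
            )
        )
    return cases


def write_benchmark(path: str | Path, cases: list[BenchmarkCase]) -> None:
    data = [
        {
            "target": c.target.smiles,
            "pathway": [format_reaction(s) for s in c.reference_pathway],
            "blocks": sorted(m.smiles for m in c.reference_blocks),
            "category": c.category,
        }
        for c in cases
    ]
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


# ---- route JSON ------------------------------------------------------------

def routes_to_json(target: Molecule, routes: list[Route]) -> dict:
    return {
        "target": target.smiles,
        "routes": [
            {
                "total_cost": r.total_cost,
                "length": r.length,
                "steps": [
                    {
                        "precursors": sorted(m.smiles for m in s.precursors),
                        "product": s.product.smiles,
                        "cost": s.cost,
                        "provenance": s.provenance,
                    }
                    for s in r.steps
                ],
                "leaves": sorted(m.smiles for m in r.leaves),
            }
            for r in routes
        ],
    }


def validate_routes_json(doc: dict) -> None:
    """Structural check of a route document; raises ValueError on defects."""
    if not isinstance(doc, dict) or set(doc) != {"target", "routes"}:
        raise ValueError("route document must have exactly target and routes")
    if not isinstance(doc["target"], str):
        raise ValueError("target must be a SMILES string")
    for i, route in enumerate(doc["routes"]):
        for key, typ in (
            ("total_cost", (int, float)), ("length", int),
            ("steps", list), ("leaves", list),
        ):
            if key not in route or not isinstance(route[key], typ):
                raise ValueError(f"route {i}: bad or missing {key!r}")
        step_cost = 0.0
        for j, step in enumerate(route["steps"]):
            for key in ("precursors", "product", "cost", "provenance"):
                if key not in step:
                    raise ValueError(f"route {i} step {j}: missing {key!r}")
            if not step["precursors"]:
                raise ValueError(f"route {i} step {j}: empty precursors")
            step_cost += step["cost"]
        if abs(step_cost - route["total_cost"]) > 1e-6:
            raise ValueError(f"route {i}: total_cost does not equal step sum")
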