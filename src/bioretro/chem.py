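"""Molecule and reaction-step primitives.

All molecules in this package are carried as canonical SMILES strings so
that equality, set membership (building-block termination) and pathway
matching reduce to exact string comparison.  Coenzyme A is a 48-heavy-atom
carrier that rarely participates in the reaction centre; following common
practice in biosynthesis modelling it can be collapsed to a single ``*``
attachment point and restored on output.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "ReactionStep",
    "InvalidSmilesError",
    "ReactionFormatError",
    "canonicalize",
    "parse_reaction_record",
    "format_reaction",
    "mask_coa",
    "unmask_coa",
    "strip_stereo",
    "default_coa_fragment",
]


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


class ReactionFormatError(ValueError):
    """Raised when a reaction record violates the ``p1.p2>>prod`` format."""


@dataclass(frozen=True, order=True)
class Molecule:
    """A molecule identified by its canonical SMILES.

    ``is_masked`` flags CoA-masked forms carrying a ``*`` attachment point.
    ``heavy_atom_count`` excludes the ``*`` dummy: it is a bookkeeping
    token, not an atom.
    """

    smiles: str
    is_masked: bool = field(default=False, compare=False)
    heavy_atom_count: int = field(default=0, compare=False)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles


@dataclass(frozen=True)
class ReactionStep:
    """One retro step: a set of precursors producing a single product.

    ``cost`` is the step's confidence score, the negative log-likelihood of
    the step under whichever proposer produced it (0 for raw database
    records that have not been scored).
    """

    precursors: frozenset[Molecule]
    product: Molecule
    cost: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.precursors:
            raise ValueError("a reaction step needs at least one precursor")
        if self.product in self.precursors:
            raise ValueError(
                f"self-loop step: product {self.product.smiles} among precursors"
            )
        if self.cost < 0:
            raise ValueError(f"negative step cost {self.cost}")

    @property
    def key(self) -> tuple[tuple[str, ...], str]:
        """Identity of the step: sorted precursor SMILES plus product SMILES."""
        return (tuple(sorted(m.smiles for m in self.precursors)), self.product.smiles)


def _mol_from_smiles(raw: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {raw!r}")
    return mol


def _heavy_atoms(mol: Chem.Mol) -> int:
    # dummy atoms (atomic number 0) are excluded on purpose
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _molecule_from_mol(mol: Chem.Mol) -> Molecule:
    smiles = Chem.MolToSmiles(mol)
    n_dummy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    return Molecule(
        smiles=smiles,
        is_masked=n_dummy > 0,
        heavy_atom_count=_heavy_atoms(mol),
    )


def canonicalize(raw: str) -> Molecule:
    """Parse ``raw`` and return the canonical :class:`Molecule`.

    Stereochemistry descriptors are preserved.  Canonicalization is
    idempotent: feeding the returned SMILES back yields an equal molecule.

    Raises
    ------
    InvalidSmilesError
        If ``raw`` is empty or not valid SMILES.
    """
    if not raw or not raw.strip():
        raise InvalidSmilesError("empty SMILES string")
    return _molecule_from_mol(_mol_from_smiles(raw.strip()))


def parse_reaction_record(line: str, cost: float = 0.0, provenance: str = "") -> ReactionStep:
    """Parse one reaction SMILES record ``precursor1.precursor2>>product``.

    The right-hand side must be a single component (multi-product records
    are decomposed upstream, see :func:`bioretro.curation.decompose_multiproduct`).
    Precursor order is not significant; they form a set.
    """
    text = line.strip()
    if text.count(">>") != 1:
        raise ReactionFormatError(f"expected exactly one '>>' separator in {line!r}")
    left, right = text.split(">>")
    if not left.strip() or not right.strip():
        raise ReactionFormatError(f"empty reaction side in {line!r}")
    product_parts = [p for p in right.split(".") if p.strip()]
    if len(product_parts) != 1:
        raise ReactionFormatError(
            f"expected a single product component, got {len(product_parts)} in {line!r}"
        )
    precursors = frozenset(
        canonicalize(part) for part in left.split(".") if part.strip()
    )
    product = canonicalize(product_parts[0])
    return ReactionStep(precursors=precursors, product=product, cost=cost,
                        provenance=provenance)


def format_reaction(step: ReactionStep) -> str:
    """Render a step back to ``p1.p2>>prod`` with precursors sorted."""
    left = ".".join(sorted(m.smiles for m in step.precursors))
    return f"{left}>>{step.product.smiles}"


@lru_cache(maxsize=1)
def default_coa_fragment() -> str:
    """The S-rooted coenzyme A fragment SMILES shipped with the package."""
    text = (
        importlib.resources.files("bioretro.data")
        .joinpath("coa_fragment.smi")
        .read_text(encoding="utf-8")
    )
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            return line
    raise RuntimeError("coa_fragment.smi contains no pattern")


@lru_cache(maxsize=4)
def _coa_query(fragment: str) -> Chem.Mol:
    query = _mol_from_smiles(fragment)
    # stereo-agnostic matching: databases annotate the carrier inconsistently
    Chem.RemoveStereochemistry(query)
    return query


def mask_coa(m: Molecule, fragment: str | None = None) -> Molecule:
    """Collapse every coenzyme A moiety of ``m`` to a ``*`` attachment point.

    The configured fragment is rooted at the thiol sulfur, so the ``*``
    stands for S-CoA and a thioester ``CC(=O)S-CoA`` becomes ``CC(=O)*``.
    Molecules without the moiety — and free CoA itself, whose masked form
    would be a bare dummy — are returned unchanged.
    """
    fragment = fragment or default_coa_fragment()
    mol = _mol_from_smiles(m.smiles)
    query = _coa_query(fragment)
    if not mol.HasSubstructMatch(query):
        return m
    replaced = Chem.ReplaceSubstructs(
        mol, query, Chem.MolFromSmiles("*"), replaceAll=True
    )[0]
    out = Chem.MolFromSmiles(Chem.MolToSmiles(replaced))
    if out is None or _heavy_atoms(out) == 0:
        return m
    return _molecule_from_mol(out)


def unmask_coa(m: Molecule, fragment: str | None = None) -> Molecule:
    """Restore every ``*`` attachment point of a masked molecule to S-CoA."""
    if "*" not in m.smiles:
        return m
    fragment = fragment or default_coa_fragment()
    mol = _mol_from_smiles(m.smiles)
    replaced = Chem.ReplaceSubstructs(
        mol,
        Chem.MolFromSmarts("[#0]"),
        _mol_from_smiles(fragment),
        replaceAll=True,
    )[0]
    out = Chem.MolFromSmiles(Chem.MolToSmiles(replaced))
    if out is None:
        raise InvalidSmilesError(f"unmasking produced invalid structure from {m.smiles}")
    return _molecule_from_mol(out)


def strip_stereo(m: Molecule) -> Molecule:
    """Remove all tetrahedral and double-bond stereo descriptors."""
    mol = _mol_from_smiles(m.smiles)
    Chem.RemoveStereochemistry(mol)
    return _molecule_from_mol(mol)


def read_molecule_list(lines: Iterable[str]) -> list[Molecule]:
    """Read a molecule list: one SMILES per line, ``#`` comments allowed."""
    out = []
    for line in lines:
        body = line.split("#", 1)[0].strip()
        if body:
            out.append(canonicalize(body.split("\t")[0]))
    return out
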