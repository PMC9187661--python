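"""Reaction-dataset curation.

Builds a precursor–metabolite pair dataset from raw multi-substrate,
multi-product reaction records: multi-product decomposition, cofactor
removal, maximum-common-substructure pair derivation, natural-product
similarity screening, a stereochemistry audit, and reproducible splits.

The central filtering rule keeps a (substrates, product) pair only when
some substrate shares a maximum common substructure covering more than a
configurable fraction (default 0.4) of the product's heavy atoms — i.e.
the substrate plausibly contributes the product's skeleton rather than
acting as a donor of a small group.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFMCS
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem import FindPotentialStereo

from .chem import Molecule, ReactionStep, canonicalize, mask_coa

logger = logging.getLogger(__name__)

__all__ = [
    "RawReaction",
    "PairDataset",
    "StereoAudit",
    "CofactorRemovalError",
    "mcs_atom_fraction",
    "derive_precursor_pairs",
    "decompose_multiproduct",
    "remove_cofactors",
    "np_similarity_screen",
    "stereo_audit",
    "split_dataset",
    "build_pair_dataset",
    "default_cofactors",
]

#: heavy-atom fraction of the product that the best substrate MCS must
#: strictly exceed for the pair to be kept
MCS_FRACTION_THRESHOLD = 0.4

#: Tanimoto similarity (Morgan radius-2 fingerprints) at or above which a
#: reaction counts as natural-product-like
NP_SIMILARITY_THRESHOLD = 0.8

#: per-pair MCS search budget in seconds
MCS_TIMEOUT_S = 10


class CofactorRemovalError(ValueError):
    """Raised when deleting cofactors empties a reaction side."""


@dataclass(frozen=True)
class RawReaction:
    """A raw database reaction: substrate set >> product set."""

    substrates: frozenset[Molecule]
    products: frozenset[Molecule]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError("raw reaction needs nonempty substrates and products")


@dataclass
class PairDataset:
    """Mono-product precursor→metabolite pairs with train/valid/test labels."""

    pairs: list[ReactionStep]
    splits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.splits and len(self.splits) != len(self.pairs):
            raise ValueError("split labels must align with pairs")
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate pairs in dataset")

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, label: str) -> list[ReactionStep]:
        return [p for p, s in zip(self.pairs, self.splits) if s == label]


@dataclass(frozen=True)
class StereoAudit:
    """Counts from a stereochemistry annotation audit."""

    n_molecules: int
    n_with_centers: int
    n_fully_annotated: int
    n_half_annotated: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_molecules": self.n_molecules,
            "n_with_centers": self.n_with_centers,
            "n_fully_annotated": self.n_fully_annotated,
            "n_half_annotated": self.n_half_annotated,
        }


def default_cofactors() -> frozenset[Molecule]:
    """The cofactor list shipped with the package (editable data file)."""
    text = (
        importlib.resources.files("bioretro.data")
        .joinpath("cofactors.smi")
        .read_text(encoding="utf-8")
    )
    mols = []
    for line in text.splitlines():
        body = line.split("#", 1)[0].strip()
        if body:
            mols.append(canonicalize(body.split("\t")[0]))
    return frozenset(mols)


def mcs_atom_fraction(
    candidate: Molecule, metabolite: Molecule, timeout: int = MCS_TIMEOUT_S
) -> float:
    """Heavy atoms of the maximum common substructure over the metabolite's.

    Atoms are compared by element, bonds by connectivity irrespective of
    order, and ring bonds may only match ring bonds.  The denominator is
    always the metabolite.  On an MCS timeout the best bound found so far
    is returned and a warning logged.
    """
    cand = Chem.MolFromSmiles(candidate.smiles)
    metab = Chem.MolFromSmiles(metabolite.smiles)
    denom = metabolite.heavy_atom_count
    if denom == 0:
        return 0.0
    res = rdFMCS.FindMCS(
        [cand, metab],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareAny,
        ringMatchesRingOnly=True,
        maximizeBonds=False,
        timeout=timeout,
    )
    if res.canceled:
        logger.warning(
            "MCS timed out for %s vs %s; using lower bound %d atoms",
            candidate.smiles, metabolite.smiles, res.numAtoms,
        )
    return res.numAtoms / denom


def decompose_multiproduct(rxn: RawReaction) -> list[RawReaction]:
    """Split a multi-product reaction into mono-product reactions.

    Every emitted reaction keeps the full original substrate set.
    """
    return [
        RawReaction(substrates=rxn.substrates, products=frozenset([p]),
                    source=rxn.source)
        for p in sorted(rxn.products)
    ]


def remove_cofactors(
    rxn: RawReaction, cofactors: frozenset[Molecule] | None = None
) -> RawReaction:
    """Delete cofactor molecules from both sides of a reaction.

    Raises
    ------
    CofactorRemovalError
        If either side is emptied; such reactions are excluded upstream.
    """
    if cofactors is None:
        cofactors = default_cofactors()
    subs = rxn.substrates - cofactors
    prods = rxn.products - cofactors
    if not subs or not prods:
        raise CofactorRemovalError(
            f"cofactor removal emptied a side of {_render(rxn)}"
        )
    if subs == rxn.substrates and prods == rxn.products:
        return rxn
    return RawReaction(substrates=subs, products=prods, source=rxn.source)


def derive_precursor_pairs(
    rxn: RawReaction,
    threshold: float = MCS_FRACTION_THRESHOLD,
    require_all: bool = False,
) -> list[ReactionStep]:
    """Derive mono-product precursor pairs passing the MCS fraction rule.

    For each product, the full substrate set is kept as precursors iff at
    least one substrate (or every substrate, with ``require_all``) has an
    MCS covering strictly more than ``threshold`` of the product's heavy
    atoms.  Substrates equal to the product are ignored (no self loops).
    """
    steps: list[ReactionStep] = []
    seen: set[tuple] = set()
    for mono in decompose_multiproduct(rxn):
        (product,) = mono.products
        substrates = frozenset(s for s in mono.substrates if s != product)
        if not substrates:
            continue
        fractions = [mcs_atom_fraction(s, product) for s in sorted(substrates)]
        keep = all(f > threshold for f in fractions) if require_all else any(
            f > threshold for f in fractions
        )
        if not keep:
            continue
        step = ReactionStep(precursors=substrates, product=product,
                            cost=0.0, provenance=rxn.source)
        if step.key not in seen:
            seen.add(step.key)
            steps.append(step)
    return steps


def np_similarity_screen(
    rxns: list[RawReaction],
    reference: frozenset[Molecule] | set[Molecule],
    threshold: float = NP_SIMILARITY_THRESHOLD,
) -> list[RawReaction]:
    """Keep reactions with a component Tanimoto-similar to a reference set.

    Similarity is computed on Morgan radius-2 (ECFP4-class) fingerprints;
    a reaction passes when the maximum similarity between any of its
    components and any reference molecule is at or above ``threshold``.
    """
    if not reference:
        raise ValueError("reference set must be nonempty")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

    def fp(m: Molecule):
        return gen.GetFingerprint(Chem.MolFromSmiles(m.smiles))

    ref_fps = [fp(m) for m in sorted(reference)]
    kept = []
    for rxn in rxns:
        best = 0.0
        for comp in sorted(rxn.substrates | rxn.products):
            sims = DataStructs.BulkTanimotoSimilarity(fp(comp), ref_fps)
            best = max(best, max(sims))
            if best >= threshold:
                break
        if best >= threshold:
            kept.append(rxn)
    return kept


def stereo_audit(mols: list[Molecule]) -> StereoAudit:
    """Audit stereo annotation completeness over a molecule list.

    A "potential center" is any tetrahedral or double-bond stereo element
    the perception algorithm finds, annotated or not.
    """
    n_with = n_full = n_half = 0
    for m in mols:
        mol = Chem.MolFromSmiles(m.smiles)
        elements = FindPotentialStereo(mol)
        total = len(elements)
        if total == 0:
            continue
        n_with += 1
        specified = sum(1 for e in elements if str(e.specified) == "Specified")
        if specified == total:
            n_full += 1
        if specified * 2 >= total:
            n_half += 1
    return StereoAudit(
        n_molecules=len(mols),
        n_with_centers=n_with,
        n_fully_annotated=n_full,
        n_half_annotated=n_half,
    )


def split_dataset(
    pairs: PairDataset, n_test: int, n_valid: int, seed: int
) -> PairDataset:
    """Label pairs train/valid/test by a uniform seeded random draw."""
    n = len(pairs.pairs)
    if n_test + n_valid >= n:
        raise ValueError(
            f"cannot hold out {n_test}+{n_valid} pairs from a dataset of {n}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = ["train"] * n
    for i in order[:n_test]:
        labels[i] = "test"
    for i in order[n_test:n_test + n_valid]:
        labels[i] = "valid"
    return PairDataset(pairs=list(pairs.pairs), splits=labels)


def build_pair_dataset(
    rxns: list[RawReaction],
    cofactors: frozenset[Molecule] | None = None,
    threshold: float = MCS_FRACTION_THRESHOLD,
    mask: bool = True,
) -> PairDataset:
    """Full curation pipeline: decompose → strip cofactors → derive pairs →
    CoA-mask → deduplicate.

    Reactions emptied by cofactor removal are dropped (logged), not fatal.
    """
    steps: list[ReactionStep] = []
    seen: set[tuple] = set()
    for rxn in rxns:
        try:
            clean = remove_cofactors(rxn, cofactors)
        except CofactorRemovalError as exc:
            logger.info("dropped reaction: %s", exc)
            continue
        for step in derive_precursor_pairs(clean, threshold=threshold):
            if mask:
                step = ReactionStep(
                    precursors=frozenset(mask_coa(p) for p in step.precursors),
                    product=mask_coa(step.product),
                    cost=step.cost,
                    provenance=step.provenance,
                )
            if step.key not in seen:
                seen.add(step.key)
                steps.append(step)
    return PairDataset(pairs=steps, splits=["train"] * len(steps))


def _render(rxn: RawReaction) -> str:
    left = ".".join(sorted(m.smiles for m in rxn.substrates))
    right = ".".join(sorted(m.smiles for m in rxn.products))
    return f"{left}>>{right}"
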