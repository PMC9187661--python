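"""Dataset curation rules against the exhaustive common-subgraph oracle."""

import pytest

from bioretro.chem import canonicalize, mask_coa, unmask_coa
from bioretro.curation import (
    CofactorRemovalError,
    PairDataset,
    RawReaction,
    build_pair_dataset,
    decompose_multiproduct,
    derive_precursor_pairs,
    mcs_atom_fraction,
    np_similarity_screen,
    remove_cofactors,
    split_dataset,
    stereo_audit,
)

from .oracles import max_common_subgraph_atoms


def rxn(left, right, source="synthetic"):
    return RawReaction(
        substrates=frozenset(canonicalize(s) for s in left),
        products=frozenset(canonicalize(s) for s in right),
        source=source,
    )


# ≤12-heavy-atom molecules for oracle-checked MCS comparisons
ORACLE_PAIRS = [
    ("CCO", "CCOC(C)=O"),
    ("CC(=O)O", "CCOC(C)=O"),
    ("O", "CCCC"),
    ("O", "OCC"),
    ("CCO", "CCO"),
    ("CCN", "NCCO"),
    ("CCCC", "CC(C)C"),
    ("OCC=O", "OCCCN"),
    ("c1ccccc1", "Cc1ccccc1"),
    ("C1CC1", "CCC"),  # ring bonds must not match chain bonds
    ("NCCS", "NCCCO"),
    ("CC(N)C(=O)O", "CCC(N)C(=O)O"),
]


class TestMcsAtomFraction:
    @pytest.mark.parametrize("cand,metab", ORACLE_PAIRS)
    def test_matches_exhaustive_oracle(self, cand, metab):
        c, m = canonicalize(cand), canonicalize(metab)
        expected = max_common_subgraph_atoms(cand, metab) / m.heavy_atom_count
        assert mcs_atom_fraction(c, m) == pytest.approx(expected)

    def test_identical_molecules_give_one(self):
        m = canonicalize("CC(=O)OC1=CC=CC=C1C(=O)O")
        assert mcs_atom_fraction(m, m) == pytest.approx(1.0)

    def test_denominator_is_the_metabolite(self):
        small, big = canonicalize("CCO"), canonicalize("CCOC(C)=O")
        assert mcs_atom_fraction(small, big) == pytest.approx(0.5)
        assert mcs_atom_fraction(big, small) == pytest.approx(1.0)


class TestDecomposeMultiproduct:
    def test_mono_product_is_identity(self):
        r = rxn(["CCO", "CCN"], ["CCOC(C)=O"])
        assert decompose_multiproduct(r) == [r]

    @pytest.mark.parametrize("products,n", [(["CCC", "CCO"], 2),
                                            (["CCC", "CCO", "CCN"], 3)])
    def test_each_product_keeps_all_substrates(self, products, n):
        r = rxn(["CC", "OCC"], products)
        out = decompose_multiproduct(r)
        assert len(out) == n
        assert all(sub.substrates == r.substrates for sub in out)
        assert {next(iter(sub.products)) for sub in out} == r.products


class TestRemoveCofactors:
    NAD = canonicalize("CC(=O)C")  # stand-in cofactors for a small fixture
    NADH = canonicalize("CC(O)C")
    COF = frozenset([NAD, NADH])

    def test_deletes_cofactors_both_sides(self):
        r = rxn(["OCC(O)C(O)O", self.NAD.smiles], ["O=CC(O)C(O)O", self.NADH.smiles])
        out = remove_cofactors(r, self.COF)
        assert out.substrates == {canonicalize("OCC(O)C(O)O")}
        assert out.products == {canonicalize("O=CC(O)C(O)O")}

    def test_untouched_reaction_unchanged(self):
        r = rxn(["CCO"], ["CC=O"])
        assert remove_cofactors(r, self.COF) is r

    def test_emptied_side_is_rejected(self):
        with pytest.raises(CofactorRemovalError):
            remove_cofactors(rxn([self.NAD.smiles], [self.NADH.smiles]), self.COF)


class TestDerivePrecursorPairs:
    def test_esterification_kept_above_threshold(self):
        steps = derive_precursor_pairs(rxn(["CCO", "CC(=O)O"], ["CCOC(C)=O"]))
        assert len(steps) == 1
        assert steps[0].precursors == {canonicalize("CCO"), canonicalize("CC(=O)O")}

    def test_unrelated_substrate_dropped(self):
        assert derive_precursor_pairs(rxn(["O"], ["CCCC"])) == []

    def test_threshold_is_a_strict_inequality(self):
        # the whole product is common: fraction exactly 1.0
        containing = rxn(["CCCCO"], ["CCCC"])
        assert derive_precursor_pairs(containing, threshold=1.0) == []
        assert len(derive_precursor_pairs(containing, threshold=0.99)) == 1
        # fraction exactly 0.5 fails threshold 0.5 but passes 0.49
        half = rxn(["CCO"], ["CCOC(C)=O"])
        assert derive_precursor_pairs(half, threshold=0.5) == []
        assert len(derive_precursor_pairs(half, threshold=0.49)) == 1

    def test_invariant_to_substrate_ordering(self):
        a = derive_precursor_pairs(rxn(["CCO", "CC(=O)O"], ["CCOC(C)=O"]))
        b = derive_precursor_pairs(rxn(["CC(=O)O", "CCO"], ["CCOC(C)=O"]))
        assert [s.key for s in a] == [s.key for s in b]

    def test_keep_decision_follows_oracle_at_threshold(self):
        # single-substrate reactions where the oracle decides keep vs drop
        for sub, prod in ORACLE_PAIRS:
            c, m = canonicalize(sub), canonicalize(prod)
            if c == m:
                continue
            frac = max_common_subgraph_atoms(sub, prod) / m.heavy_atom_count
            steps = derive_precursor_pairs(rxn([sub], [prod]), threshold=0.4)
            assert bool(steps) == (frac > 0.4), (sub, prod, frac)


class TestNpSimilarityScreen:
    def test_reference_component_is_kept(self):
        r = rxn(["CCO"], ["CCOC(C)=O"])
        kept = np_similarity_screen([r], {canonicalize("CCOC(C)=O")})
        assert kept == [r]

    def test_dissimilar_reaction_dropped(self):
        r = rxn(["CCCCCCCC"], ["CCCCCCCCO"])
        assert np_similarity_screen([r], {canonicalize("c1ccncc1")}) == []

    def test_zero_threshold_keeps_everything(self):
        rxns = [rxn(["CCO"], ["CC=O"]), rxn(["CCCC"], ["CCC(C)O"])]
        assert np_similarity_screen(rxns, {canonicalize("O=C=O")},
                                    threshold=0.0) == rxns


class TestStereoAudit:
    def test_counts_on_known_molecules(self):
        report = stereo_audit([
            canonicalize("CCO"),                 # no centers
            canonicalize("C[C@H](N)C(=O)O"),     # 1 center, annotated
            canonicalize("CC(N)C(=O)O"),         # 1 potential, unannotated
            canonicalize("C[C@H](O)C(C)N"),      # 2 centers, 1 annotated
        ])
        assert report.n_molecules == 4
        assert report.n_with_centers == 3
        assert report.n_fully_annotated == 1
        assert report.n_half_annotated == 2


class TestSplitDataset:
    def _dataset(self, n=10):
        steps = [
            derive_precursor_pairs(rxn([f"{'C'*i}CO"], [f"{'C'*i}CCO"]))[0]
            for i in range(1, n + 1)
        ]
        return PairDataset(pairs=steps, splits=["train"] * n)

    def test_deterministic_and_disjoint(self):
        ds = self._dataset()
        a = split_dataset(ds, n_test=2, n_valid=2, seed=7)
        b = split_dataset(ds, n_test=2, n_valid=2, seed=7)
        assert a.splits == b.splits
        assert a.splits.count("test") == 2 and a.splits.count("valid") == 2
        assert a.splits.count("train") == 6

    def test_zero_holdout_is_all_train(self):
        ds = self._dataset()
        assert set(split_dataset(ds, 0, 0, seed=1).splits) == {"train"}

    def test_oversized_holdout_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._dataset(), n_test=6, n_valid=6, seed=1)


class TestPipeline:
    def test_pipeline_masks_and_deduplicates(self, acetyl_coa_smiles):
        water = canonicalize("O")
        reactions = [
            rxn(["CCO", "CC(=O)O"], ["CCOC(C)=O", "O"]),
            rxn(["CC(=O)O", "CCO"], ["CCOC(C)=O"]),  # duplicate after ordering
            rxn([acetyl_coa_smiles], ["CC(=O)OC"]),
        ]
        ds = build_pair_dataset(reactions, cofactors=frozenset([water]))
        keys = [p.key for p in ds.pairs]
        assert len(keys) == len(set(keys))
        masked = [p for p in ds.pairs if any(m.is_masked for m in p.precursors)]
        assert masked, "CoA precursor should be masked in the dataset"
        # masked forms restore to the original canonical structure
        (step,) = masked
        (pre,) = step.precursors
        assert unmask_coa(pre) == canonicalize(acetyl_coa_smiles)

    def test_emptied_reactions_are_dropped_not_fatal(self):
        water = canonicalize("O")
        ds = build_pair_dataset(
            [rxn(["O"], ["O"]), rxn(["CCO"], ["CC=O"])],
            cofactors=frozenset([water]),
        )
        assert len(ds.pairs) == 1
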