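"""Fingerprints, interface contacts, and feature-vector algebra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from targetsf import features
from targetsf.features import (atom_environment_id, concat_features,
                               detect_contacts, grid_features, morgan_fp,
                               plec_fp, tanimoto)
from targetsf.structures import MolecularStructure, ProteinLigandComplex

from .conftest import permuted_copy, random_rotation


class TestEnvironmentIds:
    def test_symmetric_atoms_share_identifiers(self, ethane):
        for depth in (0, 1, 2):
            assert atom_environment_id(ethane, 0, depth) == \
                atom_environment_id(ethane, 1, depth)

    def test_identifier_multiset_invariant_to_atom_order(self, propane):
        rng = np.random.default_rng(3)
        shuffled = permuted_copy(propane, rng)
        original = sorted(atom_environment_id(propane, i, 2) for i in range(3))
        permuted = sorted(atom_environment_id(shuffled, i, 2)
                          for i in range(3))
        assert original == permuted

    def test_degree_separates_centre_from_terminal(self, propane):
        assert atom_environment_id(propane, 0, 0) != \
            atom_environment_id(propane, 1, 0)

    def test_element_enters_depth_zero(self, ethane):
        oxo = MolecularStructure(
            elements=["O", "C"], coords=ethane.coords,
            bonds=[(0, 1, 1)], n_hydrogens=[1, 3])
        assert atom_environment_id(oxo, 0, 0) != \
            atom_environment_id(ethane, 0, 0)


class TestMorgan:
    def test_single_heavy_atom_sets_one_bit(self, single_carbon):
        """Deeper environments of an isolated atom cover the same atom
        set and are deduplicated — matching the reference circular
        fingerprint, which also yields one on-bit for methane."""
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        assert int(morgan_fp(single_carbon).values.sum()) == 1
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=512)
        rdkit_bits = gen.GetFingerprint(Chem.MolFromSmiles("C")).GetNumOnBits()
        assert rdkit_bits == 1

    def test_ethane_at_most_two_unique_environments(self, ethane):
        assert int(morgan_fp(ethane).values.sum()) <= 2

    def test_permutation_invariance(self):
        from targetsf.synth import gen_molecule

        rng = np.random.default_rng(0)
        for seed in range(5):
            mol = gen_molecule(seed, 12)
            assert np.array_equal(morgan_fp(mol).values,
                                  morgan_fp(permuted_copy(mol, rng)).values)

    def test_empty_molecule_is_error(self):
        empty = MolecularStructure(elements=[], coords=np.zeros((0, 3)))
        with pytest.raises(ValueError):
            morgan_fp(empty)

    def test_popcount_bounded_by_environment_count(self):
        from targetsf.synth import gen_molecule

        for seed in range(5):
            mol = gen_molecule(seed + 50, 14)
            n_env = len(features._deduped_environments(mol, 2))
            assert int(morgan_fp(mol).values.sum()) <= n_env


class TestTanimoto:
    def test_self_similarity_is_one(self):
        v = np.zeros(64); v[[1, 5, 9]] = 1
        assert tanimoto(v, v) == 1.0

    def test_disjoint_is_zero_and_both_empty_is_zero(self):
        a, b = np.zeros(64), np.zeros(64)
        a[1] = 1; b[2] = 1
        assert tanimoto(a, b) == 0.0
        assert tanimoto(np.zeros(8), np.zeros(8)) == 0.0

    def test_closed_form_half(self):
        a, b = np.zeros(16), np.zeros(16)
        a[[1, 2, 3]] = 1; b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == 0.5

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(8), np.zeros(9))

    @given(st.lists(st.booleans(), min_size=4, max_size=64),
           st.lists(st.booleans(), min_size=4, max_size=64))
    def test_symmetric_and_bounded(self, a, b):
        n = min(len(a), len(b))
        va, vb = np.array(a[:n]), np.array(b[:n])
        s = tanimoto(va, vb)
        assert s == tanimoto(vb, va)
        assert 0.0 <= s <= 1.0


class TestContacts:
    def test_distant_ligand_no_contacts(self, single_carbon):
        far = MolecularStructure(elements=["N"], coords=[[50.0, 0, 0]],
                                 res_names=["ALA"], res_numbers=[1],
                                 chains=["A"])
        cx = ProteinLigandComplex(receptor=far, ligand=single_carbon)
        assert detect_contacts(cx, 4.5) == []

    def test_exact_cutoff_boundary_included(self, single_carbon):
        at = MolecularStructure(elements=["N"], coords=[[4.5, 0, 0]],
                                res_names=["ALA"], res_numbers=[1],
                                chains=["A"])
        cx = ProteinLigandComplex(receptor=at, ligand=single_carbon)
        assert len(detect_contacts(cx, 4.5)) == 1

    def test_hydrogens_excluded(self):
        lig = MolecularStructure(elements=["C", "H"],
                                 coords=[[0, 0, 0], [1.0, 0, 0]],
                                 bonds=[(0, 1, 1)])
        prot = MolecularStructure(elements=["H", "O"],
                                  coords=[[2.0, 0, 0], [3.0, 0, 0]],
                                  bonds=[(0, 1, 1)])
        cx = ProteinLigandComplex(receptor=prot, ligand=lig)
        contacts = detect_contacts(cx, 4.5)
        assert contacts == [(0, 1, pytest.approx(3.0))]

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            lig = MolecularStructure(
                elements=["C", "N", "O"], coords=rng.uniform(0, 6, (3, 3)))
            prot = MolecularStructure(
                elements=["C", "O"], coords=rng.uniform(0, 6, (2, 3)))
            cx = ProteinLigandComplex(receptor=prot, ligand=lig)
            got = {(a, b) for a, b, _ in detect_contacts(cx, 4.5)}
            expected = {
                (i, j)
                for i in range(3) for j in range(2)
                if np.linalg.norm(lig.coords[i] - prot.coords[j]) <= 4.5}
            assert got == expected


class TestPlec:
    def test_contact_free_complex_gives_zero_vector(self, single_carbon):
        far = MolecularStructure(elements=["N"], coords=[[50.0, 0, 0]])
        cx = ProteinLigandComplex(receptor=far, ligand=single_carbon)
        fp = plec_fp(cx)
        assert len(fp) == 4092 and fp.values.sum() == 0

    def test_single_pair_expands_to_full_depth_cross_product(self,
                                                             toy_complex):
        # (1+1) ligand depths x (5+1) protein depths = 12 pair identifiers
        fp = plec_fp(toy_complex)
        assert int(fp.values.sum()) == 12

    def test_diagonal_pairing_is_leaner(self, toy_complex):
        fp = plec_fp(toy_complex, pairing="diagonal")
        assert int(fp.values.sum()) == 6  # depths 0..5 paired (1,5)-clipped

    def test_rototranslation_invariance(self):
        from targetsf.synth import gen_molecule, gen_pocket_complex

        rng = np.random.default_rng(21)
        cx = gen_pocket_complex(4, gen_molecule(4, 10), plant_signal=True)
        moved = cx.transformed(random_rotation(rng), rng.uniform(-9, 9, 3))
        assert np.array_equal(plec_fp(cx).values, plec_fp(moved).values)

    def test_folding_stays_in_range(self):
        from targetsf.synth import gen_molecule, gen_pocket_complex

        cx = gen_pocket_complex(5, gen_molecule(5, 10), plant_signal=True)
        fp = plec_fp(cx, size=128)
        assert len(fp) == 128
        assert set(np.unique(fp.values)) <= {0, 1}


class TestGrid:
    def test_length_is_2052_at_default_powers(self, toy_complex):
        assert len(grid_features(toy_complex)) == 2052

    def test_length_formula_for_other_powers(self, toy_complex):
        assert len(grid_features(toy_complex, ecfp_power=5, splif_power=4)) \
            == 2 ** 5 + 3 * 2 ** 4 + 4

    def test_contact_free_complex_zeroes_interface_blocks(self,
                                                          single_carbon):
        far = MolecularStructure(elements=["N"], coords=[[60.0, 0, 0]])
        cx = ProteinLigandComplex(receptor=far, ligand=single_carbon)
        v = grid_features(cx).values
        assert v[512:].sum() == 0  # SPLIF, hbond and salt blocks empty

    def test_salt_bridge_counted_from_charged_pair(self):
        lig = MolecularStructure(elements=["N"], coords=[[0.0, 0, 0]],
                                 formal_charges=[1], n_hydrogens=[3])
        prot = MolecularStructure(elements=["O"], coords=[[3.0, 0, 0]],
                                  formal_charges=[-1])
        cx = ProteinLigandComplex(receptor=prot, ligand=lig)
        assert grid_features(cx).values[-1] == 1

    def test_neutral_pair_is_not_a_salt_bridge(self):
        lig = MolecularStructure(elements=["N"], coords=[[0.0, 0, 0]],
                                 n_hydrogens=[2])
        prot = MolecularStructure(elements=["O"], coords=[[3.0, 0, 0]])
        cx = ProteinLigandComplex(receptor=prot, ligand=lig)
        assert grid_features(cx).values[-1] == 0

    def test_hbond_lands_in_matching_distance_bin(self):
        # N-H donor 2.8 Å from O acceptor: second bin (2, 3]
        lig = MolecularStructure(elements=["N"], coords=[[0.0, 0, 0]],
                                 n_hydrogens=[2])
        prot = MolecularStructure(elements=["O"], coords=[[2.8, 0, 0]])
        cx = ProteinLigandComplex(receptor=prot, ligand=lig)
        hbond = grid_features(cx).values[512 + 3 * 512: 512 + 3 * 512 + 3]
        assert list(hbond) == [0, 1, 0]

    def test_counts_are_non_negative(self):
        from targetsf.synth import gen_molecule, gen_pocket_complex

        cx = gen_pocket_complex(9, gen_molecule(9, 12), plant_signal=True)
        assert (grid_features(cx).values >= 0).all()

    def test_rototranslation_invariance(self):
        from targetsf.synth import gen_molecule, gen_pocket_complex

        rng = np.random.default_rng(31)
        cx = gen_pocket_complex(6, gen_molecule(6, 10), plant_signal=True)
        moved = cx.transformed(random_rotation(rng), rng.uniform(-9, 9, 3))
        assert np.array_equal(grid_features(cx).values,
                              grid_features(moved).values)


class TestConcat:
    def test_lengths_add(self, toy_complex, single_carbon):
        combined = concat_features(morgan_fp(single_carbon),
                                   plec_fp(toy_complex))
        assert len(combined) == 512 + 4092 == 4604
        assert combined.scheme == "COMBINED"

    def test_argument_order_normalized(self, toy_complex, single_carbon):
        m, p = morgan_fp(single_carbon), plec_fp(toy_complex)
        assert np.array_equal(concat_features(m, p).values,
                              concat_features(p, m).values)

    def test_same_scheme_rejected(self, single_carbon):
        with pytest.raises(ValueError):
            concat_features(morgan_fp(single_carbon),
                            morgan_fp(single_carbon))

    def test_zero_inputs_give_zero_vector(self, single_carbon):
        from targetsf.features import FeatureVector

        z1 = FeatureVector("MORGAN", np.zeros(8))
        z2 = FeatureVector("PLEC", np.zeros(8))
        assert concat_features(z1, z2).values.sum() == 0


class TestPersistence:
    def test_matrix_round_trip_with_sidecar(self, tmp_path):
        X = np.arange(12, dtype=float).reshape(3, 4)
        features.save_features(tmp_path / "feats", X, "PLEC",
                               {"size": 4}, ["a", "b", "c"])
        back, meta = features.load_features(tmp_path / "feats")
        assert np.array_equal(back, X)
        assert meta["compound_ids"] == ["a", "b", "c"]
        assert meta["n_columns"] == 4
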