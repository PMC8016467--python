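"""Compound featurizer correctness and invariances."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from dtikit import chem
from dtikit.tokenize import PAD_INDEX, SMILES_CHARSET, UNK_INDEX

from conftest import MOLECULE_ALIASES

# frozen toolkit-oracle fixture: on-bit positions of the circular fingerprint
# of ethanol at radius 2 / 1024 bits (recorded from a reference run)
CCO_MORGAN_ONBITS = (33, 80, 222, 294, 386, 807)


class TestMorgan:
    def test_methane_has_exactly_one_environment(self):
        fp = chem.morgan_fingerprint("C", radius=2, n_bits=1024)
        assert fp.popcount == 1

    def test_frozen_ethanol_fixture(self):
        fp = chem.morgan_fingerprint("CCO", radius=2, n_bits=1024)
        assert tuple(np.flatnonzero(fp.bits)) == CCO_MORGAN_ONBITS

    def test_invalid_smiles_rejected(self):
        with pytest.raises(ValueError):
            chem.morgan_fingerprint("C1CC")

    def test_radius_zero_counts_atom_environments(self):
        # radius-0 environments of ethanol: CH3 carbon, CH2 carbon, hydroxyl
        # oxygen differ in their atom invariants -> 3 distinct environments
        fp = chem.morgan_fingerprint("CCO", radius=0, n_bits=1024)
        assert fp.popcount == 3


class TestPubchem:
    def test_length_is_always_881(self):
        for s in ("C", "CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1"):
            assert chem.pubchem_fingerprint(s).length == 881

    def test_methane_matches_key_definition_oracle(self):
        # independent evaluation of the packaged key table for methane:
        # 4 implicit hydrogens -> only the H>=4 element key can fire;
        # no ring or bond-pattern key applies to a single atom
        fp = chem.pubchem_fingerprint("C")
        keys = chem.load_pubchem_keys()
        expected_on = [idx for idx, kind, params in keys
                       if kind == "element" and params == "H,4"]
        assert list(np.flatnonzero(fp.bits)) == expected_on

    def test_benzene_sets_an_aromatic_ring_key(self):
        fp = chem.pubchem_fingerprint("c1ccccc1")
        keys = chem.load_pubchem_keys()
        arom = [idx for idx, kind, params in keys if kind == "ring_arom"]
        assert fp.bits[arom].sum() >= 1

    def test_methane_aromatic_keys_are_zero(self):
        fp = chem.pubchem_fingerprint("C")
        keys = chem.load_pubchem_keys()
        arom = [idx for idx, kind, params in keys if kind == "ring_arom"]
        assert fp.bits[arom].sum() == 0

    def test_element_count_section_against_direct_recount(self):
        # oracle: recount elements with the toolkit and re-apply thresholds
        s = "CC(=O)Nc1ccc(O)cc1"  # paracetamol
        mol = Chem.MolFromSmiles(s)
        counts = {}
        for a in mol.GetAtoms():
            counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
        counts["H"] = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
        fp = chem.pubchem_fingerprint(s)
        for idx, kind, params in chem.load_pubchem_keys():
            if kind != "element":
                continue
            sym, mn = params.split(",")
            assert fp.bits[idx] == int(counts.get(sym, 0) >= int(mn))


def path_sets(smiles, max_len):
    """Independent linear-path enumerator for tiny molecules (<=3 atoms)."""
    mol = Chem.MolFromSmiles(smiles)
    paths = set()
    for atom in mol.GetAtoms():
        paths.add((atom.GetAtomicNum(),))
    for length in range(1, max_len + 1):
        for path in Chem.FindAllPathsOfLengthN(mol, length, useBonds=True):
            paths.add(tuple(sorted(
                mol.GetBondWithIdx(b).GetBeginAtom().GetAtomicNum() for b in path)))
    return paths


class TestDaylight:
    def test_single_atom_has_a_bit(self):
        assert chem.daylight_fingerprint("C", 256).popcount >= 1

    def test_substructure_bits_are_subset(self):
        # path-set oracle on <=3 atoms: paths("C") is a subset of paths("CC"),
        # so the hashed bits must be too
        assert path_sets("C", 3) <= path_sets("CC", 3)
        a = chem.daylight_fingerprint("C", 256)
        b = chem.daylight_fingerprint("CC", 256)
        assert np.all(b.bits >= a.bits)

    def test_default_length(self):
        assert chem.daylight_fingerprint("CCO").length == 2048


class TestDescriptors2D:
    def test_molecular_weight_of_ethanol(self):
        # atomic-mass hand sum: 2*12.011 + 6*1.008 + 15.999 = 46.069
        raw = chem.raw_descriptors("CCO")
        mw = raw.values[list(raw.names).index("MolWt")]
        assert mw == pytest.approx(46.07, abs=0.01)

    def test_outputs_in_unit_interval(self):
        for s in ("CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1"):
            v = chem.descriptors_2d(s).values
            assert np.all(v >= 0) and np.all(v <= 1)

    def test_deterministic(self):
        a = chem.descriptors_2d("CCO").values
        b = chem.descriptors_2d("CCO").values
        assert np.array_equal(a, b)


class TestSmilesLabelEncode:
    def test_padding_and_mask(self):
        ts = chem.smiles_label_encode("CCO", max_len=5)
        c, o = SMILES_CHARSET["C"], SMILES_CHARSET["O"]
        assert ts.indices.tolist() == [c, c, o, PAD_INDEX, PAD_INDEX]
        assert ts.mask.tolist() == [1, 1, 1, 0, 0]

    def test_truncation(self):
        ts = chem.smiles_label_encode("C" * 30, max_len=10)
        assert ts.mask.sum() == 10

    def test_unknown_character_maps_to_unk(self):
        ts = chem.smiles_label_encode("C§O", max_len=5)
        assert ts.indices[1] == UNK_INDEX


class TestMolGraph:
    def test_single_atom_graph(self):
        g = chem.smiles_to_graph("C")
        assert g.n_atoms == 1 and len(g.bond_list) == 0

    def test_ethanol_topology_and_oxygen_onehot(self):
        g = chem.smiles_to_graph("CCO")
        assert g.n_atoms == 3 and len(g.bond_list) == 2
        o_row = g.atom_features[2]
        o_pos = chem._GRAPH_ELEMENTS.index("O")
        assert o_row[o_pos] == 1.0
        assert o_row[: len(chem._GRAPH_ELEMENTS) + 1].sum() == 1.0

    def test_benzene_aromatic_flags(self):
        # aromaticity oracle: toolkit perception marks all 6 atoms/bonds
        g = chem.smiles_to_graph("c1ccccc1")
        assert g.n_atoms == 6 and len(g.bond_list) == 6
        arom_col = len(chem._GRAPH_ELEMENTS) + 1 + 6 + 1
        assert np.all(g.atom_features[:, arom_col] == 1.0)
        arom_bond = chem._BOND_ORDERS.index(Chem.BondType.AROMATIC)
        assert np.all(g.bond_features[:, arom_bond] == 1.0)

    def test_disconnected_smiles_kept_whole(self):
        g = chem.smiles_to_graph("CCO.CC")
        assert g.n_atoms == 5 and len(g.bond_list) == 3


@pytest.mark.parametrize("featurize", [
    lambda s: chem.morgan_fingerprint(s, 2, 512).bits,
    lambda s: chem.pubchem_fingerprint(s).bits,
    lambda s: chem.daylight_fingerprint(s, 512).bits,
    lambda s: chem.descriptors_2d(s).values,
    lambda s: chem.smiles_to_graph(s).atom_features.sum(axis=0),
], ids=["morgan", "pubchem", "daylight", "desc2d", "graph-atom-sums"])
def test_canonical_invariance_over_alias_pairs(featurize):
    """Two SMILES spellings of one molecule featurize identically."""
    assert len(MOLECULE_ALIASES) >= 20
    for a, b in MOLECULE_ALIASES:
        assert np.allclose(featurize(a), featurize(b)), (a, b)


def test_repeated_calls_are_byte_identical():
    for fn in (lambda: chem.morgan_fingerprint("CCO").bits,
               lambda: chem.pubchem_fingerprint("CCO").bits,
               lambda: chem.descriptors_2d("CCO").values):
        assert np.array_equal(fn(), fn())
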