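from collections import Counter
from itertools import permutations

import numpy as np
import pytest

from mole8.structures import Atom, Molecule, perceive_bonds
from mole8.internal_coords import (
    enumerate_bond_obs, enumerate_angle_obs, enumerate_dihedral_obs,
    detect_hbond_obs, count_nhx,
)
from mole8.fixtures import (
    make_ethanol, make_water, make_methylamine, make_chain_molecule,
    make_hbonded_diol,
)
from .conftest import random_rigid_transform


def class_counts(obs):
    return Counter(o.class_label for o in obs)


def brute_force_dihedral_paths(mol):
    """Independent path enumeration: ordered quadruples along bonds, halved."""
    bonds = {tuple(sorted(b)) for b in mol.bonds}
    count = 0
    for i, j, k, l in permutations(range(mol.n_atoms), 4):
        if (tuple(sorted((i, j))) in bonds and tuple(sorted((j, k))) in bonds
                and tuple(sorted((k, l))) in bonds):
            count += 1
    return count // 2


class TestBonds:
    def test_ethanol_bond_classes(self, ethanol):
        assert class_counts(enumerate_bond_obs(ethanol, "element")) == {
            "C-C": 1, "C-H": 5, "C-O": 1, "H-O": 1}

    def test_h2(self):
        h2 = Molecule("h2", [Atom("H", np.zeros(3)),
                             Atom("H", np.array([0.74, 0, 0]))],
                      bonds=frozenset({(0, 1)}))
        assert class_counts(enumerate_bond_obs(h2, "element")) == {"H-H": 1}

    def test_reversed_atom_order_gives_same_classes(self, ethanol):
        rev = perceive_bonds(Molecule("rev", ethanol.atoms[::-1]))
        assert class_counts(enumerate_bond_obs(rev, "element")) == \
            class_counts(enumerate_bond_obs(ethanol, "element"))

    def test_observation_count_equals_bond_count(self, toy50):
        for m in toy50[:10]:
            assert len(enumerate_bond_obs(m, "element")) == len(m.bonds)


class TestAngles:
    def test_ethanol_element_level_counts(self, ethanol):
        assert class_counts(enumerate_angle_obs(ethanol, "element")) == {
            "C-C-H": 5, "H-C-H": 4, "H-C-O": 2, "C-O-H": 1, "C-C-O": 1}

    def test_water_angle_value(self):
        obs = enumerate_angle_obs(make_water(), "element")
        assert len(obs) == 1
        assert obs[0].class_label == "H-O-H"
        assert obs[0].value == pytest.approx(104.5, abs=1e-6)

    def test_granularity_changes_labels_never_counts(self, ethanol):
        assert len(enumerate_angle_obs(ethanol, "element+connectivity")) == \
            len(enumerate_angle_obs(ethanol, "element")) == 13

    def test_closed_form_count(self, toy50):
        for m in toy50[:10]:
            expect = sum(d * (d - 1) // 2
                         for d in (m.degree(i) for i in range(m.n_atoms)))
            assert len(enumerate_angle_obs(m, "element")) == expect


class TestDihedrals:
    def test_anti_butane_backbone_torsion(self):
        butane = make_chain_molecule(["C", "C", "C", "C"], "butane")
        cccc = [o for o in enumerate_dihedral_obs(butane, "element")
                if o.class_label == "C-C-C-C"]
        assert len(cccc) == 1
        assert cccc[0].value == pytest.approx(180.0, abs=1e-6)

    def test_ethanol_count_matches_brute_force(self, ethanol):
        obs = enumerate_dihedral_obs(ethanol, "element")
        assert len(obs) == brute_force_dihedral_paths(ethanol) == 12
        assert class_counts(obs) == {"H-C-C-H": 6, "H-C-C-O": 3,
                                     "C-C-O-H": 1, "H-C-O-H": 2}

    def test_mirror_image_has_identical_values(self, ethanol):
        mirrored = ethanol.with_coords(ethanol.coords * np.array([1.0, 1.0, -1.0]))
        vals = sorted(o.value for o in enumerate_dihedral_obs(ethanol, "element"))
        mvals = sorted(o.value for o in enumerate_dihedral_obs(mirrored, "element"))
        assert np.allclose(vals, mvals, atol=1e-8)

    def test_values_in_range(self, toy50):
        for m in toy50[:10]:
            for o in enumerate_dihedral_obs(m, "element"):
                assert 0.0 <= o.value <= 180.0


class TestHBonds:
    def test_ethanol_has_none(self, ethanol):
        assert detect_hbond_obs(ethanol) == []

    def test_diol_contact_at_requested_distance(self):
        obs = detect_hbond_obs(make_hbonded_diol(2.0))
        assert len(obs) == 1
        assert obs[0].class_label == "OH-O"
        assert obs[0].value == pytest.approx(2.0, abs=1e-8)

    def test_contact_outside_window_ignored(self):
        assert detect_hbond_obs(make_hbonded_diol(2.7)) == []


class TestNHx:
    def test_methylamine(self):
        assert count_nhx(make_methylamine()) == {2: 1}

    def test_ethanol_empty(self, ethanol):
        assert count_nhx(ethanol) == {}

    def test_mixed_primary_and_secondary(self):
        m = make_chain_molecule(["N", "C", "N", "C"], "mixed")
        assert count_nhx(m) == {1: 1, 2: 1}


class TestInvariance:
    def test_class_counts_and_values_invariant_under_rigid_motion(self, toy50):
        rng = np.random.default_rng(7)
        for m in toy50[:3] + [make_ethanol()]:
            ref = {
                "bond": class_counts(enumerate_bond_obs(m, "element")),
                "angle": class_counts(enumerate_angle_obs(m, "element+connectivity")),
                "dihedral": class_counts(enumerate_dihedral_obs(m, "element")),
            }
            ref_vals = sorted(o.value for o in enumerate_angle_obs(m, "element"))
            for _ in range(20):
                t = m.with_coords(random_rigid_transform(m.coords, rng))
                assert class_counts(enumerate_bond_obs(t, "element")) == ref["bond"]
                assert class_counts(
                    enumerate_angle_obs(t, "element+connectivity")) == ref["angle"]
                assert class_counts(enumerate_dihedral_obs(t, "element")) == ref["dihedral"]
                vals = sorted(o.value for o in enumerate_angle_obs(t, "element"))
                assert np.allclose(vals, ref_vals, atol=1e-7)
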