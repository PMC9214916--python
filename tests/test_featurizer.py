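import numpy as np
import pytest

from mole8.structures import Molecule, perceive_bonds
from mole8.featurizer import (
    FeatureDictionary, fit_feature_bins, build_dictionary,
    encode_molecule, encode_matrix, molecule_observations,
)
from mole8.fixtures import make_ethanol, make_toy_dataset, make_methylamine
from .conftest import random_rigid_transform


def class_sum(vec, dictionary, family, label):
    return float(vec.values[dictionary.class_slice(family, label)].sum())


class TestFitFeatureBins:
    def test_degenerate_class_single_bin_covers_line(self):
        bins = fit_feature_bins([1.09] * 40, "bond", "C-H", 0.07)
        assert len(bins) == 1
        assert bins[0].maximum == pytest.approx(1.09)
        assert bins[0].lower == -np.inf and bins[0].upper == np.inf

    def test_bimodal_sample_recovers_generating_modes(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(1.33, 0.01, 1000),
                               rng.normal(1.54, 0.01, 1000)])
        bins = fit_feature_bins(vals, "bond", "C-C", 0.07)
        assert len(bins) == 2
        assert bins[0].maximum == pytest.approx(1.33, abs=0.01)
        assert bins[1].maximum == pytest.approx(1.54, abs=0.01)
        assert 1.40 < bins[0].upper == bins[1].lower < 1.48

    def test_halving_bandwidth_never_reduces_bin_count(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(60, 3, 300), rng.normal(120, 3, 300),
                               rng.normal(175, 2, 300)])
        wide = fit_feature_bins(vals, "angle", "C-C4-C", 0.2)
        narrow = fit_feature_bins(vals, "angle", "C-C4-C", 0.1)
        assert len(narrow) >= len(wide)

    def test_bins_tile_the_line(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(1.2, 0.02, 200), rng.normal(1.5, 0.02, 200)])
        bins = fit_feature_bins(vals, "bond", "C-O", 0.07)
        assert bins[0].lower == -np.inf and bins[-1].upper == np.inf
        for a, b in zip(bins[:-1], bins[1:]):
            assert a.upper == b.lower
            assert a.lower < a.maximum < a.upper


class TestBuildDictionary:
    def test_bond_classes_match_dataset(self, toy50, toy50_dictionary):
        seen = set()
        for m in toy50 + [make_ethanol()]:
            for o in molecule_observations(m, toy50_dictionary.config):
                if o.family == "bond":
                    seen.add(o.class_label)
        assert {lab for fam, lab in toy50_dictionary.classes("bond")} == seen

    def test_rebuild_is_byte_identical(self, toy50):
        a = build_dictionary(toy50).to_json()
        b = build_dictionary(toy50).to_json()
        assert a == b

    def test_first_nitrogen_adds_classes(self):
        mols = [m for m in make_toy_dataset(40, seed=3)
                if all(a.element != "N" for a in m.atoms)]
        base = build_dictionary(mols)
        grown = build_dictionary(mols + [make_methylamine()])
        assert len(grown.classes()) > len(base.classes())

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            build_dictionary([])


class TestEncode:
    def test_ethanol_class_sums_match_its_connectivity(self, toy50_dictionary, ethanol):
        fv = encode_molecule(ethanol, toy50_dictionary)
        d = toy50_dictionary
        assert class_sum(fv, d, "bond", "C-H") == 5
        assert class_sum(fv, d, "bond", "H-O") == 1
        assert class_sum(fv, d, "bond", "C-C") == 1
        hbond_total = sum(class_sum(fv, d, fam, lab) for fam, lab in d.classes("hbond"))
        assert hbond_total == 0

    def test_atom_slots_are_100_weighted(self, toy50_dictionary, ethanol):
        fv = encode_molecule(ethanol, toy50_dictionary)
        assert fv.values[:4].tolist() == [200.0, 600.0, 0.0, 100.0]

    def test_bond_count_conservation(self, toy50, toy50_dictionary):
        d = toy50_dictionary
        for m in toy50[:10]:
            fv = encode_molecule(m, d)
            total = sum(fv.values[4 + k] for k, b in enumerate(d.bins)
                        if b.family == "bond")
            in_dict = sum(1 for o in molecule_observations(m, d.config)
                          if o.family == "bond"
                          and d.class_bins("bond", o.class_label))
            assert total == in_dict == len(m.bonds)

    def test_unknown_classes_reported_not_fatal(self, toy50):
        no_n = [m for m in toy50 if all(a.element != "N" for a in m.atoms)]
        d = build_dictionary(no_n)
        fv = encode_molecule(make_methylamine(), d)
        assert sum(fv.dropped_classes.values()) > 0

    def test_assignment_matches_brute_force_interval_oracle(self, toy50_dictionary):
        from mole8.featurizer import _assign_bin
        rng = np.random.default_rng(11)
        for fam, lab in toy50_dictionary.classes():
            bins = toy50_dictionary.class_bins(fam, lab)
            lo = min(b.maximum for b in bins) - 1.0
            hi = max(b.maximum for b in bins) + 1.0
            for v in rng.uniform(lo, hi, 1000):
                oracle = next(k for k, b in enumerate(bins)
                              if b.lower < v <= b.upper)
                assert _assign_bin(bins, v) == oracle

    def test_encoding_invariant_under_rigid_motion_and_permutation(
            self, toy50, toy50_dictionary):
        rng = np.random.default_rng(5)
        for m in toy50[:2] + [make_ethanol()]:
            ref = encode_molecule(m, toy50_dictionary).values
            for _ in range(20):
                t = perceive_bonds(
                    m.with_coords(random_rigid_transform(m.coords, rng)))
                assert np.array_equal(
                    encode_molecule(t, toy50_dictionary).values, ref)
            perm = rng.permutation(m.n_atoms)
            shuffled = perceive_bonds(
                Molecule("p", [m.atoms[i] for i in perm]))
            assert np.array_equal(
                encode_molecule(shuffled, toy50_dictionary).values, ref)

    def test_json_round_trip_preserves_encoding(self, toy50, toy50_dictionary):
        back = FeatureDictionary.from_json(toy50_dictionary.to_json())
        assert back.to_json() == toy50_dictionary.to_json()
        assert back.fingerprint() == toy50_dictionary.fingerprint()
        for m in toy50[:5]:
            assert np.array_equal(encode_molecule(m, back).values,
                                  encode_molecule(m, toy50_dictionary).values)

    def test_total_length_accounting(self, toy50_dictionary):
        d = toy50_dictionary
        assert d.total_length == 4 + len(d.bins) + len(d.nhx_slots)
        X, ids, _ = encode_matrix([make_ethanol()], d)
        assert X.shape == (1, d.total_length)
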