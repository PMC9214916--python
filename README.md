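# mole8

Explainable molecular representations and energy models for small CHNO
organic molecules.

DFT-quality energies are expensive; classical force fields are cheap but
their energies are not comparable across systems. `mole8` implements a
middle path: a count-based molecular representation built from the
distributions of internal coordinates, coupled to standard regressors, that
predicts DFT-level electronic and free energies (kcal/mol) from 3D
geometries — including geometries that are only *near* the potential-energy
minimum, such as force-field-optimised structures.

## The representation

For every class of internal coordinate in a training database — bond
lengths by atom pair (C–C, C–H, …), angles by token triple, dihedrals by
token path, hydrogen-bond H⋯acceptor distances by donor/acceptor type — a
Gaussian kernel density estimate is fitted over the pooled values. Every
local maximum of the density becomes a feature; the flanking minima delimit
the interval of values assigned to it. A molecule is encoded by counting
its observations per bin, preceded by 100-weighted atom counts and followed
by NH_x group counts:

    x(M) = [ 100·n_C, 100·n_H, 100·n_N, 100·n_O,
             counts per bond bin, per angle bin, per dihedral bin,
             per H-bond bin, n_NH, n_NH2, n_NH3 ]

The encoding is invariant under rotation, translation, reflection and atom
permutation, and every entry is directly readable: the C–H bin near 1.09 Å
of ethanol holds exactly 5. Models on top: kernel ridge regression with an
RBF kernel K(x, x′) = exp(−‖x−x′‖²/2σ²), a two-hidden-layer ReLU network,
SGD linear regression and a random forest. A distortion-augmentation module
generates replicas with every atom displaced exactly δ along a random axis
(targets kept at the minimum's energies), which makes the trained models
robust to off-minimum input geometries.

See `docs/methods.md` for the full model description, numerical choices and
limitations.

## Worked example

```sh
python examples/ethanol_representation.py
```

prints

```
feature dictionary: 175 slots
atom slots (C,H,N,O x 100): [200.0, 600.0, 0.0, 100.0]
bond counts by class: {'C-C': 1, 'C-H': 5, 'C-O': 1, 'H-O': 1}
angle counts (element level): {'C-C-H': 5, 'H-C-H': 4, 'C-C-O': 1, 'H-C-O': 2, 'C-O-H': 1}
hydrogen bonds detected: 0
```

Ethanol (C₂H₆O) contributes one C–C, one C–O, one O–H and five C–H bonds;
its 13 bonded angles split 5 CCH / 4 HCH / 2 OCH / 1 COH / 1 CCO; it has no
intramolecular hydrogen bond, so every H-bond feature is zero; and its atom
slots are the element counts times 100.

The other examples each exercise one capability and print what the numbers
mean: `curation_and_split.py` (the six cleaning rules and the
stoichiometry-grouped 33% split), `distortion_constant.py` (the distortion
constant C growing from 0.7 to 52 as δ goes from 0.0005 to 0.1 Å), and
`end_to_end_krr.py` (full pipeline on synthetic linear-in-counts energies;
test MAE 0.96 kcal/mol against a 1 kcal/mol noise floor).

A thin CLI wraps the same pipeline for shell use:

```sh
mole8 fixtures --out data --n 200 --seed 0
mole8 run --structures data --targets data/targets.csv --out run --family krr
```

## Library layout

| module | contents |
|---|---|
| `mole8.structures` | XYZ/SDF I/O, covalent-radius bond perception, QC-log energy extraction |
| `mole8.internal_coords` | bond/angle/dihedral/H-bond enumeration with canonical class labels |
| `mole8.curation` | cleaning filters, free-energy deduplication, stoichiometry split |
| `mole8.featurizer` | KDE bin fitting, the feature dictionary, molecule encoding |
| `mole8.augment` | distorted replicas and the distortion constant |
| `mole8.models` | KRR / NN / MLR / RFR training, prediction, MAE, learning curves |
| `mole8.fixtures` | synthetic molecules, probe cases and toy datasets (no downloads) |
| `mole8.pipeline`, `mole8.cli` | end-to-end runs with manifests and reproducible seeds |

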