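# Methods

## The representation

A molecule with elements restricted to C, H, N and O is encoded as a
fixed-length vector of non-negative counts. The slots, in deterministic
order, are:

1. **Atom slots** — the number of C, H, N and O atoms, each multiplied
   by 100. The weighting makes molecular composition the dominant term in
   kernel distances, matching its dominant contribution to total energy.
2. **KDE bins** for every *class* of internal coordinate observed in a
   training set, family by family (bonds, angles, dihedrals, hydrogen
   bonds), classes in alphabetical order, bins by ascending location.
3. **NH_x slots** — the number of nitrogen atoms carrying x hydrogens
   (x = 1, 2, 3), one slot per x value observed in training.

A *class* is a canonical token string: for bonds the sorted pair of atom
tokens ("C-H"), for angles the terminal tokens sorted around the fixed
central token ("H1-C4-H1" at connectivity granularity), for dihedrals the
lexicographically smaller direction of the token path, and for hydrogen
bonds one of OH-O, OH-N, NH-O, NH-N (donor heavy atom + acceptor element).
Tokens order elements C < H < N < O, so relabelling a reversed tuple yields
the identical string. The default granularities — element-only for bonds
and dihedrals, element+connectivity for angles — are the best-performing
combination reported for the method.

For each class, the values pooled over the training set get a Gaussian KDE;
every local maximum of the density becomes a feature, and the local minima
flanking it delimit the half-open interval `(lower, upper]` of values
assigned to it. Outermost bounds are ±∞, so off-distribution values (e.g.
from distorted or force-field geometries) always land in an edge bin rather
than being dropped; observations of a *class* absent from the dictionary are
dropped and tallied, which is the expected regime when extrapolating to
larger molecules. Encoding is invariant under rotation, translation,
reflection (dihedrals use |torsion| ∈ [0°, 180°]) and atom permutation.

### KDE numerics

The bandwidth is a *factor* multiplying the per-class sample standard
deviation (the Gaussian-KDE convention for a scalar bandwidth); the tuned
value 0.07 is used for bonds and angles and mirrored for dihedrals and
H-bond distances, whose widths the method leaves free. The density is
evaluated on a 2048-point uniform grid spanning the data range padded by
3 bandwidths; maxima/minima are grid local extrema. Localization error is
the grid step (~1e-3 of the data range), far below any chemical length
scale. Degenerate classes — a single observation, or repeated values whose
spread is below 1e-9 of their magnitude — yield one bin covering the whole
line. Maxima that no strictly interior minimum separates are merged,
keeping the denser one. A value exactly on a boundary belongs to the lower
bin; ties are measure-zero for continuous data.

## Bond perception and curation

Bonds are perceived by the covalent-radius rule: atoms i, j are bonded when
`d(i,j) <= 1.15 × (r_cov(i) + r_cov(j))` with single-bond radii H 0.31,
C 0.76, N 0.71, O 0.66 Å. This is deterministic, self-contained and
reproduces standard organic connectivity; the 1.15 factor is configurable.
Pairs closer than 0.3 Å raise a degenerate-geometry error.

Curation applies six rules in fixed precedence (first match is the recorded
reason, so removal counts are disjoint): imaginary lowest frequency;
any element outside {C,H,N,O}; any bond longer than 1.6 Å; any tetravalent
nitrogen (zwitterions); any 3-coordinate carbon whose neighbours are all
H(connectivity 1), O(2) or N(3) (incomplete octet); any 4-coordinate carbon
with a bond angle above 160°. The large-angle threshold is not printed in
the method's main text; 160° catches near-planar/linear sp³ carbons without
touching normal molecules and is configurable. Molecules lacking a stored
frequency skip the frequency rule with a warning. Free-energy deduplication
keeps the lexicographically smallest id per exactly-equal value (an optional
tolerance exists, default 0).

## Train/test split

Molecules are grouped by stoichiometry (formula key like `C2H6O1`), the
single largest energy determinant. Per group: one molecule → unassigned
(it cannot be represented on both sides); two → one each to train and test
at random; three or more → random split with the test count rounded up from
the 0.33 fraction and clamped to leave at least one molecule per side. The
aggregate test share is therefore slightly above 33%. Deterministic given
the seed.

## Distortion augmentation

A replica displaces every atom independently by exactly δ along one of the
six axis directions ±x, ±y, ±z chosen uniformly (the sign is sampled so the
distortion neighbourhood is symmetric; the axis choice is per atom).
Replicas keep the original's bonds, targets (the energies of the true
minimum) and gain an id tag. The distortion constant

    C = (1/N) Σ_j Σ_i |X_i^j − D_i^j|

is the mean over N molecules of the L1 distance between original and
distorted feature vectors. The feature sum is *not* divided by the number
of features: with ~10² features that normalisation would put the reported
constants two orders of magnitude below their published 3.49–36.23 range,
so the unnormalised sum is the reading consistent with those magnitudes.
Atom slots are excluded by default — they are distortion-invariant, so this
changes nothing numerically (a flag restores strict literalism).

## Models

Four regression families sit behind one train/predict surface, all from
scikit-learn:

* **krr** — `KernelRidge` with `K(x,x') = exp(−‖x−x'‖²/(2σ²))`; configs are
  written in the kernel width σ and converted to the toolkit's
  `gamma = 1/(2σ²)` internally. Defaults σ = 100 (the printed tested
  width) and α = 1e-11 (the best published regulariser); α doubles as the
  numerical jitter for the kernel solve.
* **nn** — `MLPRegressor`, two ReLU hidden layers (default width 256),
  linear output, MSE loss, batch 64, adam or sgd, L2 factor. Training uses
  a 3-stage step-decay schedule (lr, lr/3, lr/10 over the epoch budget) via
  warm restarts; a fixed learning rate leaves adam on a plateau well above
  the achievable error.
* **mlr** — `SGDRegressor` least squares with L2.
* **rfr** — `RandomForestRegressor`; defaults use all features and 100% of
  the samples per tree, the best-performing setting reported for the
  method.

Conditioning: feature standardization is **off** by default — the
100-weighted atom slots are an intentional scale signal in kernel
distances. The nn family divides all features by the atom weight (100),
a *uniform* rescaling that preserves the count geometry; per-column
standardization was rejected because it inflates rarely-populated bins and
measurably destroys NN generalization (test error an order of magnitude
worse on the synthetic task). nn and mlr also normalise the target to zero
mean and unit variance internally (SGD on kcal-scale targets diverges);
mlr additionally standardizes columns and transforms its coefficients back
to the original feature space, so `TrainedModel.coefficients` is directly
interpretable as kcal/mol per count. Predictions are always returned in
kcal/mol. A trained model stores the feature-dictionary fingerprint
(sha256 of its canonical JSON) and refuses vectors of the wrong length or
provenance. All randomness flows through one integer seed.

## The synthetic data generator

`fixtures` builds everything programmatically: idealized template molecules
(ethanol, water, amines, a gauche diol with an exact-distance intramolecular
H-bond contact, …) from hand-coded internal coordinates (tetrahedral
angles, staggered conformers, textbook bond lengths), six filter-probe
molecules each violating exactly one cleaning rule, and a toy dataset of
random open-chain CHNO molecules (1–8 heavy atoms, carbon-rich) whose
energies are **linear in internal-coordinate class counts by construction**
(atom terms on a per-element scale plus bond-energy-scale class terms,
~−35 to −111 kcal/mol per bond) with Gaussian noise of 1 kcal/mol. Isomeric
chains populate multi-member stoichiometry groups; rare formulas appear as
singletons, so the split rules are exercised naturally.

By default toy geometries sit exactly on their idealized minima — the
analogue of a database of optimized structures, where each chemical
environment contributes one precise value per internal coordinate, and the
KDE degenerates to one bin per environment. For the distortion study the
generator instead applies 0.02 Å Gaussian coordinate jitter ("thermal"
spread): within-class widths then sit well above the smallest distortion
(0.0005 Å) and below the largest (0.1 Å), which is the regime in which the
distortion constant is informative, as it is for a diverse real database.

What passing tests on this generator do **not** show: real DFT energies are
not linear in counts, real bond-length distributions have chemistry-driven
multimodality rather than template atoms, and real databases have no exact
duplicates. The tests validate the machinery (enumeration, binning,
assignment, split, augmentation, training) and the recoverability of a
known generating law — not chemical accuracy, which requires the full
~57k-molecule DFT database the published headline errors rest on.

## Desk-scale study sizes

The test and acceptance workloads use 50–800-molecule synthetic sets
(about 500 training molecules for the model-recovery checks, a
10 000-molecule pool for the split-share check, 60 molecules × 5 seeds for
the distortion study). These sizes were chosen so each check's statistical
signal (noise floor ~1 kcal/mol, split share within ±2 points, strict
monotonicity of C) is resolvable while the whole suite runs in minutes on
one CPU.

## Known limitations

* No ring perception, aromaticity, formal charges or stereodescriptors;
  conjugation and ring strain are invisible to local counts.
* Bond perception is a radius rule; unusual bonding (e.g. very long bonds)
  is exactly what curation removes rather than models.
* The QC-log extractor reads only the final SCF energy, the thermal free
  energy and the frequency block of the common log dialect.
* KRR memory/time scale quadratically with training size; the published
  guidance — kernel models up to ~9 heavy atoms, neural networks beyond —
  applies unchanged.
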