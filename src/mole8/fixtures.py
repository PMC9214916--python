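"""Programmatic generation of molecules and datasets for tests and demos.

Everything here is synthetic: idealized geometries are hand-coded internal
coordinates converted to Cartesians (tetrahedral angles, staggered
conformers, textbook bond lengths), and the toy energies are linear in
internal-coordinate class counts by construction so that model recovery is
checkable exactly. No downloads, no external structure generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structures import Atom, Molecule, perceive_bonds
from .internal_coords import enumerate_bond_obs

__all__ = [
    "make_ethanol", "make_water", "make_methane", "make_ammonia",
    "make_methanol", "make_methylamine", "make_ethane", "make_formaldehyde",
    "make_hbonded_diol", "make_chain_molecule", "make_filter_probes",
    "ToyEnergyModel", "make_toy_dataset", "make_linear_problem",
]

TETRA = 109.471  # degrees

#: Idealized single-bond lengths (Angstrom) between heavy elements and to H.
BOND_LENGTHS = {
    ("C", "C"): 1.52, ("C", "N"): 1.47, ("C", "O"): 1.43,
    ("N", "N"): 1.45, ("N", "O"): 1.42, ("O", "O"): 1.45,
    ("C", "H"): 1.09, ("N", "H"): 1.01, ("O", "H"): 0.96,
}

VALENCE = {"C": 4, "N": 3, "O": 2}


def _bond_length(a: str, b: str) -> float:
    key = (a, b) if (a, b) in BOND_LENGTHS else (b, a)
    return BOND_LENGTHS[key]


# ---------------------------------------------------------------------------
# internal-coordinate -> Cartesian helpers
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               r: float, theta: float, phi: float) -> np.ndarray:
    """Position of a new atom D bonded to C with |DC| = r,
    angle(D, C, B) = theta and torsion(D, C, B, A) = phi (degrees)."""
    th, ph = np.radians(theta), np.radians(phi)
    local = np.array([-r * np.cos(th),
                      r * np.sin(th) * np.cos(ph),
                      r * np.sin(th) * np.sin(ph)])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("reference atoms are collinear; torsion undefined")
    n /= nn
    m = np.cross(n, bc)
    return c + local[0] * bc + local[1] * m + local[2] * n


def _tetra_directions(units: list[np.ndarray], n_new: int) -> list[np.ndarray]:
    """Unit vectors completing an (approximately) tetrahedral coordination
    around a center that already has the given neighbour unit vectors."""
    th = np.radians(TETRA)
    if len(units) == 0:
        base = [np.array([1.0, 0.0, 0.0])]
        return base + _tetra_directions(base, n_new - 1) if n_new > 1 else base
    if len(units) == 1:
        u = units[0]
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(u, ref)) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
        p = np.cross(u, ref)
        p /= np.linalg.norm(p)
        q = np.cross(u, p)
        out = []
        for k in range(3):
            az = np.radians(120.0 * k)
            d = np.cos(th) * u + np.sin(th) * (np.cos(az) * p + np.sin(az) * q)
            out.append(d / np.linalg.norm(d))
        return out[:n_new]
    if len(units) == 2:
        b = -(units[0] + units[1])
        b /= np.linalg.norm(b)
        p = np.cross(units[0], units[1])
        p /= np.linalg.norm(p)
        half = np.radians(TETRA / 2.0)
        out = [np.cos(half) * b + np.sin(half) * p,
               np.cos(half) * b - np.sin(half) * p]
        return [d / np.linalg.norm(d) for d in out[:n_new]]
    b = -sum(units)
    b /= np.linalg.norm(b)
    return [b][:n_new]


def make_chain_molecule(elements: list[str], mol_id: str,
                        backbone_dihedral: float = 180.0,
                        jitter_sd: float = 0.0,
                        rng: np.random.Generator | None = None) -> Molecule:
    """Idealized open-chain molecule from a heavy-atom element sequence.

    The heavy backbone is laid out with tetrahedral angles and the given
    backbone torsion (anti by default); hydrogens fill each heavy atom's
    remaining valence in staggered tetrahedral directions. Optionally the
    final coordinates get Gaussian jitter. Bonds are perceived by covalent
    radii on the final geometry.
    """
    heavy = list(elements)
    pos = [np.zeros(3)]
    if len(heavy) >= 2:
        pos.append(np.array([_bond_length(heavy[0], heavy[1]), 0.0, 0.0]))
    if len(heavy) >= 3:
        r = _bond_length(heavy[1], heavy[2])
        th = np.radians(TETRA)
        pos.append(pos[1] + np.array([-r * np.cos(th), r * np.sin(th), 0.0]))
    for k in range(3, len(heavy)):
        pos.append(place_atom(pos[k - 3], pos[k - 2], pos[k - 1],
                              _bond_length(heavy[k - 1], heavy[k]),
                              TETRA, backbone_dihedral))
    symbols = list(heavy)
    coords = list(pos)
    # fill hydrogens
    for i, el in enumerate(heavy):
        nbr = [j for j in (i - 1, i + 1) if 0 <= j < len(heavy)]
        n_h = VALENCE[el] - len(nbr)
        if n_h <= 0:
            continue
        units = [(coords[j] - coords[i]) / np.linalg.norm(coords[j] - coords[i])
                 for j in nbr]
        for d in _tetra_directions(units, n_h):
            symbols.append("H")
            coords.append(coords[i] + _bond_length(el, "H") * d)
    xyz = np.array(coords)
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        xyz = xyz + rng.normal(0.0, jitter_sd, xyz.shape)
    mol = Molecule(id=mol_id, atoms=[Atom(s, c) for s, c in zip(symbols, xyz)])
    return perceive_bonds(mol)


# ---------------------------------------------------------------------------
# named template molecules
# ---------------------------------------------------------------------------

def make_ethanol() -> Molecule:
    """Idealized staggered ethanol: C-C 1.52, C-O 1.43, O-H 0.96, C-H 1.09 A.

    9 atoms in the order C, C, O, H(O), 3x H(C1), 2x H(C2); bond perception
    yields 8 bonds (1 CC, 1 CO, 1 OH, 5 CH) and there is no intramolecular
    hydrogen bond.
    """
    c1 = np.zeros(3)
    c2 = np.array([1.52, 0.0, 0.0])
    th = np.radians(TETRA)
    o = c2 + np.array([-1.43 * np.cos(th), 1.43 * np.sin(th), 0.0])
    ho = place_atom(c1, c2, o, 0.96, TETRA, 180.0)
    h1 = [place_atom(o, c2, c1, 1.09, TETRA, phi) for phi in (60.0, 180.0, 300.0)]
    # substituents on C2 sit 120 deg from O about the C1-C2 axis
    h2 = [place_atom(h1[0], c1, c2, 1.09, TETRA, phi) for phi in (180.0, 300.0)]
    coords = [c1, c2, o, ho, *h1, *h2]
    symbols = ["C", "C", "O", "H", "H", "H", "H", "H", "H"]
    mol = Molecule(id="ethanol", atoms=[Atom(s, c) for s, c in zip(symbols, coords)])
    return perceive_bonds(mol)


def make_water() -> Molecule:
    o = np.zeros(3)
    ang = np.radians(104.5)
    h1 = np.array([0.96, 0.0, 0.0])
    h2 = np.array([0.96 * np.cos(ang), 0.96 * np.sin(ang), 0.0])
    return perceive_bonds(Molecule("water", [Atom("O", o), Atom("H", h1), Atom("H", h2)]))


def make_methane() -> Molecule:
    return make_chain_molecule(["C"], "methane")


def make_ammonia() -> Molecule:
    return make_chain_molecule(["N"], "ammonia")


def make_methanol() -> Molecule:
    return make_chain_molecule(["C", "O"], "methanol")


def make_methylamine() -> Molecule:
    return make_chain_molecule(["C", "N"], "methylamine")


def make_ethane() -> Molecule:
    return make_chain_molecule(["C", "C"], "ethane")


def make_formaldehyde() -> Molecule:
    """H2C=O with a 1.21 A CO bond and trigonal-planar carbon."""
    c = np.zeros(3)
    o = np.array([1.21, 0.0, 0.0])
    a = np.radians(120.0)
    h1 = np.array([1.09 * np.cos(a), 1.09 * np.sin(a), 0.0])
    h2 = np.array([1.09 * np.cos(a), -1.09 * np.sin(a), 0.0])
    return perceive_bonds(Molecule(
        "formaldehyde", [Atom("C", c), Atom("O", o), Atom("H", h1), Atom("H", h2)]))


def make_hbonded_diol(h_acceptor_distance: float = 2.0) -> Molecule:
    """Ethylene-glycol-like gauche conformer with one intramolecular O-H...O
    contact at exactly the requested H...acceptor distance.

    The donor hydroxyl hydrogen is placed on the intersection of the sphere
    of radius 0.96 A around its oxygen and the sphere of the requested
    radius around the acceptor oxygen, in the O-O plane.
    """
    base = make_chain_molecule(["O", "C", "C", "O"], "diol", backbone_dihedral=60.0)
    coords = base.coords.copy()
    o_donor, o_acc = 0, 3
    d = float(np.linalg.norm(coords[o_acc] - coords[o_donor]))
    r_oh, r_ha = 0.96, h_acceptor_distance
    if not (abs(d - r_oh) < r_ha < d + r_oh):
        raise ValueError(f"geometry infeasible: O-O distance {d:.2f} A")
    cos_a = (d * d + r_oh * r_oh - r_ha * r_ha) / (2.0 * d * r_oh)
    axis = (coords[o_acc] - coords[o_donor]) / d
    # in-plane perpendicular using the donor's carbon as the plane reference
    ref = coords[1] - coords[o_donor]
    perp = ref - np.dot(ref, axis) * axis
    perp /= np.linalg.norm(perp)
    sin_a = np.sqrt(max(0.0, 1.0 - cos_a * cos_a))
    h_pos = coords[o_donor] + r_oh * (cos_a * axis - sin_a * perp)
    # the donor O's hydrogen is the first H bonded to atom 0 in the template
    donor_h = min(j for j in base.neighbors(o_donor) if base.atoms[j].element == "H")
    coords[donor_h] = h_pos
    # point the acceptor's own hydroxyl H away from the donor oxygen
    acc_h = min(j for j in base.neighbors(o_acc) if base.atoms[j].element == "H")
    away = coords[o_acc] - coords[o_donor]
    away /= np.linalg.norm(away)
    coords[acc_h] = coords[o_acc] + 0.96 * away
    return perceive_bonds(base.with_coords(coords))


# ---------------------------------------------------------------------------
# filter probes
# ---------------------------------------------------------------------------

def make_filter_probes() -> list[Molecule]:
    """Six molecules, each violating exactly one cleaning rule."""
    probes = []

    m = replace(make_ethanol(), id="probe-imaginary_freq", lowest_frequency=-50.0)
    probes.append(m)

    ch3f = make_methane()
    coords = ch3f.coords.copy()
    h_idx = 1
    u = coords[h_idx] - coords[0]
    coords[h_idx] = coords[0] + 1.38 * u / np.linalg.norm(u)
    atoms = [Atom("C", coords[0])] + [
        Atom("F" if i == h_idx else "H", coords[i]) for i in range(1, 5)]
    probes.append(replace(perceive_bonds(Molecule("probe-out_of_alphabet", atoms)),
                          lowest_frequency=50.0))

    stretched = make_chain_molecule(["C", "C"], "probe-long_bond")
    coords = stretched.coords.copy()
    shift = np.array([0.18, 0.0, 0.0])  # C-C 1.52 -> 1.70
    for j in [1] + [k for k in range(2, stretched.n_atoms)
                    if stretched.bond_length(1, k) < 1.3]:
        coords[j] = coords[j] + shift
    probes.append(replace(perceive_bonds(stretched.with_coords(coords)),
                          lowest_frequency=50.0))

    n = np.zeros(3)
    dirs = _tetra_directions([], 1) + []
    u0 = dirs[0]
    hs = [1.01 * u0] + [1.01 * d for d in _tetra_directions([u0], 3)]
    probes.append(replace(
        perceive_bonds(Molecule("probe-tetravalent_N",
                                [Atom("N", n)] + [Atom("H", h) for h in hs])),
        lowest_frequency=50.0))

    # 3-coordinate carbon with neighbours H(1), H(1), O(2)
    c = np.zeros(3)
    o = np.array([1.43, 0.0, 0.0])
    uo = o / np.linalg.norm(o)
    hc = [c + 1.09 * d for d in _tetra_directions([uo], 2)]
    ho = place_atom(hc[0], c, o, 0.96, TETRA, 180.0)
    probes.append(replace(
        perceive_bonds(Molecule("probe-carbon_octet",
                                [Atom("C", c), Atom("O", o), Atom("H", hc[0]),
                                 Atom("H", hc[1]), Atom("H", ho)])),
        lowest_frequency=50.0))

    # methane with one H-C-H angle opened to 170 degrees
    a = np.radians(85.0)
    h_wide = [np.array([np.sin(a), 0.0, np.cos(a)]) * 1.09,
              np.array([-np.sin(a), 0.0, np.cos(a)]) * 1.09]
    b = np.radians(TETRA / 2.0)
    h_rest = [np.array([0.0, np.sin(b), -np.cos(b)]) * 1.09,
              np.array([0.0, -np.sin(b), -np.cos(b)]) * 1.09]
    probes.append(replace(
        perceive_bonds(Molecule("probe-large_angle_C4",
                                [Atom("C", np.zeros(3))] +
                                [Atom("H", h) for h in h_wide + h_rest])),
        lowest_frequency=50.0))
    return probes


# ---------------------------------------------------------------------------
# toy dataset with a linear-in-counts energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyEnergyModel:
    """Synthetic stand-in for DFT targets: energy linear in class counts.

    ``energy = sum_class coeff[class] * count(class) + N(0, noise_sd)``,
    with atom coefficients applied per unit of the 100-weighted atom slot.
    Linearity makes coefficient recovery by regression checkable.
    """

    coefficients: dict = field(default_factory=lambda: {
        # per unit of the weighted atom slot (i.e. per 0.01 atom)
        "atom:C": -1.50, "atom:H": -0.30, "atom:N": -1.20, "atom:O": -1.00,
        # per bond observation, rough single-bond-energy scale (kcal/mol)
        "bond:C-C": -83.0, "bond:C-H": -99.0, "bond:C-N": -73.0,
        "bond:C-O": -86.0, "bond:H-N": -93.0, "bond:H-O": -111.0,
        "bond:H-H": -104.0, "bond:N-N": -40.0, "bond:N-O": -55.0,
        "bond:O-O": -35.0,
    })
    noise_sd: float = 1.0  # kcal/mol
    seed: int = 0

    def clean_energy(self, molecule: Molecule) -> float:
        e = 0.0
        for el in ("C", "H", "N", "O"):
            n_el = sum(1 for a in molecule.atoms if a.element == el)
            e += self.coefficients.get(f"atom:{el}", 0.0) * 100.0 * n_el
        for obs in enumerate_bond_obs(molecule, "element"):
            e += self.coefficients.get(f"bond:{obs.class_label}", 0.0)
        return e

    def energy(self, molecule: Molecule, rng: np.random.Generator) -> float:
        return self.clean_energy(molecule) + (
            rng.normal(0.0, self.noise_sd) if self.noise_sd > 0 else 0.0)


def make_toy_dataset(n: int = 500,
                     energy_model: ToyEnergyModel | None = None,
                     jitter_sd: float = 0.0,
                     seed: int = 0,
                     max_heavy: int = 8) -> list[Molecule]:
    """Random open-chain CHNO molecules with synthetic linear energies.

    Heavy-atom sequences are drawn at random (carbon-rich, lengths 1 to
    ``max_heavy``), so isomers populate multi-member stoichiometry groups
    while rare formulas appear as singletons — exactly the structure the
    stoichiometry split rules need. By default every molecule sits exactly
    on its idealized minimum geometry (mirroring a database of optimized
    structures, where each internal coordinate takes one precise value per
    chemical environment); ``jitter_sd`` adds Gaussian coordinate noise for
    robustness experiments. Energies come from the toy model evaluated on
    the generated geometry plus Gaussian noise. Deterministic under the
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    em = energy_model or ToyEnergyModel()
    rng = np.random.default_rng(seed)
    elems = np.array(["C", "N", "O"])
    mols = []
    for k in range(n):
        L = int(rng.integers(1, max_heavy + 1))
        seq = list(rng.choice(elems, size=L, p=[0.6, 0.2, 0.2]))
        m = make_chain_molecule(seq, f"toy-{k:04d}", jitter_sd=jitter_sd, rng=rng)
        e = em.energy(m, rng)
        g = e + 15.0 + (rng.normal(0.0, em.noise_sd) if em.noise_sd > 0 else 0.0)
        mols.append(replace(m, electronic_energy=e, free_energy=g,
                            lowest_frequency=float(rng.uniform(20.0, 200.0)),
                            provenance={"template": "".join(seq)}))
    return mols


def make_linear_problem(n: int = 400, d: int = 12, noise_sd: float = 0.0,
                        seed: int = 0):
    """Synthetic count-style regression design with known coefficients.

    The first four columns mimic 100-weighted atom slots; the rest are
    Poisson counts. Returns (X, y, coef, intercept).
    """
    rng = np.random.default_rng(seed)
    X = np.empty((n, d))
    X[:, :4] = 100.0 * rng.integers(0, 9, size=(n, 4))
    X[:, 4:] = rng.poisson(3.0, size=(n, d - 4))
    coef = rng.normal(0.0, 5.0, size=d)
    coef[:4] /= 100.0
    intercept = rng.normal(0.0, 10.0)
    y = X @ coef + intercept
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return X, y, coef, intercept
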