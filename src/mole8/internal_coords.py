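"""Enumeration and canonical labelling of internal coordinates.

Every bond, bonded angle, bonded dihedral, hydrogen-bond contact and NH_x
group of a molecule becomes a :class:`FeatureObservation` with a canonical
class label. Labels are built from atom tokens — the element symbol alone
("C") or element plus connectivity ("C4") depending on the family's
granularity — ordered by the fixed element order C < H < N < O so that
relabelling a reversed atom tuple yields the identical string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .structures import Molecule, DegenerateGeometryError

__all__ = [
    "FeatureObservation",
    "Granularity",
    "ELEMENT_ORDER",
    "HBOND_MIN",
    "HBOND_MAX",
    "atom_token",
    "enumerate_bond_obs",
    "enumerate_angle_obs",
    "enumerate_dihedral_obs",
    "detect_hbond_obs",
    "count_nhx",
    "observations_to_records",
]

log = logging.getLogger(__name__)

Granularity = Literal["element", "element+connectivity"]

#: Canonical element sort order used for all class labels.
ELEMENT_ORDER = {"C": 0, "H": 1, "N": 2, "O": 3}

#: Hydrogen-bond detection window, H...acceptor distance in Angstrom.
HBOND_MIN = 1.3
HBOND_MAX = 2.6


@dataclass(frozen=True)
class FeatureObservation:
    """One measured internal coordinate with its canonical class label.

    ``value`` is Angstrom for bond/hbond families and degrees for
    angle/dihedral families.
    """

    family: str  # bond | angle | dihedral | hbond
    class_label: str
    value: float
    atom_indices: tuple[int, ...]

    def __post_init__(self):
        if self.family in ("bond", "hbond") and self.value <= 0:
            raise ValueError(f"{self.family} value must be positive")
        if self.family == "angle" and not (0.0 < self.value <= 180.0 + 1e-9):
            raise ValueError("angle must lie in (0, 180] degrees")
        if self.family == "dihedral" and not (-1e-9 <= self.value <= 180.0 + 1e-9):
            raise ValueError("dihedral must lie in [0, 180] degrees")


def atom_token(molecule: Molecule, i: int, granularity: Granularity) -> str:
    el = molecule.atoms[i].element
    if granularity == "element":
        return el
    return f"{el}{molecule.degree(i)}"


def _token_key(tok: str) -> tuple[int, int]:
    el = tok[0]
    conn = int(tok[1:]) if len(tok) > 1 else 0
    return (ELEMENT_ORDER.get(el, 99), conn)


def _angle_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1, v2 = p0 - p1, p2 - p1
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-8 or n2 < 1e-8:
        raise DegenerateGeometryError("coincident atoms in angle")
    cos = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _torsion_deg(p0, p1, p2, p3) -> float | None:
    """Absolute torsion in [0, 180]; None when three consecutive atoms are collinear."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        return None
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(abs(np.degrees(np.arctan2(y, x))))


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_bond_obs(molecule: Molecule,
                       granularity: Granularity = "element") -> list[FeatureObservation]:
    """One observation per perceived bond, labelled by the sorted token pair."""
    out = []
    for i, j in sorted(molecule.bonds):
        ti, tj = atom_token(molecule, i, granularity), atom_token(molecule, j, granularity)
        a, b = sorted((ti, tj), key=_token_key)
        out.append(FeatureObservation("bond", f"{a}-{b}",
                                      molecule.bond_length(i, j), (i, j)))
    return out


def enumerate_angle_obs(molecule: Molecule,
                        granularity: Granularity = "element+connectivity"
                        ) -> list[FeatureObservation]:
    """One observation per connected triple i-j-k with j central.

    Each unordered pair of neighbours of j is counted once, so the number of
    observations is sum_j d_j (d_j - 1) / 2 over atom degrees.
    """
    coords = molecule.coords
    out = []
    for j in range(molecule.n_atoms):
        nbrs = molecule.neighbors(j)
        tj = atom_token(molecule, j, granularity)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                ti, tk = atom_token(molecule, i, granularity), atom_token(molecule, k, granularity)
                lo, hi = sorted((ti, tk), key=_token_key)
                value = _angle_deg(coords[i], coords[j], coords[k])
                out.append(FeatureObservation("angle", f"{lo}-{tj}-{hi}",
                                              value, (i, j, k)))
    return out


def enumerate_dihedral_obs(molecule: Molecule,
                           granularity: Granularity = "element"
                           ) -> list[FeatureObservation]:
    """One observation per undirected bonded path i-j-k-l.

    The value is the absolute torsion in [0, 180] degrees (the
    representation is achiral); the label is the lexicographically smaller
    of the forward and reversed token sequences. Paths whose torsion is
    undefined (three consecutive collinear atoms) are skipped with a logged
    warning.
    """
    coords = molecule.coords
    out = []
    for j, k in sorted(molecule.bonds):
        for i in molecule.neighbors(j):
            if i == k:
                continue
            for l in molecule.neighbors(k):
                if l == j or l == i:
                    continue
                toks = tuple(atom_token(molecule, a, granularity) for a in (i, j, k, l))
                keys_f = tuple(_token_key(t) for t in toks)
                keys_r = tuple(_token_key(t) for t in toks[::-1])
                label_toks = toks if keys_f <= keys_r else toks[::-1]
                value = _torsion_deg(coords[i], coords[j], coords[k], coords[l])
                if value is None:
                    log.warning("%s: torsion %s undefined (collinear atoms); skipped",
                                molecule.id, (i, j, k, l))
                    continue
                out.append(FeatureObservation("dihedral", "-".join(label_toks),
                                              value, (i, j, k, l)))
    return out


def detect_hbond_obs(molecule: Molecule) -> list[FeatureObservation]:
    """Geometric hydrogen-bond detection.

    Donors are hydrogens covalently bonded to N or O; acceptors are N or O
    atoms not covalently bonded to that hydrogen. A contact is recorded when
    the H...acceptor distance lies in [1.3, 2.6] Angstrom, labelled
    OH-O / OH-N / NH-O / NH-N by donor heavy atom and acceptor element.
    """
    coords = molecule.coords
    out = []
    acceptors = [i for i, a in enumerate(molecule.atoms) if a.element in ("N", "O")]
    for h in range(molecule.n_atoms):
        if molecule.atoms[h].element != "H":
            continue
        heavy = [n for n in molecule.neighbors(h)
                 if molecule.atoms[n].element in ("N", "O")]
        if not heavy:
            continue
        donor_el = molecule.atoms[heavy[0]].element
        bonded_to_h = set(molecule.neighbors(h))
        for acc in acceptors:
            if acc == h or acc in bonded_to_h:
                continue
            d = float(np.linalg.norm(coords[h] - coords[acc]))
            if HBOND_MIN <= d <= HBOND_MAX:
                label = f"{donor_el}H-{molecule.atoms[acc].element}"
                out.append(FeatureObservation("hbond", label, d, (h, acc)))
    return out


def count_nhx(molecule: Molecule) -> dict[int, int]:
    """Count nitrogen atoms by the number x of bonded hydrogens (x >= 1)."""
    counts: dict[int, int] = {}
    for i, a in enumerate(molecule.atoms):
        if a.element != "N":
            continue
        x = sum(1 for n in molecule.neighbors(i) if molecule.atoms[n].element == "H")
        if x >= 1:
            counts[x] = counts.get(x, 0) + 1
    return counts


def observations_to_records(molecule_id: str,
                            observations: Iterable[FeatureObservation]) -> list[dict]:
    """Flatten observations into CSV-ready records."""
    return [
        {"molecule_id": molecule_id, "family": o.family, "class_label": o.class_label,
         "value": o.value, "indices": ";".join(map(str, o.atom_indices))}
        for o in observations
    ]
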