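"""Molecular structures: I/O, bond perception and QC-log energy extraction.

The package works on small organic molecules built from C, H, N and O.
Other elements are representable (so that curation can reject them) but are
flagged as out-of-alphabet. All coordinates are in Angstrom and all energies
in kcal/mol; unit conversion happens at ingestion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Molecule",
    "ParseError",
    "ExtractionError",
    "DegenerateGeometryError",
    "ALLOWED_ELEMENTS",
    "COVALENT_RADII",
    "HARTREE_TO_KCALMOL",
    "read_structure",
    "write_structure",
    "perceive_bonds",
    "extract_qc_results",
    "read_targets",
    "attach_targets",
]

ALLOWED_ELEMENTS = ("C", "H", "N", "O")

#: Single-bond covalent radii (Angstrom). The CHNO entries drive bond
#: perception; the others exist only so out-of-alphabet molecules can still
#: be perceived and then rejected by curation.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "B": 0.84,
}

HARTREE_TO_KCALMOL = 627.5094740631

#: Pairs closer than this are considered physically overlapping.
MIN_ATOM_DISTANCE = 0.3


class ParseError(ValueError):
    """A structure file could not be parsed."""


class ExtractionError(ValueError):
    """A requested quantity is missing from a QC log file."""


class DegenerateGeometryError(ValueError):
    """Geometry contains (near-)coincident atoms."""


@dataclass(frozen=True)
class Atom:
    element: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("atom coordinates must be finite")
        object.__setattr__(self, "position", pos)

    @property
    def in_alphabet(self) -> bool:
        return self.element in ALLOWED_ELEMENTS


@dataclass
class Molecule:
    """A molecule: ordered atoms, an undirected bond list and optional targets.

    Bonds are stored as a frozenset of sorted ``(i, j)`` index pairs.
    ``electronic_energy`` and ``free_energy`` are kcal/mol (free energy at
    298.15 K); ``lowest_frequency`` is cm^-1.
    """

    id: str
    atoms: list[Atom]
    bonds: frozenset[tuple[int, int]] = frozenset()
    electronic_energy: float | None = None
    free_energy: float | None = None
    lowest_frequency: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValueError("molecule must contain at least one atom")
        norm = set()
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < len(self.atoms) and 0 <= j < len(self.atoms)):
                raise ValueError(f"bond ({i},{j}) references a missing atom")
            norm.add((min(i, j), max(i, j)))
        self.bonds = frozenset(norm)

    # -- convenience views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def out_of_alphabet(self) -> bool:
        return any(not a.in_alphabet for a in self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def degree(self, i: int) -> int:
        return sum(1 for a, b in self.bonds if i in (a, b))

    def bond_length(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.atoms[i].position - self.atoms[j].position))

    def with_coords(self, coords: np.ndarray, new_id: str | None = None) -> "Molecule":
        atoms = [Atom(a.element, c) for a, c in zip(self.atoms, np.asarray(coords, float))]
        return replace(self, id=new_id or self.id, atoms=atoms)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def _read_xyz(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: expected atom count") from None
    if len(lines) < n + 2:
        raise ParseError(f"{path}: expected {n} atom lines, file has {len(lines) - 2}")
    atoms = []
    for k in range(n):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 'element x y z'")
        el = parts[0].capitalize()
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric coordinate") from None
        atoms.append(Atom(el, np.array(xyz)))
    return Molecule(id=path.stem, atoms=atoms, provenance={"source": str(path), "format": "xyz"})


def _read_sdf(path: Path) -> Molecule:
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise ParseError(f"{path}: RDKit could not parse the SDF/MOL block")
    conf = mol.GetConformer()
    atoms = [
        Atom(mol.GetAtomWithIdx(i).GetSymbol(), np.array(conf.GetAtomPosition(i)))
        for i in range(mol.GetNumAtoms())
    ]
    bonds = frozenset(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return Molecule(id=path.stem, atoms=atoms, bonds=bonds,
                    provenance={"source": str(path), "format": "sdf"})


def read_structure(path: str | Path, fmt: str | None = None) -> Molecule:
    """Read a molecule from an XYZ or SDF (V2000) file.

    XYZ files carry no connectivity (bonds are perceived later);
    SDF bond blocks are honoured as given. Out-of-alphabet elements are
    accepted here — curation decides what to do with them.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt in ("sdf", "mol"):
        return _read_sdf(path)
    raise ValueError(f"unsupported structure format: {fmt!r}")


def write_structure(molecule: Molecule, path: str | Path, fmt: str | None = None) -> None:
    """Write a molecule as XYZ (atoms only) or SDF V2000 (atoms + bonds)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        rows = [str(molecule.n_atoms), molecule.id]
        for a in molecule.atoms:
            x, y, z = a.position
            rows.append(f"{a.element} {x:.10f} {y:.10f} {z:.10f}")
        path.write_text("\n".join(rows) + "\n")
        return
    if fmt in ("sdf", "mol"):
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        rw = Chem.RWMol()
        for a in molecule.atoms:
            at = Chem.Atom(a.element)
            at.SetNoImplicit(True)
            rw.AddAtom(at)
        for i, j in sorted(molecule.bonds):
            rw.AddBond(i, j, Chem.BondType.SINGLE)
        conf = Chem.Conformer(molecule.n_atoms)
        for i, a in enumerate(molecule.atoms):
            conf.SetAtomPosition(i, Point3D(*a.position))
        rw.AddConformer(conf)
        m = rw.GetMol()
        m.SetProp("_Name", molecule.id)
        Chem.MolToMolFile(m, str(path), kekulize=False)
        return
    raise ValueError(f"unsupported structure format: {fmt!r}")


# ---------------------------------------------------------------------------
# bond perception
# ---------------------------------------------------------------------------

def perceive_bonds(molecule: Molecule, scale: float = 1.15) -> Molecule:
    """Perceive covalent bonds by the covalent-radius-sum rule.

    Two atoms are bonded when their distance is at most
    ``scale * (r_cov(i) + r_cov(j))``. Deterministic, idempotent, and
    invariant under rigid motion of the coordinates.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    coords = molecule.coords
    n = molecule.n_atoms
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    if n > 1 and dist[iu].min() < MIN_ATOM_DISTANCE:
        i = int(np.argmin(dist[iu]))
        raise DegenerateGeometryError(
            f"{molecule.id}: atoms closer than {MIN_ATOM_DISTANCE} A "
            f"(min distance {dist[iu].min():.3f} A)")
    radii = np.array([COVALENT_RADII.get(a.element, 0.75) for a in molecule.atoms])
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonded = (dist <= cutoff) & np.triu(np.ones((n, n), bool), k=1)
    bonds = frozenset((int(i), int(j)) for i, j in zip(*np.nonzero(bonded)))
    return replace(molecule, bonds=bonds)


# ---------------------------------------------------------------------------
# QC log extraction
# ---------------------------------------------------------------------------

_SCF_RE = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+\.\d+)")
_FREE_RE = re.compile(r"Sum of electronic and thermal Free Energies\s*=\s*(-?\d+\.\d+)")
_FREQ_RE = re.compile(r"Frequencies\s*--\s*((?:-?\d+\.\d+\s*)+)")


def extract_qc_results(path: str | Path) -> tuple[float, float, float]:
    """Extract (electronic_energy, free_energy, lowest_frequency) from a QC log.

    Minimal text extraction for the widely used quantum-chemistry log
    dialect: the last ``SCF Done`` energy, the last thermochemistry free
    energy, and the minimum over all ``Frequencies --`` rows. Hartree values
    are converted to kcal/mol. Missing quantities raise
    :class:`ExtractionError` naming the quantity; there are no silent
    defaults.
    """
    text = Path(path).read_text()
    scf = _SCF_RE.findall(text)
    if not scf:
        raise ExtractionError("electronic_energy not found")
    free = _FREE_RE.findall(text)
    if not free:
        raise ExtractionError("free_energy not found")
    freq_rows = _FREQ_RE.findall(text)
    if not freq_rows:
        raise ExtractionError("lowest_frequency not found")
    freqs = [float(v) for row in freq_rows for v in row.split()]
    return (
        float(scf[-1]) * HARTREE_TO_KCALMOL,
        float(free[-1]) * HARTREE_TO_KCALMOL,
        min(freqs),
    )


# ---------------------------------------------------------------------------
# target tables
# ---------------------------------------------------------------------------

def read_targets(path: str | Path) -> pd.DataFrame:
    """Read a per-molecule target table (columns: id, electronic_energy, free_energy)."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("target CSV must have an 'id' column")
    return df.set_index("id")


def attach_targets(molecules: Iterable[Molecule], targets: pd.DataFrame) -> list[Molecule]:
    """Attach CSV targets to molecules by id. CSV values take precedence."""
    out = []
    for m in molecules:
        if m.id in targets.index:
            row = targets.loc[m.id]
            kw = {}
            for col in ("electronic_energy", "free_energy", "lowest_frequency"):
                if col in targets.columns and pd.notna(row[col]):
                    kw[col] = float(row[col])
            m = replace(m, **kw)
        out.append(m)
    return out
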