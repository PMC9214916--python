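"""Database cleaning filters and the stoichiometry-grouped train/test split.

The cleaning rules target artefacts of automated dataset generation:
transition states (imaginary frequencies), out-of-alphabet elements,
unusually long bonds, zwitterionic tetravalent nitrogens, carbons that do
not complete the octet, and near-planar/linear four-coordinate carbons.
Each removed molecule gets exactly one reason code — the first matching
rule wins — so removal counts are disjoint.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .structures import Molecule
from .internal_coords import enumerate_angle_obs

__all__ = [
    "FilterConfig",
    "FilterReport",
    "SplitAssignment",
    "apply_filters",
    "dedupe_free_energy",
    "stoichiometry_key",
    "split_by_stoichiometry",
]

log = logging.getLogger(__name__)

REASONS = (
    "imaginary_freq", "out_of_alphabet", "long_bond", "tetravalent_N",
    "carbon_octet", "large_angle_C4", "duplicate_free_energy",
)


@dataclass(frozen=True)
class FilterConfig:
    max_bond_length: float = 1.6       # Angstrom
    large_angle_threshold: float = 160.0  # degrees, at 4-coordinate carbons
    free_energy_tolerance: float = 0.0    # kcal/mol; 0 = bitwise equality


@dataclass
class FilterReport:
    kept: list[str]
    removed: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.kept) & set(self.removed)
        if overlap:
            raise ValueError(f"ids both kept and removed: {sorted(overlap)}")

    def kept_molecules(self, molecules: list[Molecule]) -> list[Molecule]:
        keep = set(self.kept)
        return [m for m in molecules if m.id in keep]

    def to_json(self) -> str:
        return json.dumps({"kept": self.kept, "removed": self.removed},
                          sort_keys=True, indent=1)


@dataclass
class SplitAssignment:
    train: set[str]
    test: set[str]
    unassigned: set[str]
    seed: int

    def __post_init__(self):
        if (self.train & self.test) or (self.train & self.unassigned) or (self.test & self.unassigned):
            raise ValueError("split sets must be disjoint")

    def to_json(self) -> str:
        return json.dumps({"train": sorted(self.train), "test": sorted(self.test),
                           "unassigned": sorted(self.unassigned), "seed": self.seed},
                          sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _violates_carbon_octet(m: Molecule, i: int) -> bool:
    """3-coordinate carbon whose neighbours are all H(1) / O(2) / N(3)."""
    nbrs = m.neighbors(i)
    if m.atoms[i].element != "C" or len(nbrs) != 3:
        return False
    for n in nbrs:
        el, deg = m.atoms[n].element, m.degree(n)
        if not ((el == "H" and deg == 1) or (el == "O" and deg == 2)
                or (el == "N" and deg == 3)):
            return False
    return True


def _removal_reason(m: Molecule, cfg: FilterConfig) -> str | None:
    if m.lowest_frequency is None:
        log.warning("%s: lowest_frequency absent; imaginary-frequency filter skipped", m.id)
    elif m.lowest_frequency < 0:
        return "imaginary_freq"
    if m.out_of_alphabet:
        return "out_of_alphabet"
    if any(m.bond_length(i, j) > cfg.max_bond_length for i, j in m.bonds):
        return "long_bond"
    if any(a.element == "N" and m.degree(i) >= 4 for i, a in enumerate(m.atoms)):
        return "tetravalent_N"
    if any(_violates_carbon_octet(m, i) for i in range(m.n_atoms)):
        return "carbon_octet"
    c4 = {i for i, a in enumerate(m.atoms) if a.element == "C" and m.degree(i) == 4}
    if c4:
        for obs in enumerate_angle_obs(m, "element"):
            if obs.atom_indices[1] in c4 and obs.value > cfg.large_angle_threshold:
                return "large_angle_C4"
    return None


def apply_filters(molecules: list[Molecule],
                  config: FilterConfig | None = None) -> FilterReport:
    """Apply the six cleaning rules in their fixed precedence order.

    Chemistry problems are reported, never raised; molecules must already
    carry perceived bonds.
    """
    cfg = config or FilterConfig()
    kept, removed = [], {}
    for m in molecules:
        reason = _removal_reason(m, cfg)
        if reason is None:
            kept.append(m.id)
        else:
            removed[m.id] = reason
    return FilterReport(kept=kept, removed=removed)


def dedupe_free_energy(molecules: list[Molecule],
                       tolerance: float = 0.0) -> FilterReport:
    """Keep one molecule per free-energy value (smallest id wins).

    With the default zero tolerance, equality is exact; a positive tolerance
    clusters values within ``tolerance`` kcal/mol of a group's first value.
    """
    for m in molecules:
        if m.free_energy is None:
            raise ValueError(f"{m.id}: free_energy required for deduplication")
    kept, removed = [], {}
    groups: list[tuple[float, list[str]]] = []
    for m in sorted(molecules, key=lambda m: m.id):
        for gval, ids in groups:
            if (m.free_energy == gval if tolerance == 0.0
                    else abs(m.free_energy - gval) <= tolerance):
                ids.append(m.id)
                break
        else:
            groups.append((m.free_energy, [m.id]))
    for _, ids in groups:
        keep, *rest = sorted(ids)
        kept.append(keep)
        for r in rest:
            removed[r] = "duplicate_free_energy"
    order = {m.id: k for k, m in enumerate(molecules)}
    kept.sort(key=order.__getitem__)
    return FilterReport(kept=kept, removed=removed)


# ---------------------------------------------------------------------------
# stoichiometry split
# ---------------------------------------------------------------------------

def stoichiometry_key(molecule: Molecule) -> str:
    """Canonical formula key, e.g. ethanol -> 'C2H6O1'; zero counts omitted."""
    counts = {el: 0 for el in ("C", "H", "N", "O")}
    for a in molecule.atoms:
        if a.element in counts:
            counts[a.element] += 1
    return "".join(f"{el}{counts[el]}" for el in ("C", "H", "N", "O")
                   if counts[el] > 0) or "X"


def split_by_stoichiometry(molecules: list[Molecule],
                           test_fraction: float = 0.33,
                           seed: int = 0) -> SplitAssignment:
    """Stoichiometry-grouped train/test split.

    Per formula group: a single molecule is left unassigned (it cannot be
    represented in both sets); a pair is split one/one at random; larger
    groups are split at ``test_fraction`` (test size rounded up, with at
    least one molecule on each side). Deterministic given the seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for m in molecules:
        groups.setdefault(stoichiometry_key(m), []).append(m.id)
    train, test, unassigned = set(), set(), set()
    for key in sorted(groups):
        ids = sorted(groups[key])
        if len(ids) == 1:
            unassigned.add(ids[0])
            continue
        perm = rng.permutation(len(ids))
        ids = [ids[k] for k in perm]
        if len(ids) == 2:
            train.add(ids[0])
            test.add(ids[1])
            continue
        n_test = math.ceil(test_fraction * len(ids))
        n_test = max(1, min(len(ids) - 1, n_test))
        test.update(ids[:n_test])
        train.update(ids[n_test:])
    return SplitAssignment(train=train, test=test, unassigned=unassigned, seed=seed)
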