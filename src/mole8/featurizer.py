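"""The KDE-binned count representation.

For every internal-coordinate class observed in a training set (e.g. the
C-C bond lengths, the H-C4-H angles, the OH-O hydrogen-bond distances), a
Gaussian kernel density estimate is fitted over the pooled values. Every
local maximum of the density becomes one feature; the local minima flanking
a maximum delimit the interval of values assigned to it, so the bins of a
class tile the real line without overlap (outermost bounds are +-inf). A
molecule is encoded by counting, per bin, how many of its observations fall
inside the bin's interval, preceded by the four atom counts weighted by 100
and followed by the NH_x group counts.

The result is a fixed-length, explainable, rotation/translation/permutation
invariant count vector suitable for kernel ridge regression and other
standard learners.
"""

from __future__ import annotations

import hashlib
import json
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .structures import Molecule, ALLOWED_ELEMENTS
from .internal_coords import (
    FeatureObservation,
    enumerate_bond_obs,
    enumerate_angle_obs,
    enumerate_dihedral_obs,
    detect_hbond_obs,
    count_nhx,
)

__all__ = [
    "FeatureBin",
    "FeaturizerConfig",
    "FeatureDictionary",
    "FeatureVector",
    "fit_feature_bins",
    "build_dictionary",
    "encode_molecule",
    "encode_matrix",
    "molecule_observations",
]

SCHEMA_VERSION = 1

FAMILY_ORDER = ("bond", "angle", "dihedral", "hbond")

#: Atom-count slots are multiplied by this weight.
ATOM_WEIGHT = 100.0


@dataclass(frozen=True)
class FeatureBin:
    """One KDE maximum of one class, owning the half-open interval (lower, upper]."""

    family: str
    class_label: str
    maximum: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (self.lower < self.maximum < self.upper):
            raise ValueError(
                f"bin bounds must bracket the maximum: "
                f"{self.lower} < {self.maximum} < {self.upper} fails")


@dataclass(frozen=True)
class FeaturizerConfig:
    """KDE bandwidth factors (relative to the per-class sample standard
    deviation) and token granularities per family.

    The 0.07 bond/angle factors are the representation's tuned widths; the
    dihedral and H-bond factors default to the same value. Granularities:
    angles carry connectivity tokens, bonds and dihedrals element-only.
    """

    bandwidth_bond: float = 0.07
    bandwidth_angle: float = 0.07
    bandwidth_dihedral: float = 0.07
    bandwidth_hbond: float = 0.07
    granularity_bond: str = "element"
    granularity_angle: str = "element+connectivity"
    granularity_dihedral: str = "element"
    grid_points: int = 2048
    grid_pad_bandwidths: float = 3.0
    absolute_bandwidth: bool = False  # if True, factors are absolute widths

    def bandwidth(self, family: str) -> float:
        return getattr(self, f"bandwidth_{family}")

    def granularity(self, family: str) -> str:
        return getattr(self, f"granularity_{family}", "element")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class FeatureVector:
    molecule_id: str
    values: np.ndarray
    dropped_classes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def molecule_observations(molecule: Molecule,
                          config: FeaturizerConfig) -> list[FeatureObservation]:
    """All bond/angle/dihedral/H-bond observations of one molecule."""
    return (enumerate_bond_obs(molecule, config.granularity_bond)
            + enumerate_angle_obs(molecule, config.granularity_angle)
            + enumerate_dihedral_obs(molecule, config.granularity_dihedral)
            + detect_hbond_obs(molecule))


# ---------------------------------------------------------------------------
# KDE binning
# ---------------------------------------------------------------------------

def fit_feature_bins(values, family: str, class_label: str,
                     bandwidth: float, config: FeaturizerConfig | None = None
                     ) -> list[FeatureBin]:
    """Fit the KDE of one class and convert its maxima into bins.

    ``bandwidth`` is a factor multiplying the sample standard deviation
    (the Gaussian-KDE convention for a scalar bandwidth argument), or an
    absolute width when the config requests it. Degenerate classes (single
    value, zero variance) yield one bin covering the whole line.
    """
    cfg = config or FeaturizerConfig()
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError(f"class {class_label!r} has no observations")

    std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    scale = max(1.0, float(np.abs(vals).max()))
    if vals.size == 1 or std <= 1e-9 * scale:
        # single distinct value (to numerical precision): one bin, whole line
        return [FeatureBin(family, class_label, float(vals[0]), -np.inf, np.inf)]

    h = bandwidth if cfg.absolute_bandwidth else bandwidth * std
    bw_method = bandwidth / std if cfg.absolute_bandwidth else bandwidth
    kde = gaussian_kde(vals, bw_method=bw_method)
    pad = cfg.grid_pad_bandwidths * h
    grid = np.linspace(vals.min() - pad, vals.max() + pad, cfg.grid_points)
    dens = kde(grid)

    interior = np.arange(1, len(grid) - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    maxima_idx = interior[is_max]
    if maxima_idx.size == 0:  # numerically flat density
        return [FeatureBin(family, class_label, float(np.median(vals)), -np.inf, np.inf)]
    # boundary between consecutive maxima = location of the lowest density;
    # maxima that no minimum strictly separates are merged (keep the denser)
    keep = [int(maxima_idx[0])]
    boundaries: list[float] = []
    for b in maxima_idx[1:]:
        a = keep[-1]
        k = a + int(np.argmin(dens[a:b + 1]))
        if not (grid[a] < grid[k] < grid[b]):
            if dens[b] > dens[a]:
                keep[-1] = int(b)
            continue
        keep.append(int(b))
        boundaries.append(float(grid[k]))
    maxima = grid[keep]
    edges = [-np.inf, *boundaries, np.inf]
    return [FeatureBin(family, class_label, float(m), float(lo), float(hi))
            for m, lo, hi in zip(maxima, edges[:-1], edges[1:])]


# ---------------------------------------------------------------------------
# the dictionary
# ---------------------------------------------------------------------------

@dataclass
class FeatureDictionary:
    """Ordered, serializable definition of the full representation.

    Slot layout: 4 atom-count slots (C, H, N, O), then all bins grouped by
    family in the order bond, angle, dihedral, hbond (classes alphabetical
    within a family, bins by ascending maximum within a class), then the
    NH_x slots in ascending x.
    """

    bins: list[FeatureBin]
    nhx_slots: list[int]
    config: FeaturizerConfig

    def __post_init__(self):
        self.bins = sorted(
            self.bins,
            key=lambda b: (FAMILY_ORDER.index(b.family), b.class_label, b.maximum))
        self._index = self._build_index()

    def _build_index(self):
        idx: dict[tuple[str, str], tuple[int, list[FeatureBin]]] = {}
        pos = len(ALLOWED_ELEMENTS)
        for b in self.bins:
            key = (b.family, b.class_label)
            if key not in idx:
                idx[key] = (pos, [])
            idx[key][1].append(b)
            pos += 1
        return idx

    @property
    def total_length(self) -> int:
        return len(ALLOWED_ELEMENTS) + len(self.bins) + len(self.nhx_slots)

    def class_bins(self, family: str, class_label: str) -> list[FeatureBin]:
        return self._index.get((family, class_label), (0, []))[1]

    def class_slice(self, family: str, class_label: str) -> slice:
        start, bins = self._index[(family, class_label)]
        return slice(start, start + len(bins))

    def classes(self, family: str | None = None) -> list[tuple[str, str]]:
        keys = list(self._index)
        if family is not None:
            keys = [k for k in keys if k[0] == family]
        return keys

    def feature_names(self) -> list[str]:
        names = [f"atom:{el}" for el in ALLOWED_ELEMENTS]
        names += [f"{b.family}:{b.class_label}@{b.maximum:.6g}" for b in self.bins]
        names += [f"nhx:{x}" for x in self.nhx_slots]
        return names

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "nhx_slots": self.nhx_slots,
            "bins": [
                {"family": b.family, "class_label": b.class_label,
                 "maximum": b.maximum,
                 "lower": None if np.isinf(b.lower) else b.lower,
                 "upper": None if np.isinf(b.upper) else b.upper}
                for b in self.bins
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureDictionary":
        payload = json.loads(text)
        cfg = FeaturizerConfig(**payload["config"])
        bins = [
            FeatureBin(d["family"], d["class_label"], d["maximum"],
                       -np.inf if d["lower"] is None else d["lower"],
                       np.inf if d["upper"] is None else d["upper"])
            for d in payload["bins"]
        ]
        return cls(bins=bins, nhx_slots=list(payload["nhx_slots"]), config=cfg)

    def fingerprint(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def build_dictionary(training_molecules: list[Molecule],
                     config: FeaturizerConfig | None = None) -> FeatureDictionary:
    """Pool observations over the training set and fit bins per class."""
    cfg = config or FeaturizerConfig()
    if not training_molecules:
        raise ValueError("cannot build a feature dictionary from an empty training set")
    pooled: dict[tuple[str, str], list[float]] = {}
    nhx_seen: set[int] = set()
    for m in training_molecules:
        if not m.bonds:
            raise ValueError(f"{m.id}: molecule has no bonds; perceive bonds first")
        for obs in molecule_observations(m, cfg):
            pooled.setdefault((obs.family, obs.class_label), []).append(obs.value)
        nhx_seen.update(count_nhx(m))
    bins = []
    for (family, label), vals in pooled.items():
        bins.extend(fit_feature_bins(vals, family, label, cfg.bandwidth(family), cfg))
    return FeatureDictionary(bins=bins, nhx_slots=sorted(nhx_seen), config=cfg)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _assign_bin(bins: list[FeatureBin], value: float) -> int:
    """Index of the bin whose (lower, upper] interval contains value.

    Bins are sorted by maximum; internal boundaries are shared, so a simple
    bisection over the upper bounds is exact (a value equal to a boundary
    belongs to the bin below it).
    """
    uppers = [b.upper for b in bins[:-1]]
    return bisect_left(uppers, value)


def encode_molecule(molecule: Molecule,
                    dictionary: FeatureDictionary) -> FeatureVector:
    """Encode one molecule against a fitted dictionary.

    Observations whose class is absent from the dictionary are dropped and
    tallied in ``dropped_classes`` (this is what happens when the model
    extrapolates to larger molecules with unseen classes); they are never
    fatal.
    """
    if not molecule.bonds:
        raise ValueError(f"{molecule.id}: molecule has no bonds; perceive bonds first")
    vec = np.zeros(dictionary.total_length)
    for k, el in enumerate(ALLOWED_ELEMENTS):
        vec[k] = ATOM_WEIGHT * sum(1 for a in molecule.atoms if a.element == el)
    dropped: dict[str, int] = {}
    for obs in molecule_observations(molecule, dictionary.config):
        bins = dictionary.class_bins(obs.family, obs.class_label)
        if not bins:
            key = f"{obs.family}:{obs.class_label}"
            dropped[key] = dropped.get(key, 0) + 1
            continue
        sl = dictionary.class_slice(obs.family, obs.class_label)
        vec[sl.start + _assign_bin(bins, obs.value)] += 1
    nhx = count_nhx(molecule)
    base = len(ALLOWED_ELEMENTS) + len(dictionary.bins)
    for k, x in enumerate(dictionary.nhx_slots):
        vec[base + k] = nhx.get(x, 0)
    return FeatureVector(molecule.id, vec, dropped)


def encode_matrix(molecules: list[Molecule],
                  dictionary: FeatureDictionary
                  ) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Encode many molecules into a dense matrix; returns (X, ids, dropped)."""
    vecs = [encode_molecule(m, dictionary) for m in molecules]
    dropped: dict[str, int] = {}
    for v in vecs:
        for k, c in v.dropped_classes.items():
            dropped[k] = dropped.get(k, 0) + c
    X = np.vstack([v.values for v in vecs]) if vecs else np.empty((0, dictionary.total_length))
    return X, [v.molecule_id for v in vecs], dropped
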