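"""Distorted-replicate data augmentation.

Training on geometries sampled around the potential-energy-surface minimum
(each atom translated by a fixed small amount along a random coordinate
axis, with the undistorted minimum's energies kept as targets) makes the
downstream models robust to force-field-quality input geometries. The
distortion constant quantifies how far the count representation moves under
a given displacement magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Molecule

__all__ = [
    "DistortionConfig",
    "make_distorted_replica",
    "augment_training_set",
    "distortion_constant",
]

#: Number of leading feature slots that hold the (distortion-invariant)
#: weighted atom counts.
N_ATOM_SLOTS = 4


@dataclass(frozen=True)
class DistortionConfig:
    deltas: tuple[float, ...] = (0.01,)  # displacement magnitudes, Angstrom
    seed: int = 0
    replicates_per_delta: int = 1

    def __post_init__(self):
        if any(d <= 0 for d in self.deltas):
            raise ValueError("all deltas must be positive")


def make_distorted_replica(molecule: Molecule, delta: float,
                           rng: np.random.Generator,
                           tag: str = "d") -> Molecule:
    """Copy a molecule with every atom displaced ``delta`` along one axis.

    Each atom independently picks one of the six axis directions
    (+-x, +-y, +-z) uniformly, so each replica atom lies exactly ``delta``
    Angstrom from its source. Bonds and target energies are copied
    unchanged (the targets remain those of the true minimum); the id gains
    a replica tag.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    n = molecule.n_atoms
    axes = rng.integers(0, 3, size=n)
    signs = rng.choice((-1.0, 1.0), size=n)
    disp = np.zeros((n, 3))
    disp[np.arange(n), axes] = signs * delta
    return molecule.with_coords(molecule.coords + disp,
                                new_id=f"{molecule.id}__{tag}{delta:g}")


def augment_training_set(molecules: list[Molecule],
                         config: DistortionConfig) -> list[Molecule]:
    """Originals plus all distorted replicas, deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    out = list(molecules)
    for delta in config.deltas:
        for r in range(config.replicates_per_delta):
            tag = "d" if config.replicates_per_delta == 1 else f"r{r}d"
            for m in molecules:
                out.append(make_distorted_replica(m, delta, rng, tag=tag))
    return out


def distortion_constant(original_vectors, distorted_vectors,
                        exclude_atom_slots: bool = True) -> float:
    """Mean over molecules of the L1 distance between original and
    distorted feature vectors.

    C = (1/N) sum_j sum_i |X_i^j - D_i^j|. The sum over features is not
    normalised by the vector length; the leading weighted atom-count slots
    are excluded by default since atom counts are invariant under
    distortion (including them changes nothing, as their difference is 0 —
    the flag exists for strict literalism).
    """
    X = np.asarray([np.asarray(getattr(v, "values", v), float) for v in original_vectors])
    D = np.asarray([np.asarray(getattr(v, "values", v), float) for v in distorted_vectors])
    if X.shape != D.shape:
        raise ValueError(f"mismatched shapes {X.shape} vs {D.shape}")
    if X.shape[0] == 0:
        raise ValueError("need at least one molecule")
    if exclude_atom_slots:
        X, D = X[:, N_ATOM_SLOTS:], D[:, N_ATOM_SLOTS:]
    return float(np.abs(X - D).sum(axis=1).mean())
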