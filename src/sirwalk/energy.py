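"""Lennard-Jones self-interaction of the walker with its visit history.

The pair potential is u(r) = eps * [(r0/r)^12 - 2 (r0/r)^6], with minimum -eps
at r = r0.  The walker's energy at a position is the plain sum of u over all
previously visited positions — no cutoff truncation, no neighbour lists (the
chains are at most a few dozen positions long).  Distances below a hard core
of 0.1 r0 map to +inf, which makes the corresponding Boltzmann weight exactly
zero instead of overflowing r^-12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PotentialParams",
    "lj_pair",
    "total_energy",
    "pairwise_energies",
    "interaction_energy",
    "HARD_CORE_FRACTION",
]

#: Fraction of r0 below which a pair is treated as a hard-core overlap.
HARD_CORE_FRACTION = 0.1


@dataclass(frozen=True)
class PotentialParams:
    """Lennard-Jones parameters: well depth ``epsilon`` (kB = 1 energy units)
    and equilibrium distance ``r0`` (units of the step distance d0)."""

    epsilon: float = 1.0
    r0: float = 1.0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if not self.r0 > 0:
            raise ValueError(f"r0 must be > 0, got {self.r0}")

    @property
    def hard_core(self) -> float:
        return HARD_CORE_FRACTION * self.r0


def lj_pair(r, params: PotentialParams):
    """Pair energy eps * [(r0/r)^12 - 2 (r0/r)^6]; scalar or array in, same out.

    Valid for r > 0; r <= 0 raises.  The minimum is exactly -eps at r = r0 and
    the zero crossing sits at 2^(-1/6) r0.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("pair distance must be positive")
    s6 = (params.r0 / r_arr) ** 6
    out = params.epsilon * (s6 * s6 - 2.0 * s6)
    return float(out) if np.isscalar(r) else out


def pairwise_energies(distances: np.ndarray, params: PotentialParams) -> np.ndarray:
    """LJ energy per distance, with +inf for hard-core overlaps (d < 0.1 r0)."""
    d = np.asarray(distances, dtype=float)
    core = d < params.hard_core
    safe = np.where(core, params.r0, d)  # avoid overflow before masking
    s6 = (params.r0 / safe) ** 6
    u = params.epsilon * (s6 * s6 - 2.0 * s6)
    return np.where(core, np.inf, u)


def total_energy(position, visited, params: PotentialParams) -> float:
    """Interaction energy of ``position`` with every point in ``visited``.

    Sum of the pair potential over all previous visits (the bonded neighbour
    included).  Returns +inf — never NaN — when any pair sits inside the hard
    core.
    """
    visited = np.atleast_2d(np.asarray(visited, dtype=float))
    if visited.size == 0:
        raise ValueError("visited must be non-empty")
    pos = np.asarray(position, dtype=float)
    d = np.linalg.norm(visited - pos, axis=1)
    return float(np.sum(pairwise_energies(d, params)))


def interaction_energy(positions, params: PotentialParams) -> float:
    """Total LJ energy over all unordered pairs of a finished configuration."""
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        return 0.0
    from scipy.spatial.distance import pdist

    return float(np.sum(pairwise_energies(pdist(pts), params)))
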