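"""The self-interacting walker.

One trajectory grows step by step from the origin.  At every step the walker
considers a fixed set of candidate directions (points on the sphere of radius
d0 around its current position) and picks one with probability proportional to
exp(-U/kBT), where U is the Lennard-Jones energy of the candidate against the
whole visit history.  The energy of the current position is the same for all
candidates, so weighting by U alone is identical to weighting by the energy
difference of the move; the weights are max-shifted before exponentiation for
numerical stability.

A Metropolis variant (uniform proposal, accept with min(1, exp(-dU/kBT))) is
available through ``rule="metropolis"`` to probe sensitivity to the selection
rule; the categorical rule is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .energy import PotentialParams, pairwise_energies
from .geometry import DirectionSet, generate_direction_set

__all__ = ["WalkParams", "Trajectory", "TrappedWalkerError", "step_weights", "simulate"]


class TrappedWalkerError(RuntimeError):
    """Every candidate move is forbidden (infinite energy)."""

    def __init__(self, step_index: int):
        self.step_index = step_index
        super().__init__(f"walker trapped at step {step_index}: all candidate moves have infinite energy")


@dataclass(frozen=True)
class WalkParams:
    """Full parameter set of one simulation.

    temperature : kB T in energy units (kB = 1).
    potential   : LJ well depth epsilon and equilibrium distance r0.
    d0          : step distance; the unit of length (default 1).
    n_steps     : number of moves; the trajectory has n_steps + 1 positions.
    n_directions: size of the candidate direction set.
    method      : sphere-sampling construction ("fibonacci" or "geodesic").
    rule        : "categorical" (default) or "metropolis" selection.
    rotate_directions : apply a fresh random rotation to the direction set at
                  every step (sensitivity probe for the angular
                  discretization; default off).
    seed        : RNG seed; identical seeds give bit-identical trajectories.
    """

    temperature: float = 1.0
    potential: PotentialParams = field(default_factory=PotentialParams)
    d0: float = 1.0
    n_steps: int = 50
    n_directions: int = 15_212
    method: str = "fibonacci"
    rule: str = "categorical"
    rotate_directions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not self.d0 > 0:
            raise ValueError(f"d0 must be > 0, got {self.d0}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.rule not in ("categorical", "metropolis"):
            raise ValueError(f"unknown rule {self.rule!r}")

    def with_seed(self, seed: int) -> "WalkParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Trajectory:
    """An ordered list of visited positions plus the parameters that made it.

    ``positions`` is an (n_steps + 1, 3) array starting at the origin with
    every consecutive distance equal to d0.  ``per_step_energy[n]`` is the
    walker's interaction energy with positions 0..n-1 on arriving at position
    n (entry 0 is 0 by convention: the origin has no history).
    """

    positions: np.ndarray
    params: WalkParams
    per_step_energy: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


def _candidate_energies(visited: np.ndarray, candidates: np.ndarray,
                        potential: PotentialParams) -> np.ndarray:
    # Squared distances throughout: (r0/r)^6 = (r0^2/r^2)^3, no sqrt needed.
    # In-place arithmetic keeps the per-step temporaries to a minimum.
    d2 = cdist(candidates, visited, metric="sqeuclidean")
    core = d2 < potential.hard_core**2
    has_core = core.any()
    if has_core:
        np.copyto(d2, potential.r0**2, where=core)  # placeholder, masked below
    s2 = np.divide(potential.r0**2, d2, out=d2)     # (r0/r)^2, reusing d2
    s4 = np.multiply(s2, s2)
    s6 = np.multiply(s4, s2, out=s4)                # (r0/r)^6
    shifted = np.subtract(s6, 2.0, out=s2)          # (r0/r)^6 - 2
    u = np.multiply(s6, shifted, out=s6)            # (r0/r)^12 - 2 (r0/r)^6
    np.multiply(u, potential.epsilon, out=u)
    if has_core:
        np.copyto(u, np.inf, where=core)
    return np.sum(u, axis=1)


def step_weights(current, visited, candidates: DirectionSet, params: WalkParams) -> np.ndarray:
    """Normalized selection probabilities over the candidate directions.

    p_j is proportional to exp(-U_j / kB T) with U_j the LJ energy of
    candidate j against ``visited``; the constant energy of the current
    position cancels on normalization.  Adding any constant to all candidate
    energies leaves the result unchanged (max-shift before exponentiation).
    """
    current = np.asarray(current, dtype=float)
    visited = np.atleast_2d(np.asarray(visited, dtype=float))
    cand_pos = current + params.d0 * candidates.directions
    energies = _candidate_energies(visited, cand_pos, params.potential)
    return boltzmann_probabilities(energies, params.temperature)


def boltzmann_probabilities(energies: np.ndarray, temperature: float) -> np.ndarray:
    """exp(-U/kBT), max-shifted and normalized; +inf energies get weight 0."""
    e = np.asarray(energies, dtype=float)
    finite = np.isfinite(e)
    if not finite.any():
        raise TrappedWalkerError(-1)
    shift = e[finite].min()
    with np.errstate(over="ignore"):
        w = np.where(finite, np.exp(-(e - shift) / temperature), 0.0)
    return w / w.sum()


def simulate(params: WalkParams, directions: DirectionSet | None = None) -> Trajectory:
    """Grow one trajectory of ``params.n_steps`` moves from the origin.

    The first move is selected by the same rule as every other: with only the
    origin visited, all candidates share the same single-pair energy and the
    choice is uniform.  A precomputed ``directions`` set may be passed to
    avoid rebuilding it across runs; it must match params.n_directions/method.
    """
    if directions is None:
        directions = generate_direction_set(params.n_directions, params.method)
    dirs = directions.directions
    rng = np.random.default_rng(params.seed)

    n = params.n_steps
    positions = np.zeros((n + 1, 3))
    per_step_energy = np.zeros(n + 1)

    for step in range(n):
        current = positions[step]
        visited = positions[: step + 1]
        step_dirs = dirs @ _random_rotation(rng).T if params.rotate_directions else dirs
        cand = current + params.d0 * step_dirs
        energies = _candidate_energies(visited, cand, params.potential)
        if not np.isfinite(energies).any():
            raise TrappedWalkerError(step)
        if params.rule == "categorical":
            finite = np.isfinite(energies)
            shift = energies[finite].min()
            with np.errstate(over="ignore"):
                w = np.exp(-(energies - shift) / params.temperature)
            w[~finite] = 0.0
            cum = np.cumsum(w)
            choice = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            choice = min(choice, len(dirs) - 1)
        else:
            if step == 0:
                current_energy = 0.0
            else:
                d_cur = np.linalg.norm(positions[:step] - current, axis=1)
                current_energy = float(np.sum(pairwise_energies(d_cur, params.potential)))
            choice = _metropolis_choice(energies, current_energy, params.temperature, rng, step)
        positions[step + 1] = cand[choice]
        per_step_energy[step + 1] = energies[choice]

    return Trajectory(positions=positions, params=params, per_step_energy=per_step_energy)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _metropolis_choice(energies: np.ndarray, current_energy: float,
                       temperature: float, rng: np.random.Generator, step: int) -> int:
    # Uniform proposal, accepted with min(1, exp(-dU/kBT)) against the
    # walker's energy at its current position, re-proposing until acceptance.
    # Proposing-until-acceptance is rejection sampling: the selected move is
    # distributed over candidates with weights min(1, exp(-dU/kBT)), which is
    # what is drawn here directly.  If every weight underflows (deep in a well
    # at very low T) the minimum-energy candidate — the T -> 0 limit of the
    # rule — is taken.
    with np.errstate(over="ignore", invalid="ignore"):
        w = np.exp(np.minimum(0.0, -(energies - current_energy) / temperature))
    w[~np.isfinite(energies)] = 0.0
    total = w.sum()
    if total <= 0.0 or not np.isfinite(total):
        finite = np.where(np.isfinite(energies), energies, np.inf)
        return int(np.argmin(finite))
    return int(rng.choice(len(energies), p=w / total))
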