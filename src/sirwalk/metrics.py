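"""Order parameters of a trajectory.

Compactness is measured by the radius of gyration; helical order by a sliding
window over the chain connections.  A window of K + 1 consecutive connections
(K + 2 positions) qualifies as one helical turn when every local turn inside
it has the same handedness and the K turning angles sum to more than 2*pi;
K = 10 by default, deliberately longer than the 4–5 steps an observed helical
turn actually takes, so that a window tolerates small fluctuations.  A
position is helical when it belongs to at least one qualifying window, and the
helix fraction H is the fraction of helical positions — 0 for a coil or a
straight line, 1 for a perfect helix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import PotentialParams, interaction_energy
from .geometry import _COPLANAR_TOL
from .walker import Trajectory

__all__ = [
    "HelixAnnotation",
    "radius_of_gyration",
    "squared_radius_of_gyration",
    "helix_fraction",
    "end_to_end_distance",
    "mean_energy",
]

DEFAULT_WINDOW = 10


@dataclass(frozen=True)
class HelixAnnotation:
    """Per-position helix assignment of one trajectory.

    is_helical     : boolean flag per visited position.
    n_h            : number of helical positions.
    H              : helix fraction n_h / (number of positions).
    steps_per_turn : azimuthal turn period (connections per full 2*pi
                     rotation about the local helix axis), averaged over
                     qualifying windows; NaN when no window qualifies.
    handedness     : "right", "left", "mixed" or "none".
    """

    is_helical: np.ndarray
    n_h: int
    H: float
    steps_per_turn: float
    handedness: str


def squared_radius_of_gyration(positions) -> float:
    """Mean squared distance of the positions from their centroid."""
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    if pts.size == 0:
        raise ValueError("positions must be non-empty")
    centered = pts - pts.mean(axis=0)
    return float(np.mean(np.sum(centered**2, axis=1)))


def radius_of_gyration(positions) -> float:
    """Root-mean-square distance of the positions from their centroid."""
    return float(np.sqrt(squared_radius_of_gyration(positions)))


def end_to_end_distance(positions) -> float:
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    return float(np.linalg.norm(pts[-1] - pts[0]))


def _turn_angles_and_signs(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Turning angle at every interior position and handedness of every
    connection triple, vectorized over the whole chain."""
    conns = np.diff(pts, axis=0)
    norms = np.linalg.norm(conns, axis=1)
    # angles[j]: angle between connection j and j+1  (len = n_conns - 1)
    dots = np.sum(conns[:-1] * conns[1:], axis=1)
    denom = norms[:-1] * norms[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), np.nan)
    angles = np.arccos(np.clip(cosang, -1.0, 1.0))
    # signs[j]: handedness of connections (j, j+1, j+2)  (len = n_conns - 2)
    triple = np.sum(np.cross(conns[:-2], conns[1:-1]) * conns[2:], axis=1)
    scale = norms[:-2] * norms[1:-1] * norms[2:]
    signs = np.sign(triple)
    signs[np.abs(triple) <= _COPLANAR_TOL * scale] = 0
    return angles, signs.astype(int)


def _window_turn_period(conns: np.ndarray, sign: int) -> float:
    """Azimuthal steps per turn of one helical window.

    The helix axis is estimated as the (handedness-aligned) mean of the
    normalized cross products of consecutive connections; the period is
    2*pi over the mean rotation of the connections projected onto the plane
    perpendicular to that axis.  Exact for ideal helices at any rise.
    """
    cross = np.cross(conns[:-1], conns[1:]) * sign
    norms = np.linalg.norm(cross, axis=1)
    axis = np.sum(cross / norms[:, None], axis=0)
    axis /= np.linalg.norm(axis)
    proj = conns - np.outer(conns @ axis, axis)
    proj /= np.linalg.norm(proj, axis=1, keepdims=True)
    dphi = np.arccos(np.clip(np.sum(proj[:-1] * proj[1:], axis=1), -1.0, 1.0))
    return float(2.0 * np.pi / dphi.mean())


def helix_fraction(positions, K: int = DEFAULT_WINDOW) -> HelixAnnotation:
    """Detect helical segments with the K-connection sliding-window rule.

    A window covers positions i .. i+K+1 (K+1 connections).  It qualifies
    when (a) every handedness sign inside it is the same and nonzero and
    (b) its K turning angles sum to more than 2*pi.  Windows containing a
    degenerate (zero-length or coplanar) turn are disqualified, not errors.
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    m = len(pts)
    is_hel = np.zeros(m, dtype=bool)
    if m < K + 2:
        return HelixAnnotation(is_hel, 0, 0.0, float("nan"), "none")

    conns = np.diff(pts, axis=0)
    angles, signs = _turn_angles_and_signs(pts)
    window_spts: list[float] = []
    window_signs: list[int] = []
    n_windows = m - (K + 1)
    for i in range(n_windows):
        a = angles[i : i + K]          # K turning angles
        s = signs[i : i + K - 1]       # K-1 handedness signs
        if np.any(np.isnan(a)):
            continue
        if s[0] == 0 or np.any(s != s[0]):
            continue
        total = float(a.sum())
        if total > 2.0 * np.pi:
            is_hel[i : i + K + 2] = True
            window_spts.append(_window_turn_period(conns[i : i + K + 1], int(s[0])))
            window_signs.append(int(s[0]))

    n_h = int(is_hel.sum())
    H = n_h / m
    if not window_spts:
        return HelixAnnotation(is_hel, n_h, H, float("nan"), "none")
    spt = float(np.mean(window_spts))
    uniq = set(window_signs)
    handed = "right" if uniq == {1} else "left" if uniq == {-1} else "mixed"
    return HelixAnnotation(is_hel, n_h, H, spt, handed)


def mean_energy(trajectory: Trajectory, per_position: bool = True) -> float:
    """Interaction energy of the finished configuration.

    Sum of the LJ pair potential over all unordered pairs of visited
    positions; divided by the number of positions when ``per_position`` is
    true (the default), which is the natural intensive measure for comparing
    phases.
    """
    total = interaction_energy(trajectory.positions, trajectory.params.potential)
    if per_position:
        return total / len(trajectory.positions)
    return total
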