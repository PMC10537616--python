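"""Sphere sampling and the angular/chirality primitives of the walk.

The walker moves by picking one of a large, fixed set of near-uniform unit
vectors; the helix detector needs the turning angle between consecutive chain
connections and the handedness (left/right) of each local turn.  Both live
here so the walker and the metrics share one definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DirectionSet",
    "generate_direction_set",
    "geodesic_counts",
    "bond_angle",
    "turn_sign",
]

#: |triple product| below this (relative to the product of connection norms)
#: counts as coplanar.
_COPLANAR_TOL = 1e-9


@dataclass(frozen=True)
class DirectionSet:
    """An ordered set of unit vectors distributed near-uniformly on the sphere.

    Attributes
    ----------
    directions : (count, 3) float array of unit vectors.
    count : number of vectors.
    method : construction used ("fibonacci" or "geodesic").
    """

    directions: np.ndarray
    method: str = "fibonacci"
    count: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.directions, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        object.__setattr__(self, "directions", arr)
        object.__setattr__(self, "count", arr.shape[0])

    def __len__(self) -> int:
        return self.count


def _fibonacci_sphere(count: int) -> np.ndarray:
    # Golden-spiral lattice: z descends in equal-area bands, azimuth advances
    # by the golden angle.  Deterministic and valid for any count.
    i = np.arange(count, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / count
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden_angle = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden_angle * i
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def geodesic_counts(around: int, n: int = 2) -> list[int]:
    """The ``n`` icosahedral-geodesic vertex counts (10 f^2 + 2) nearest ``around``."""
    f0 = max(1, round(np.sqrt(max(around - 2, 8) / 10.0)))
    cand = sorted({10 * f * f + 2 for f in range(max(1, f0 - 3), f0 + 4)},
                  key=lambda c: (abs(c - around), c))
    return sorted(cand[:n])


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    return verts, faces


def _geodesic_sphere(frequency: int) -> np.ndarray:
    # Subdivide each icosahedron face into f^2 triangles on the barycentric
    # grid, project every grid point to the unit sphere, and deduplicate the
    # shared edge/corner points.
    verts, faces = _icosahedron()
    f = frequency
    pts = []
    for (a, b, c) in faces:
        va, vb, vc = verts[a], verts[b], verts[c]
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                p = (i * va + j * vb + k * vc) / f
                pts.append(p / np.linalg.norm(p))
    pts = np.asarray(pts)
    # Deduplicate via rounding; grid points from adjacent faces coincide
    # exactly up to fp noise, far below the 1e-9 bucket.
    key = np.round(pts, 9)
    _, idx = np.unique(key, axis=0, return_index=True)
    out = pts[np.sort(idx)]
    # Lexicographic order makes the construction order-independent.
    order = np.lexsort((out[:, 2], out[:, 1], out[:, 0]))
    return out[order]


def generate_direction_set(count: int, method: str = "fibonacci") -> DirectionSet:
    """Build ``count`` near-uniform unit vectors on the sphere.

    Parameters
    ----------
    count : number of directions, at least 4.
    method : "fibonacci" (golden-spiral lattice, any count) or "geodesic"
        (icosahedral geodesic vertices; count must equal 10 f^2 + 2 for an
        integer frequency f — e.g. 15212 = 10*39^2 + 2).

    The construction is deterministic: identical arguments give identical
    vectors in identical order.
    """
    if count < 4:
        raise ValueError(f"count must be >= 4, got {count}")
    if method == "fibonacci":
        dirs = _fibonacci_sphere(count)
    elif method == "geodesic":
        f_sq = (count - 2) / 10.0
        f = int(round(np.sqrt(f_sq))) if f_sq > 0 else 0
        if f < 1 or 10 * f * f + 2 != count:
            near = geodesic_counts(count)
            raise ValueError(
                f"geodesic direction sets require count = 10 f^2 + 2; "
                f"{count} is not of that form (nearest valid counts: {near})"
            )
        dirs = _geodesic_sphere(f)
    else:
        raise ValueError(f"unknown method {method!r}; use 'fibonacci' or 'geodesic'")
    return DirectionSet(directions=dirs, method=method)


def _connections(*points: np.ndarray) -> list[np.ndarray]:
    pts = [np.asarray(p, dtype=float) for p in points]
    conns = [q - p for p, q in zip(pts, pts[1:])]
    for v in conns:
        if not np.linalg.norm(v) > 0.0:
            raise ValueError("degenerate geometry: zero-length connection")
    return conns


def bond_angle(a, b, c) -> float:
    """Turning angle at ``b``: the angle in [0, pi] between (b-a) and (c-b).

    Zero for three collinear points walked in one direction, pi for an exact
    reversal.  Raises ``ValueError`` on zero-length connections.
    """
    u, v = _connections(a, b, c)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def turn_sign(a, b, c, d) -> int:
    """Handedness of the local turn through four consecutive points.

    Sign of the scalar triple product (b-a) x (c-b) . (d-c): +1 for a
    right-handed turn, -1 for left-handed, 0 when the three connections are
    coplanar (within a scale-relative tolerance of 1e-9).  Invariant under
    rigid motions, odd under reflection.
    """
    u, v, w = _connections(a, b, c, d)
    triple = float(np.dot(np.cross(u, v), w))
    scale = np.linalg.norm(u) * np.linalg.norm(v) * np.linalg.norm(w)
    if abs(triple) <= _COPLANAR_TOL * scale:
        return 0
    return 1 if triple > 0 else -1
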