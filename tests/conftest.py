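import numpy as np
import pytest

from sirwalk.energy import PotentialParams
from sirwalk.walker import WalkParams


def make_helix(n_points: int, steps_per_turn: float, rise: float = 0.3,
               handedness: int = 1) -> np.ndarray:
    """Ideal helix with a given azimuthal period, rescaled to unit bond length."""
    i = np.arange(n_points, dtype=float)
    phi = handedness * 2.0 * np.pi * i / steps_per_turn
    pts = np.column_stack([np.cos(phi), np.sin(phi), rise * i])
    bond = np.linalg.norm(pts[1] - pts[0])
    return pts / bond


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20230907)


@pytest.fixture
def fast_params():
    """Small but physical parameter set for quick simulations."""
    return WalkParams(
        temperature=1.0,
        potential=PotentialParams(1.0, 1.0),
        n_steps=20,
        n_directions=300,
        seed=42,
    )
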