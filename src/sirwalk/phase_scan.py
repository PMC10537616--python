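"""Parameter sweeps and phase-transition analysis.

A temperature sweep at fixed (r0, epsilon) produces one ensemble summary per
grid point; a transition temperature is read off either as the point of
steepest change of the mean radius of gyration on the log-T axis (refined by
local quadratic interpolation) or as the interpolated crossing of the mean
helix fraction through 0.5.  Transition temperatures collected over a grid of
well depths are fitted through the origin, kB Tc = lambda * epsilon, one
lambda per transition line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .energy import PotentialParams
from .ensemble import EnsembleSummary, run_ensemble
from .geometry import generate_direction_set
from .walker import WalkParams

__all__ = [
    "SweepResult",
    "LambdaFit",
    "sweep_temperature",
    "sweep_r0",
    "estimate_transition_temperature",
    "estimate_both_transitions",
    "fit_lambda",
    "phase_diagram",
    "label_phases",
]

#: Relative spread of the observable below which a sweep counts as flat
#: (no transition).
_FLAT_REL_TOL = 0.02


@dataclass
class SweepResult:
    """Ensemble summaries along one parameter axis.

    ``axis`` names the swept parameter ("T", "r0" or "epsilon"); ``grid`` is
    strictly increasing with one summary per grid point.  ``transitions``
    holds (kind, Tc) pairs filled in by the transition estimators.
    """

    axis: str
    grid: np.ndarray
    summaries: list[EnsembleSummary]
    base: WalkParams
    n_runs: int
    base_seed: int
    transitions: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("sweep grid must be strictly increasing")
        if len(self.grid) != len(self.summaries):
            raise ValueError("one summary per grid point required")

    def observable(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.summaries])

    def to_frame(self) -> pd.DataFrame:
        rows = [s.to_dict() for s in self.summaries]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LambdaFit:
    """Through-origin fit kB Tc = lambda * epsilon for one transition line."""

    lam: float
    transition_kind: str
    epsilon_grid: np.ndarray
    Tc_values: np.ndarray
    residual: float


def _run_grid(base: WalkParams, axis: str, grid, n_runs: int, base_seed: int,
              K: int) -> SweepResult:
    grid = np.asarray(grid, dtype=float)
    directions = generate_direction_set(base.n_directions, base.method)
    summaries = []
    for i, value in enumerate(grid):
        if axis == "T":
            p = replace(base, temperature=float(value))
        elif axis == "r0":
            p = replace(base, potential=PotentialParams(base.potential.epsilon, float(value)))
        elif axis == "epsilon":
            p = replace(base, potential=PotentialParams(float(value), base.potential.r0))
        else:
            raise ValueError(f"unknown sweep axis {axis!r}")
        summaries.append(
            run_ensemble(p, n_runs=n_runs, base_seed=base_seed + i * n_runs,
                         K=K, directions=directions)
        )
    return SweepResult(axis=axis, grid=grid, summaries=summaries, base=base,
                       n_runs=n_runs, base_seed=base_seed)


def sweep_temperature(base: WalkParams, T_grid, n_runs: int = 100,
                      base_seed: int = 0, K: int = 10) -> SweepResult:
    """One ensemble per temperature on a (preferably log-spaced) grid."""
    return _run_grid(base, "T", T_grid, n_runs, base_seed, K)


def sweep_r0(base: WalkParams, r0_grid, n_runs: int = 100,
             base_seed: int = 0, K: int = 10) -> SweepResult:
    """One ensemble per LJ equilibrium distance at fixed temperature."""
    return _run_grid(base, "r0", r0_grid, n_runs, base_seed, K)


def _steepest_log_slope(T: np.ndarray, y: np.ndarray,
                        direction: str | None) -> float | None:
    x = np.log(T)
    slopes = np.diff(y) / np.diff(x)
    mids = 0.5 * (x[:-1] + x[1:])
    if direction == "increasing":
        score = slopes
    elif direction == "decreasing":
        score = -slopes
    else:
        score = np.abs(slopes)
    k = int(np.argmax(score))
    # a directional transition must carry a substantial share of the curve's
    # total variation, not just a noise wiggle against the dominant trend
    if score[k] <= 0.1 * np.abs(slopes).max():
        return None
    # quadratic refinement through the three neighbouring slope magnitudes
    if 0 < k < len(score) - 1:
        s0, s1, s2 = score[k - 1], score[k], score[k + 1]
        denom = s0 - 2 * s1 + s2
        if denom < 0:
            shift = 0.5 * (s0 - s2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            dx = 0.5 * (mids[min(k + 1, len(mids) - 1)] - mids[max(k - 1, 0)])
            return float(np.exp(mids[k] + shift * dx))
    return float(np.exp(mids[k]))


def estimate_transition_temperature(
    sweep: SweepResult,
    observable: str = "Rg",
    T_min: float | None = None,
    T_max: float | None = None,
    direction: str | None = None,
) -> float | None:
    """Locate a transition temperature on a temperature sweep.

    observable "Rg": temperature of steepest change of the mean radius of
    gyration against log T, refined by a local quadratic through the
    neighbouring slopes; ``direction`` may restrict the search to slopes
    where Rg increases ("increasing") or decreases ("decreasing") with T.
    observable "H": linearly interpolated (in log T) crossing of the mean
    helix fraction through 0.5.

    Returns None — the no-transition sentinel — for a flat curve or when the
    helix fraction never straddles 0.5.  ``T_min``/``T_max`` clip the grid
    before estimation (branch selection on reentrant curves).
    """
    if sweep.axis != "T":
        raise ValueError("transition estimation requires a temperature sweep")
    T = sweep.grid
    mask = np.ones_like(T, dtype=bool)
    if T_min is not None:
        mask &= T >= T_min
    if T_max is not None:
        mask &= T <= T_max
    T = T[mask]
    if len(T) < 3:
        raise ValueError("fewer than 3 grid points in the selected range")

    if observable == "Rg":
        y = sweep.observable("mean_Rg")[mask]
        if np.ptp(y) <= _FLAT_REL_TOL * max(1.0, float(np.abs(y).max())):
            return None
        return _steepest_log_slope(T, y, direction)
    if observable == "H":
        h = sweep.observable("mean_H")[mask]
        x = np.log(T)
        # lowest-T crossing of 0.5 (helix melts as T rises)
        for j in range(len(h) - 1):
            lo, hi = h[j], h[j + 1]
            if (lo - 0.5) * (hi - 0.5) <= 0 and lo != hi:
                t = (0.5 - lo) / (hi - lo)
                return float(np.exp(x[j] + t * (x[j + 1] - x[j])))
        return None
    raise ValueError(f"unknown observable {observable!r}")


def estimate_both_transitions(sweep: SweepResult) -> dict[str, float | None]:
    """Coil–globule and globule–helix transition temperatures of one sweep.

    The globule–helix temperature is the mean-H = 0.5 crossing.  The
    coil–globule temperature is the steepest increase of mean Rg with log T,
    searched above the helix boundary so the low-T helix jump (where Rg
    *decreases* with T) cannot masquerade as the collapse.
    """
    tc_gh = estimate_transition_temperature(sweep, "H")
    T_min = 4.0 * tc_gh if tc_gh is not None else None
    tc_cg = estimate_transition_temperature(sweep, "Rg", T_min=T_min,
                                            direction="increasing")
    sweep.transitions = []
    if tc_cg is not None:
        sweep.transitions.append(("coil_globule", tc_cg))
    if tc_gh is not None:
        sweep.transitions.append(("globule_helix", tc_gh))
    if tc_cg is None and tc_gh is None:
        # large-r0 regime: extended strings unwind into coils, Rg falling with T
        tc_sc = estimate_transition_temperature(sweep, "Rg", direction="decreasing")
        if tc_sc is not None:
            sweep.transitions.append(("string_coil", tc_sc))
            return {"coil_globule": None, "globule_helix": None, "string_coil": tc_sc}
    return {"coil_globule": tc_cg, "globule_helix": tc_gh}


def fit_lambda(epsilon_grid, Tc_values, transition_kind: str = "") -> LambdaFit:
    """Least-squares slope of Tc against epsilon through the origin.

    lambda = sum(eps * Tc) / sum(eps^2); the residual is the RMS misfit.
    Requires at least 3 (epsilon, Tc) pairs.
    """
    eps = np.asarray(epsilon_grid, dtype=float)
    tc = np.asarray(Tc_values, dtype=float)
    if len(eps) != len(tc) or len(eps) < 3:
        raise ValueError("fit_lambda needs at least 3 (epsilon, Tc) pairs")
    lam = float(np.sum(eps * tc) / np.sum(eps**2))
    residual = float(np.sqrt(np.mean((tc - lam * eps) ** 2)))
    return LambdaFit(lam=lam, transition_kind=transition_kind,
                     epsilon_grid=eps, Tc_values=tc, residual=residual)


def label_phases(frame: pd.DataFrame) -> pd.DataFrame:
    """Assign helix / globule / coil labels to a (T, epsilon) table.

    Helix takes precedence: mean_H >= 0.5.  Among the remaining cells of each
    epsilon, a cell is globule when its mean Rg lies below the midpoint of the
    globule and coil plateaus (the min and max non-helix Rg at that epsilon),
    else coil.
    """
    frame = frame.copy()
    frame["phase"] = "coil"
    for _, idx in frame.groupby("epsilon").groups.items():
        sub = frame.loc[idx]
        helix = sub["mean_H"] >= 0.5
        rest = sub.loc[~helix, "mean_Rg"]
        if len(rest) > 0:
            mid = 0.5 * (rest.min() + rest.max())
            frame.loc[rest.index, "phase"] = np.where(rest < mid, "globule", "coil")
        frame.loc[sub.index[helix], "phase"] = "helix"
    return frame


def phase_diagram(
    T_grid,
    epsilon_grid,
    base: WalkParams,
    n_runs: int = 100,
    base_seed: int = 0,
    K: int = 10,
) -> tuple[pd.DataFrame, dict[str, LambdaFit]]:
    """Map the (T, epsilon) plane at fixed r0 and fit both transition lines.

    Returns a tidy table (one row per grid cell, with phase labels) and the
    through-origin lambda fits of the coil–globule and globule–helix lines
    (a line is fitted only where at least 3 epsilon values yielded a Tc).
    """
    eps_grid = np.asarray(epsilon_grid, dtype=float)
    frames = []
    tcs: dict[str, list[tuple[float, float]]] = {"coil_globule": [], "globule_helix": []}
    for j, eps in enumerate(eps_grid):
        b = replace(base, potential=PotentialParams(float(eps), base.potential.r0))
        sweep = sweep_temperature(b, T_grid, n_runs=n_runs,
                                  base_seed=base_seed + j * 1_000_000, K=K)
        both = estimate_both_transitions(sweep)
        for kind, tc in both.items():
            if tc is not None:
                tcs[kind].append((float(eps), tc))
        frames.append(sweep.to_frame())
    table = label_phases(pd.concat(frames, ignore_index=True))
    fits: dict[str, LambdaFit] = {}
    for kind, pairs in tcs.items():
        if len(pairs) >= 3:
            e, t = zip(*pairs)
            fits[kind] = fit_lambda(e, t, transition_kind=kind)
    return table, fits
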