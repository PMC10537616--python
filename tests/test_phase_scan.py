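import numpy as np
import pandas as pd
import pytest

from sirwalk.energy import PotentialParams
from sirwalk.ensemble import EnsembleSummary
from sirwalk.phase_scan import (
    SweepResult,
    estimate_transition_temperature,
    fit_lambda,
    label_phases,
    sweep_temperature,
)
from sirwalk.walker import WalkParams


def _fake_sweep(T_grid, Rg=None, H=None):
    """Wrap synthetic curves in a SweepResult without running simulations."""
    base = WalkParams()
    summaries = []
    for i, T in enumerate(T_grid):
        rg = 1.0 if Rg is None else float(Rg[i])
        h = 0.0 if H is None else float(H[i])
        summaries.append(
            EnsembleSummary(
                params=base, n_runs=1, base_seed=0,
                mean_Rg=rg, sem_Rg=0.0, mean_Rg2=rg**2, sem_Rg2=0.0,
                mean_H=h, sem_H=0.0,
                mean_energy_per_position=0.0, mean_energy_total=0.0,
                mean_steps_per_turn=float("nan"), mean_Ree2=0.0,
                n_trapped=0, representative_trajectory=None,
            )
        )
    return SweepResult(axis="T", grid=np.asarray(T_grid), summaries=summaries,
                       base=base, n_runs=1, base_seed=0)


def _logistic_rg(T_grid, midpoint, lo=2.0, hi=4.0, width=0.25):
    x = np.log(np.asarray(T_grid) / midpoint) / width
    return lo + (hi - lo) / (1.0 + np.exp(-x))


class TestTransitionEstimator:
    def test_logistic_midpoint_recovered(self):
        T = np.geomspace(0.01, 100, 25)
        sweep = _fake_sweep(T, Rg=_logistic_rg(T, midpoint=2.0))
        tc = estimate_transition_temperature(sweep, "Rg")
        spacing = T[1] / T[0]
        assert tc is not None
        assert tc / 2.0 < spacing and 2.0 / tc < spacing

    def test_flat_curve_gives_sentinel(self):
        T = np.geomspace(0.01, 100, 15)
        sweep = _fake_sweep(T, Rg=np.full_like(T, 3.0))
        assert estimate_transition_temperature(sweep, "Rg") is None

    def test_agrees_with_brute_force_on_finer_grid(self):
        # oracle: argmax |dRg/dlnT| evaluated on a 10x finer synthetic grid
        T_coarse = np.geomspace(0.01, 100, 17)
        T_fine = np.geomspace(0.01, 100, 170)
        mid = 1.37
        tc = estimate_transition_temperature(
            _fake_sweep(T_coarse, Rg=_logistic_rg(T_coarse, mid)), "Rg")
        fine_rg = _logistic_rg(T_fine, mid)
        slopes = np.abs(np.diff(fine_rg) / np.diff(np.log(T_fine)))
        tc_fine = np.sqrt(T_fine[:-1] * T_fine[1:])[np.argmax(slopes)]
        coarse_spacing = T_coarse[1] / T_coarse[0]
        assert max(tc, tc_fine) / min(tc, tc_fine) < coarse_spacing

    def test_H_crossing_interpolated(self):
        T = np.geomspace(0.001, 10, 20)
        h = 1.0 / (1.0 + (T / 0.05) ** 2)  # smooth melt around T = 0.05
        sweep = _fake_sweep(T, H=h)
        tc = estimate_transition_temperature(sweep, "H")
        assert tc == pytest.approx(0.05, rel=0.25)

    def test_H_never_crossing_gives_sentinel(self):
        T = np.geomspace(0.001, 10, 10)
        sweep = _fake_sweep(T, H=np.full_like(T, 0.2))
        assert estimate_transition_temperature(sweep, "H") is None

    def test_direction_restriction(self):
        # V-shaped curve: decreasing then increasing with T
        T = np.geomspace(0.001, 100, 31)
        rg = _logistic_rg(T, 1.0, lo=2.0, hi=4.0) + _logistic_rg(
            T, 0.01, lo=3.0, hi=0.0)
        sweep = _fake_sweep(T, Rg=rg)
        up = estimate_transition_temperature(sweep, "Rg", direction="increasing")
        down = estimate_transition_temperature(sweep, "Rg", direction="decreasing")
        assert down < 0.1 < up

    def test_string_coil_detected_when_no_collapse(self):
        # monotone decreasing Rg with no helix: the string-coil crossover
        from sirwalk.phase_scan import estimate_both_transitions

        T = np.geomspace(0.001, 100, 21)
        rg = _logistic_rg(T, 2.0, lo=14.0, hi=6.0)  # falls with T
        sweep = _fake_sweep(T, Rg=rg)
        both = estimate_both_transitions(sweep)
        assert both["coil_globule"] is None and both["globule_helix"] is None
        kinds = dict(sweep.transitions)
        assert "string_coil" in kinds
        assert kinds["string_coil"] == pytest.approx(2.0, rel=0.5)

    def test_requires_temperature_axis(self):
        sweep = _fake_sweep(np.geomspace(0.01, 1, 5))
        sweep.axis = "r0"
        with pytest.raises(ValueError):
            estimate_transition_temperature(sweep, "Rg")


class TestFitLambda:
    def test_exact_proportionality(self):
        eps = np.array([0.5, 1.0, 2.0, 5.0])
        fit = fit_lambda(eps, 1.25 * eps)
        assert fit.lam == pytest.approx(1.25, rel=1e-14)
        assert fit.residual == pytest.approx(0.0, abs=1e-14)
        fit2 = fit_lambda(eps, 0.05 * eps)
        assert fit2.lam == pytest.approx(0.05, rel=1e-14)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(77)
        eps = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 5.0])
        lam = 0.8
        tc = lam * eps * (1.0 + 0.05 * rng.normal(size=eps.size))
        fit = fit_lambda(eps, tc)
        assert fit.lam == pytest.approx(lam, rel=0.10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_lambda([1.0, 2.0], [1.0, 2.0])


class TestLabelPhases:
    def test_three_phase_labels(self):
        frame = pd.DataFrame({
            "epsilon": [1.0] * 4,
            "temperature": [0.01, 0.1, 1.0, 10.0],
            "mean_H": [0.9, 0.1, 0.0, 0.0],
            "mean_Rg": [5.0, 2.0, 2.2, 4.5],
        })
        labeled = label_phases(frame)
        assert list(labeled["phase"]) == ["helix", "globule", "globule", "coil"]


class TestSweepMachinery:
    def test_sweep_runs_and_is_tidy(self):
        base = WalkParams(potential=PotentialParams(1.0, 1.0),
                          n_steps=10, n_directions=100)
        T = np.geomspace(0.1, 10, 4)
        sweep = sweep_temperature(base, T, n_runs=3, base_seed=0)
        frame = sweep.to_frame()
        assert len(frame) == 4
        assert {"temperature", "mean_Rg", "mean_H", "sem_Rg"} <= set(frame.columns)
        assert np.array_equal(frame["temperature"].to_numpy(), T)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            SweepResult(axis="T", grid=np.array([1.0, 0.5]), summaries=[None, None],
                        base=WalkParams(), n_runs=1, base_seed=0)
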