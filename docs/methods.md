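# Methods

## The model

`sirwalk` simulates a growing self-interacting random walk (SIRW) in
continuous three-dimensional space.  A walker starts at the origin and takes
`N` moves of fixed length `d0`.  At every step the possible moves are a fixed
set of `M` near-uniform unit directions on the sphere of radius `d0` around
the current position, and the walker selects one of them at random with
probability

    P(candidate j)  ∝  exp(−U_j / kB T),

where `U_j` is the total interaction energy of candidate position `j` with
*every* previously visited position (the bonded neighbour included), summed
over the Lennard-Jones pair potential

    u(r) = ε [ (r0/r)^12 − 2 (r0/r)^6 ],

which has its minimum `−ε` at the equilibrium distance `r0`.  The energy of
the current position is common to all candidates, so weighting by `U_j` is
identical to weighting by the energy difference of the move; the weights are
max-shifted before exponentiation, which makes the selection exact in floating
point at any temperature.  Each visited position is one "monomer": the
finished trajectory is read as a polymer conformation, with `d0` the bond
length (the unit of length) and `kB = 1` (temperature in energy units).

There is no bending potential, no chain relaxation (the walk only grows), and
no cutoff truncation of the potential: with at most 51 positions the exact
pair sum is cheap.

Depending on `(T, ε, r0)` the trajectory is an extended random coil, a compact
disordered globule, an ordered helix, or a near-straight string, and the
package maps the transitions between these phases.

## Step-selection rules

The default rule is categorical sampling over the full candidate set with
Boltzmann weights, as above.  A second rule (`rule="metropolis"`) proposes
directions uniformly and accepts with `min(1, exp(−ΔU/kB T))` against the
current position's energy, re-proposing until acceptance; because
propose-until-accept is rejection sampling, it is drawn in closed form with
weights `min(1, exp(−ΔU/kB T))`.  The two rules differ materially at low
temperature: the categorical rule concentrates on the few lowest-energy
candidates and reliably discovers the helical ground-state-like growth
pattern, while the Metropolis rule accepts the first not-uphill proposal and
produces noticeably more disordered low-temperature structures (mean helix
fraction ≈ 0.2 instead of ≈ 1.0 at `r0 = 1.52`, `T = 0.01`).  All reported
results use the categorical rule; the switch exists to probe this
sensitivity.

### Numerical details

- Candidate energies use squared distances only (`(r0/r)^6 = (r0²/r²)³`).
- Pairs closer than a hard core of `0.1 r0` get energy `+inf` (selection
  weight exactly 0, never NaN).  At such distances the LJ energy exceeds
  `10^11 ε`, so the Boltzmann weight underflows to zero for every
  temperature in the studied range anyway; the core only prevents
  floating-point overflow in `r^−12`.
- If every candidate is forbidden the walker raises a trapped-walker error;
  with ≥ 2000 directions this has never been observed (a candidate sphere
  cannot be fully covered by hard cores of radius `0.1 r0 ≤ 0.25 d0`).
- One seeded `numpy` generator per trajectory; ensembles use seeds
  `base_seed + run_index`, so any single run is re-creatable and ensemble
  averages are independent of execution order.

## Candidate directions

The direction set is deterministic and fixed for the whole simulation.  Two
constructions are provided:

- **fibonacci** (default): the golden-spiral lattice, valid for any count.
- **geodesic**: vertices of an icosahedral geodesic sphere, valid for counts
  `10 f² + 2`; `f = 39` gives the reference count of 15,212 directions.

Both satisfy the same uniformity bounds (centroid norm < 0.01, no pairwise
angular separation below half the mean-density angle), and at ≥ 2000
directions the phase behaviour is insensitive to the construction.  The
angular resolution does matter for the most fragile helix (see below).

## Order parameters

**Radius of gyration.**  `Rg = sqrt( (1/M) Σ_i |R_i − R̄|² )` over the `M`
visited positions (`M = N + 1 = 51` for the standard walk).  Both `Rg` and
`Rg²` are reported by every ensemble.  *Scale caveat:* the reference plateau
and phase values this package is checked against (6.25 → 14.39 for the
globule-coil collapse; ≈ 16 → ≈ 9 → "above 20" along the reentrant curve) are
on the `Rg²` scale in units of `d0²`: a straight chain of 51 unit bonds has
`Rg = 14.72 d0` at most, so quoted coil/helix values of 14.39 and > 20 cannot
be root-mean-square radii.  Comparisons therefore use `mean_Rg2`.

**Helix fraction.**  A sliding window of `K + 1` consecutive connections
(`K + 2` positions, `K = 10` by default) qualifies as one helical turn when
(a) every local turn inside it has the same nonzero handedness — the sign of
the scalar triple product of three consecutive connection vectors — and
(b) the `K` turning angles between consecutive connections sum to more than
`2π`.  A position is *helical* if it belongs to at least one qualifying
window; `H` is the fraction of helical positions, 0 for coils and lines,
1 for a perfect helix.  `K = 10` is deliberately longer than the 4–6 steps an
observed turn actually takes, so a window tolerates fluctuations.  Windows
containing a coplanar (sign-0) or degenerate turn are disqualified, not
errors: a flat segment is not a helix turn.

**Steps per turn.**  Reported as the azimuthal turn period: per qualifying
window, the helix axis is estimated as the handedness-aligned mean of the
normalized cross products of consecutive connections, and the period is `2π`
over the mean rotation of the connections projected perpendicular to that
axis.  On ideal helices this recovers the geometric period exactly (to
< 0.5 % at any rise), whereas `2πK / Σ(turning angles)` overestimates the
period whenever the helix has rise, because the bond turning angle is smaller
than the azimuthal rotation (e.g. 4.53 for a geometrically 4.13-period
simulated helix).

**Energies.**  Ensembles report the final-configuration LJ energy both in
total and per position.  The per-position value is the intensive measure used
for phase comparisons; note that for `r0 > 2^(1/6) d0` the 50 bonded pairs sit
on the repulsive branch and dominate the total.

## Ensembles, sweeps and transition estimators

Observables are arithmetic means over independent runs (1000 in the reference
protocol; 100 is the fast default, with standard errors reported).  Per-run
`Rg` and `H` are evaluated on the finished 51-position configuration, not as
time averages.

Temperature sweeps use log-spaced grids (the studied range spans five
decades, `T ∈ [0.001, 100]`).  Two transition estimators are defined:

- **Rg estimator:** the temperature of steepest change of `mean_Rg` against
  `ln T`, refined by a quadratic through the three neighbouring slope
  magnitudes; an optional direction restriction selects slopes where `Rg`
  increases or decreases with `T`.
- **H estimator:** the (log-linearly interpolated) crossing of `mean_H`
  through 0.5, taking the lowest-temperature crossing.

A flat curve (relative spread ≤ 2 %) returns a no-transition sentinel rather
than raising.  For reentrant sweeps the combined helper estimates the
globule–helix temperature from the `H` crossing first, then searches the
coil–globule collapse among *increasing* slopes above four times that
temperature, so the low-temperature helix jump (where `Rg` decreases with
`T`) cannot masquerade as the collapse.

Transition lines in the `(T, ε)` plane at fixed `r0` are fitted through the
origin, `kB Tc = λ ε`, by least squares (`λ = Σ ε·Tc / Σ ε²`), one λ per
transition kind.  Phase labels in the diagram give helix (`mean_H ≥ 0.5`)
precedence over the globule/coil split (below/above the midpoint of the
non-helix `Rg` extremes at that ε), since helix and globule are both compact.

## Study conditions and scaled-down settings

The reference protocol is 50 steps (51 positions), 15,212 candidate
directions and 1000 runs per parameter set.  The package's test and
reproduction scripts use scaled-down conditions chosen once: 2000 candidate
directions and 50–100 runs per grid point, with 17–21-point log-T grids.
At these settings every phase boundary reproduces within the stochastic
scatter of the full protocol.  The one quantity that is sensitive to angular
resolution is the helix-fraction peak of the third (widest-turn, `r0 ≈ 1.82`)
helix window, which reaches ≈ 0.88 at 2000 directions and ≥ 0.9 only near the
full 15,212; the window scan therefore locates windows with a coarse scan and
evaluates their peaks at full resolution.

## Measured phase picture (what the code reproduces)

At `ε = 1`, `T = 0.01`, scanning `r0` from 1.0 to 2.5 yields compact globules
(`r0 ≲ 1.4`), three disjoint stable-helix windows with mean helix fraction
peaks ≥ 0.9 near `r0 = 1.52, 1.69, 1.82` (azimuthal periods ≈ 4.1, 5.0 and
5.8 steps per turn), a fourth unstable helical bump near `r0 ≈ 1.9` that never
reaches a peak of 0.9, and extended strings beyond.  At `r0 = 1.0` the model
collapses from coil (`mean_Rg² ≈ 15`) to globule (`mean_Rg² ≈ 2.7`) through a
single steep transition near `T ≈ 0.9`.  At `r0 = 1.52` the curve is
reentrant — helix (`Rg² ≈ 30`) → globule (`Rg² ≈ 5`) → coil (`Rg² ≈ 20`) —
with a coil–globule temperature near 1.15 and a globule–helix temperature
near 0.046, and the two transition lines fit `λ ≈ 1.15` and `λ ≈ 0.046`
over `ε ∈ {0.5, 1, 2, 5}`.  At `r0 = 2.25` only a string–coil crossover
remains.  All of these numbers are recomputed, not stored, by
`scripts/acceptance.py` and the acceptance tests.

## Known limitations

- The walk is a growth process, not an equilibrium ensemble: the helices it
  forms are kinetically selected and differ from the variational
  minimum-energy helix of the same potential (which has a longer period).
  No claim of equilibrium sampling is made.
- The low-temperature globule at `r0 = 1.0` is near-greedily packed
  (`mean_Rg² ≈ 2.7`); reported reference values for that plateau (≈ 6.25)
  correspond to a visibly looser globule, and the discrepancy survives both
  selection rules.  The collapse itself (monotone, single steep step, 5-6×
  plateau separation) is robust.
- `steps_per_turn` is only defined where at least one window qualifies; it is
  NaN otherwise.
- The high-temperature limit approaches a pure random walk slowly
  (`T^(−1/12)` residual excluded volume from the `r^−12` core): end-to-end
  statistics match the ideal walk within 5 % only for `T ≳ 10^12`.
- Trajectories are short (51 positions); none of the estimators attempt
  finite-size scaling, and transitions are crossovers, not sharp.
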