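# sirwalk

Self-interacting random walks in continuous 3D space: a minimal growth model
for the coil–globule–helix phase behaviour of polymers.

A walker starts at the origin and takes 50 steps of fixed length d₀.  At each
step it chooses among ~10³–10⁴ near-uniform directions on the sphere around
its current position, with probability

&nbsp;&nbsp;&nbsp;&nbsp;P(move) ∝ exp(−U/k_BT),&nbsp;&nbsp;&nbsp;&nbsp;
U = Σₖ ε[(r₀/rₖ)¹² − 2(r₀/rₖ)⁶],

where the sum runs over *all* previously visited positions — the walk
remembers where it has been and interacts with its own history through a
Lennard-Jones potential (well depth ε, equilibrium distance r₀).  That single
isotropic interaction is enough to produce, as the temperature drops, the
classic coil-to-globule collapse and — for r₀ ≈ 1.5 d₀ — a further transition
from globule into an ordered *helix*, with no bending potential and no
anisotropic terms.  The trajectory reads naturally as a Cα trace: r₀ ≈ 1.5 d₀
mirrors the ratio of nonbonded-contact to bond distance in real proteins, and
the three stable helix geometries the model produces echo the 3₁₀/α/π helix
family.

The package is for anyone studying toy models of polymer collapse and helix
formation: it provides the walker, the order parameters (radius of gyration,
window-based helix fraction, steps per helical turn), seeded ensemble
averaging, temperature/r₀ sweeps with transition-temperature estimators, the
k_BT_c = λε transition-line fits, and XYZ/PDB export for molecular viewers.

## A worked example

Grow one walk deep in the helical regime and measure it:

```
$ sirwalk simulate --temperature 0.01 --epsilon 1.0 --r0 1.52 \
      --steps 50 --directions 2000 --seed 7 --out helix.xyz
wrote 51 positions to helix.xyz

$ sirwalk metrics --in helix.xyz
positions       : 51
Rg              : 5.5184
helix fraction H: 1.0000
steps per turn  : 4.172
handedness      : right
```

Every one of the 51 visited positions sits inside a uniformly-turning window
(H = 1: a perfect helix), the turn closes in ≈ 4.2 steps — the tightest of
the model's three stable helices — and this particular seed happened to grow
right-handed (the model is achiral; left and right occur equally often).

The same regime as a seeded 100-run ensemble, from Python:

```python
from sirwalk import WalkParams, PotentialParams, run_ensemble

params = WalkParams(temperature=0.01, potential=PotentialParams(1.0, 1.52),
                    n_steps=50, n_directions=2000)
s = run_ensemble(params, n_runs=100, base_seed=1)
print(s.mean_H, s.sem_H, s.mean_Rg2, s.mean_steps_per_turn)
# 0.9743 0.0121 29.53 4.158
```

The ensemble-mean helix fraction ⟨H⟩ = 0.97 ± 0.01: essentially every run at
T = 0.01 forms a helix.  Raise the temperature to 0.1 and the same call gives
⟨H⟩ ≈ 0.1 with ⟨Rg²⟩ ≈ 6 — the compact *globule* phase, which is disordered
but even smaller than the helix; by T = 10 the walk is an open random coil
with ⟨Rg²⟩ ≈ 20.  That large-small-large (reentrant) sequence in Rg with
falling temperature is the helix–globule–coil signature, and
`sirwalk sweep` / `sirwalk phase-diagram` map it systematically:

```bash
sirwalk sweep --axis T --grid-log 0.001 100 21 --r0 1.52 --runs 100 --out sweep.csv
sirwalk phase-diagram --r0 1.52 --runs 50 --out diagram.csv --lambda-out lines.json
```

The sweep prints the two estimated transition temperatures (coil–globule near
T ≈ 1.2, globule–helix near T ≈ 0.05 at ε = 1); the phase diagram fits the
two transition lines k_BT_c = λε across ε ∈ [0.5, 5].

`--published` on any command switches from the fast defaults (2000
directions, 100 runs) to the reference protocol (15,212 directions,
1000 runs).

## Layout

| module | contents |
|---|---|
| `sirwalk.geometry` | sphere direction sets (Fibonacci / geodesic), turning angles, handedness |
| `sirwalk.energy` | LJ pair potential, history interaction energies |
| `sirwalk.walker` | `WalkParams`, `simulate`, Boltzmann step selection |
| `sirwalk.metrics` | Rg, helix fraction (window rule), steps per turn, energies |
| `sirwalk.ensemble` | seeded multi-run averaging with SEMs |
| `sirwalk.phase_scan` | T/r₀ sweeps, transition estimators, λ fits, phase diagram |
| `sirwalk.trajectory_io` | XYZ/PDB/CSV/JSON/YAML I/O |
| `sirwalk.cli` | the `sirwalk` command |
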