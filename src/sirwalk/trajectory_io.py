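"""File I/O: XYZ and PDB trajectory export, position parsing, run configs.

Coordinates are dimensionless multiples of the step distance d0 everywhere
inside the package; the PDB writer alone converts to Angstroms, by default
3.8 A per step — the Calpha–Calpha bond distance of real proteins — so that a
helical walk displays at protein-like dimensions in molecular viewers.  All
writers are byte-deterministic for a given input.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .energy import PotentialParams
from .walker import Trajectory, WalkParams

__all__ = [
    "RunConfig",
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "read_positions",
    "CA_SCALE",
]

#: Default Angstrom-per-step scale of the PDB writer (Calpha-Calpha distance).
CA_SCALE = 3.8


@dataclass
class RunConfig:
    """Serializable description of a run: walk parameters plus plumbing."""

    temperature: float = 1.0
    epsilon: float = 1.0
    r0: float = 1.0
    d0: float = 1.0
    n_steps: int = 50
    n_directions: int = 15_212
    method: str = "fibonacci"
    rule: str = "categorical"
    seed: int = 0
    n_runs: int = 100
    T_grid: list[float] = field(default_factory=list)
    epsilon_grid: list[float] = field(default_factory=list)
    r0_grid: list[float] = field(default_factory=list)
    output: str = ""
    output_format: str = "xyz"
    log_level: str = "INFO"

    def walk_params(self) -> WalkParams:
        return WalkParams(
            temperature=self.temperature,
            potential=PotentialParams(self.epsilon, self.r0),
            d0=self.d0,
            n_steps=self.n_steps,
            n_directions=self.n_directions,
            method=self.method,
            rule=self.rule,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) + "\n"
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        data = (json.loads(path.read_text()) if path.suffix == ".json"
                else yaml.safe_load(path.read_text()))
        return cls.from_dict(data)


def _comment_line(params: WalkParams) -> str:
    p = params
    return (f"sirwalk T={p.temperature:g} epsilon={p.potential.epsilon:g} "
            f"r0={p.potential.r0:g} d0={p.d0:g} seed={p.seed} rule={p.rule}")


def write_xyz(trajectory: Trajectory, path) -> None:
    """Standard XYZ: count line, parameter comment, one 'C x y z' per visit."""
    pts = trajectory.positions
    lines = [str(len(pts)), _comment_line(trajectory.params)]
    for x, y, z in pts:
        lines.append(f"C {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_directions_xyz(directions, path) -> None:
    """Dump a direction set (unit vectors) to XYZ for visual inspection."""
    vecs = np.asarray(getattr(directions, "directions", directions), dtype=float)
    lines = [str(len(vecs)), "sirwalk direction set (unit sphere)"]
    for x, y, z in vecs:
        lines.append(f"C {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> np.ndarray:
    """Read one XYZ frame back into an (n, 3) position array."""
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        count = int(raw[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: expected an atom count")
    body = raw[2 : 2 + count]
    if len(body) < count:
        raise ValueError(f"{path}: expected {count} atom lines, found {len(body)}")
    pts = []
    for i, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {i}: expected 'symbol x y z'")
        try:
            pts.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise ValueError(f"{path}: line {i}: non-numeric coordinate")
    return np.asarray(pts)


def write_pdb(trajectory: Trajectory, path, scale: float = CA_SCALE) -> None:
    """Export the walk as a Calpha trace: one CA atom per visit, chain A.

    ``scale`` converts step units to Angstroms (default 3.8, the protein
    Calpha–Calpha bond distance) and is recorded in a REMARK; no CONECT
    records are written, viewers infer the trace from residue order.
    """
    p = trajectory.params
    lines = [
        f"REMARK 250 SIRWALK CA TRACE SCALE={scale:g} A PER STEP",
        f"REMARK 250 {_comment_line(p).upper()}",
    ]
    for i, (x, y, z) in enumerate(trajectory.positions, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY A{i:4d}    "
            f"{x * scale:8.3f}{y * scale:8.3f}{z * scale:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_pdb_ca(path) -> np.ndarray:
    pts = []
    chain = None
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if line[12:16].strip() != "CA":
            continue
        this_chain = line[21]
        if chain is None:
            chain = this_chain
        elif this_chain != chain:
            continue  # first chain only
        try:
            pts.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        except ValueError:
            raise ValueError(f"{path}: line {i}: malformed ATOM coordinates")
    if not pts:
        raise ValueError(f"{path}: no CA atoms found")
    return np.asarray(pts)


def read_positions(path, format: str | None = None) -> np.ndarray:
    """Load an ordered 3D point list from an XYZ file or a PDB Calpha trace.

    The format is inferred from the suffix when not given.  PDB files
    contribute the CA atoms of their first chain, in record order.
    """
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz")
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "pdb":
        return _read_pdb_ca(path)
    raise ValueError(f"unknown format {fmt!r}; use 'xyz' or 'pdb'")
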