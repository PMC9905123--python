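"""Trajectory file I/O: extended XYZ (native, read/write), LAMMPS text
dump (read via MDAnalysis, plus a minimal writer), and CSV energy series.

The native format is extended XYZ: the comment line carries the cubic box
as a Lattice entry, a Properties descriptor, the frame time and per-frame
energies.  Coordinates are written wrapped with 12 significant digits, so
a write -> read round trip preserves positions to printed precision and
the frame count exactly.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .engine import Trajectory
from .system import StatePoint

__all__ = [
    "write_xyz",
    "write_lammps_dump",
    "read_trajectory",
    "write_energies_csv",
    "read_energies_csv",
]

_FMT = "%.12g"


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path) -> None:
    """Write a trajectory as extended XYZ (one frame per block)."""
    box = traj.box_side
    lattice = f'"{box:.12g} 0 0 0 {box:.12g} 0 0 0 {box:.12g}"'
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            n = traj.n_particles
            fh.write(f"{n}\n")
            fh.write(
                f"Lattice={lattice} "
                f"Properties=species:S:1:pos:R:3:vel:R:3 "
                f"Time={traj.times[f]:.12g} "
                f"PotentialEnergy={traj.potential_energy[f]:.12g} "
                f"KineticEnergy={traj.kinetic_energy[f]:.12g}\n")
            pos = traj.positions[f]
            vel = traj.velocities[f]
            cid = traj.chain_id
            for i in range(n):
                sp = f"C{cid[i]}" if cid is not None else "LJ"
                fh.write(f"{sp} {pos[i,0]:.12g} {pos[i,1]:.12g} "
                         f"{pos[i,2]:.12g} {vel[i,0]:.12g} {vel[i,1]:.12g} "
                         f"{vel[i,2]:.12g}\n")


def _parse_xyz(path) -> Trajectory:
    times, poss, vels, pes, kes = [], [], [], [], []
    box = None
    chain_id = None
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            comment = fh.readline()
            m = re.search(r'Lattice="([^"]+)"', comment)
            if not m:
                raise ValueError(f"{path}: frame without a Lattice entry — "
                                 f"box information is required")
            lat = np.fromstring(m.group(1), sep=" ").reshape(3, 3)
            if not np.allclose(lat, np.diag(np.diag(lat))) or \
               not np.allclose(np.diag(lat), lat[0, 0]):
                raise ValueError(f"{path}: only cubic boxes are supported")
            box = float(lat[0, 0])
            tm = re.search(r"Time=([-\d.eE+]+)", comment)
            pm = re.search(r"PotentialEnergy=([-\d.eE+]+)", comment)
            km = re.search(r"KineticEnergy=([-\d.eE+]+)", comment)
            pos = np.empty((n, 3))
            vel = np.zeros((n, 3))
            species = []
            for i in range(n):
                parts = fh.readline().split()
                species.append(parts[0])
                pos[i] = [float(x) for x in parts[1:4]]
                if len(parts) >= 7:
                    vel[i] = [float(x) for x in parts[4:7]]
            times.append(float(tm.group(1)) if tm else float(len(times)))
            poss.append(pos)
            vels.append(vel)
            pes.append(float(pm.group(1)) if pm else np.nan)
            kes.append(float(km.group(1)) if km else np.nan)
            if chain_id is None and species and species[0].startswith("C") \
               and species[0][1:].isdigit():
                chain_id = np.array([int(s[1:]) for s in species],
                                    dtype=np.int64)
    if not poss:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(np.array(times), np.array(poss), np.array(vels),
                      np.array(pes), np.array(kes),
                      np.zeros(len(times)), box, chain_id=chain_id)


# ---------------------------------------------------------------------------
# LAMMPS text dump
# ---------------------------------------------------------------------------

def write_lammps_dump(traj: Trajectory, path) -> None:
    """Minimal LAMMPS-style text dump (id type x y z vx vy vz)."""
    box = traj.box_side
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            n = traj.n_particles
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{f}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{n}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0 {box:.12g}\n")
            fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
            pos, vel = traj.positions[f], traj.velocities[f]
            cid = traj.chain_id
            for i in range(n):
                t = (cid[i] + 1) if cid is not None else 1
                fh.write(f"{i+1} {t} {pos[i,0]:.12g} {pos[i,1]:.12g} "
                         f"{pos[i,2]:.12g} {vel[i,0]:.12g} {vel[i,1]:.12g} "
                         f"{vel[i,2]:.12g}\n")


_KNOWN_DUMP_COLS = {"id", "mol", "type", "element", "mass", "q",
                    "x", "y", "z", "xs", "ys", "zs", "xu", "yu", "zu",
                    "xsu", "ysu", "zsu", "ix", "iy", "iz",
                    "vx", "vy", "vz", "fx", "fy", "fz"}


def _validate_dump_header(path) -> None:
    """Raise informative errors for dumps missing box bounds or using
    unrecognised atom columns, before handing the file to MDAnalysis."""
    text_head = []
    with open(path) as fh:
        for _ in range(200):
            line = fh.readline()
            if not line:
                break
            text_head.append(line)
            if line.startswith("ITEM: ATOMS"):
                break
    head = "".join(text_head)
    if "ITEM: BOX BOUNDS" not in head:
        raise ValueError(f"{path}: no 'ITEM: BOX BOUNDS' record — box "
                         f"information is required in every frame")
    m = re.search(r"ITEM: ATOMS (.+)", head)
    if not m:
        raise ValueError(f"{path}: no 'ITEM: ATOMS' record found")
    cols = m.group(1).split()
    unknown = [c for c in cols if c not in _KNOWN_DUMP_COLS]
    if unknown:
        raise ValueError(f"{path}: unknown dump columns {unknown}; "
                         f"header found: 'ITEM: ATOMS {m.group(1)}'")
    if "id" not in cols:
        raise ValueError(f"{path}: dump lacks an 'id' column; particle "
                         f"order cannot be normalised")
    if not ({"x", "y", "z"} <= set(cols) or {"xs", "ys", "zs"} <= set(cols)
            or {"xu", "yu", "zu"} <= set(cols)):
        raise ValueError(f"{path}: no usable coordinate columns among "
                         f"'ITEM: ATOMS {m.group(1)}'")


def _parse_lammps_dump(path) -> Trajectory:
    import MDAnalysis as mda

    _validate_dump_header(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # mass/element guessing chatter
        u = mda.Universe(str(path), format="LAMMPSDUMP",
                         lammps_coordinate_convention="auto")
        times, poss, vels = [], [], []
        box = None
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None or dims[0] <= 0:
                raise ValueError(f"{path}: frame without box dimensions")
            box = float(dims[0])
            poss.append(ts.positions.astype(np.float64).copy())
            if ts.has_velocities:
                vels.append(ts.velocities.astype(np.float64).copy())
            else:
                vels.append(np.zeros_like(poss[-1]))
            times.append(float(ts.data.get("step", len(times))))
    poss = np.array(poss)
    poss -= poss.min() if poss.min() < 0 else 0.0   # shift origin if needed
    np.mod(poss, box, out=poss)
    F = len(times)
    nan = np.full(F, np.nan)
    return Trajectory(np.array(times, dtype=float), poss, np.array(vels),
                      nan.copy(), nan.copy(), np.zeros(F), box)


def read_trajectory(path, format: Optional[str] = None) -> Trajectory:
    """Read an extended-XYZ or LAMMPS text-dump trajectory.

    `format` is "xyz" or "lammps"; when omitted it is inferred from the
    suffix (.xyz -> xyz, anything else is sniffed for LAMMPS ITEM records).
    Particle order in dumps is normalised by atom id; scaled (xs) dump
    coordinates are unscaled by the box.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.suffix == ".xyz":
            format = "xyz"
        else:
            with open(path) as fh:
                format = "lammps" if fh.readline().startswith("ITEM:") else "xyz"
    if format == "xyz":
        return _parse_xyz(path)
    if format == "lammps":
        return _parse_lammps_dump(path)
    raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# energy series
# ---------------------------------------------------------------------------

def write_energies_csv(traj: Trajectory, path, metadata: Optional[dict] = None
                       ) -> None:
    """Energy time series as CSV: time, KE, PE, E_total, T_kinetic.

    Run parameters are embedded as '# key=value' comment lines so every
    output carries what is needed to regenerate it.
    """
    df = pd.DataFrame({
        "time": traj.times,
        "KE": traj.kinetic_energy,
        "PE": traj.potential_energy,
        "E_total": traj.total_energy,
        "T_kinetic": traj.kinetic_temperature,
    })
    with open(path, "w") as fh:
        meta = dict(metadata or {})
        if traj.state is not None:
            meta.setdefault("rho_star", traj.state.rho_star)
            meta.setdefault("T_star", traj.state.T_star)
        if traj.params is not None:
            for k, v in vars(traj.params).items():
                meta.setdefault(k, v)
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_energies_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
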