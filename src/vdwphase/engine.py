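"""Lennard-Jones + harmonic-bond force field and NVE / Nose-Hoover NVT
velocity-Verlet integration.

Pair interactions use the 6-12 LJ potential Phi(r) = 4 eps [(sigma/r)^12 -
(sigma/r)^6] with plain truncation at r_cut (no energy shift, no tail
correction) and the minimum-image convention in a cubic periodic box.
Chain bonds are harmonic, U_b(r) = k_b (r - sigma)^2 with k_b = 75000,
stiff enough to pin bonded beads at separation sigma; directly bonded
pairs are excluded from the LJ sum, all other intra-chain pairs are not.

Temperature control is a Nose-Hoover chain of three thermostats (the
form used by LAMMPS `fix nvt`), masses Q_1 = g k_B T tau_damp^2 and
Q_2 = Q_3 = k_B T tau_damp^2 with g = 3(n-1) translational degrees of
freedom after momentum removal, integrated with the reversible
Martyna-Tuckerman-Klein half-step splitting around the velocity-Verlet
core.  A single Nose-Hoover variable is non-ergodic for weakly coupled or
harmonic systems (it fails to thermalise an ideal gas at all); the chain
restores canonical kinetic-energy fluctuations.  The thermostat scales all
velocities uniformly, so a zero total momentum is preserved exactly.

The inner loops are numba-jitted; a half neighbour list with skin is
rebuilt (via a cell grid, or an all-pairs scan when the box is under three
cells across) whenever any particle has moved more than half the skin.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .system import (Configuration, SimulationParams, StatePoint,
                     build_chain_configuration, build_configuration,
                     chain_defaults)

__all__ = [
    "Frame",
    "Trajectory",
    "pair_energy_forces",
    "bond_energy_forces",
    "integrate_nve",
    "integrate_nvt",
    "run_state_point",
    "EnergyDivergenceError",
]

log = logging.getLogger("vdwphase")


class EnergyDivergenceError(RuntimeError):
    """NVE total energy drifted by more than 1% — unstable time step."""


# ---------------------------------------------------------------------------
# jitted kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_neighbors(pos, box, rlist, chain_id, pi, pj, sh):
    """Half neighbour list (i<j) within rlist, excluding directly bonded
    chain neighbours.  Returns the pair count, or -1 on capacity overflow.
    Uses a cell grid when at least 3 cells fit per side, else all pairs.

    `sh[k]` records the periodic image shift to add to pos[i] - pos[j] so
    the force kernel needs no minimum-image arithmetic.  Positions must be
    wrapped into [0, box) when the list is built; the recorded image stays
    the minimum image while every listed pair remains closer than half the
    box, which the skin update interval guarantees."""
    n = pos.shape[0]
    rl2 = rlist * rlist
    hbox = 0.5 * box
    cap = pi.shape[0]
    count = 0
    has_chain = chain_id.shape[0] > 0
    ncell = int(box / rlist)
    if ncell >= 3:
        cell_sz = box / ncell
        nc3 = ncell * ncell * ncell
        head = np.full(nc3, -1, dtype=np.int64)
        nxt = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            cx = int(pos[i, 0] / cell_sz) % ncell
            cy = int(pos[i, 1] / cell_sz) % ncell
            cz = int(pos[i, 2] / cell_sz) % ncell
            c = (cx * ncell + cy) * ncell + cz
            nxt[i] = head[c]
            head[c] = i
        for i in range(n):
            cx = int(pos[i, 0] / cell_sz) % ncell
            cy = int(pos[i, 1] / cell_sz) % ncell
            cz = int(pos[i, 2] / cell_sz) % ncell
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    for oz in range(-1, 2):
                        c2 = (((cx + ox) % ncell) * ncell
                              + ((cy + oy) % ncell)) * ncell + ((cz + oz) % ncell)
                        j = head[c2]
                        while j != -1:
                            if j > i:
                                dx = pos[i, 0] - pos[j, 0]
                                dy = pos[i, 1] - pos[j, 1]
                                dz = pos[i, 2] - pos[j, 2]
                                sx = 0.0
                                sy = 0.0
                                sz = 0.0
                                if dx > hbox:
                                    sx = -box
                                elif dx < -hbox:
                                    sx = box
                                if dy > hbox:
                                    sy = -box
                                elif dy < -hbox:
                                    sy = box
                                if dz > hbox:
                                    sz = -box
                                elif dz < -hbox:
                                    sz = box
                                dx += sx
                                dy += sy
                                dz += sz
                                if dx * dx + dy * dy + dz * dz <= rl2:
                                    if not (has_chain and chain_id[i] == chain_id[j]
                                            and (j - i == 1 or i - j == 1)):
                                        if count >= cap:
                                            return -1
                                        pi[count] = i
                                        pj[count] = j
                                        sh[count, 0] = sx
                                        sh[count, 1] = sy
                                        sh[count, 2] = sz
                                        count += 1
                            j = nxt[j]
    else:
        ibox = 1.0 / box
        for i in range(n):
            xi = pos[i, 0]
            yi = pos[i, 1]
            zi = pos[i, 2]
            for j in range(i + 1, n):
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                dz = zi - pos[j, 2]
                sx = -box * round(dx * ibox)
                sy = -box * round(dy * ibox)
                sz = -box * round(dz * ibox)
                dx += sx
                dy += sy
                dz += sz
                if dx * dx + dy * dy + dz * dz <= rl2:
                    if not (has_chain and chain_id[i] == chain_id[j]
                            and j - i == 1):
                        if count >= cap:
                            return -1
                        pi[count] = i
                        pj[count] = j
                        sh[count, 0] = sx
                        sh[count, 1] = sy
                        sh[count, 2] = sz
                        count += 1
    return count


@njit(cache=True, fastmath=True)
def _lj_forces(pos, rc2, e_shift, pi, pj, sh, npairs, forces):
    """LJ energy/forces over a half pair list; returns (pe, min_r2 seen).

    Pair displacements use the image shifts recorded at list build time
    (see _build_neighbors), so no minimum-image arithmetic is needed here.
    e_shift is subtracted per interacting pair (0 for plain truncation;
    Phi(r_cut) for a cutoff-shifted potential with identical forces)."""
    pe = 0.0
    min_r2 = 1.0e30
    for k in range(npairs):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0] + sh[k, 0]
        dy = pos[i, 1] - pos[j, 1] + sh[k, 1]
        dz = pos[i, 2] - pos[j, 2] + sh[k, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            min_r2 = min(min_r2, r2)
            sr2 = 1.0 / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            pe += 4.0 * (sr12 - sr6) - e_shift
            fs = 24.0 * (2.0 * sr12 - sr6) * sr2
            fx = fs * dx
            fy = fs * dy
            fz = fs * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return pe, min_r2


@njit(cache=True, fastmath=True)
def _bond_forces(pos, box, bi, bj, k_bond, forces):
    """Harmonic bond energy/forces; U = k_b (r - 1)^2 per bond."""
    e = 0.0
    for k in range(bi.shape[0]):
        i = bi[k]
        j = bj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - 1.0
        e += k_bond * dr * dr
        if r > 0.0:
            fs = -2.0 * k_bond * dr / r
            fx = fs * dx
            fy = fs * dy
            fz = fs * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return e



@njit(cache=True, fastmath=True)
def _nhc_half(ke2, v1, v2, v3, dth, gdof, T, Q1, Q2, Q3):
    """Advance the 3-link Nose-Hoover chain by dth and return the particle
    velocity scale factor plus updated chain velocities.

    ke2 is twice the kinetic energy (sum m v^2).  Standard reversible
    Suzuki/Trotter update: drive the chain top-down, scale, then bottom-up.
    """
    dt4 = 0.5 * dth
    dt8 = 0.25 * dth
    G3 = (Q2 * v2 * v2 - T) / Q3
    v3 += dt4 * G3
    aa = math.exp(-dt8 * v3)
    G2 = (Q1 * v1 * v1 - T) / Q2
    v2 = v2 * aa * aa + dt4 * G2 * aa
    aa = math.exp(-dt8 * v2)
    G1 = (ke2 - gdof * T) / Q1
    v1 = v1 * aa * aa + dt4 * G1 * aa
    s = math.exp(-dth * v1)
    ke2 = ke2 * s * s
    aa = math.exp(-dt8 * v2)
    G1 = (ke2 - gdof * T) / Q1
    v1 = v1 * aa * aa + dt4 * G1 * aa
    aa = math.exp(-dt8 * v3)
    G2 = (Q1 * v1 * v1 - T) / Q2
    v2 = v2 * aa * aa + dt4 * G2 * aa
    G3 = (Q2 * v2 * v2 - T) / Q3
    v3 += dt4 * G3
    return s, v1, v2, v3


@njit(cache=True, fastmath=True)
def _run_md(pos, vel, box, chain_id, bi, bj, k_bond,
            r_cut, rlist, e_shift, dt, n_steps, stride,
            use_thermostat, T_target, Q1, Q2, Q3, gdof,
            pi, pj, sh, frame_pos, frame_vel, frame_ke, frame_pe, frame_xi):
    """Velocity-Verlet core with an optional 3-link Nose-Hoover chain.

    Frames are sampled every `stride` steps (after the step completes).
    Returns (status, xi1, min_r2): status 0 ok, 1 neighbour overflow.
    """
    n = pos.shape[0]
    rc2 = r_cut * r_cut
    ibox = 1.0 / box
    use_lj = r_cut > 0.0
    skin_half2 = 0.25 * (rlist - r_cut) ** 2
    xi1 = 0.0
    xi2 = 0.0
    xi3 = 0.0
    min_r2_all = 1.0e30

    for i in range(n):
        pos[i, 0] -= box * math.floor(pos[i, 0] * ibox)
        pos[i, 1] -= box * math.floor(pos[i, 1] * ibox)
        pos[i, 2] -= box * math.floor(pos[i, 2] * ibox)
    ref = pos.copy()
    npairs = 0
    if use_lj:
        npairs = _build_neighbors(pos, box, rlist, chain_id, pi, pj, sh)
        if npairs < 0:
            return 1, xi1, min_r2_all

    forces = np.zeros((n, 3))
    pe = 0.0
    if use_lj:
        pe, mr2 = _lj_forces(pos, rc2, e_shift, pi, pj, sh, npairs, forces)
        if mr2 < min_r2_all:
            min_r2_all = mr2
    if bi.shape[0] > 0:
        pe += _bond_forces(pos, box, bi, bj, k_bond, forces)

    halfdt = 0.5 * dt
    iframe = 0
    for step in range(n_steps):
        if use_thermostat:
            ke2 = 0.0
            for i in range(n):
                ke2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            s, xi1, xi2, xi3 = _nhc_half(ke2, xi1, xi2, xi3, halfdt,
                                         gdof, T_target, Q1, Q2, Q3)
            for i in range(n):
                vel[i, 0] *= s
                vel[i, 1] *= s
                vel[i, 2] *= s

        for i in range(n):
            vel[i, 0] += halfdt * forces[i, 0]
            vel[i, 1] += halfdt * forces[i, 1]
            vel[i, 2] += halfdt * forces[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]

        if use_lj:
            # positions are not rewrapped between rebuilds, so the direct
            # difference to the rebuild reference is the true displacement
            maxdisp2 = 0.0
            for i in range(n):
                dx = pos[i, 0] - ref[i, 0]
                dy = pos[i, 1] - ref[i, 1]
                dz = pos[i, 2] - ref[i, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > maxdisp2:
                    maxdisp2 = d2
            if maxdisp2 > skin_half2:
                for i in range(n):
                    pos[i, 0] -= box * math.floor(pos[i, 0] * ibox)
                    pos[i, 1] -= box * math.floor(pos[i, 1] * ibox)
                    pos[i, 2] -= box * math.floor(pos[i, 2] * ibox)
                npairs = _build_neighbors(pos, box, rlist, chain_id, pi, pj, sh)
                if npairs < 0:
                    return 1, xi1, min_r2_all
                for i in range(n):
                    ref[i, 0] = pos[i, 0]
                    ref[i, 1] = pos[i, 1]
                    ref[i, 2] = pos[i, 2]

        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        pe = 0.0
        if use_lj:
            pe, mr2 = _lj_forces(pos, rc2, e_shift, pi, pj, sh, npairs, forces)
            if mr2 < min_r2_all:
                min_r2_all = mr2
        if bi.shape[0] > 0:
            pe += _bond_forces(pos, box, bi, bj, k_bond, forces)

        for i in range(n):
            vel[i, 0] += halfdt * forces[i, 0]
            vel[i, 1] += halfdt * forces[i, 1]
            vel[i, 2] += halfdt * forces[i, 2]

        if use_thermostat:
            ke2 = 0.0
            for i in range(n):
                ke2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            s, xi1, xi2, xi3 = _nhc_half(ke2, xi1, xi2, xi3, halfdt,
                                         gdof, T_target, Q1, Q2, Q3)
            for i in range(n):
                vel[i, 0] *= s
                vel[i, 1] *= s
                vel[i, 2] *= s

        if (step + 1) % stride == 0:
            ke = 0.0
            for i in range(n):
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                frame_pos[iframe, i, 0] = pos[i, 0] - box * math.floor(
                    pos[i, 0] * ibox)
                frame_pos[iframe, i, 1] = pos[i, 1] - box * math.floor(
                    pos[i, 1] * ibox)
                frame_pos[iframe, i, 2] = pos[i, 2] - box * math.floor(
                    pos[i, 2] * ibox)
                frame_vel[iframe, i, 0] = vel[i, 0]
                frame_vel[iframe, i, 1] = vel[i, 1]
                frame_vel[iframe, i, 2] = vel[i, 2]
            frame_ke[iframe] = 0.5 * ke
            frame_pe[iframe] = pe
            frame_xi[iframe] = xi1
            iframe += 1

    return 0, xi1, min_r2_all


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """A single sampled frame (a view into a Trajectory)."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray
    potential_energy: float
    kinetic_energy: float
    thermostat_state: float
    box_side: float
    chain_id: Optional[np.ndarray] = None


@dataclass
class Trajectory:
    """Time-ordered frames plus per-frame energies from one state point.

    Frame times are strictly increasing with uniform spacing
    dt * sampling_stride.  Positions are stored wrapped.
    """

    times: np.ndarray
    positions: np.ndarray           # (F, n, 3)
    velocities: np.ndarray          # (F, n, 3)
    potential_energy: np.ndarray    # (F,)
    kinetic_energy: np.ndarray      # (F,)
    thermostat_xi: np.ndarray       # (F,)
    box_side: float
    state: Optional[StatePoint] = None
    params: Optional[SimulationParams] = None
    chain_id: Optional[np.ndarray] = None
    chain_length: Optional[int] = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential_energy + self.kinetic_energy

    @property
    def kinetic_temperature(self) -> np.ndarray:
        g = 3 * (self.n_particles - 1)
        return 2.0 * self.kinetic_energy / g

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.positions[i],
                     self.velocities[i], float(self.potential_energy[i]),
                     float(self.kinetic_energy[i]), float(self.thermostat_xi[i]),
                     self.box_side, self.chain_id)

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))

    def tail(self, fraction: float) -> "Trajectory":
        """Trajectory restricted to the last (1 - fraction) of the frames."""
        start = math.ceil(fraction * self.n_frames)
        start = min(start, self.n_frames - 1)
        return Trajectory(self.times[start:], self.positions[start:],
                          self.velocities[start:], self.potential_energy[start:],
                          self.kinetic_energy[start:], self.thermostat_xi[start:],
                          self.box_side, self.state, self.params,
                          self.chain_id, self.chain_length)


# ---------------------------------------------------------------------------
# public force/energy API
# ---------------------------------------------------------------------------

def _chain_array(config: Configuration) -> np.ndarray:
    if config.chain_id is None:
        return np.empty(0, dtype=np.int64)
    return config.chain_id


def _check_cutoff(r_cut: float, box: float) -> None:
    if r_cut >= box / 2.0:
        raise ValueError(
            f"r_cut={r_cut} must be below half the box side ({box / 2.0:.4f}) "
            f"for the minimum-image convention")


def _pair_capacity(n: int, rho: float, rlist: float) -> int:
    est = 0.5 * (4.0 / 3.0) * math.pi * rlist**3 * max(rho, 0.05)
    return int(n * (1.6 * est + 32))


def pair_energy_forces(config: Configuration, r_cut: float):
    """Truncated-LJ potential energy and forces for a configuration.

    Energy is the sum of Phi_LJ(r) over minimum-image pairs with r < r_cut;
    forces are the exact negative gradients (Newton's third law holds
    pairwise).  Directly bonded chain neighbours are excluded.  Emits a
    warning if any interacting pair is closer than 0.5 sigma.
    """
    box = config.box_side
    _check_cutoff(r_cut, box)
    n = config.n_particles
    cap = _pair_capacity(n, config.rho_star, r_cut)
    chain = _chain_array(config)
    while True:
        pi = np.empty(cap, dtype=np.int64)
        pj = np.empty(cap, dtype=np.int64)
        sh = np.empty((cap, 3))
        npairs = _build_neighbors(config.positions, box, r_cut, chain,
                                  pi, pj, sh)
        if npairs >= 0:
            break
        cap *= 2
    forces = np.zeros((n, 3))
    pe, min_r2 = _lj_forces(config.positions, r_cut * r_cut, 0.0,
                            pi, pj, sh, npairs, forces)
    if min_r2 < 0.25:
        warnings.warn(
            f"pair distance {math.sqrt(min_r2):.3f} sigma below 0.5 sigma: "
            f"near-singular LJ forces", RuntimeWarning, stacklevel=2)
    return float(pe), forces


def bond_energy_forces(config: Configuration, k_bond: float = 75000.0):
    """Harmonic bond energy sum k_b (r - sigma)^2 and exact gradient forces."""
    if config.chain_id is None:
        raise ValueError("configuration has no chain topology")
    bonds = config.bonds()
    forces = np.zeros((config.n_particles, 3))
    e = _bond_forces(config.positions, config.box_side,
                     np.ascontiguousarray(bonds[:, 0]),
                     np.ascontiguousarray(bonds[:, 1]), k_bond, forces)
    return float(e), forces


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------

def _integrate(config: Configuration, params: SimulationParams,
               T_star: Optional[float]) -> Trajectory:
    n = config.n_particles
    box = config.box_side
    r_cut = params.r_cut
    if r_cut > 0 and r_cut >= box / 2.0:
        clamped = box / 2.0 - 1e-6
        log.warning("r_cut=%.3f does not fit in box %.3f; clamped to %.6f",
                    r_cut, box, clamped)
        r_cut = clamped
    rlist = r_cut + params.neighbor_skin if r_cut > 0 else 0.0
    e_shift = 0.0
    if params.shift_energy and r_cut > 0:
        e_shift = 4.0 * (r_cut**-12 - r_cut**-6)

    stride = min(params.sampling_stride, params.n_steps)
    n_frames = params.n_steps // stride
    frame_pos = np.empty((n_frames, n, 3))
    frame_vel = np.empty((n_frames, n, 3))
    frame_ke = np.empty(n_frames)
    frame_pe = np.empty(n_frames)
    frame_xi = np.empty(n_frames)

    bonds = config.bonds()
    bi = np.ascontiguousarray(bonds[:, 0])
    bj = np.ascontiguousarray(bonds[:, 1])
    chain = _chain_array(config)

    pos = config.positions.copy()
    vel = config.velocities.copy()
    gdof = 3 * (n - 1) if n > 1 else 3
    use_nh = T_star is not None
    T = float(T_star) if use_nh else 0.0
    tau2 = params.thermostat_damping**2
    Q1 = gdof * T * tau2 if use_nh else 1.0
    Q23 = T * tau2 if use_nh else 1.0

    cap = _pair_capacity(n, config.rho_star, max(rlist, 1.0))
    while True:
        pi = np.empty(cap, dtype=np.int64)
        pj = np.empty(cap, dtype=np.int64)
        sh = np.empty((cap, 3))
        status, xi, min_r2 = _run_md(
            pos, vel, box, chain, bi, bj, params.k_bond,
            r_cut, rlist, e_shift, params.dt, params.n_steps, stride,
            use_nh, T, Q1, Q23, Q23, float(gdof),
            pi, pj, sh, frame_pos, frame_vel, frame_ke, frame_pe, frame_xi)
        if status == 0:
            break
        cap *= 2  # neighbour list overflow: retry with more room

    if min_r2 < 0.25 and r_cut > 0:
        log.warning("minimum pair distance %.3f sigma during run",
                    math.sqrt(min_r2))

    times = params.dt * stride * np.arange(1, n_frames + 1)
    traj = Trajectory(times, frame_pos, frame_vel, frame_pe, frame_ke,
                      frame_xi, box, state=None, params=params,
                      chain_id=config.chain_id, chain_length=config.chain_length)

    if not use_nh:
        e = traj.total_energy
        drift = float(np.max(np.abs(e - e[0]))) / max(abs(float(e[0])), 1e-12)
        if drift > 1e-2:
            raise EnergyDivergenceError(
                f"relative NVE energy drift {drift:.3e} exceeds 1e-2; "
                f"reduce dt (currently {params.dt})")
    return traj


def integrate_nve(config: Configuration, params: SimulationParams) -> Trajectory:
    """Microcanonical velocity-Verlet run; aborts on >1% energy drift."""
    return _integrate(config, params, None)


def integrate_nvt(config: Configuration, params: SimulationParams,
                  T_star: float) -> Trajectory:
    """Canonical run with a single Nose-Hoover thermostat at T*.

    Logs a warning if the kinetic temperature averaged over the
    post-equilibration window misses T* by more than 10%.
    """
    traj = _integrate(config, params, T_star)
    tail = traj.tail(params.equilibration_fraction)
    T_kin = float(np.mean(tail.kinetic_temperature))
    if abs(T_kin - T_star) > 0.10 * T_star:
        log.warning("kinetic temperature %.4f did not settle within 10%% of "
                    "target %.4f after equilibration", T_kin, T_star)
    return traj


def run_state_point(state: StatePoint, system_kind: str = "monomer",
                    params: Optional[SimulationParams] = None,
                    n_particles: int = 4000,
                    chain_length: int = 20,
                    arrangement: str = "auto") -> Trajectory:
    """Simulate one (rho*, T*) state point and return the analysis window.

    Builds a configuration (random placement, falling back to a lattice at
    densities where overlap-free insertion fails), runs NVT, and discards
    the leading `equilibration_fraction` of the sampled frames — with the
    defaults, the last third of a 5000 tau_LJ run (about 1666 tau_LJ).

    For chains, `n_particles` counts beads and must be a multiple of
    `chain_length` (default 200 chains x 20 beads = 4000 beads).
    """
    if system_kind == "monomer":
        if params is None:
            params = SimulationParams()
        cfg = build_configuration(n_particles, state, arrangement=arrangement,
                                  seed=params.seed)
    elif system_kind == "chain":
        if params is None:
            params = chain_defaults()
        if n_particles % chain_length:
            raise ValueError("n_particles must be a multiple of chain_length")
        cfg = build_chain_configuration(n_particles // chain_length,
                                        chain_length, state, seed=params.seed)
    else:
        raise ValueError(f"unknown system_kind {system_kind!r}")
    traj = integrate_nvt(cfg, params, state.T_star)
    out = traj.tail(params.equilibration_fraction)
    out.state = state
    return out
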