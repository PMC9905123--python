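"""Domain types in reduced Lennard-Jones units and configuration builders.

Everything in this package works in reduced units: lengths in units of the
LJ size parameter sigma, energies in units of the well depth epsilon, masses
in units of the particle mass m, and temperature in units of epsilon/k_B.
The LJ time unit is tau_LJ = sqrt(m sigma^2 / epsilon).  With
epsilon = sigma = m = k_B = 1 all of these are unity and starred quantities
(rho*, T*) are plain numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ReducedUnits",
    "StatePoint",
    "Configuration",
    "SimulationParams",
    "build_configuration",
    "build_chain_configuration",
    "make_fixture",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when a random builder cannot place particles without overlap."""


@dataclass(frozen=True)
class ReducedUnits:
    """The reduced (LJ) unit system.  All base constants are exactly 1."""

    epsilon: float = 1.0
    sigma: float = 1.0
    mass: float = 1.0
    k_B: float = 1.0

    @property
    def tau_LJ(self) -> float:
        """LJ time unit sqrt(m sigma^2 / epsilon); equal to 1 in reduced units."""
        return math.sqrt(self.mass * self.sigma**2 / self.epsilon)


@dataclass(frozen=True)
class StatePoint:
    """A thermodynamic state point: number density rho* and temperature T*."""

    rho_star: float
    T_star: float

    def __post_init__(self) -> None:
        if not self.rho_star > 0:
            raise ValueError(f"rho_star must be positive, got {self.rho_star}")
        if not self.T_star > 0:
            raise ValueError(f"T_star must be positive, got {self.T_star}")


@dataclass
class SimulationParams:
    """Integration and force-field parameters.

    Defaults follow the monomer protocol: cutoff 6.85 sigma, time step
    0.005 tau_LJ, Nose-Hoover damping time 1.0 tau_LJ.  Chain systems use
    dt = 0.001 and damping 10.0 (see :func:`chain_defaults`).  A cutoff of
    exactly 0 disables pair interactions (ideal gas), used for thermostat
    validation.

    `shift_energy` shifts the pair potential so it vanishes at the cutoff
    (forces unchanged).  Production runs use plain truncation (default);
    the shifted form gives a smooth conserved energy for NVE diagnostics,
    where the truncation discontinuity would otherwise dominate the drift.
    """

    r_cut: float = 6.85
    dt: float = 0.005
    n_steps: int = 1_000_000
    thermostat_damping: float = 1.0
    k_bond: float = 75000.0
    seed: int = 0
    equilibration_fraction: float = 2.0 / 3.0
    sampling_stride: int = 100
    neighbor_skin: float = 0.4
    shift_energy: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if self.r_cut < 0:
            raise ValueError("r_cut must be >= 0")

    def replace(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


def chain_defaults(**overrides) -> SimulationParams:
    """Parameters for bead-spring chains: smaller dt (stiff bonds), slower thermostat."""
    kw = dict(dt=0.001, n_steps=5_000_000, thermostat_damping=10.0,
              sampling_stride=500)
    kw.update(overrides)
    return SimulationParams(**kw)


@dataclass
class Configuration:
    """A particle configuration in a cubic periodic box.

    Positions are always wrapped into [0, box_side).  ``chain_id`` is None
    for monomer systems; for chain systems every chain occupies
    ``chain_length`` consecutive particle indices and bonds connect
    consecutive beads of the same chain.
    """

    positions: np.ndarray
    velocities: np.ndarray
    box_side: float
    chain_id: Optional[np.ndarray] = None
    chain_length: Optional[int] = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have the same shape")
        if self.chain_id is not None:
            self.chain_id = np.ascontiguousarray(self.chain_id, dtype=np.int64)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def rho_star(self) -> float:
        return self.n_particles / self.box_side**3

    @property
    def n_chains(self) -> int:
        if self.chain_id is None:
            raise ValueError("monomer configuration has no chains")
        return int(self.chain_id.max()) + 1

    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) array of bonded index pairs (consecutive beads)."""
        if self.chain_id is None:
            return np.empty((0, 2), dtype=np.int64)
        i = np.arange(self.n_particles - 1)
        mask = self.chain_id[i] == self.chain_id[i + 1]
        return np.column_stack([i[mask], i[mask] + 1])

    def wrap(self) -> None:
        """Wrap positions back into [0, box_side) in place."""
        np.mod(self.positions, self.box_side, out=self.positions)


def box_side_for(n: int, rho_star: float) -> float:
    """Cubic box side for n particles at number density rho*."""
    return (n / rho_star) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# velocity initialisation
# ---------------------------------------------------------------------------

def _init_velocities(n: int, T_star: float, rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities with exactly zero total momentum and
    kinetic energy rescaled to (3/2)(n-1) k_B T* (momentum removal eats
    three degrees of freedom; we count 3(n-1))."""
    if n == 1:
        return np.zeros((1, 3))
    v = rng.normal(0.0, math.sqrt(T_star), size=(n, 3))
    v -= v.mean(axis=0)
    ke = 0.5 * float(np.sum(v * v))
    target = 1.5 * (n - 1) * T_star
    if ke > 0:
        v *= math.sqrt(target / ke)
    return v


# ---------------------------------------------------------------------------
# monomer builders
# ---------------------------------------------------------------------------

_MIN_SEP = 0.85  # overlap rejection radius for random placement, in sigma


def _random_positions(n: int, box: float, min_sep: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Sequential random insertion with a cell grid for overlap checks."""
    cell = max(min_sep, 1e-9)
    ncell = max(1, int(box / cell))
    cell = box / ncell
    grid: dict[tuple, list[int]] = {}
    pos = np.empty((n, 3))
    min_sep2 = min_sep * min_sep
    budget = 100 * n
    placed = 0
    while placed < n:
        if budget <= 0:
            raise PlacementError(
                f"could not place {n} particles at separation {min_sep} "
                f"after the attempt budget; density too high for random "
                f"placement — use arrangement='lattice'")
        budget -= 1
        p = rng.uniform(0.0, box, size=3)
        ci = tuple((p // cell).astype(int) % ncell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = ((ci[0] + dx) % ncell, (ci[1] + dy) % ncell,
                           (ci[2] + dz) % ncell)
                    for j in grid.get(key, ()):
                        d = p - pos[j]
                        d -= box * np.round(d / box)
                        if float(d @ d) < min_sep2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pos[placed] = p
            grid.setdefault(ci, []).append(placed)
            placed += 1
    return pos


def _lattice_positions(n: int, box: float) -> np.ndarray:
    """Simple-cubic lattice filling; sites beyond n are left vacant."""
    m = math.ceil(n ** (1.0 / 3.0))
    a = box / m
    idx = np.arange(m**3)[:n]
    i, j, k = idx // (m * m), (idx // m) % m, idx % m
    return (np.column_stack([i, j, k]) + 0.5) * a


def build_configuration(n: int, state: StatePoint,
                        arrangement: str = "random",
                        seed: int = 0) -> Configuration:
    """Build a monomer configuration at a state point.

    Parameters
    ----------
    n : particle count.
    state : target (rho*, T*); fixes the box side (n/rho*)^(1/3) and the
        initial kinetic temperature.
    arrangement : "random" (overlap-rejecting insertion, minimum pair
        separation 0.85 sigma), "lattice" (simple cubic), or "auto"
        (random with lattice fallback at high density).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    box = box_side_for(n, state.rho_star)
    if arrangement == "auto":
        try:
            pos = _random_positions(n, box, _MIN_SEP, rng)
        except PlacementError:
            pos = _lattice_positions(n, box)
    elif arrangement == "random":
        pos = _random_positions(n, box, _MIN_SEP, rng)
    elif arrangement == "lattice":
        pos = _lattice_positions(n, box)
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    vel = _init_velocities(n, state.T_star, rng)
    cfg = Configuration(pos, vel, box)
    cfg.wrap()
    return cfg


# ---------------------------------------------------------------------------
# chain builder
# ---------------------------------------------------------------------------

def build_chain_configuration(n_chains: int, chain_length: int,
                              state: StatePoint, seed: int = 0) -> Configuration:
    """Place bead-spring chains as self-avoiding random walks with bond
    length sigma.  The box is sized from the total bead count and rho*.
    """
    if n_chains < 1 or chain_length < 2:
        raise ValueError("need n_chains >= 1 and chain_length >= 2")
    n = n_chains * chain_length
    rng = np.random.default_rng(seed)
    box = box_side_for(n, state.rho_star)

    cell = _MIN_SEP
    ncell = max(1, int(box / cell))
    cell = box / ncell
    grid: dict[tuple, list[int]] = {}
    pos = np.empty((n, 3))
    min_sep2 = _MIN_SEP**2

    def clashes(p: np.ndarray, skip: int) -> bool:
        ci = (p // cell).astype(int) % ncell
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = ((ci[0] + dx) % ncell, (ci[1] + dy) % ncell,
                           (ci[2] + dz) % ncell)
                    for j in grid.get(key, ()):
                        if j == skip:
                            continue
                        d = p - pos[j]
                        d -= box * np.round(d / box)
                        if float(d @ d) < min_sep2:
                            return True
        return False

    def register(p: np.ndarray, i: int) -> None:
        ci = tuple((p // cell).astype(int) % ncell)
        grid.setdefault(ci, []).append(i)

    budget = 200 * n
    bead = 0
    for c in range(n_chains):
        start = bead
        while bead < start + chain_length:
            if budget <= 0:
                raise PlacementError(
                    f"self-avoiding chain placement failed at chain {c}; "
                    f"density {state.rho_star} too high for random growth")
            budget -= 1
            if bead == start:
                p = rng.uniform(0.0, box, size=3)
                if clashes(p, -1):
                    continue
            else:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                p = np.mod(pos[bead - 1] + u, box)
                # the previous bead sits at exactly sigma; don't count it
                if clashes(p, bead - 1):
                    continue
            pos[bead] = p
            register(p, bead)
            bead += 1

    vel = _init_velocities(n, state.T_star, rng)

    # The stiff bond-stretch modes (omega ~ 2 sqrt(k_b)) exchange energy
    # with the soft LJ bath only on Landau-Teller (exponentially long)
    # timescales, so each near-integrable mode keeps roughly the energy it
    # starts with.  Bonds are built at exactly sigma (zero potential), so
    # plain Maxwell-Boltzmann velocities would leave every stretch mode at
    # half its canonical energy.  Boost the along-bond relative velocity by
    # sqrt(2) so each mode starts with its full canonical mean energy and
    # <(r - sigma)^2> relaxes to k_B T / (2 k_b).
    # independent Gaussian kicks add the missing T/2 per stretch mode
    # (pairwise opposite, so total momentum stays exactly zero)
    for c in range(n_chains):
        for i in range(c * chain_length, (c + 1) * chain_length - 1):
            d = pos[i + 1] - pos[i]
            d -= box * np.round(d / box)
            u = d / np.linalg.norm(d)
            w = rng.normal(0.0, math.sqrt(2.0 * state.T_star))
            vel[i + 1] += 0.5 * w * u
            vel[i] -= 0.5 * w * u

    chain_id = np.repeat(np.arange(n_chains), chain_length)
    cfg = Configuration(pos, vel, box, chain_id=chain_id,
                        chain_length=chain_length)
    cfg.wrap()
    return cfg


# ---------------------------------------------------------------------------
# test fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, *, seed: int = 0, **params) -> Configuration:
    """Deterministic fixture configurations for analysis validation.

    kind="ideal_gas": uniform independent positions (overlaps allowed);
        params: n, rho_star, T_star (optional, default 1.0).
    kind="multi_cluster": compact blobs of given sizes with internal
        nearest-neighbour spacing < 1.3 sigma and inter-blob gaps > 2 sigma;
        params: sizes (sequence), box_side.
    kind="cube_corners": 8 particles at the corners of a cube;
        params: side, box_side (default 10 * side).
    """
    rng = np.random.default_rng(seed)
    if kind == "ideal_gas":
        n = int(params["n"])
        rho = float(params["rho_star"])
        T = float(params.get("T_star", 1.0))
        box = box_side_for(n, rho)
        pos = rng.uniform(0.0, box, size=(n, 3))
        return Configuration(pos, _init_velocities(n, T, rng), box)

    if kind == "multi_cluster":
        sizes = [int(s) for s in params["sizes"]]
        box = float(params["box_side"])
        radii = [1.0 + 1.2 * s ** (1.0 / 3.0) for s in sizes]
        centers: list[np.ndarray] = []
        for r, s in zip(radii, sizes):
            for _ in range(10_000):
                c = rng.uniform(0.0, box, size=3)
                ok = True
                for c2, r2 in zip(centers, radii):
                    d = c - c2
                    d -= box * np.round(d / box)
                    if np.linalg.norm(d) < r + r2 + 2.5:
                        ok = False
                        break
                if ok:
                    centers.append(c)
                    break
            else:
                raise PlacementError(
                    f"cannot fit {len(sizes)} disjoint blobs in box {box}")
        chunks = []
        for c, r, s in zip(centers, radii, sizes):
            blob = np.empty((s, 3))
            blob[0] = c
            for i in range(1, s):
                while True:
                    u = rng.normal(size=3)
                    u = u / np.linalg.norm(u) * rng.uniform(0.9, 1.2)
                    p = blob[rng.integers(i)] + u
                    if np.linalg.norm(p - c) <= r:
                        blob[i] = p
                        break
            chunks.append(blob)
        pos = np.mod(np.vstack(chunks), box)
        return Configuration(pos, np.zeros_like(pos), box)

    if kind == "cube_corners":
        a = float(params["side"])
        box = float(params.get("box_side", 10.0 * a))
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                            for k in (0, 1)], dtype=float) * a
        pos = corners + (box - a) / 2.0
        return Configuration(pos, np.zeros_like(pos), box)

    raise ValueError(f"unknown fixture kind {kind!r}")
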