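"""Phase-boundary estimators from trajectory observables.

Four densities bound the two-phase region at a given temperature:

* rho_L (liquid binodal): divide the box into cubic bins of side ~2 sigma
  and pool the per-bin occupancy counts over the analysis frames.  The
  probability P0 of an empty bin decreases with density; rho_L is the
  density where P0 first vanishes (drops below a small threshold, linearly
  interpolated between scan points).
* rho_V (vapor binodal): the mean size of the per-frame largest cluster,
  <n_lar>/n_m, grows rapidly on entering the coexistence region; rho_V is
  the density of steepest growth of log <n_lar> on the low-density side.
* rho_sL (liquid-side spinodal): the mean size over *all* clusters <n>
  grows rapidly at a higher density; the density of steepest growth of
  log <n> is the primary estimate, cross-checked against the sudden drop
  in the specific heat C_v.
* rho_sV (vapor-side spinodal): C_v(rho) shows sudden spikes inside the
  spinodal region; the tallest spike on the low-density side marks rho_sV.

C_v is the canonical fluctuation estimator var(E)/(k_B T*^2) on the total
energy per system.  The surface tension of a droplet follows from energy
equipartition of its shape fluctuations, sigma_ten = k_B T / u^2, with u^2
the time variance of the droplet's radius of gyration; system-spanning
droplets are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import Trajectory

__all__ = [
    "OccupancyHistogram",
    "ThermoStats",
    "PhaseBoundaryEstimate",
    "UndefinedBoundary",
    "occupancy_histogram",
    "locate_binodal_liquid",
    "locate_binodal_vapor",
    "locate_spinodal_low",
    "locate_spinodal_high",
    "specific_heat",
    "surface_tension",
]

log = logging.getLogger("vdwphase")

DEFAULT_BIN_SIDE = 2.0
DEFAULT_P0_THRESHOLD = 0.005
SPIKE_FACTOR = 2.0          # a C_v spike must exceed 2x the baseline median
MIN_DROPLET_SIZE = 50       # smallest droplet used for surface tension


class UndefinedBoundary(Exception):
    """A locator could not identify its boundary in the scanned range.

    Carries a human-readable reason; callers that scan grids catch this
    and record the boundary as undefined rather than fabricating a value.
    """


@dataclass
class OccupancyHistogram:
    """Pooled occupancy distribution of cubic bins over analysis frames."""

    bin_side: float
    counts_distribution: np.ndarray   # P_k for k = 0, 1, 2, ...
    n_bins: int
    n_frames_averaged: int

    @property
    def P0(self) -> float:
        return float(self.counts_distribution[0])


@dataclass
class ThermoStats:
    """Fluctuation thermodynamics of one state point."""

    T_star: float
    C_v: Optional[float] = None        # per system, in k_B
    sigma_ten: Optional[float] = None  # k_B T / u^2
    u_sq: Optional[float] = None       # time variance of droplet R_g


@dataclass
class PhaseBoundaryEstimate:
    """The four boundary densities at one temperature.

    Any entry may be None (undefined in the scanned range).  `methods`
    maps field names to short method tags; `uncertainty` holds the
    scan-grid half-spacing at each estimate.
    """

    T_star: float
    rho_V: Optional[float] = None
    rho_sV: Optional[float] = None
    rho_sL: Optional[float] = None
    rho_L: Optional[float] = None
    methods: dict = field(default_factory=dict)
    uncertainty: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def ordering_ok(self) -> Optional[bool]:
        """Check rho_V < rho_sV <= rho_sL < rho_L; None if any undefined."""
        vals = (self.rho_V, self.rho_sV, self.rho_sL, self.rho_L)
        if any(v is None for v in vals):
            return None
        return vals[0] < vals[1] <= vals[2] < vals[3]


# ---------------------------------------------------------------------------
# occupancy histogram and rho_L
# ---------------------------------------------------------------------------

def occupancy_histogram(traj: Trajectory,
                        bin_side: float = DEFAULT_BIN_SIDE) -> OccupancyHistogram:
    """Occupancy distribution of cubic bins of side ~bin_side.

    The grid has floor(box/bin_side) bins per axis anchored at the origin;
    the residual sliver is merged into the last bin of each axis (so the
    actual bin side is box/m).  Counts are pooled over all frames; P_k is
    the fraction of (bin, frame) observations holding exactly k particles.
    """
    box = traj.box_side
    if bin_side > box:
        raise ValueError("bin_side exceeds the box side")
    m = int(box / bin_side)
    if m**3 < 8:
        raise ValueError(
            f"grid of {m}^3 bins is too coarse; need at least 8 bins "
            f"(box {box:.3f}, bin side {bin_side})")
    nbins = m**3
    edges = box / m
    pooled = np.zeros(0, dtype=np.int64)
    for f in range(traj.n_frames):
        idx = (traj.positions[f] // edges).astype(np.int64)
        np.clip(idx, 0, m - 1, out=idx)   # merge sliver into last bin
        flat = (idx[:, 0] * m + idx[:, 1]) * m + idx[:, 2]
        occ = np.bincount(flat, minlength=nbins)
        kmax = occ.max()
        hist = np.bincount(occ)
        if len(hist) > len(pooled):
            pooled = np.pad(pooled, (0, len(hist) - len(pooled)))
        pooled[:len(hist)] += hist
    P = pooled / pooled.sum()
    return OccupancyHistogram(edges, P, nbins, traj.n_frames)


def locate_binodal_liquid(rho: Sequence[float], p0: Sequence[float],
                          threshold: float = DEFAULT_P0_THRESHOLD) -> float:
    """Liquid binodal: smallest density where P0 first drops below the
    threshold, linearly interpolated between adjacent scan points."""
    rho = np.asarray(rho, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if len(rho) < 3:
        raise ValueError("need at least 3 scan points")
    if np.any(np.diff(rho) <= 0):
        raise ValueError("densities must be strictly increasing")
    below = p0 < threshold
    if not below.any():
        raise UndefinedBoundary(
            f"P0 never drops below {threshold} in the scanned range "
            f"(min P0 = {p0.min():.4g})")
    k = int(np.argmax(below))
    if k == 0:
        return float(rho[0])
    # interpolate the crossing between points k-1 and k
    x0, x1 = rho[k - 1], rho[k]
    y0, y1 = p0[k - 1], p0[k]
    if y0 == y1:
        return float(x1)
    return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0))


# ---------------------------------------------------------------------------
# cluster-growth locators
# ---------------------------------------------------------------------------

def _max_log_slope(rho: np.ndarray, y: np.ndarray,
                   allowed: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Density (midpoint convention) of the maximum discrete slope of
    log y, over intervals whose index is allowed.  Returns
    (rho_mid, max_slope, all_slopes)."""
    logy = np.log(np.maximum(y, 1e-300))
    slopes = np.diff(logy) / np.diff(rho)
    masked = np.where(allowed, slopes, -np.inf)
    k = int(np.argmax(masked))
    return float(0.5 * (rho[k] + rho[k + 1])), float(slopes[k]), slopes


def locate_binodal_vapor(rho: Sequence[float],
                         nlar: Sequence[float],
                         n_m: Optional[float] = None) -> float:
    """Vapor binodal: density of steepest growth of log <n_lar> on the
    low-density side (below the curve's half-maximum), midpoint convention.
    `nlar` may be given raw with n_m for normalisation, or pre-normalised.
    """
    rho = np.asarray(rho, dtype=float)
    y = np.asarray(nlar, dtype=float)
    if n_m is not None:
        y = y / n_m
    if len(rho) < 5:
        raise ValueError("need at least 5 scan points")
    half = y.min() + 0.5 * (y.max() - y.min())
    above = y >= half
    if above.all() or not above.any():
        raise UndefinedBoundary("largest-cluster curve has no low-density rise")
    rho_half = rho[int(np.argmax(above))]
    allowed = 0.5 * (rho[:-1] + rho[1:]) <= rho_half
    if not allowed.any():
        allowed = np.zeros(len(rho) - 1, dtype=bool)
        allowed[0] = True
    rho_v, smax, slopes = _max_log_slope(rho, y, allowed)
    finite = slopes[np.isfinite(slopes)]
    noise_floor = 3.0 * float(np.median(np.abs(finite))) if len(finite) else 0.0
    if smax <= noise_floor:
        raise UndefinedBoundary(
            f"largest-cluster growth (max log-slope {smax:.3g}) does not "
            f"exceed the noise floor {noise_floor:.3g}")
    return rho_v


def locate_spinodal_high(rho: Sequence[float], n_mean: Sequence[float],
                         cv: Optional[Sequence[float]] = None,
                         grid_tolerance: int = 2):
    """Liquid-side spinodal from the rapid growth of the all-cluster mean
    size <n>, cross-checked against the sudden drop in C_v.

    Returns (rho_sL, rho_from_cv, consistent).  rho_from_cv is None when no
    C_v curve is given; `consistent` is False (and a warning logged) when
    the two estimates disagree by more than `grid_tolerance` grid spacings.
    """
    rho = np.asarray(rho, dtype=float)
    y = np.asarray(n_mean, dtype=float)
    if len(rho) < 5:
        raise ValueError("need at least 5 scan points")
    allowed = np.ones(len(rho) - 1, dtype=bool)
    rho_sl, smax, _ = _max_log_slope(rho, y, allowed)
    if smax <= 0:
        raise UndefinedBoundary("mean cluster size never grows")

    rho_cv = None
    consistent = True
    if cv is not None:
        c = np.asarray(cv, dtype=float)
        dslope = np.diff(c) / np.diff(rho)
        k = int(np.argmin(dslope))          # steepest decrease
        rho_cv = float(0.5 * (rho[k] + rho[k + 1]))
        spacing = float(np.median(np.diff(rho)))
        if abs(rho_cv - rho_sl) > grid_tolerance * spacing:
            consistent = False
            log.warning("rho_sL cross-check: <n>-growth at %.3f vs C_v drop "
                        "at %.3f differ by more than %d grid spacings",
                        rho_sl, rho_cv, grid_tolerance)
    return rho_sl, rho_cv, consistent


def locate_spinodal_low(rho: Sequence[float], cv: Sequence[float],
                        spike_factor: float = SPIKE_FACTOR) -> float:
    """Vapor-side spinodal: the tallest qualifying C_v spike on the
    low-density side (below the global C_v drop).

    A spike is a local maximum that exceeds both neighbours and is at
    least `spike_factor` times the low-density baseline median.
    """
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(cv, dtype=float)
    if len(rho) < 5:
        raise ValueError("need at least 5 scan points")
    dslope = np.diff(c) / np.diff(rho)
    drop = int(np.argmin(dslope))           # index of steepest C_v decrease
    hi = max(drop + 1, 3)                   # spikes live below the drop
    baseline = float(np.median(c[:hi]))
    best = None
    best_h = -np.inf
    for k in range(1, hi):
        if k + 1 >= len(c):
            break
        if c[k] > c[k - 1] and c[k] > c[k + 1] and c[k] >= spike_factor * baseline:
            if c[k] > best_h:
                best_h = c[k]
                best = k
    if best is None:
        raise UndefinedBoundary(
            f"no C_v spike exceeds {spike_factor}x the baseline median "
            f"({baseline:.3g}) below the C_v drop")
    return float(rho[best])


# ---------------------------------------------------------------------------
# fluctuation thermodynamics
# ---------------------------------------------------------------------------

def specific_heat(traj: Trajectory, min_frames: int = 100,
                  use_total_energy: bool = True) -> float:
    """Canonical specific heat per system from energy fluctuations,
    C_v = (<E^2> - <E>^2) / (k_B T*^2), over the analysis window.

    Uses total energy E = KE + PE by default; set use_total_energy=False
    for the potential-only variant plus the analytic kinetic term
    (3/2)(n-1) k_B.
    """
    if traj.state is None:
        raise ValueError("trajectory carries no state point (need T*)")
    if traj.n_frames < min_frames:
        raise ValueError(
            f"need at least {min_frames} analysis frames, got {traj.n_frames}")
    T = traj.state.T_star
    if use_total_energy:
        e = traj.total_energy
        return float(np.var(e) / T**2)
    e = traj.potential_energy
    return float(np.var(e) / T**2 + 1.5 * (traj.n_particles - 1))


def surface_tension(rg_series: Sequence[float], T_star: float,
                    sizes: Optional[Sequence[float]] = None,
                    spanning: Optional[Sequence[bool]] = None,
                    min_size: int = MIN_DROPLET_SIZE,
                    min_frames: int = 100) -> ThermoStats:
    """Surface tension from droplet shape fluctuations.

    sigma_ten = k_B T* / u^2 where u^2 is the time variance of the
    droplet's radius of gyration.  The estimator refuses (returns
    sigma_ten=None) for short series, droplets below `min_size`, droplets
    that ever span the box, or a constant series.
    """
    rg = np.asarray(rg_series, dtype=float)
    if len(rg) < min_frames:
        return ThermoStats(T_star=T_star)
    if spanning is not None and bool(np.any(spanning)):
        return ThermoStats(T_star=T_star)
    if sizes is not None and float(np.median(sizes)) < min_size:
        return ThermoStats(T_star=T_star)
    u_sq = float(np.var(rg))
    if u_sq <= 0.0:
        return ThermoStats(T_star=T_star, u_sq=0.0)
    return ThermoStats(T_star=T_star, sigma_ten=T_star / u_sq, u_sq=u_sq)
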