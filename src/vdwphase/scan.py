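"""Orchestration of (rho*, T*) grids and phase-diagram assembly.

`run_scan` simulates every grid point, applies all per-state-point
estimators (P0, cluster statistics, C_v, surface tension) and collects one
table row per point; `assemble_boundaries` turns the table into
binodal/spinodal lines per temperature and fits the critical point.

The critical-point fit uses the mean-field order-parameter law
(rho_L - rho_V) = A (T_c - T)^(1/2) — so (rho_L - rho_V)^2 is linear in T
and T_c is its root — together with the rectilinear-diameter law
(rho_L + rho_V)/2 = rho_c + b (T_c - T) evaluated at T_c for rho_c.

Two presets are provided: "paper" (4000 particles, r_cut 6.85 sigma, 1e6
steps) matching the full monomer protocol, and "desk" (1000 particles,
r_cut 4 sigma, 5e4 steps) for workstation-scale scans.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import boundaries as bnd
from .boundaries import (PhaseBoundaryEstimate, UndefinedBoundary,
                         locate_binodal_liquid, locate_binodal_vapor,
                         locate_spinodal_high, locate_spinodal_low,
                         occupancy_histogram, specific_heat, surface_tension)
from .clusters import trajectory_cluster_stats
from .engine import Trajectory, run_state_point
from .system import SimulationParams, StatePoint, chain_defaults

__all__ = [
    "PRESETS",
    "PhaseDiagram",
    "preset_params",
    "analyze_state_point",
    "run_scan",
    "assemble_boundaries",
]

log = logging.getLogger("vdwphase")

PRESETS = {
    "desk": dict(n_particles=1000, r_cut=4.0, n_steps=50_000),
    "paper": dict(n_particles=4000, r_cut=6.85, n_steps=1_000_000),
}

TABLE_COLUMNS = ["rho_star", "T_star", "seed", "n_particles", "P0",
                 "mean_n", "mean_nlar", "mean_rg", "mean_rg_lar",
                 "Cv", "sigma_ten", "u_sq", "param_hash", "error"]


def preset_params(preset: str, system_kind: str = "monomer",
                  **overrides) -> tuple[SimulationParams, int]:
    """(SimulationParams, n_particles) for a named preset."""
    cfg = dict(PRESETS[preset])
    n = cfg.pop("n_particles")
    n = overrides.pop("n_particles", n)
    if system_kind == "chain":
        base = chain_defaults()
        # chain protocol keeps its own step counts (dt is 5x smaller):
        # 5e6 steps at full scale, 2.5e5 at desk scale = the same tau_LJ span
        cfg["n_steps"] = 250_000 if preset == "desk" else base.n_steps
        cfg.update(overrides)
        params = base.replace(**cfg)
    else:
        cfg.update(overrides)
        params = SimulationParams(**cfg)
    return params, n


@dataclass
class PhaseDiagram:
    """Assembled binodal/spinodal lines with a critical-point estimate."""

    estimates: list            # PhaseBoundaryEstimate per temperature
    T_c: Optional[float] = None
    rho_c: Optional[float] = None
    amplitude: Optional[float] = None   # A in (rho_L - rho_V) = A sqrt(T_c - T)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "T_c": self.T_c,
            "rho_c": self.rho_c,
            "amplitude": self.amplitude,
            "metadata": self.metadata,
            "boundaries": [
                {"T_star": e.T_star, "rho_V": e.rho_V, "rho_sV": e.rho_sV,
                 "rho_sL": e.rho_sL, "rho_L": e.rho_L,
                 "methods": e.methods, "warnings": e.warnings}
                for e in self.estimates
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# per-state-point analysis
# ---------------------------------------------------------------------------

def analyze_state_point(traj: Trajectory,
                        contact_cutoff: float = 1.3,
                        bin_side: float = 2.0,
                        level: str = "atom") -> dict:
    """All scalar estimators for one analysed trajectory window."""
    occ = occupancy_histogram(traj, bin_side)
    stats = trajectory_cluster_stats(traj, contact_cutoff, level)
    try:
        cv = specific_heat(traj)
    except ValueError:
        cv = np.nan
    T = traj.state.T_star if traj.state else np.nan
    ts = surface_tension(stats.rg_series_droplet, T,
                         sizes=stats.size_series_droplet,
                         spanning=stats.spanning_series_droplet)
    return {
        "P0": occ.P0,
        "mean_n": stats.mean_size,
        "mean_nlar": stats.mean_largest_size,
        "mean_rg": stats.mean_rg,
        "mean_rg_lar": stats.mean_rg_largest,
        "Cv": cv,
        "sigma_ten": ts.sigma_ten if ts.sigma_ten is not None else np.nan,
        "u_sq": ts.u_sq if ts.u_sq is not None else np.nan,
    }


def _param_hash(params: SimulationParams) -> str:
    """Short stable digest of the integration parameters for provenance."""
    import hashlib
    blob = repr(sorted(vars(params).items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _state_seed(base_seed: int, i_rho: int, i_T: int, i_rep: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), i_rho, i_T, i_rep])
    return int(ss.generate_state(1)[0] % (2**31))


def run_scan(densities: Sequence[float], temperatures: Sequence[float],
             system_kind: str = "monomer",
             params: Optional[SimulationParams] = None,
             n_particles: Optional[int] = None,
             preset: str = "desk",
             seeds: Sequence[int] = (0,),
             contact_cutoff: float = 1.3,
             bin_side: float = 2.0,
             checkpoint: Optional[str] = None,
             chain_length: int = 20) -> pd.DataFrame:
    """Run every (rho*, T*, seed) state point and tabulate the estimators.

    When `checkpoint` names a CSV file, completed rows are reloaded and
    skipped on restart, and each new row is appended as it completes.
    Individual state-point failures are recorded in the `error` column and
    the scan continues.  Cluster statistics are computed at chain level
    for chain systems.
    """
    densities = list(densities)
    temperatures = list(temperatures)
    if not densities or not temperatures:
        raise ValueError("density and temperature grids must be non-empty")
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError("densities must be strictly increasing")

    if params is None:
        params, n_default = preset_params(preset, system_kind)
    else:
        n_default = PRESETS[preset]["n_particles"]
    n = n_particles if n_particles is not None else n_default
    level = "chain" if system_kind == "chain" else "atom"

    done: set[tuple] = set()
    rows: list[dict] = []
    ckpt = Path(checkpoint) if checkpoint else None
    if ckpt is not None and ckpt.exists():
        prev = pd.read_csv(ckpt)
        rows = prev.to_dict("records")
        done = {(round(r["rho_star"], 10), round(r["T_star"], 10),
                 int(r["seed"])) for r in rows}

    for i_T, T in enumerate(temperatures):
        for i_rho, rho in enumerate(densities):
            for i_rep, base_seed in enumerate(seeds):
                seed = _state_seed(base_seed, i_rho, i_T, i_rep)
                key = (round(rho, 10), round(T, 10), seed)
                if key in done:
                    continue
                row = {"rho_star": rho, "T_star": T, "seed": seed,
                       "n_particles": n, "error": "",
                       "param_hash": _param_hash(params)}
                try:
                    p = params.replace(seed=seed)
                    traj = run_state_point(StatePoint(rho, T), system_kind,
                                           p, n_particles=n,
                                           chain_length=chain_length)
                    row.update(analyze_state_point(traj, contact_cutoff,
                                                   bin_side, level))
                except Exception as exc:   # record and continue
                    log.warning("state point (rho=%.3f, T=%.3f) failed: %s",
                                rho, T, exc)
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
                if ckpt is not None:
                    pd.DataFrame(rows).to_csv(ckpt, index=False)
                log.info("scan: rho=%.3f T=%.3f done (%d/%d)", rho, T,
                         len(rows), len(densities) * len(temperatures)
                         * len(seeds))
    df = pd.DataFrame(rows)
    for c in TABLE_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return df[TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# boundary assembly and critical point
# ---------------------------------------------------------------------------

def boundaries_at_temperature(sub: pd.DataFrame, T: float,
                              p0_threshold: float = 0.005
                              ) -> PhaseBoundaryEstimate:
    """Apply the four locators to one temperature's scan rows."""
    sub = sub.sort_values("rho_star")
    ok = sub["error"].fillna("").astype(str) == ""
    sub = sub[ok]
    rho = sub["rho_star"].to_numpy()
    est = PhaseBoundaryEstimate(T_star=T)
    spacing = float(np.median(np.diff(rho))) if len(rho) > 1 else np.nan

    def attempt(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (UndefinedBoundary, ValueError) as exc:
            est.warnings.append(f"{name}: {exc}")
            return None

    est.rho_L = attempt("rho_L", locate_binodal_liquid, rho,
                        sub["P0"].to_numpy(), p0_threshold)
    est.methods["rho_L"] = "P0-vanishing"
    nm = sub["n_particles"].to_numpy(dtype=float)
    est.rho_V = attempt("rho_V", locate_binodal_vapor, rho,
                        sub["mean_nlar"].to_numpy() / nm)
    est.methods["rho_V"] = "nlar-growth"
    r = attempt("rho_sL", locate_spinodal_high, rho,
                sub["mean_n"].to_numpy(), sub["Cv"].to_numpy())
    if r is not None:
        est.rho_sL, rho_cv, consistent = r
        est.methods["rho_sL"] = "n-growth(Cv-drop cross-check)"
        if rho_cv is not None:
            est.methods["rho_sL_cv"] = f"{rho_cv:.4f}"
        if not consistent:
            est.warnings.append("rho_sL cross-check disagrees with C_v drop")
    est.rho_sV = attempt("rho_sV", locate_spinodal_low, rho,
                         sub["Cv"].to_numpy())
    est.methods["rho_sV"] = "Cv-spike"
    for k in ("rho_V", "rho_sV", "rho_sL", "rho_L"):
        if getattr(est, k) is not None:
            est.uncertainty[k] = spacing / 2.0
    if est.ordering_ok() is False:
        est.warnings.append("boundary ordering rho_V < rho_sV <= rho_sL < "
                            "rho_L violated")
    return est


def fit_critical_point(temperatures, rho_V, rho_L):
    """Mean-field critical-point fit from binodal branches.

    (rho_L - rho_V)^2 = A^2 (T_c - T) is fit linearly in T; T_c is the
    root.  rho_c comes from the rectilinear-diameter line evaluated at T_c.
    Returns (T_c, rho_c, A).  Needs >= 2 temperatures.
    """
    T = np.asarray(temperatures, dtype=float)
    dV = np.asarray(rho_V, dtype=float)
    dL = np.asarray(rho_L, dtype=float)
    if len(T) < 2:
        raise ValueError("need at least 2 temperatures with both binodal "
                         "branches defined")
    y = (dL - dV) ** 2
    slope, intercept = np.polyfit(T, y, 1)
    if slope >= 0:
        raise ValueError("order parameter does not shrink with T; "
                         "cannot locate T_c")
    T_c = -intercept / slope
    A = float(np.sqrt(-slope))
    d = 0.5 * (dL + dV)
    c1, c0 = np.polyfit(T, d, 1)
    rho_c = float(c0 + c1 * T_c)
    return float(T_c), rho_c, A


def assemble_boundaries(table: pd.DataFrame,
                        p0_threshold: float = 0.005) -> PhaseDiagram:
    """Per-temperature boundary estimates plus the critical-point fit.

    Temperatures whose estimates violate rho_V < rho_L are excluded from
    the critical fit (with a logged warning).  T_c is left undefined when
    fewer than two usable temperatures remain.
    """
    temps = sorted(table["T_star"].unique())
    estimates = [boundaries_at_temperature(table[table["T_star"] == T], T,
                                           p0_threshold) for T in temps]
    usable = [e for e in estimates
              if e.rho_V is not None and e.rho_L is not None
              and e.rho_V < e.rho_L]
    for e in estimates:
        if e.rho_V is not None and e.rho_L is not None and e not in usable:
            log.warning("T*=%.3f violates rho_V < rho_L; excluded from the "
                        "critical fit", e.T_star)
    diagram = PhaseDiagram(estimates=estimates,
                           metadata={"temperatures": temps,
                                     "p0_threshold": p0_threshold,
                                     "beta": 0.5,
                                     "n_usable": len(usable)})
    if len(usable) >= 2:
        try:
            T_c, rho_c, A = fit_critical_point(
                [e.T_star for e in usable],
                [e.rho_V for e in usable],
                [e.rho_L for e in usable])
            diagram.T_c, diagram.rho_c, diagram.amplitude = T_c, rho_c, A
            # above the fitted critical temperature the two phases are
            # indistinguishable: report no boundary densities there
            for e in diagram.estimates:
                if e.T_star >= T_c:
                    e.warnings.append("T* >= fitted T_c; boundaries "
                                      "suppressed")
                    e.rho_V = e.rho_sV = e.rho_sL = e.rho_L = None
            top = max(usable, key=lambda e: e.T_star)
            if not (min(top.rho_V, top.rho_L) <= rho_c
                    <= max(top.rho_V, top.rho_L)):
                log.warning("rho_c=%.3f falls outside the highest-"
                            "temperature binodal pair (%.3f, %.3f)",
                            rho_c, top.rho_V, top.rho_L)
        except ValueError as exc:
            log.warning("critical-point fit failed: %s", exc)
    else:
        log.warning("fewer than 2 usable temperatures; T_c undefined")
    return diagram
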