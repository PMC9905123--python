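"""Occupancy statistics, boundary locators and fluctuation estimators on
constructed curves and fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vdwphase.boundaries import (UndefinedBoundary, locate_binodal_liquid,
                                 locate_binodal_vapor, locate_spinodal_high,
                                 locate_spinodal_low, occupancy_histogram,
                                 specific_heat, surface_tension)
from vdwphase.engine import Trajectory
from vdwphase.system import StatePoint, make_fixture


def traj_from_positions(frames, box, state=None):
    P = np.array(frames, dtype=float)
    F = P.shape[0]
    z = np.zeros(F)
    return Trajectory(np.arange(1.0, F + 1), P, np.zeros_like(P), z.copy(),
                      z.copy(), z.copy(), box, state=state)


# ---------------------------------------------------------------------------
# occupancy histogram
# ---------------------------------------------------------------------------

def test_empty_box_P0_is_one():
    traj = traj_from_positions(np.zeros((1, 0, 3)), 8.0)
    occ = occupancy_histogram(traj, 2.0)
    assert occ.P0 == 1.0


def test_lattice_matched_to_grid_gives_P1():
    m = 4
    box = 2.0 * m
    centers = (np.stack(np.meshgrid(*[np.arange(m)] * 3), -1)
               .reshape(-1, 3) + 0.5) * 2.0
    occ = occupancy_histogram(traj_from_positions([centers], box), 2.0)
    assert occ.counts_distribution[1] == pytest.approx(1.0, abs=1e-12)
    assert occ.P0 == pytest.approx(0.0, abs=1e-12)


def test_occupancy_distribution_sums_to_one():
    rng = np.random.default_rng(3)
    pos = rng.uniform(0, 10.0, size=(4, 100, 3))
    occ = occupancy_histogram(traj_from_positions(pos, 10.0), 2.0)
    assert occ.counts_distribution.sum() == pytest.approx(1.0, abs=1e-12)
    assert occ.n_frames_averaged == 4


def test_occupancy_sliver_merged_into_last_bin():
    # box 9 with bin side 2 -> 4 bins per axis of effective side 2.25
    pos = np.array([[8.9, 8.9, 8.9]])   # lives in the merged sliver
    occ = occupancy_histogram(traj_from_positions([pos], 9.0), 2.0)
    assert occ.n_bins == 64
    assert occ.bin_side == pytest.approx(2.25)
    # exactly one occupied bin
    assert occ.counts_distribution[1] == pytest.approx(1 / 64)


def test_occupancy_grid_too_coarse_fails():
    traj = traj_from_positions(np.zeros((1, 2, 3)), 3.0)
    with pytest.raises(ValueError, match="too coarse"):
        occupancy_histogram(traj, 2.0)


def test_ideal_gas_occupancy_poisson_single_density():
    """Uniform positions: P0 matches the Poisson law exp(-rho * V_bin)."""
    rho = 0.2
    vals = []
    for seed in range(10):
        cfg = make_fixture("ideal_gas", n=4000, rho_star=rho, seed=seed)
        occ = occupancy_histogram(
            traj_from_positions([cfg.positions], cfg.box_side), 2.0)
        vals.append(occ.P0)
    expected = np.exp(-rho * occ.bin_side**3)
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - expected) < 3 * se + 1e-4


@settings(deadline=None, max_examples=15, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(10, 300))
def test_occupancy_normalisation_property(seed, n):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 12.0, size=(2, n, 3))
    occ = occupancy_histogram(traj_from_positions(pos, 12.0), 2.0)
    assert occ.counts_distribution.sum() == pytest.approx(1.0, abs=1e-12)
    assert (occ.counts_distribution >= 0).all()


# ---------------------------------------------------------------------------
# rho_L locator
# ---------------------------------------------------------------------------

def test_binodal_liquid_linear_crossing():
    rho = np.linspace(0.3, 0.7, 41)
    p0 = np.maximum(0.0, 0.5 - rho)
    assert locate_binodal_liquid(rho, p0, 0.005) == pytest.approx(0.495,
                                                                  abs=1e-9)


def test_binodal_liquid_never_crossing_flags():
    rho = np.linspace(0.3, 0.7, 11)
    with pytest.raises(UndefinedBoundary):
        locate_binodal_liquid(rho, 0.2 - 0.1 * (rho - 0.3), 0.005)


def test_binodal_liquid_interpolates_between_grid_points():
    rho = np.array([0.55, 0.58, 0.61, 0.64, 0.67, 0.70])
    p0 = np.array([0.05, 0.03, 0.012, 0.002, 0.0, 0.0])
    got = locate_binodal_liquid(rho, p0, 0.005)
    # crossing between 0.61 and 0.64: 0.61 + 0.03*(0.012-0.005)/(0.012-0.002)
    assert got == pytest.approx(0.631, abs=1e-9)


# ---------------------------------------------------------------------------
# rho_V locator
# ---------------------------------------------------------------------------

def test_binodal_vapor_logistic_inflection():
    rho = np.arange(0.01, 0.101, 0.01)
    y = 0.01 + 1.0 / (1.0 + np.exp(-(rho - 0.05) / 0.004))
    got = locate_binodal_vapor(rho, y)
    assert got == pytest.approx(0.05, abs=0.011)


def test_binodal_vapor_flat_curve_undefined():
    rho = np.linspace(0.01, 0.1, 10)
    with pytest.raises(UndefinedBoundary):
        locate_binodal_vapor(rho, 1000.0 + 10.0 * rho)


def test_binodal_vapor_step_midpoint():
    rho = np.array([0.01, 0.02, 0.03, 0.04, 0.06, 0.08, 0.10])
    y = np.array([10.0, 10, 10, 10, 3500, 3500, 3500])
    got = locate_binodal_vapor(rho, y, n_m=4000)
    assert got == pytest.approx(0.05, abs=1e-9)


# ---------------------------------------------------------------------------
# spinodal locators
# ---------------------------------------------------------------------------

def test_spinodal_low_single_spike():
    rho = np.arange(0.02, 0.22, 0.02)
    cv = np.full_like(rho, 1.0)
    cv[4] = 5.0                     # spike at rho = 0.10
    cv[-1] = 0.2                    # high-density drop
    assert locate_spinodal_low(rho, cv) == pytest.approx(0.10)


def test_spinodal_low_tallest_of_two_spikes():
    rho = np.arange(0.02, 0.22, 0.02)
    cv = np.full_like(rho, 1.0)
    cv[3] = 4.0                     # rho = 0.08
    cv[5] = 6.0                     # rho = 0.12 (tallest)
    cv[-1] = 0.1
    assert locate_spinodal_low(rho, cv) == pytest.approx(0.12)


def test_spinodal_low_monotone_curve_undefined():
    rho = np.arange(0.02, 0.22, 0.02)
    with pytest.raises(UndefinedBoundary):
        locate_spinodal_low(rho, np.linspace(1.0, 2.0, len(rho)))


def test_spinodal_high_consistent_with_cv_drop():
    rho = np.arange(0.30, 0.52, 0.01)
    n = 2.0 + 3000.0 / (1.0 + np.exp(-(rho - 0.40) / 0.002))
    cv = np.where(rho <= 0.41, 5.0, 1.0)
    rho_sl, rho_cv, ok = locate_spinodal_high(rho, n, cv)
    assert rho_sl == pytest.approx(0.40, abs=0.011)
    assert rho_cv == pytest.approx(0.415, abs=0.011)
    assert ok


def test_spinodal_high_inconsistency_warns():
    rho = np.arange(0.30, 0.60, 0.01)
    n = 2.0 + 3000.0 / (1.0 + np.exp(-(rho - 0.40) / 0.002))
    cv = np.where(rho <= 0.50, 5.0, 1.0)   # drop far from the <n> rise
    rho_sl, rho_cv, ok = locate_spinodal_high(rho, n, cv)
    assert rho_sl == pytest.approx(0.40, abs=0.011)
    assert rho_cv == pytest.approx(0.505, abs=0.011)
    assert not ok


def test_spinodal_high_hand_computed_slopes():
    rho = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
    n = np.array([2.0, 2.2, 2.5, 3.0, 30.0, 40.0, 45.0])
    rho_sl, _, _ = locate_spinodal_high(rho, n)
    # steepest log slope: log(30/3)/0.1 between 0.4 and 0.5
    assert rho_sl == pytest.approx(0.45)


def test_locators_are_pure_functions():
    rho = np.arange(0.02, 0.22, 0.02)
    cv = np.full_like(rho, 1.0)
    cv[4] = 5.0
    cv[-1] = 0.2
    assert locate_spinodal_low(rho, cv) == locate_spinodal_low(rho, cv)


# ---------------------------------------------------------------------------
# fluctuation estimators
# ---------------------------------------------------------------------------

def _traj_with_energy(e, T):
    F = len(e)
    z = np.zeros(F)
    pos = np.zeros((F, 2, 3))
    return Trajectory(np.arange(1.0, F + 1), pos, np.zeros_like(pos),
                      np.asarray(e, float), z.copy(), z.copy(), 10.0,
                      state=StatePoint(0.1, T))


def test_specific_heat_constant_energy_is_zero():
    traj = _traj_with_energy(np.full(200, -5.0), 1.1)
    assert specific_heat(traj) == 0.0


def test_specific_heat_known_variance():
    rng = np.random.default_rng(0)
    e = rng.normal(0.0, 2.0, size=100_000)
    traj = _traj_with_energy(e, 2.0)
    # var(E)/T^2 = 4/4 = 1
    assert specific_heat(traj) == pytest.approx(1.0, rel=0.02)


def test_specific_heat_needs_enough_frames():
    with pytest.raises(ValueError, match="frames"):
        specific_heat(_traj_with_energy(np.zeros(10), 1.0))


def test_surface_tension_formula_and_scaling():
    rng = np.random.default_rng(1)
    rg = rng.normal(3.0, np.sqrt(0.5), size=20_000)
    rg = (rg - rg.mean()) / rg.std() * np.sqrt(0.5) + 3.0  # exact var 0.5
    ts1 = surface_tension(rg, 1.0)
    assert ts1.u_sq == pytest.approx(0.5, rel=1e-9)
    assert ts1.sigma_ten == pytest.approx(2.0, rel=1e-9)
    ts2 = surface_tension(rg, 2.0)
    assert ts2.sigma_ten == pytest.approx(4.0, rel=1e-9)  # linear in T


def test_surface_tension_refuses_degenerate_inputs():
    const = np.full(500, 3.0)
    assert surface_tension(const, 1.0).sigma_ten is None   # zero variance
    short = np.array([3.0, 3.1] * 10)
    assert surface_tension(short, 1.0).sigma_ten is None   # short series
    rng = np.random.default_rng(2)
    rg = rng.normal(3.0, 0.5, size=500)
    spanning = np.zeros(500, bool)
    spanning[7] = True
    assert surface_tension(rg, 1.0, spanning=spanning).sigma_ten is None
    small = np.full(500, 10.0)
    assert surface_tension(rg, 1.0, sizes=small).sigma_ten is None
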