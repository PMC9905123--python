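"""Contact graphs, clustering and gyration radii, checked against
brute-force oracles and closed-form geometries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import cluster_oracle, contact_pairs_oracle, partition_from_labels
from vdwphase.clusters import (cluster_gyration, contact_graph, find_clusters,
                               trajectory_cluster_stats)
from vdwphase.engine import Frame, Trajectory
from vdwphase.system import StatePoint, make_fixture


def frame_of(positions, box, chain_id=None, t=0.0):
    positions = np.asarray(positions, dtype=float)
    return Frame(t, positions, np.zeros_like(positions), 0.0, 0.0, 0.0,
                 box, chain_id)


def traj_of(frames_positions, box, chain_id=None):
    P = np.array(frames_positions, dtype=float)
    F = P.shape[0]
    z = np.zeros(F)
    return Trajectory(np.arange(1.0, F + 1), P, np.zeros_like(P), z.copy(),
                      z.copy(), z.copy(), box, chain_id=chain_id)


def test_contact_cutoff_inclusion():
    f = frame_of([[1, 1, 1], [2.2, 1, 1]], 20.0)
    assert contact_graph(f, 1.3)[0, 1] == 1      # r = 1.2 <= 1.3
    f = frame_of([[1, 1, 1], [2.4, 1, 1]], 20.0)
    assert contact_graph(f, 1.3)[0, 1] == 0      # r = 1.4 > 1.3


def test_single_atom_empty_graph():
    f = frame_of([[1, 1, 1]], 10.0)
    assert contact_graph(f, 1.3).nnz == 0


def test_contact_across_periodic_boundary():
    box = 10.0
    f = frame_of([[0.1, 5, 5], [box - 0.1, 5, 5]], box)
    adj = contact_graph(f, 1.3)
    assert adj[0, 1] == 1    # minimum-image distance 0.2


def test_contact_graph_oracle_random():
    rng = np.random.default_rng(12)
    box = 6.0
    pos = rng.uniform(0, box, size=(100, 3))
    f = frame_of(pos, box)
    adj = contact_graph(f, 1.3).tocoo()
    got = {(min(i, j), max(i, j)) for i, j in zip(adj.row, adj.col)}
    assert got == contact_pairs_oracle(pos, box, 1.3)


def test_find_clusters_constructed_blobs():
    cfg = make_fixture("multi_cluster", sizes=(3, 3, 4), box_side=30.0, seed=1)
    cs = find_clusters(frame_of(cfg.positions, cfg.box_side), 1.3)
    assert sorted(cs.sizes) == [3, 3, 4]
    assert cs.sizes.sum() == 10


def test_all_distant_atoms_are_singletons():
    pos = np.array([[i * 3.0, 1, 1] for i in range(5)])
    cs = find_clusters(frame_of(pos, 30.0), 1.3)
    assert cs.n_clusters == 5
    assert np.all(cs.sizes == 1)


def test_atom_clustering_matches_union_find_oracle():
    rng = np.random.default_rng(7)
    n = 50
    box = (n / 0.4) ** (1 / 3)
    pos = rng.uniform(0, box, size=(n, 3))
    cs = find_clusters(frame_of(pos, box), 1.3)
    assert partition_from_labels(cs.membership) == cluster_oracle(pos, box, 1.3)


def test_chain_level_single_contact_merges():
    """Two 20-bead chains touching through one atom contact form one
    chain-level cluster of size 2."""
    a = np.array([[i * 1.0 + 5, 5.0, 5.0] for i in range(20)])
    b = np.array([[i * 1.0 + 5, 6.2, 5.0] if i == 0 else
                  [i * 1.0 + 5, 15.0, 5.0] for i in range(20)])
    pos = np.vstack([a, b])
    cid = np.repeat([0, 1], 20)
    f = frame_of(pos, 40.0, chain_id=cid)
    cs = find_clusters(f, 1.3, level="chain")
    assert cs.level == "chain"
    assert list(cs.sizes) == [2]
    # atom level: the two chains plus their touching beads form one component
    cs_atom = find_clusters(f, 1.3, level="atom")
    assert cs_atom.sizes.max() >= 21


def test_chain_level_requires_topology():
    with pytest.raises(ValueError, match="chain"):
        find_clusters(frame_of([[1, 1, 1]], 10.0), 1.3, level="chain")


def test_gyration_cube_corners():
    cfg = make_fixture("cube_corners", side=2.0)
    f = frame_of(cfg.positions, cfg.box_side)
    rg = cluster_gyration(f, range(8), contact_cutoff=3.9)
    assert rg == pytest.approx(math.sqrt(3.0), abs=1e-12)


def test_gyration_two_points_across_boundary():
    box = 10.0
    f = frame_of([[0.05, 5, 5], [box - 0.15, 5, 5]], box)
    rg = cluster_gyration(f, [0, 1], 1.3)
    assert rg == pytest.approx(0.1, abs=1e-12)


def test_gyration_interior_blob_matches_direct_formula():
    cfg = make_fixture("multi_cluster", sizes=(30,), box_side=40.0, seed=3)
    pos = cfg.positions.copy()
    # move the blob's centre to mid-box so it cannot straddle the boundary
    com = pos.mean(axis=0)
    d = pos - com
    d -= cfg.box_side * np.round(d / cfg.box_side)
    pos = d + cfg.box_side / 2.0
    f = frame_of(pos, cfg.box_side)
    rg = cluster_gyration(f, range(30), 1.3)
    direct = np.sqrt(np.mean(np.sum((pos - pos.mean(0)) ** 2, axis=1)))
    assert rg == pytest.approx(direct, abs=1e-12)


def test_gyration_disconnected_members_fail():
    pos = np.array([[1.0, 1, 1], [8.0, 1, 1]])
    with pytest.raises(ValueError, match="not connected"):
        cluster_gyration(frame_of(pos, 20.0), [0, 1], 1.3)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(shift=st.tuples(*[st.floats(-20, 20) for _ in range(3)]))
def test_gyration_invariant_under_periodic_shifts(shift):
    """R_g is unchanged by rigid translations, including across the
    boundary (a spec-level invariant of the unwrapping)."""
    cfg = make_fixture("multi_cluster", sizes=(12,), box_side=15.0, seed=6)
    f0 = frame_of(cfg.positions, cfg.box_side)
    rg0 = cluster_gyration(f0, range(12), 1.3)
    shifted = np.mod(cfg.positions + np.asarray(shift), cfg.box_side)
    rg1 = cluster_gyration(frame_of(shifted, cfg.box_side), range(12), 1.3)
    assert rg1 == pytest.approx(rg0, abs=1e-9)


def test_spanning_cluster_detected():
    box = 10.0
    pos = np.array([[i * 1.0 + 0.5, 5, 5] for i in range(10)])  # full ring
    f = frame_of(pos, box)
    rg, spanning = cluster_gyration(f, range(10), 1.3, return_spanning=True)
    assert spanning
    compact = make_fixture("multi_cluster", sizes=(10,), box_side=box, seed=2)
    _, sp2 = cluster_gyration(frame_of(compact.positions, box), range(10),
                              1.3, return_spanning=True)
    assert not sp2


def test_largest_tie_breaks_to_lowest_index():
    pos = np.array([[1.0, 1, 1], [2.0, 1, 1],      # cluster A (atoms 0,1)
                    [8.0, 8, 8], [9.0, 8, 8]])     # cluster B (atoms 2,3)
    cs = find_clusters(frame_of(pos, 20.0), 1.3)
    assert 0 in cs.members(cs.largest_label)


def test_trajectory_stats_all_singletons():
    pos = np.array([[i * 3.0, 1, 1] for i in range(6)])
    stats = trajectory_cluster_stats(traj_of([pos, pos], 30.0), 1.3)
    assert stats.mean_size == 1.0
    assert stats.mean_largest_size == 1.0
    assert stats.mean_rg == 0.0


def test_trajectory_stats_alternating_partitions():
    """Frames alternating one 40-blob and two 20-blobs: <n_lar> = 30 and
    <n> = (40 + 20) / 2 = 30 (hand arithmetic)."""
    one = make_fixture("multi_cluster", sizes=(40,), box_side=40.0, seed=1)
    two = make_fixture("multi_cluster", sizes=(20, 20), box_side=40.0, seed=2)
    traj = traj_of([one.positions, two.positions], 40.0)
    stats = trajectory_cluster_stats(traj, 1.3)
    assert stats.mean_largest_size == pytest.approx(30.0)
    assert stats.mean_size == pytest.approx(30.0)
    assert stats.per_frame_largest.tolist() == [40.0, 20.0]


def test_trajectory_stats_hand_computed_three_frames():
    f1 = make_fixture("multi_cluster", sizes=(3, 3, 4), box_side=30.0, seed=3)
    f2 = make_fixture("multi_cluster", sizes=(5, 5), box_side=30.0, seed=4)
    f3 = make_fixture("multi_cluster", sizes=(10,), box_side=30.0, seed=5)
    traj = traj_of([f1.positions, f2.positions, f3.positions], 30.0)
    stats = trajectory_cluster_stats(traj, 1.3)
    # frame means: (3+3+4)/3, (5+5)/2, 10 -> average
    assert stats.mean_size == pytest.approx((10 / 3 + 5 + 10) / 3)
    assert stats.mean_largest_size == pytest.approx((4 + 5 + 10) / 3)


def test_partition_property_random_frames():
    rng = np.random.default_rng(21)
    for n, rho in [(60, 0.1), (80, 0.3), (120, 0.5)]:
        box = (n / rho) ** (1 / 3)
        pos = rng.uniform(0, box, size=(n, 3))
        cs = find_clusters(frame_of(pos, box), 1.3)
        assert cs.sizes.sum() == n
        assert np.all(cs.sizes >= 1)


def test_empty_trajectory_rejected():
    t = traj_of([np.zeros((3, 3))], 10.0)
    t.times = t.times[:0]
    t.positions = t.positions[:0]
    with pytest.raises(ValueError):
        trajectory_cluster_stats(t, 1.3)
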