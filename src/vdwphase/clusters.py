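"""Contact-graph clustering and cluster size / gyration statistics.

Two atoms are in contact when their minimum-image distance does not exceed
the contact cutoff (1.3 sigma by default).  A cluster is a connected
component of the contact graph; for chain systems, two chains belong to
the same cluster when they share at least one inter-chain atom contact
(connected components of the chain-quotient graph).  Isolated particles
count as clusters of size 1, which keeps the cluster sizes a partition of
the system at every density.

Radii of gyration are computed on coordinates unwrapped by a breadth-first
traversal of the contact graph using minimum-image displacements, so
clusters straddling the periodic boundary are measured correctly.  A
cluster whose unwrapped extent reaches the box side along any axis is
flagged as spanning (such system-spanning droplets are excluded from the
surface-tension estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order, connected_components
from scipy.spatial import cKDTree

from .engine import Frame, Trajectory

__all__ = [
    "ClusterSet",
    "ClusterStats",
    "contact_graph",
    "find_clusters",
    "cluster_gyration",
    "trajectory_cluster_stats",
]

DEFAULT_CONTACT_CUTOFF = 1.3


@dataclass
class ClusterSet:
    """Cluster membership for one frame at one level (atom or chain)."""

    frame_time: float
    membership: np.ndarray   # per-particle (atom level) or per-chain label
    sizes: np.ndarray        # member count per cluster label
    level: str               # "atom" | "chain"

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def largest_label(self) -> int:
        """Label of the largest cluster; ties broken by the lowest minimum
        member index (deterministic)."""
        mx = self.sizes.max()
        tied = np.flatnonzero(self.sizes == mx)
        if len(tied) == 1:
            return int(tied[0])
        firsts = [np.argmax(self.membership == lab) for lab in tied]
        return int(tied[int(np.argmin(firsts))])

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.membership == label)


@dataclass
class ClusterStats:
    """Time-averaged cluster statistics over a trajectory's analysis window.

    mean_size is <n>, the per-frame mean cluster size averaged over frames;
    mean_largest_size is <n_lar>; mean_rg and mean_rg_largest are the
    matching gyration-radius averages.  rg_series_largest is the per-frame
    R_g of the largest cluster (the input to the surface-tension
    estimator), with matching size and spanning-flag series.
    """

    mean_size: float
    mean_largest_size: float
    mean_rg: float
    mean_rg_largest: float
    per_frame_size: np.ndarray
    per_frame_largest: np.ndarray
    per_frame_rg: np.ndarray
    per_frame_rg_largest: np.ndarray
    rg_series_largest: np.ndarray
    size_series_largest: np.ndarray
    spanning_series_largest: np.ndarray
    # droplet series for the surface-tension estimator: the largest
    # NON-spanning cluster per frame (falls back to the largest cluster,
    # with the spanning flag set, when every candidate spans the box)
    rg_series_droplet: np.ndarray = None
    size_series_droplet: np.ndarray = None
    spanning_series_droplet: np.ndarray = None
    level: str = "atom"


# ---------------------------------------------------------------------------
# contact graph and components
# ---------------------------------------------------------------------------

def _contact_pairs(positions: np.ndarray, box: float,
                   cutoff: float) -> np.ndarray:
    """(m, 2) array of minimum-image contact pairs, via a periodic k-d tree."""
    if cutoff >= box / 2.0:
        raise ValueError(f"contact cutoff {cutoff} must be below half the "
                         f"box side {box / 2.0:.4f}")
    pos = np.mod(positions, box)
    # cKDTree requires coordinates strictly inside [0, boxsize)
    pos[pos >= box] = 0.0
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def contact_graph(frame: Frame, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
                  ) -> sparse.csr_matrix:
    """Symmetric adjacency (CSR, no self-edges) of atoms within the cutoff."""
    n = frame.positions.shape[0]
    pairs = _contact_pairs(frame.positions, frame.box_side, contact_cutoff)
    if len(pairs) == 0:
        return sparse.csr_matrix((n, n))
    data = np.ones(len(pairs), dtype=np.int8)
    adj = sparse.coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    return (adj + adj.T).tocsr()


def find_clusters(frame: Frame,
                  contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                  level: str = "atom") -> ClusterSet:
    """Connected components of the contact graph at atom or chain level."""
    n = frame.positions.shape[0]
    pairs = _contact_pairs(frame.positions, frame.box_side, contact_cutoff)
    if level == "atom":
        n_nodes = n
        edges = pairs
    elif level == "chain":
        if frame.chain_id is None:
            raise ValueError("chain-level clustering requires chain topology")
        cid = frame.chain_id
        n_nodes = int(cid.max()) + 1
        if len(pairs):
            ci, cj = cid[pairs[:, 0]], cid[pairs[:, 1]]
            inter = ci != cj
            edges = np.column_stack([ci[inter], cj[inter]])
        else:
            edges = pairs
    else:
        raise ValueError(f"unknown level {level!r}")

    if len(edges):
        data = np.ones(len(edges), dtype=np.int8)
        adj = sparse.coo_matrix((data, (edges[:, 0], edges[:, 1])),
                                shape=(n_nodes, n_nodes))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n_nodes)
    sizes = np.bincount(labels)
    return ClusterSet(frame.time, labels, sizes, level)


# ---------------------------------------------------------------------------
# gyration radius with periodic unwrapping
# ---------------------------------------------------------------------------

def _unwrap_members(positions: np.ndarray, box: float, members: np.ndarray,
                    cutoff: float, detect_wrap: bool = False):
    """Unwrap a connected member set by BFS over its contact graph,
    accumulating minimum-image displacements from each node's BFS parent.

    With detect_wrap=True returns (unwrapped, wraps): `wraps` is True when
    some contact edge closes a loop around the box — its unwrapped
    displacement disagrees with the minimum image — i.e. the cluster is
    periodically connected to its own image (it spans the box)."""
    pos = positions[members]
    m = len(members)
    if m == 1:
        return (pos.copy(), False) if detect_wrap else pos.copy()
    pairs = _contact_pairs(pos, box, cutoff) if cutoff < box / 2.0 else None
    if pairs is None:
        # tiny box: build adjacency from an explicit minimum-image scan
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.round(d / box)
        r2 = np.sum(d * d, axis=-1)
        ii, jj = np.nonzero(np.triu(r2 <= cutoff**2, k=1))
        pairs = np.column_stack([ii, jj])
    data = np.ones(len(pairs), dtype=np.int8)
    adj = sparse.coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(m, m))
    adj = (adj + adj.T).tocsr()
    order, pred = breadth_first_order(adj, 0, directed=False,
                                      return_predecessors=True)
    if len(order) != m:
        raise ValueError("member set is not connected at the contact cutoff; "
                         "unwrapping is undefined")
    out = np.empty_like(pos)
    out[0] = pos[0]
    for node in order[1:]:
        p = pred[node]
        d = pos[node] - pos[p]
        d -= box * np.round(d / box)
        out[node] = out[p] + d
    if not detect_wrap:
        return out
    # non-tree contact edges must agree with the minimum image; a mismatch
    # means the cluster is connected around the box
    i, j = pairs[:, 0], pairs[:, 1]
    dmin = pos[i] - pos[j]
    dmin -= box * np.round(dmin / box)
    wraps = bool(np.any(np.abs((out[i] - out[j]) - dmin) > 1e-6))
    return out, wraps


def cluster_gyration(frame: Frame, members: Sequence[int],
                     contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     return_spanning: bool = False):
    """Radius of gyration of one cluster, unwrapped across the boundary.

    R_g = sqrt( (1/n) sum_i |r_i - r_cm|^2 ) on BFS-unwrapped coordinates.
    With return_spanning=True also reports whether the cluster spans the
    box: either its unwrapped extent reaches the box side along some axis,
    or a contact edge connects it around the periodic boundary.
    """
    members = np.asarray(members, dtype=np.int64)
    if return_spanning:
        unwrapped, wraps = _unwrap_members(frame.positions, frame.box_side,
                                           members, contact_cutoff,
                                           detect_wrap=True)
    else:
        unwrapped = _unwrap_members(frame.positions, frame.box_side, members,
                                    contact_cutoff)
    com = unwrapped.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum((unwrapped - com) ** 2, axis=1))))
    if return_spanning:
        extent = unwrapped.max(axis=0) - unwrapped.min(axis=0)
        spanning = wraps or bool(np.any(extent >= frame.box_side - 1e-9))
        return rg, spanning
    return rg


# ---------------------------------------------------------------------------
# trajectory-level statistics
# ---------------------------------------------------------------------------

def trajectory_cluster_stats(traj: Trajectory,
                             contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                             level: str = "atom") -> ClusterStats:
    """Per-frame and time-averaged cluster sizes and gyration radii.

    <n> averages over *all* clusters of a frame (singletons included,
    R_g = 0 for a singleton); n_lar is the size of the frame's largest
    cluster.  For chain-level statistics, sizes count chains but R_g is
    computed over the member beads.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    F = traj.n_frames
    mean_sz = np.empty(F)
    largest_sz = np.empty(F)
    mean_rg = np.empty(F)
    rg_largest = np.empty(F)
    spanning = np.zeros(F, dtype=bool)

    rg_droplet = np.zeros(F)
    size_droplet = np.zeros(F)
    span_droplet = np.zeros(F, dtype=bool)

    for f in range(F):
        frame = traj.frame(f)
        cs = find_clusters(frame, contact_cutoff, level)
        mean_sz[f] = cs.sizes.mean()
        lab = cs.largest_label
        largest_sz[f] = cs.sizes[lab]

        def atoms_of(c):
            if level == "chain":
                return np.flatnonzero(np.isin(frame.chain_id, cs.members(c)))
            return cs.members(c)

        rgs = np.zeros(cs.n_clusters)
        spans = np.zeros(cs.n_clusters, dtype=bool)
        for c in range(cs.n_clusters):
            if cs.sizes[c] < 2:
                continue
            rgs[c], spans[c] = cluster_gyration(frame, atoms_of(c),
                                                contact_cutoff,
                                                return_spanning=True)
        if cs.sizes[lab] < 2 and level == "chain":
            # single-chain "cluster": R_g of its beads still meaningful
            atoms = np.flatnonzero(frame.chain_id == cs.members(lab)[0])
            if len(atoms) > 1:
                rgs[lab], spans[lab] = cluster_gyration(
                    frame, atoms, contact_cutoff, return_spanning=True)
        spanning[f] = spans[lab]
        mean_rg[f] = rgs.mean()
        rg_largest[f] = rgs[lab]

        # droplet = largest non-spanning cluster (by size, ties to the
        # largest-label rule); fall back to the largest cluster if all span
        order = np.argsort(-cs.sizes, kind="stable")
        chosen = None
        for c in order:
            if cs.sizes[c] >= 2 and not spans[c]:
                chosen = c
                break
        if chosen is None:
            chosen = lab
            span_droplet[f] = True
        rg_droplet[f] = rgs[chosen]
        size_droplet[f] = cs.sizes[chosen]

    return ClusterStats(
        mean_size=float(mean_sz.mean()),
        mean_largest_size=float(largest_sz.mean()),
        mean_rg=float(mean_rg.mean()),
        mean_rg_largest=float(rg_largest.mean()),
        per_frame_size=mean_sz,
        per_frame_largest=largest_sz,
        per_frame_rg=mean_rg,
        per_frame_rg_largest=rg_largest,
        rg_series_largest=rg_largest,
        size_series_largest=largest_sz,
        spanning_series_largest=spanning,
        rg_series_droplet=rg_droplet,
        size_series_droplet=size_droplet,
        spanning_series_droplet=span_droplet,
        level=level,
    )
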