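"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's accelerated code paths:
LJ energies/forces by direct all-pairs summation, contact graphs by an
O(N^2) scan, and clustering by a plain union-find, so the fast
implementations are checked against independent routes.
"""

from __future__ import annotations

import numpy as np
import pytest

from vdwphase.scan import run_scan

# grid for the desk-scale T*=1.1 monomer scan shared by the acceptance
# tests: spans rho* in [0.01, 0.9] (15 densities) and contains the six
# liquid-branch densities {0.55 ... 0.70} used for the rho_L check
DESK_DENSITIES = [0.01, 0.04, 0.08, 0.14, 0.20, 0.28, 0.36, 0.46,
                  0.55, 0.58, 0.61, 0.64, 0.67, 0.70, 0.90]
RHO_L_DENSITIES = [0.55, 0.58, 0.61, 0.64, 0.67, 0.70]


@pytest.fixture(scope="session")
def desk_scan_table():
    """Full desk-preset monomer scan at T*=1.1 (the expensive fixture;
    computed once per session and shared by the boundary tests)."""
    return run_scan(DESK_DENSITIES, [1.1], preset="desk", seeds=[1])


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def minimum_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def lj_oracle(positions: np.ndarray, box: float, r_cut: float,
              exclude: set[tuple[int, int]] = frozenset()):
    """Direct all-pairs truncated-LJ energy and forces (no neighbour list)."""
    n = len(positions)
    energy = 0.0
    forces = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in exclude:
                continue
            d = minimum_image(positions[i] - positions[j], box)
            r2 = float(d @ d)
            if r2 < r_cut**2:
                sr6 = r2 ** -3
                energy += 4.0 * (sr6**2 - sr6)
                fs = 24.0 * (2.0 * sr6**2 - sr6) / r2
                forces[i] += fs * d
                forces[j] -= fs * d
    return energy, forces


def contact_pairs_oracle(positions: np.ndarray, box: float,
                         cutoff: float) -> set[tuple[int, int]]:
    """Exhaustive minimum-image pair scan."""
    n = len(positions)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = minimum_image(positions[i] - positions[j], box)
            if float(d @ d) <= cutoff**2:
                out.add((i, j))
    return out


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_oracle(positions: np.ndarray, box: float, cutoff: float,
                   chain_id: np.ndarray | None = None) -> list[frozenset]:
    """Brute-force union-find clustering over the O(N^2) edge list.

    With chain_id given, returns chain-level clusters from the quotient
    graph (chains adjacent iff any inter-chain atom contact).
    """
    pairs = contact_pairs_oracle(positions, box, cutoff)
    if chain_id is None:
        n = len(positions)
        uf = UnionFind(n)
        for i, j in pairs:
            uf.union(i, j)
        groups: dict[int, set] = {}
        for i in range(n):
            groups.setdefault(uf.find(i), set()).add(i)
    else:
        n_chains = int(chain_id.max()) + 1
        uf = UnionFind(n_chains)
        for i, j in pairs:
            if chain_id[i] != chain_id[j]:
                uf.union(int(chain_id[i]), int(chain_id[j]))
        groups = {}
        for c in range(n_chains):
            groups.setdefault(uf.find(c), set()).add(c)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def partition_from_labels(labels: np.ndarray) -> list[frozenset]:
    groups: dict[int, set] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)
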