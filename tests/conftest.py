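"""Shared fixtures: in-memory MDAnalysis universes, random detailed-balance
networks, and brute-force oracles used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dridscape.constants import log_eyring_prefactor
from dridscape.network import KineticNetwork


def make_chain_universe(coords_nm: np.ndarray, bonds=None, dt: float = 20.0):
    """Build an in-memory MDAnalysis universe for an n-bead chain.

    ``coords_nm`` has shape (n_frames, n_atoms, 3) in nm; each bead is its
    own residue named BEA with atom name CA; consecutive beads are bonded
    unless an explicit bond list is given.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    coords_nm = np.asarray(coords_nm, dtype=float)
    n_frames, n_atoms, _ = coords_nm.shape
    u = mda.Universe.empty(n_atoms, n_residues=n_atoms,
                           atom_resindex=np.arange(n_atoms),
                           residue_segindex=np.zeros(n_atoms, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("name", ["CA"] * n_atoms)
    u.add_TopologyAttr("resname", ["BEA"] * n_atoms)
    u.add_TopologyAttr("resid", np.arange(1, n_atoms + 1))
    u.add_TopologyAttr("type", ["C"] * n_atoms)
    if bonds is None:
        bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    if bonds:
        u.add_TopologyAttr("bonds", bonds)
    u.load_new(coords_nm * 10.0, format=MemoryReader, dt=dt)  # nm -> Angstrom
    return u


def random_db_network(n_states: int, seed: int, extra_edges: int = 2,
                      temperature: float = 310.0,
                      barrier_offset=(0.5, 3.0)) -> KineticNetwork:
    """Random connected network with detailed-balance rates.

    Energies U(0, 3) k_B T; connectivity a random spanning tree plus
    ``extra_edges`` shortcuts; each barrier sits U(lo, hi) above the higher
    adjacent minimum; rates follow the Eyring inversion, so p_j k_jk is
    symmetric by construction.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, 3.0, n_states)
    f -= f.min()
    edges = set()
    order = rng.permutation(n_states)
    for i in range(1, n_states):
        j = int(order[i]); k = int(order[rng.integers(0, i)])
        edges.add((min(j, k), max(j, k)))
    for _ in range(extra_edges):
        j, k = rng.integers(0, n_states, 2)
        if j != k:
            edges.add((min(int(j), int(k)), max(int(j), int(k))))
    barriers = {e: max(f[e[0]], f[e[1]]) + rng.uniform(*barrier_offset)
                for e in sorted(edges)}
    c = log_eyring_prefactor(temperature)
    rates = np.zeros((n_states, n_states))
    for (j, k), fh in barriers.items():
        rates[j, k] = np.exp(c - (fh - f[j]))
        rates[k, j] = np.exp(c - (fh - f[k]))
    p = np.exp(-f)
    return KineticNetwork(free_energy=f, rates=rates, barriers=barriers,
                          temperature=temperature, probability=p / p.sum())


def brute_force_moments(coords_nm, centroid_id, reference_ids, exclusion):
    """Naive loop evaluation of the three reciprocal-distance moments."""
    recip = []
    for j in reference_ids:
        if j in exclusion:
            continue
        d = float(np.sqrt(sum((coords_nm[j][a] - coords_nm[centroid_id][a]) ** 2
                              for a in range(3))))
        recip.append(1.0 / d)
    n = len(recip)
    mu = sum(recip) / n
    nu = (sum((r - mu) ** 2 for r in recip) / n) ** 0.5
    third = sum((r - mu) ** 3 for r in recip) / n
    xi = np.sign(third) * abs(third) ** (1.0 / 3.0)
    return mu, nu, xi


def brute_force_superbasins(free_energy, barriers, threshold):
    """All-pairs path search: j,k share a basin iff some path has every
    barrier < threshold (strict), both endpoints present."""
    n = len(free_energy)
    present = [i for i in range(n) if free_energy[i] < threshold]
    groups = []
    assigned = set()
    for start in present:
        if start in assigned:
            continue
        group = {start}
        frontier = [start]
        while frontier:
            cur = frontier.pop()
            for (j, k), fh in barriers.items():
                if fh >= threshold:
                    continue
                other = None
                if j == cur and k in present:
                    other = k
                elif k == cur and j in present:
                    other = j
                if other is not None and other not in group:
                    group.add(other)
                    frontier.append(other)
        assigned |= group
        groups.append(frozenset(group))
    return set(groups)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
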