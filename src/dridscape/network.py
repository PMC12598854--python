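"""Kinetic transition networks from discrete state trajectories.

Each cluster (state) is treated as a free-energy minimum.  Minimum free
energies follow from equilibrium occupation probabilities,

    F_i = -ln p_i           (units of k_B T, global minimum shifted to 0),

directed rates from observed transition counts,

    k_jk = C_jk / (n_j * dt)    (ps^-1),

and transition-state free energies from inverting the Eyring-Polanyi
relation k = (k_B T / h) exp(-dF/k_B T).  The one-sided barrier anchored on
the reactant is

    F_jk^(1) = F_j - ln k_jk + ln(k_B T / h * 1 ps),

and the reported barrier is the average of the forward and backward
one-sided values, which removes the finite-sampling asymmetry (and is
invariant to whether the one-sided formula anchors on the reactant or the
product state).  The network, restricted to its largest connected component,
is written to / read from PATHSAMPLE-dialect ``min.data`` / ``ts.data``
files with 1-based minimum ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .clustering import ClusterModel, StateTrajectory, assign
from .constants import log_eyring_prefactor
from .drid import DRIDTrajectory

__all__ = [
    "TransitionCounts",
    "StateStats",
    "KineticNetwork",
    "count_transitions",
    "estimate_rates",
    "free_energies",
    "barrier",
    "build_network",
    "write_pathsample_db",
    "read_pathsample_db",
    "read_pathsample_db_files",
    "project_reference_states",
]


@dataclass
class TransitionCounts:
    """Off-diagonal transition counts C_jk and per-state occupancies n_j."""

    counts: np.ndarray
    occupancy: np.ndarray
    frame_interval: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.occupancy = np.asarray(self.occupancy)
        if self.counts.shape != (self.occupancy.size, self.occupancy.size):
            raise ValueError("counts must be square over the occupancy states")

    @property
    def n_states(self) -> int:
        return self.occupancy.size


@dataclass
class StateStats:
    """Equilibrium probabilities and branching probabilities P_jk = C_jk / sum_k C_jk."""

    probability: np.ndarray
    branching: np.ndarray


@dataclass
class KineticNetwork:
    """Minima with free energies, directed rates and symmetrized barriers.

    Indices are 0-based network-internal ids; ``original_ids`` maps them back
    to the cluster-model state ids when the network was restricted to its
    largest connected component.
    """

    free_energy: np.ndarray            # (n,) in k_B T, min shifted to 0
    rates: np.ndarray                  # (n, n) ps^-1, 0 = no edge
    barriers: dict                     # {(j, k) with j < k: F_hat in k_B T}
    temperature: float
    probability: np.ndarray | None = None
    frame_interval: float | None = None
    counts: TransitionCounts | None = None
    original_ids: np.ndarray | None = None
    completed_pairs: set = field(default_factory=set)
    suspect_barriers: set = field(default_factory=set)

    @property
    def n_states(self) -> int:
        return self.free_energy.size

    @property
    def prefactor_log(self) -> float:
        return log_eyring_prefactor(self.temperature)

    def connected_pairs(self):
        return sorted(self.barriers)


# ---------------------------------------------------------------------------
# counting, rates, free energies, barriers
# ---------------------------------------------------------------------------

def count_transitions(st: StateTrajectory | Sequence[StateTrajectory],
                      ) -> TransitionCounts:
    """Count one-frame transitions j->k (j != k) and per-state occupancies.

    Accepts a single state trajectory or several; frame pairs are never
    counted across a trajectory boundary.
    """
    trajectories = [st] if isinstance(st, StateTrajectory) else list(st)
    if not trajectories:
        raise ValueError("no state trajectories given")
    n = trajectories[0].n_states
    dt = trajectories[0].frame_interval
    for t in trajectories:
        if t.n_states != n or t.frame_interval != dt:
            raise ValueError("state trajectories disagree on n_states or frame interval")
    counts = np.zeros((n, n), dtype=np.int64)
    occupancy = np.zeros(n, dtype=np.int64)
    for t in trajectories:
        lab = t.labels
        if lab.size == 0:
            raise ValueError("empty state trajectory")
        occupancy += np.bincount(lab, minlength=n)
        if lab.size > 1:
            a, b = lab[:-1], lab[1:]
            mask = a != b
            np.add.at(counts, (a[mask], b[mask]), 1)
    return TransitionCounts(counts, occupancy, dt)


def estimate_rates(tc: TransitionCounts) -> np.ndarray:
    """Maximum-likelihood escape rates k_jk = C_jk / (n_j * dt) in ps^-1."""
    if tc.frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = tc.counts / (tc.occupancy[:, None] * tc.frame_interval)
    rates = np.where(tc.occupancy[:, None] > 0, rates, 0.0)
    np.fill_diagonal(rates, 0.0)
    return rates


def free_energies(tc: TransitionCounts, temperature: float | None = None,
                  ) -> np.ndarray:
    """F_i = -ln(n_i / N) in k_B T, shifted so the global minimum is 0.

    Unvisited states get +inf.  ``temperature`` only documents the thermal
    scale; in k_B T units it does not enter the numbers.
    """
    total = tc.occupancy.sum()
    if total <= 0:
        raise ValueError("no frames counted")
    with np.errstate(divide="ignore"):
        f = -np.log(tc.occupancy / total)
    finite = np.isfinite(f)
    f[finite] -= f[finite].min()
    return f


def barrier(f_reactant: float, f_product: float, k_fwd: float, k_bwd: float,
            temperature: float) -> float:
    """Symmetrized transition-state free energy (k_B T) for one pair.

    Averages the reactant-anchored one-sided barriers of the forward and
    backward transitions; the average is identical under the product-anchored
    convention because both minima energies enter once either way.
    """
    if k_fwd <= 0 or k_bwd <= 0:
        raise ValueError("both directional rates must be positive")
    c = log_eyring_prefactor(temperature)
    fwd = f_reactant - np.log(k_fwd) + c
    bwd = f_product - np.log(k_bwd) + c
    return float(0.5 * (fwd + bwd))


def _branching(counts: np.ndarray) -> np.ndarray:
    out = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = counts / out[:, None]
    return np.where(out[:, None] > 0, b, 0.0)


def build_network(st: StateTrajectory | Sequence[StateTrajectory],
                  temperature: float = 310.0, strict: bool = False,
                  ) -> tuple[KineticNetwork, StateStats]:
    """Assemble the kinetic transition network from a state trajectory.

    The network is restricted to the largest connected component of the
    observed-transition graph (excluded minima are recorded on the returned
    network).  Pairs observed in only one direction get their missing rate
    completed via detailed balance, k_kj = k_jk p_j / p_k, and are flagged in
    ``completed_pairs``; with ``strict=True`` such pairs are dropped instead.
    Barriers that fall below an adjacent minimum (a finite-sampling artifact)
    are kept as computed but recorded in ``suspect_barriers``.
    """
    tc = count_transitions(st)
    visited = np.flatnonzero(tc.occupancy > 0)
    g = nx.Graph()
    g.add_nodes_from(visited.tolist())
    sym = tc.counts + tc.counts.T
    for j, k in zip(*np.nonzero(np.triu(sym, 1))):
        g.add_edge(int(j), int(k))
    component = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    keep = np.array(sorted(component), dtype=np.intp)

    sub_counts = tc.counts[np.ix_(keep, keep)]
    sub_occ = tc.occupancy[keep]
    sub_tc = TransitionCounts(sub_counts, sub_occ, tc.frame_interval)
    rates = estimate_rates(sub_tc)
    f = free_energies(sub_tc, temperature)
    p = sub_occ / sub_occ.sum()

    barriers: dict = {}
    completed: set = set()
    suspect: set = set()
    n = keep.size
    for j in range(n):
        for k in range(j + 1, n):
            k_fwd, k_bwd = rates[j, k], rates[k, j]
            if k_fwd == 0 and k_bwd == 0:
                continue
            if k_fwd == 0 or k_bwd == 0:
                if strict:
                    continue
                if k_fwd == 0:
                    k_fwd = rates[j, k] = k_bwd * p[k] / p[j]
                else:
                    k_bwd = rates[k, j] = k_fwd * p[j] / p[k]
                completed.add((j, k))
            f_hat = barrier(f[j], f[k], k_fwd, k_bwd, temperature)
            barriers[(j, k)] = f_hat
            if f_hat < max(f[j], f[k]):
                suspect.add((j, k))

    net = KineticNetwork(
        free_energy=f, rates=rates, barriers=barriers, temperature=temperature,
        probability=p, frame_interval=tc.frame_interval, counts=sub_tc,
        original_ids=keep, completed_pairs=completed, suspect_barriers=suspect,
    )
    full_p = tc.occupancy / tc.occupancy.sum()
    stats = StateStats(probability=full_p, branching=_branching(tc.counts))
    return net, stats


# ---------------------------------------------------------------------------
# PATHSAMPLE-dialect databases
# ---------------------------------------------------------------------------
# min.data:  energy  ln(vib product)  point-group order  Ix Iy Iz
# ts.data:   energy  ln(vib product)  point-group order  min1 min2  Ix Iy Iz
# Free-energy networks do not use the vibrational/symmetry/inertia fields, so
# they are written as neutral constants (1.0 / 1 / 1.0) that downstream tools
# parse cleanly.  Energies use %.17g, which round-trips doubles exactly.

def write_pathsample_db(net: KineticNetwork, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "min.data", "w") as fh:
        for e in net.free_energy:
            fh.write(f"{e:>25.17g} {1.0:>12.6f} {1:>6d} {1.0:>10.6f} {1.0:>10.6f} {1.0:>10.6f}\n")
    with open(directory / "ts.data", "w") as fh:
        for (j, k) in sorted(net.barriers):
            e = net.barriers[(j, k)]
            fh.write(
                f"{e:>25.17g} {1.0:>12.6f} {1:>6d} {j + 1:>8d} {k + 1:>8d} "
                f"{1.0:>10.6f} {1.0:>10.6f} {1.0:>10.6f}\n"
            )


def read_pathsample_db(directory: str | Path, temperature: float = 310.0,
                       ) -> KineticNetwork:
    """Read min.data / ts.data from a directory back into a network."""
    directory = Path(directory)
    return read_pathsample_db_files(directory / "min.data", directory / "ts.data",
                                    temperature)


def read_pathsample_db_files(min_data: str | Path, ts_data: str | Path,
                             temperature: float = 310.0) -> KineticNetwork:
    """Read explicit min.data / ts.data paths back into a network.

    Directed rates are reconstructed from the barriers by inverting the
    Eyring-Polanyi relation, k_jk = (k_B T/h * 1 ps) exp(-(F_hat - F_j)),
    which is the exact inverse of how the barriers were computed whenever the
    underlying rates satisfied detailed balance.
    """
    energies = []
    with open(min_data) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            try:
                energies.append(float(parts[0]))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"min.data line {lineno}: cannot parse {line!r}") from exc
    f = np.asarray(energies)
    n = f.size
    barriers: dict = {}
    with open(ts_data) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            try:
                e = float(parts[0])
                j, k = int(parts[3]) - 1, int(parts[4]) - 1
            except (IndexError, ValueError) as exc:
                raise ValueError(f"ts.data line {lineno}: cannot parse {line!r}") from exc
            if not (0 <= j < n and 0 <= k < n):
                raise ValueError(f"ts.data line {lineno}: minimum id out of range")
            if j != k:
                barriers[(min(j, k), max(j, k))] = e
    c = log_eyring_prefactor(temperature)
    rates = np.zeros((n, n))
    for (j, k), f_hat in barriers.items():
        rates[j, k] = np.exp(-(f_hat - f[j]) + c)
        rates[k, j] = np.exp(-(f_hat - f[k]) + c)
    with np.errstate(over="ignore"):
        p = np.exp(-f)
    return KineticNetwork(
        free_energy=f, rates=rates, barriers=barriers, temperature=temperature,
        probability=p / p.sum(),
    )


def project_reference_states(fingerprints: np.ndarray | DRIDTrajectory,
                             model: ClusterModel,
                             net: KineticNetwork | None = None) -> np.ndarray:
    """Map external reference conformations onto this network's state ids.

    Fingerprints are assigned to their nearest cluster center; when a network
    restricted to its largest component is given, model state ids are
    translated to network-internal ids (an id outside the component raises).
    Enables marking e.g. another system's global minimum on this landscape.
    """
    if isinstance(fingerprints, DRIDTrajectory):
        drid = fingerprints
    else:
        fp = np.atleast_2d(np.asarray(fingerprints, dtype=float))
        drid = DRIDTrajectory(fp, frame_interval=1.0, source_label="reference")
    ids = assign(drid, model).labels
    if net is None or net.original_ids is None:
        return ids
    lookup = {int(orig): new for new, orig in enumerate(net.original_ids)}
    mapped = []
    for s in ids:
        if int(s) not in lookup:
            raise ValueError(
                f"reference conformation maps to state {int(s)}, which is not in "
                "the network's largest connected component"
            )
        mapped.append(lookup[int(s)])
    return np.asarray(mapped, dtype=np.intp)
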