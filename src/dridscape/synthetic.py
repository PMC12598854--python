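"""Planted-truth synthetic fixtures: model landscapes, state trajectories
and toy bead-chain coordinate trajectories.

The generator produces the study conditions end to end: a small kinetic
network with known free energies and barriers (satisfying detailed balance
by construction, because every rate derives from the same Eyring relation
k_jk = (k_B T/h * 1 ps) exp(-(F_hat_jk - F_j))), a discrete-time Markov
state trajectory sampled from it at a fixed frame interval (20 ps by
default, the standard MD saving interval for this kind of analysis), and a
3-D bead-chain trajectory in which every frame is its state's template
structure plus isotropic Gaussian jitter.  Clustering the emitted
trajectory in DRID space with a cutoff between the jitter scale and the
template separation recovers the planted partition, which makes the full
pipeline testable against known answers.

Default condition choices: minima free energies span ~0-2.5 k_B T (the
scale of the state splittings reported for small disordered peptides),
barriers sit 6.5-8 k_B T above the higher adjacent minimum (7.5-9 k_B T for
the funnel-connecting barrier of the two-funnel topology) so that per-frame
jump probabilities at 20 ps stay well below the discrete-sampling validity
bound, and the bead-chain jitter is 0.01 nm against template separations of
order 0.1 nm in DRID space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import StateTrajectory
from .constants import ANGSTROM_PER_NM, log_eyring_prefactor
from .network import KineticNetwork

__all__ = [
    "PlantedLandscape",
    "StateTemplate",
    "make_landscape",
    "sample_state_trajectory",
    "make_templates",
    "emit_toy_trajectory",
    "occupation_standard_errors",
]

TOPOLOGIES = ("chain", "funnel", "two-funnel")


@dataclass
class PlantedLandscape:
    """Ground-truth kinetic network with known energies and barriers."""

    n_states: int
    free_energy: np.ndarray          # (n,) k_B T, min shifted to 0
    barriers: dict                   # {(j, k), j < k: F_hat in k_B T}
    temperature: float
    seed: int
    topology: str
    funnels: tuple | None = None     # for two-funnel: the two state groups

    @property
    def probability(self) -> np.ndarray:
        w = np.exp(-self.free_energy)
        return w / w.sum()

    def rates(self) -> np.ndarray:
        """Induced Eyring rates k_jk = pref * exp(-(F_hat - F_j)), ps^-1."""
        c = log_eyring_prefactor(self.temperature)
        k = np.zeros((self.n_states, self.n_states))
        for (j, l), f_hat in self.barriers.items():
            k[j, l] = np.exp(c - (f_hat - self.free_energy[j]))
            k[l, j] = np.exp(c - (f_hat - self.free_energy[l]))
        return k

    def to_network(self) -> KineticNetwork:
        return KineticNetwork(
            free_energy=self.free_energy.copy(), rates=self.rates(),
            barriers=dict(self.barriers), temperature=self.temperature,
            probability=self.probability,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_states": self.n_states,
            "free_energy_kBT": self.free_energy.tolist(),
            "barriers_kBT": {f"{j},{k}": v for (j, k), v in self.barriers.items()},
            "temperature_K": self.temperature,
            "seed": self.seed,
            "topology": self.topology,
            "funnels": None if self.funnels is None else [sorted(f) for f in self.funnels],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def make_landscape(n_states: int, topology: str = "chain", seed: int = 0,
                   temperature: float = 310.0) -> PlantedLandscape:
    """Sample a reproducible planted landscape of the requested topology.

    * ``chain``: minima 0-1-2-... connected linearly, random energies.
    * ``funnel``: linear connectivity with energies increasing along the
      chain, i.e. a single funnel draining to state 0.
    * ``two-funnel``: two internally chain-connected halves, each a funnel
      to its own lowest state, joined by one high barrier; the
      disconnectivity tree splits into exactly two top-level branches.
    """
    if n_states < 2:
        raise ValueError("need at least two states")
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; choose from {TOPOLOGIES}")
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, 2.5, size=n_states)

    edges: list[tuple[int, int]] = []
    funnels = None
    inter_edge = None
    if topology == "chain":
        edges = [(i, i + 1) for i in range(n_states - 1)]
    elif topology == "funnel":
        f = np.sort(f)
        edges = [(i, i + 1) for i in range(n_states - 1)]
    else:  # two-funnel
        half = n_states // 2
        left = list(range(half))
        right = list(range(half, n_states))
        f[left] = np.sort(f[left])
        f[right] = np.sort(f[right])
        edges = [(i, i + 1) for i in range(half - 1)]
        edges += [(i, i + 1) for i in range(half, n_states - 1)]
        inter_edge = (half - 1, half)
        edges.append(inter_edge)
        funnels = (tuple(left), tuple(right))
    f = f - f.min()

    barriers: dict = {}
    intra_offsets = rng.uniform(6.5, 8.0, size=len(edges))
    for (j, k), off in zip(edges, intra_offsets):
        barriers[(min(j, k), max(j, k))] = max(f[j], f[k]) + off
    if inter_edge is not None:
        j, k = inter_edge
        # the funnel-connecting barrier tops every intra-funnel barrier
        barriers[(min(j, k), max(j, k))] = max(barriers.values()) + rng.uniform(1.0, 2.0)
    return PlantedLandscape(n_states, f, barriers, temperature, seed, topology,
                            funnels)


def sample_state_trajectory(pl: PlantedLandscape, n_frames: int,
                            frame_interval: float = 20.0, seed: int = 0,
                            ) -> StateTrajectory:
    """Discrete-time Markov sampling with per-frame jump probability k_jk * dt.

    The initial state is drawn from the planted equilibrium distribution.
    Requires sum_k k_jk * dt < 0.5 for every state, the validity regime of
    the first-order discretization.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    k = pl.rates()
    jump_p = k * frame_interval
    total = jump_p.sum(axis=1)
    if np.any(total >= 0.5):
        worst = int(np.argmax(total))
        raise ValueError(
            f"frame interval too coarse: state {worst} has per-frame jump "
            f"probability {total[worst]:.3f} >= 0.5; use a smaller dt"
        )
    rng = np.random.default_rng(seed)
    labels = np.empty(n_frames, dtype=np.intp)
    state = int(rng.choice(pl.n_states, p=pl.probability))
    # geometric dwell-time sampling: equivalent to per-frame Bernoulli jumps
    branch = np.where(total[:, None] > 0, jump_p / total[:, None], 0.0)
    pos = 0
    while pos < n_frames:
        p_leave = total[state]
        if p_leave <= 0:
            labels[pos:] = state
            break
        dwell = rng.geometric(p_leave)  # frames spent before the jump lands
        end = min(pos + dwell, n_frames)
        labels[pos:end] = state
        pos = end
        if pos < n_frames:
            state = int(rng.choice(pl.n_states, p=branch[state]))
    return StateTrajectory(labels, pl.n_states, frame_interval)


def occupation_standard_errors(pl: PlantedLandscape, frame_interval: float,
                               n_frames: int) -> np.ndarray:
    """Asymptotic standard errors of occupation fractions from the sampler.

    Accounts for the autocorrelation of the discrete chain via the
    fundamental matrix Z = (I - T + 1 pi)^-1:
    var(p_hat_i) = [pi_i (1 - pi_i) + 2 pi_i (Z_ii - 1)] / N.
    """
    k = pl.rates()
    t = k * frame_interval
    np.fill_diagonal(t, 0.0)
    np.fill_diagonal(t, 1.0 - t.sum(axis=1))
    pi = pl.probability
    z = np.linalg.inv(np.eye(pl.n_states) - t + np.outer(np.ones(pl.n_states), pi))
    var = (pi * (1.0 - pi) + 2.0 * pi * (np.diag(z) - 1.0)) / n_frames
    return np.sqrt(np.maximum(var, 0.0))


# ---------------------------------------------------------------------------
# toy coordinate trajectories
# ---------------------------------------------------------------------------

@dataclass
class StateTemplate:
    """Per-state reference bead-chain coordinates (nm) plus jitter scale.

    ``drid_separation`` / ``drid_spread`` record the smallest inter-template
    DRID distance and the largest observed jitter-induced DRID displacement
    (both nm^-1), measured at generation; ``suggested_cutoff`` sits between
    those scales so that regular-space clustering recovers the planted
    states.
    """

    coordinates: np.ndarray      # (n_states, n_beads, 3) nm
    jitter: float                # isotropic Gaussian sigma, nm
    bond_length: float = 0.38
    drid_separation: float | None = None
    drid_spread: float | None = None

    @property
    def suggested_cutoff(self) -> float:
        if not self.drid_spread:
            raise ValueError("template carries no generation-time DRID scales")
        return 4.0 * self.drid_spread

    @property
    def n_states(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[1]

    def bonds(self) -> list[tuple[int, int]]:
        return [(i, i + 1) for i in range(self.n_beads - 1)]


def make_templates(n_states: int, n_beads: int = 8, jitter: float = 0.002,
                   seed: int = 0, min_drid_separation_factor: float = 8.0,
                   ) -> StateTemplate:
    """Random self-avoiding bead-chain templates, one per state.

    Templates are random walks with fixed bond length (0.38 nm, the
    C-alpha -- C-alpha spacing); generation retries until the smallest
    inter-template DRID distance exceeds ``min_drid_separation_factor``
    times the jitter-induced DRID spread, so planted states are recoverable
    by clustering.  The jitter default (0.002 nm) is deliberately small:
    reciprocal distances amplify positional noise by 1/d^2, and the
    within-state spread must stay well below the between-template
    separation.
    """
    from .drid import featurize_coordinates, pairwise_drid_distance

    bond = 0.38
    cent = [0, n_beads // 2, n_beads - 1]
    ref = np.arange(n_beads)
    excl = _chain_exclusions(cent, n_beads)

    for attempt in range(64):
        rng = np.random.default_rng((seed, attempt))
        coords = np.empty((n_states, n_beads, 3))
        for s in range(n_states):
            coords[s] = _random_chain(rng, n_beads, bond)
        fp = featurize_coordinates(coords, cent, ref, excl).fingerprints
        d = pairwise_drid_distance(fp, fp)
        sep = np.min(d[np.triu_indices(n_states, 1)]) if n_states > 1 else np.inf
        # empirical jitter spread: DRID distance of jittered copies to template
        spread = 0.0
        for s in range(n_states):
            noisy = coords[s][None] + rng.normal(0.0, jitter, size=(64, n_beads, 3))
            fpn = featurize_coordinates(noisy, cent, ref, excl).fingerprints
            spread = max(spread, pairwise_drid_distance(fpn, fp[s][None]).max())
        if sep > min_drid_separation_factor * max(spread, 1e-12):
            return StateTemplate(coords, jitter, bond, drid_separation=float(sep),
                                 drid_spread=float(spread))
    raise RuntimeError(
        "could not generate sufficiently separated templates; lower the jitter "
        "or the separation factor"
    )


def _random_chain(rng, n_beads, bond, min_sep=0.25):
    for _ in range(50):
        coords = np.zeros((n_beads, 3))
        ok = True
        for i in range(1, n_beads):
            for _try in range(100):
                step = rng.normal(size=3)
                cand = coords[i - 1] + bond * step / np.linalg.norm(step)
                if i < 2 or np.min(np.linalg.norm(coords[:i - 1] - cand, axis=1)) >= min_sep:
                    coords[i] = cand
                    break
            else:
                ok = False
                break
        if ok:
            return coords
    raise RuntimeError("failed to grow a self-avoiding chain")


def _chain_exclusions(centroids, n_beads):
    excl = []
    for c in centroids:
        e = {c}
        if c > 0:
            e.add(c - 1)
        if c < n_beads - 1:
            e.add(c + 1)
        excl.append(frozenset(e))
    return excl


def emit_toy_trajectory(st: StateTrajectory, templates: StateTemplate,
                        seed: int = 0, out_prefix: str | Path | None = None,
                        chunk: int = 100_000):
    """Materialize a coordinate trajectory: template of each frame's state
    plus isotropic Gaussian jitter.

    With ``out_prefix`` the trajectory is written as ``<prefix>.pdb``
    (topology with CONECT bonds) + ``<prefix>.xtc`` and the two paths are
    returned; otherwise the (n_frames, n_beads, 3) nm coordinate array is
    returned directly.
    """
    if templates.n_states < st.n_states:
        raise ValueError(
            f"{st.n_states} states in the trajectory but only "
            f"{templates.n_states} templates"
        )
    rng = np.random.default_rng(seed)
    labels = st.labels
    if out_prefix is None:
        coords = templates.coordinates[labels]
        if templates.jitter > 0:
            coords = coords + rng.normal(0.0, templates.jitter, size=coords.shape)
        return coords

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    top_path = out_prefix.with_suffix(".pdb")
    traj_path = out_prefix.with_suffix(".xtc")
    _write_topology_pdb(top_path, templates)

    from mdtraj.formats import XTCTrajectoryFile

    box = np.diag([10.0, 10.0, 10.0]).astype(np.float32)
    dt_ps = st.frame_interval
    with XTCTrajectoryFile(str(traj_path), "w") as xtc:
        for start in range(0, labels.size, chunk):
            lab = labels[start:start + chunk]
            coords = templates.coordinates[lab]
            if templates.jitter > 0:
                coords = coords + rng.normal(0.0, templates.jitter, size=coords.shape)
            times = (np.arange(start, start + lab.size) * dt_ps).astype(np.float32)
            xtc.write(coords.astype(np.float32), time=times,
                      step=np.arange(start, start + lab.size),
                      box=np.repeat(box[None], lab.size, axis=0))
    return top_path, traj_path


def _write_topology_pdb(path: Path, templates: StateTemplate) -> None:
    """Minimal PDB with one CA bead per residue and explicit CONECT records."""
    coords_a = templates.coordinates[0] * ANGSTROM_PER_NM
    with open(path, "w") as fh:
        fh.write("TITLE     dridscape toy bead chain\n")
        fh.write("CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1\n")
        for i, (x, y, z) in enumerate(coords_a, start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  BEA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        for i, j in templates.bonds():
            fh.write(f"CONECT{i + 1:5d}{j + 1:5d}\n")
        fh.write("END\n")
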