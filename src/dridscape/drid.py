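"""DRID featurization of MD trajectories.

The distribution of reciprocal interatomic distances (DRID) maps each
trajectory frame onto a low-dimensional structural fingerprint.  Two atom
sets are chosen: *m* centroids ``C`` (typically selected C-alpha atoms) and a
reference set ``A`` describing the molecular environment.  For centroid *i*
the reciprocal distances ``1/d_ij`` to every reference atom *j* -- excluding
the centroid itself and atoms covalently bonded to it -- form a distribution
whose first three moments

* ``mu_i``  -- mean,
* ``nu_i``  -- square root of the mean squared deviation,
* ``xi_i``  -- signed cube root of the mean cubed deviation,

characterize the local environment.  A frame is represented by the
3m-vector ``(mu_1, nu_1, xi_1, ..., mu_m, nu_m, xi_m)`` in nm^-1, and the
dissimilarity of two frames is the blocked metric

    s = (1/3m) * sum_i sqrt(dmu_i^2 + dnu_i^2 + dxi_i^2)

Atom selections use the MDAnalysis selection language; topology and
coordinates are read through MDAnalysis, so PDB/GRO topologies and
XTC/TRR/DCD trajectories are supported directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SelectionSpec",
    "DRIDFingerprint",
    "DRIDTrajectory",
    "resolve_selection",
    "centroid_moments",
    "featurize",
    "featurize_coordinates",
    "drid_distance",
    "pairwise_drid_distance",
]

_SIDE_CAR_VERSION = 1


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selections defining the DRID centroids and reference set.

    Parameters
    ----------
    centroid_expr
        MDAnalysis selection resolving to the m centroid atoms (set C).
    reference_expr
        MDAnalysis selection resolving to the reference set A.  Per-centroid
        exclusions (self + covalently bonded atoms) are applied afterwards.
    """

    centroid_expr: str
    reference_expr: str


@dataclass(frozen=True)
class DRIDFingerprint:
    """A single frame's DRID moments, interleaved (mu_1, nu_1, xi_1, ...)."""

    moments: np.ndarray
    m: int

    def __post_init__(self):
        mom = np.asarray(self.moments, dtype=float)
        if mom.ndim != 1 or mom.size != 3 * self.m:
            raise ValueError(
                f"moments must be a flat length-3m vector; got shape {mom.shape} for m={self.m}"
            )
        object.__setattr__(self, "moments", mom)

    @property
    def blocks(self) -> np.ndarray:
        """Moments reshaped to (m, 3) -- one (mu, nu, xi) row per centroid."""
        return self.moments.reshape(self.m, 3)


@dataclass
class DRIDTrajectory:
    """Framewise DRID representation of a trajectory.

    ``fingerprints`` is an (n_frames, 3m) float array; ``frame_interval`` is
    the saving interval in ps.
    """

    fingerprints: np.ndarray
    frame_interval: float
    source_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        fp = np.asarray(self.fingerprints, dtype=float)
        if fp.ndim != 2 or fp.shape[1] % 3 != 0:
            raise ValueError(f"fingerprints must be (n_frames, 3m); got {fp.shape}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 ps")
        self.fingerprints = fp

    @property
    def m(self) -> int:
        return self.fingerprints.shape[1] // 3

    def __len__(self) -> int:
        return self.fingerprints.shape[0]

    def __getitem__(self, i: int) -> DRIDFingerprint:
        return DRIDFingerprint(self.fingerprints[i], self.m)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the (frames x 3m) array as .npy plus a JSON metadata sidecar."""
        path = Path(path)
        if path.suffix != ".npy":
            path = path.with_suffix(path.suffix + ".npy")
        np.save(path, self.fingerprints)
        sidecar = {
            "format": "dridscape.drid_trajectory",
            "version": _SIDE_CAR_VERSION,
            "m": self.m,
            "n_frames": len(self),
            "frame_interval_ps": self.frame_interval,
            "source_label": self.source_label,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DRIDTrajectory":
        path = Path(path)
        if path.suffix != ".npy":
            path = path.with_suffix(path.suffix + ".npy")
        fp = np.load(path)
        sidecar_path = path.with_suffix(".json")
        meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        return cls(
            fingerprints=fp,
            frame_interval=float(meta.get("frame_interval_ps", 1.0)),
            source_label=str(meta.get("source_label", str(path))),
            meta={k: v for k, v in meta.items()
                  if k not in ("format", "version", "m", "n_frames",
                               "frame_interval_ps", "source_label")},
        )


# ---------------------------------------------------------------------------
# selection resolution
# ---------------------------------------------------------------------------

def resolve_selection(universe, spec: SelectionSpec,
                      bonds: Iterable[tuple[int, int]] | None = None):
    """Resolve centroid/reference selections and per-centroid exclusion sets.

    Parameters
    ----------
    universe
        An ``MDAnalysis.Universe`` (or anything with ``select_atoms``).
    spec
        The two selection expressions.
    bonds
        Optional explicit bond table as (i, j) pairs of 0-based atom indices.
        When omitted, the universe's own connectivity is used; if the topology
        carries none, bonds are guessed from interatomic distances and van der
        Waals radii (MDAnalysis ``guess_bonds``).

    Returns
    -------
    centroid_ids : (m,) int array, in selection order
    reference_ids : sorted int array
    exclusions : list of m frozensets, each containing the centroid index and
        its covalently bonded neighbours
    """
    cent = universe.select_atoms(spec.centroid_expr)
    if len(cent) == 0:
        raise ValueError(f"centroid selection matched no atoms: {spec.centroid_expr!r}")
    ref = universe.select_atoms(spec.reference_expr)
    if len(ref) == 0:
        raise ValueError(f"reference selection matched no atoms: {spec.reference_expr!r}")

    centroid_ids = np.asarray(cent.ix, dtype=np.intp)
    if np.unique(centroid_ids).size != centroid_ids.size:
        raise ValueError("centroid selection resolves the same atom more than once")
    reference_ids = np.unique(np.asarray(ref.ix, dtype=np.intp))

    adjacency = _bond_adjacency(universe, bonds)
    exclusions = []
    for ci in centroid_ids:
        excl = {int(ci)} | adjacency.get(int(ci), set())
        exclusions.append(frozenset(excl))
        if not np.setdiff1d(reference_ids, np.fromiter(excl, dtype=np.intp)).size:
            raise ValueError(
                f"no reference atom survives the exclusion set of centroid atom {ci}"
            )
    return centroid_ids, reference_ids, exclusions


def _bond_adjacency(universe, bonds):
    adjacency: dict[int, set[int]] = {}
    if bonds is not None:
        pairs = [(int(i), int(j)) for i, j in bonds]
    else:
        try:
            bond_attr = universe.bonds
        except Exception:
            bond_attr = None
        if bond_attr is None or len(bond_attr) == 0:
            try:
                universe.atoms.guess_bonds()
                bond_attr = universe.bonds
            except Exception:
                bond_attr = None
        pairs = [] if bond_attr is None else [tuple(map(int, b.atoms.ix)) for b in bond_attr]
    for i, j in pairs:
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)
    return adjacency


# ---------------------------------------------------------------------------
# moment computation
# ---------------------------------------------------------------------------

def centroid_moments(coords_nm: np.ndarray, centroid_id: int,
                     reference_ids: Sequence[int],
                     exclusion: Iterable[int]) -> tuple[float, float, float]:
    """First three DRID moments of one centroid for a single frame.

    ``coords_nm`` holds the whole frame's coordinates in nm, shape (N, 3).
    The denominator equals the number of reciprocal distances actually
    summed (reference atoms minus the exclusion set).
    """
    coords_nm = np.asarray(coords_nm, dtype=float)
    included = np.setdiff1d(np.asarray(reference_ids, dtype=np.intp),
                            np.fromiter(exclusion, dtype=np.intp))
    if included.size == 0:
        raise ValueError(f"no reference atoms left for centroid {centroid_id}")
    d = np.linalg.norm(coords_nm[included] - coords_nm[centroid_id], axis=1)
    if np.any(d == 0.0):
        raise ValueError(
            f"zero distance between centroid {centroid_id} and a reference atom; "
            "reciprocal distance diverges"
        )
    return _moments_of_reciprocal(1.0 / d)


def _moments_of_reciprocal(r: np.ndarray) -> tuple[float, float, float]:
    mu = r.mean()
    dev = r - mu
    nu = np.sqrt(np.mean(dev**2))
    third = np.mean(dev**3)
    xi = np.sign(third) * np.abs(third) ** (1.0 / 3.0)
    return float(mu), float(nu), float(xi)


def featurize_coordinates(coords_nm: np.ndarray, centroid_ids, reference_ids,
                          exclusions, frame_interval: float = 1.0,
                          source_label: str = "", frame_offset: int = 0,
                          ) -> DRIDTrajectory:
    """Vectorized DRID moments for a coordinate block of shape (n, N, 3) in nm."""
    coords_nm = np.asarray(coords_nm, dtype=float)
    if coords_nm.ndim != 3:
        raise ValueError("coords_nm must have shape (n_frames, n_atoms, 3)")
    fp = _moment_block(coords_nm, centroid_ids, reference_ids, exclusions,
                       frame_offset)
    return DRIDTrajectory(fp, frame_interval, source_label)


def _moment_block(coords_nm, centroid_ids, reference_ids, exclusions,
                  frame_offset=0):
    n = coords_nm.shape[0]
    m = len(centroid_ids)
    fp = np.empty((n, 3 * m), dtype=float)
    ref = np.asarray(reference_ids, dtype=np.intp)
    for i, (ci, excl) in enumerate(zip(centroid_ids, exclusions)):
        included = np.setdiff1d(ref, np.fromiter(excl, dtype=np.intp))
        diff = coords_nm[:, included, :] - coords_nm[:, int(ci), None, :]
        d = np.sqrt(np.einsum("fjk,fjk->fj", diff, diff))
        if np.any(d == 0.0):
            bad = int(np.argwhere(d == 0.0)[0, 0]) + frame_offset
            raise ValueError(
                f"frame {bad}: zero distance between centroid atom {ci} and a "
                "reference atom; reciprocal distance diverges"
            )
        r = 1.0 / d
        mu = r.mean(axis=1)
        dev = r - mu[:, None]
        nu = np.sqrt(np.mean(dev**2, axis=1))
        third = np.mean(dev**3, axis=1)
        xi = np.sign(third) * np.abs(third) ** (1.0 / 3.0)
        fp[:, 3 * i] = mu
        fp[:, 3 * i + 1] = nu
        fp[:, 3 * i + 2] = xi
    return fp


def featurize(universe, spec: SelectionSpec, frame_interval: float | None = None,
              bonds: Iterable[tuple[int, int]] | None = None,
              chunk_size: int = 2000, source_label: str | None = None,
              ) -> DRIDTrajectory:
    """Compute DRID fingerprints for every frame of a trajectory.

    Frames are streamed through MDAnalysis in chunks and the moments evaluated
    vectorized per chunk.  Coordinates are converted from Angstrom (MDAnalysis
    native) to nm, so the fingerprints are in nm^-1.

    Parameters
    ----------
    universe
        MDAnalysis Universe holding topology + trajectory.
    spec
        Centroid / reference selections.
    frame_interval
        Saving interval in ps; defaults to the trajectory's own ``dt``.
    bonds
        Optional explicit bond table (see :func:`resolve_selection`).
    """
    from .constants import ANGSTROM_PER_NM

    centroid_ids, reference_ids, exclusions = resolve_selection(universe, spec, bonds)
    n_atoms = len(universe.atoms)
    needed = np.unique(np.concatenate([centroid_ids, reference_ids]))
    remap = {int(a): k for k, a in enumerate(needed)}
    cent_local = np.array([remap[int(c)] for c in centroid_ids], dtype=np.intp)
    ref_local = np.array([remap[int(a)] for a in reference_ids], dtype=np.intp)
    excl_local = [frozenset(remap[a] for a in e if a in remap) | {int(cl)}
                  for e, cl in zip(exclusions, cent_local)]

    if frame_interval is None:
        dt = getattr(universe.trajectory, "dt", None)
        frame_interval = float(dt) if dt else 1.0

    blocks = []
    buf = []
    offset = 0
    for k, ts in enumerate(universe.trajectory):
        if ts.positions.shape[0] != n_atoms:
            raise ValueError(
                f"frame {k}: atom count {ts.positions.shape[0]} does not match "
                f"topology ({n_atoms})"
            )
        buf.append(ts.positions[needed] / ANGSTROM_PER_NM)
        if len(buf) == chunk_size:
            blocks.append(_moment_block(np.asarray(buf), cent_local, ref_local,
                                        excl_local, offset))
            offset += len(buf)
            buf = []
    if buf:
        blocks.append(_moment_block(np.asarray(buf), cent_local, ref_local,
                                    excl_local, offset))
    fingerprints = np.concatenate(blocks, axis=0) if blocks else np.empty((0, 3 * len(centroid_ids)))
    label = source_label if source_label is not None else getattr(
        universe.trajectory, "filename", "") or ""
    traj = DRIDTrajectory(fingerprints, frame_interval, str(label))
    traj.meta.update({
        "centroid_expr": spec.centroid_expr,
        "reference_expr": spec.reference_expr,
    })
    return traj


# ---------------------------------------------------------------------------
# the DRID distance metric
# ---------------------------------------------------------------------------

def drid_distance(f1: DRIDFingerprint | np.ndarray, f2: DRIDFingerprint | np.ndarray,
                  m: int | None = None) -> float:
    """DRID-space dissimilarity: mean of per-centroid Euclidean norms / 3.

    ``s = (1/3m) * sum_i || (mu, nu, xi)_i^(1) - (mu, nu, xi)_i^(2) ||``.
    """
    v1, m1 = _as_vector(f1, m)
    v2, m2 = _as_vector(f2, m)
    if m1 != m2:
        raise ValueError(f"fingerprint centroid counts differ: {m1} != {m2}")
    diff = (v1 - v2).reshape(m1, 3)
    return float(np.sum(np.linalg.norm(diff, axis=1)) / (3 * m1))


def pairwise_drid_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All-pairs DRID distances between fingerprint arrays (n1,3m) x (n2,3m)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1] or x.shape[1] % 3 != 0:
        raise ValueError("fingerprint dimensions incompatible")
    m = x.shape[1] // 3
    xb = x.reshape(x.shape[0], m, 3)
    yb = y.reshape(y.shape[0], m, 3)
    diff = xb[:, None, :, :] - yb[None, :, :, :]
    per_centroid = np.sqrt(np.einsum("abmk,abmk->abm", diff, diff))
    return per_centroid.sum(axis=2) / (3 * m)


def _as_vector(f, m):
    if isinstance(f, DRIDFingerprint):
        return f.moments, f.m
    v = np.asarray(f, dtype=float).ravel()
    if m is None:
        if v.size % 3 != 0:
            raise ValueError("fingerprint length must be a multiple of 3")
        m = v.size // 3
    return v, m
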