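"""Regular-space clustering in DRID space and frame-to-state assignment.

A single sequential pass over the trajectory seeds cluster centers: frame 0
becomes the first center, and a later frame becomes a new center iff its
DRID distance to *every* existing center exceeds the cutoff.  Every frame is
then assigned to its nearest center (ties to the lowest center index),
yielding the discrete state trajectory ("state-trj") underlying all kinetic
analysis.  Centers are actual trajectory frames, so states map back to
structures.

The cutoff (nm^-1) sets the granularity of the state space; for comparative
analyses across simulations it must be held fixed so that states of
comparable entropy are identified consistently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .drid import DRIDTrajectory, pairwise_drid_distance

__all__ = [
    "ClusterModel",
    "StateTrajectory",
    "regular_space_cluster",
    "assign",
    "save_model",
    "load_model",
]

_MODEL_VERSION = 1


@dataclass
class ClusterModel:
    """Regular-space cluster centers in DRID space.

    ``centers`` is an (n_centers, 3m) array in insertion order; all pairwise
    DRID distances between centers exceed ``cutoff``.
    """

    centers: np.ndarray
    cutoff: float
    max_centers: int
    seed_frames: np.ndarray | None = None

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] < 1:
            raise ValueError("a cluster model needs at least one center")
        if self.centers.shape[1] % 3 != 0:
            raise ValueError("center vectors must have length 3m")

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]

    @property
    def m(self) -> int:
        return self.centers.shape[1] // 3


@dataclass
class StateTrajectory:
    """Per-frame discrete state labels (0-based) at a fixed frame interval."""

    labels: np.ndarray
    n_states: int
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_states):
            raise ValueError("labels out of range [0, n_states)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 ps")

    def __len__(self) -> int:
        return self.labels.size

    def save(self, path: str | Path) -> None:
        """One integer per line (0-based), plus a JSON metadata sidecar."""
        path = Path(path)
        np.savetxt(path, self.labels, fmt="%d")
        sidecar = {
            "format": "dridscape.state_trajectory",
            "n_states": int(self.n_states),
            "frame_interval_ps": self.frame_interval,
            **self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StateTrajectory":
        path = Path(path)
        labels = np.loadtxt(path, dtype=np.intp, ndmin=1)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        n_states = int(meta.get("n_states", labels.max() + 1 if labels.size else 0))
        return cls(labels, n_states, float(meta.get("frame_interval_ps", 1.0)),
                   {k: v for k, v in meta.items()
                    if k not in ("format", "n_states", "frame_interval_ps")})


def regular_space_cluster(drid: DRIDTrajectory, cutoff: float,
                          max_centers: int = 2000) -> ClusterModel:
    """Seed cluster centers by a single sequential regular-space pass.

    Raises if the center count would exceed ``max_centers``: truncating the
    center set silently changes the entropy of the state decomposition, so
    the remedy is a larger cutoff, not a truncated model.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    fp = drid.fingerprints
    if fp.shape[0] == 0:
        raise ValueError("cannot cluster an empty DRID trajectory")

    centers = [fp[0]]
    seed_frames = [0]
    n = fp.shape[0]
    chunk = 8192
    start = 1
    while start < n:
        stop = min(start + chunk, n)
        block = fp[start:stop]
        # distance of the whole block to the current centers; frames within
        # cutoff of any existing center can never become centers, and new
        # centers can only come from the remaining candidates in block order
        dmat = pairwise_drid_distance(block, np.asarray(centers))
        candidate = np.flatnonzero((dmat > cutoff).all(axis=1))
        while candidate.size:
            idx = int(candidate[0])
            new_center = block[idx]
            centers.append(new_center)
            seed_frames.append(start + idx)
            if len(centers) > max_centers:
                raise ValueError(
                    f"regular-space clustering would exceed max_centers="
                    f"{max_centers}; increase the cutoff"
                )
            rest = candidate[1:]
            if rest.size == 0:
                break
            d_new = pairwise_drid_distance(block[rest], new_center[None, :])[:, 0]
            candidate = rest[d_new > cutoff]
        start = stop
    return ClusterModel(np.asarray(centers), cutoff, max_centers,
                        np.asarray(seed_frames, dtype=np.intp))


def assign(drid: DRIDTrajectory, model: ClusterModel) -> StateTrajectory:
    """Label every frame with its nearest center (ties -> lowest index)."""
    if model.m != drid.m:
        raise ValueError(
            f"model centroid count ({model.m}) does not match trajectory ({drid.m})"
        )
    fp = drid.fingerprints
    if fp.shape[0] == 0:
        raise ValueError("cannot assign an empty DRID trajectory")
    labels = np.empty(fp.shape[0], dtype=np.intp)
    chunk = 8192
    for start in range(0, fp.shape[0], chunk):
        block = fp[start:start + chunk]
        d = pairwise_drid_distance(block, model.centers)
        labels[start:start + block.shape[0]] = np.argmin(d, axis=1)
    return StateTrajectory(labels, model.n_states, drid.frame_interval)


def save_model(model: ClusterModel, path: str | Path) -> None:
    """Persist the model as self-describing JSON (portable, versioned)."""
    payload = {
        "format": "dridscape.cluster_model",
        "version": _MODEL_VERSION,
        "m": model.m,
        "cutoff": model.cutoff,
        "max_centers": model.max_centers,
        "centers": model.centers.tolist(),
        "seed_frames": None if model.seed_frames is None else model.seed_frames.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ClusterModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted cluster-model file {path}: {exc}") from exc
    if payload.get("format") != "dridscape.cluster_model":
        raise ValueError(f"{path} is not a dridscape cluster-model file")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(
            f"cluster-model version mismatch: file has {payload.get('version')}, "
            f"this build reads {_MODEL_VERSION}"
        )
    seed = payload.get("seed_frames")
    return ClusterModel(
        np.asarray(payload["centers"], dtype=float),
        float(payload["cutoff"]),
        int(payload["max_centers"]),
        None if seed is None else np.asarray(seed, dtype=np.intp),
    )
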