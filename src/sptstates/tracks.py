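"""Trajectory containers and track-level geometry.

Positions are in micrometres, frame indices are 0-based integers and the
frame interval ``tau`` is in seconds.  A :class:`TrackSet` is the universal
currency passed between the simulators, the HDP-HMM sampler and the
diffusion-type classifier.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_CSV_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


@dataclass
class Track:
    """A single 2D trajectory: integer frame indices and (x, y) in µm."""

    track_id: object
    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if self.frames.shape[0] != self.xy.shape[0]:
            raise ValueError("frames and xy must have equal length")
        if self.frames.size >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError(
                f"track {self.track_id!r}: frame indices must be strictly increasing"
            )

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class TrackSet:
    """A collection of tracks sharing one frame interval ``tau`` (s)."""

    tracks: list[Track]
    tau: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("frame interval tau must be > 0")
        for t in self.tracks:
            if len(t) < 2:
                raise ValueError(
                    f"track {t.track_id!r} has {len(t)} position(s); need >= 2"
                )

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def n_steps(self) -> int:
        """Total number of single-frame displacements across all tracks."""
        return sum(int(np.sum(np.diff(t.frames) == 1)) for t in self.tracks)


@dataclass
class StateSequence:
    """Per-track hidden-state labels, one label per displacement.

    Labels are integers in ``{1..n_states}``; ``labels[i]`` has length
    ``len(track_i) - 1``.
    """

    labels: list[np.ndarray]
    n_states: int

    def __post_init__(self) -> None:
        self.labels = [np.asarray(z, dtype=np.int64) for z in self.labels]
        for z in self.labels:
            if z.size and (z.min() < 1 or z.max() > self.n_states):
                raise ValueError("labels must lie in {1..n_states}")

    def concatenated(self) -> np.ndarray:
        if not self.labels:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(self.labels)

    @property
    def total_length(self) -> int:
        return sum(z.size for z in self.labels)


@dataclass
class GroundTruth:
    """Simulation ground truth attached to a synthetic :class:`TrackSet`."""

    state_sequence: StateSequence
    diffusion_coefficients: np.ndarray  # (K, 2) per-axis D in µm²/s
    transition_matrix: np.ndarray  # (K, K) row-stochastic
    diffusion_types: list[str] = field(default_factory=list)  # per state
    anomalous_exponents: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.diffusion_coefficients = np.atleast_2d(
            np.asarray(self.diffusion_coefficients, dtype=float)
        )
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if np.any(self.diffusion_coefficients <= 0):
            raise ValueError("all per-state diffusion coefficients must be > 0")
        rows = self.transition_matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if not self.diffusion_types:
            self.diffusion_types = ["BM"] * self.diffusion_coefficients.shape[0]

    @property
    def stationary_weights(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        P = self.transition_matrix
        vals, vecs = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        w = np.real(vecs[:, i])
        return w / w.sum()


def displacements_from_tracks(tracks: TrackSet) -> list[tuple[object, np.ndarray]]:
    """Single-frame displacement runs for every track.

    Displacements are only taken between consecutive frames; a missing frame
    splits a track into independent runs (no displacement spans the gap).
    Tracks (or run fragments) with fewer than two positions contribute
    nothing.  Returns ``[(track_id, (m, 2) array), ...]`` preserving track
    order.
    """
    runs: list[tuple[object, np.ndarray]] = []
    for t in tracks:
        if len(t) < 2:
            logger.warning("track %r has < 2 positions; skipped", t.track_id)
            continue
        gaps = np.diff(t.frames)
        # split position indices where the frame step exceeds 1
        breakpoints = np.flatnonzero(gaps != 1) + 1
        for seg in np.split(np.arange(len(t)), breakpoints):
            if seg.size < 2:
                continue
            runs.append((t.track_id, np.diff(t.xy[seg], axis=0)))
    return runs


def rotate_tracks(tracks: TrackSet, angle: float | Sequence[float]) -> TrackSet:
    """Rigidly rotate every track about its own centroid.

    ``angle`` is in radians, either one value for all tracks or one per
    track.  Step lengths are preserved exactly; used to align the camera
    x-axis with, e.g., a cell's long axis before anisotropy analysis.
    """
    angles = np.broadcast_to(np.asarray(angle, dtype=float), (len(tracks),))
    if not np.all(np.isfinite(angles)):
        raise ValueError("rotation angles must be finite")
    out = []
    for t, a in zip(tracks, angles):
        c, s = np.cos(a), np.sin(a)
        R = np.array([[c, -s], [s, c]])
        centroid = t.xy.mean(axis=0)
        out.append(Track(t.track_id, t.frames.copy(), (t.xy - centroid) @ R.T + centroid))
    return TrackSet(out, tracks.tau, dict(tracks.meta))


# ---------------------------------------------------------------------------
# CSV + JSON sidecar I/O


def write_tracks(tracks: TrackSet, path: str | Path) -> Path:
    """Write a TrackSet to ``<path>.csv`` plus a ``<path>.json`` sidecar.

    The CSV has columns ``track_id,frame,x_um,y_um``; the sidecar stores the
    frame interval and any metadata (seed, ground truth) attached to the set.
    """
    path = Path(path)
    if path.suffix == ".csv":
        path = path.with_suffix("")
    rows = []
    for t in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frames,
                    "x_um": t.xy[:, 0],
                    "y_um": t.xy[:, 1],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    csv_path = path.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {"frame_interval_s": tracks.tau, **_jsonable(tracks.meta)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_tracks(path: str | Path, tau: float | None = None) -> TrackSet:
    """Read a TrackSet from the documented CSV format.

    ``tau`` falls back to the ``frame_interval_s`` entry of a JSON sidecar
    next to the CSV; it is an error for neither to be present.  Rows are
    sorted by ``(track_id, frame)``; a duplicated frame within one track is
    an error naming that track.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV is missing columns: {missing}")
    for c in ("x_um", "y_um"):
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"column {c} is not numeric")
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if tau is None:
            tau = meta.get("frame_interval_s")
    if tau is None:
        raise ValueError(
            "frame interval unknown: no JSON sidecar and no tau argument"
        )
    df = df.sort_values(["track_id", "frame"], kind="mergesort")
    tracks = []
    for tid, g in df.groupby("track_id", sort=False):
        frames = g["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) == 0):
            raise ValueError(f"track {tid!r} has duplicate frame indices")
        tracks.append(Track(tid, frames, g[["x_um", "y_um"]].to_numpy(dtype=float)))
    return TrackSet(tracks, float(tau), meta)


def _jsonable(obj):
    """Recursively convert numpy containers to plain JSON types."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
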