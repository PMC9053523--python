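"""Same-state track segments: extraction, normalization, state-level pooling.

The diffusion-type classifier consumes maximal runs of consecutive steps
sharing one inferred state label.  Segments are normalized to zero mean and
unit pooled variance (one scale factor across x and y, preserving the
aspect ratio and hence anisotropy cues) so that classification depends on
the shape of the walk, not on its diffusion coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tracks import StateSequence, TrackSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_SEGMENT_STEPS = 40


@dataclass
class Segment:
    """A contiguous same-state coordinate run: ``n_steps + 1`` positions."""

    track_id: object
    state: int
    xy: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.xy.shape[0] - 1


@dataclass
class SegmentBatch:
    segments: list[Segment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def states(self) -> np.ndarray:
        return np.unique([s.state for s in self.segments])


def extract_segments(
    tracks: TrackSet,
    labels: StateSequence,
    min_length: int = DEFAULT_MIN_SEGMENT_STEPS,
) -> SegmentBatch:
    """Maximal constant-label coordinate runs of at least ``min_length`` steps.

    ``labels`` must hold one label per displacement of each track (length
    ``len(track) - 1``); a mismatch is an error.  Runs shorter than
    ``min_length`` are dropped (counts logged).
    """
    if len(labels.labels) != len(tracks.tracks):
        raise ValueError("labels and tracks have different track counts")
    batch = SegmentBatch()
    n_dropped = 0
    for track, z in zip(tracks, labels.labels):
        if z.size != len(track) - 1:
            raise ValueError(
                f"track {track.track_id!r}: {z.size} labels for {len(track)} positions"
            )
        boundaries = np.flatnonzero(np.diff(z) != 0) + 1
        for seg in np.split(np.arange(z.size), boundaries):
            if seg.size < min_length:
                n_dropped += 1
                continue
            xy = track.xy[seg[0] : seg[-1] + 2]
            batch.segments.append(Segment(track.track_id, int(z[seg[0]]), xy))
    if n_dropped:
        logger.info("dropped %d segments shorter than %d steps", n_dropped, min_length)
    return batch


def normalize_segment(xy: np.ndarray) -> np.ndarray:
    """Zero-mean, unit pooled-variance copy of a coordinate run.

    One scale factor is shared by x and y (the mean of the two per-axis
    variances becomes 1), so relative anisotropy survives normalization and
    the output is invariant to translation and global rescaling.  An
    immobile (zero-variance) segment cannot be normalized and raises.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("segment needs >= 2 positions")
    centred = xy - xy.mean(axis=0)
    pooled_var = centred.var(axis=0).mean()
    if pooled_var <= 0:
        raise ValueError("degenerate segment: all positions identical")
    return centred / np.sqrt(pooled_var)


def normalize_batch(windows: np.ndarray) -> np.ndarray:
    """Vectorised :func:`normalize_segment` over a (B, T, 2) stack."""
    centred = windows - windows.mean(axis=1, keepdims=True)
    pooled = centred.var(axis=1).mean(axis=1)
    pooled = np.where(pooled > 0, pooled, np.nan)
    return centred / np.sqrt(pooled)[:, None, None]


def state_type_probability(
    batch: SegmentBatch, probs: np.ndarray, class_names: tuple[str, ...]
) -> dict[int, dict]:
    """Length-weighted mean classification probability per state.

    ``probs`` holds one probability vector per segment of ``batch``.  Each
    state's vector is ``sum(len_i * p_i) / sum(len_i)`` over its segments;
    a state with no usable segment is reported as unclassifiable.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape[0] != len(batch):
        raise ValueError("one probability vector per segment required")
    out: dict[int, dict] = {}
    for state in batch.states():
        idx = [i for i, s in enumerate(batch.segments) if s.state == state]
        lengths = np.array([batch.segments[i].n_steps for i in idx], dtype=float)
        usable = [i for i, ln in zip(idx, lengths) if np.all(np.isfinite(probs[i]))]
        if not usable:
            out[int(state)] = {"classifiable": False}
            continue
        lengths = np.array([batch.segments[i].n_steps for i in usable], dtype=float)
        P = probs[usable]
        vec = (lengths[:, None] * P).sum(axis=0) / lengths.sum()
        out[int(state)] = {
            "classifiable": True,
            "probabilities": dict(zip(class_names, vec.tolist())),
            "top_type": class_names[int(np.argmax(vec))],
            "n_segments": len(usable),
        }
    return out
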