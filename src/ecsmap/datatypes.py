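"""Shared containers for trajectories, images and orientation segments.

Conventions: coordinates are micrometres in image coordinates (x right, y down,
origin top-left); frame indices are 0-based integers; the frame interval ``dt``
is a dataset-level constant in seconds (default 0.03 s, i.e. 30 ms exposure).
Orientations are axial (period pi) and reduced to [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "TrajectorySet", "BinarizedImage", "SegmentSet"]


@dataclass
class Trajectory:
    """Ordered localizations of one tracked particle.

    Frames must be strictly increasing; gaps (missing frames, e.g. from
    quantum-dot blinking) are allowed and preserved.
    """

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    recording: str = "rec0"
    region: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.frames.size == 0:
            raise ValueError("trajectory needs at least one localization")
        if not (self.frames.size == self.x.size == self.y.size):
            raise ValueError("frames, x, y must have equal length")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError(
                f"frames must be strictly increasing (track {self.track_id!r})"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"non-finite coordinates in track {self.track_id!r}")

    @property
    def n_points(self) -> int:
        return int(self.frames.size)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of localizations in micrometres."""
        return np.column_stack([self.x, self.y])


@dataclass
class TrajectorySet:
    """A collection of trajectories sharing one frame interval ``dt`` (s)."""

    trajectories: list[Trajectory]
    dt: float = 0.03
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        keys = [(t.recording, t.track_id) for t in self.trajectories]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (recording, track) pairs in set")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def recordings(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trajectories:
            seen.setdefault(t.recording, None)
        return list(seen)

    def subset(self, recording: str) -> "TrajectorySet":
        kept = [t for t in self.trajectories if t.recording == recording]
        return TrajectorySet(kept, dt=self.dt, metadata=dict(self.metadata))


@dataclass
class BinarizedImage:
    """Bilevel raster; foreground (True) is extracellular space (ECS)."""

    data: np.ndarray
    pitch_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("image must be 2D")
        if self.pitch_nm <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SegmentSet:
    """Axial orientation samples: (orientation in [0, pi), length in um) pairs."""

    orientations: np.ndarray
    lengths: np.ndarray
    owner: str = ""

    def __post_init__(self) -> None:
        self.orientations = np.mod(np.asarray(self.orientations, dtype=float), np.pi)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.orientations.size != self.lengths.size:
            raise ValueError("orientations and lengths must have equal length")
        if self.orientations.size and not np.all(self.lengths > 0):
            raise ValueError("segment lengths must be strictly positive")

    @property
    def n(self) -> int:
        return int(self.orientations.size)

    def total_length(self) -> float:
        return float(self.lengths.sum())

    @staticmethod
    def concatenate(sets: list["SegmentSet"], owner: str = "pooled") -> "SegmentSet":
        if not sets:
            return SegmentSet(np.empty(0), np.empty(0), owner=owner)
        return SegmentSet(
            np.concatenate([s.orientations for s in sets]),
            np.concatenate([s.lengths for s in sets]),
            owner=owner,
        )
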