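"""Trajectory container: time-ordered conformations with seed provenance."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Ordered conformations of one chain.

    ``frames`` has shape (n_frames, n_beads, 3) in sigma units; ``times`` is
    the reduced simulation time of each frame (strictly increasing).  The
    seed that produced the trajectory is recorded for provenance.
    """

    frames: np.ndarray
    times: np.ndarray
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_beads, 3)")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    @property
    def com(self) -> np.ndarray:
        """Center of mass per frame, shape (n_frames, 3)."""
        return self.frames.mean(axis=1)

    def times_seconds(self, time_calibration: float) -> np.ndarray:
        """Frame times in seconds given a seconds-per-reduced-time factor."""
        return self.times * time_calibration

    # ---------------------------------------------------------------- I/O

    def to_npz(self, path) -> None:
        """Save as a compressed array container with metadata."""
        np.savez_compressed(
            path,
            frames=self.frames,
            times=self.times,
            seed=np.int64(-1 if self.seed is None else self.seed),
        )

    @classmethod
    def from_npz(cls, path) -> "Trajectory":
        with np.load(path) as d:
            seed = int(d["seed"])
            return cls(
                frames=d["frames"],
                times=d["times"],
                seed=None if seed < 0 else seed,
            )

    def to_xyz(self, path, labels=None) -> None:
        """Write as multi-frame XYZ text (element column from A/B labels)."""
        n = self.n_beads
        if labels is None:
            labels = ["C"] * n
        with open(path, "w") as fh:
            for f in range(self.n_frames):
                fh.write(f"{n}\n")
                fh.write(f"t={self.times[f]:.8g}\n")
                for el, (x, y, z) in zip(labels, self.frames[f]):
                    fh.write(f"{el} {x:.8g} {y:.8g} {z:.8g}\n")

    @classmethod
    def from_xyz(cls, path) -> "Trajectory":
        frames, times = [], []
        with open(path) as fh:
            lines = fh.read().split("\n")
        i = 0
        while i < len(lines) and lines[i].strip():
            n = int(lines[i])
            comment = lines[i + 1]
            t = len(times)
            if "t=" in comment:
                t = float(comment.split("t=")[1].split()[0])
            coords = np.array(
                [lines[i + 2 + k].split()[1:4] for k in range(n)], dtype=float
            )
            frames.append(coords)
            times.append(t)
            i += 2 + n
        return cls(frames=np.array(frames), times=np.array(times, dtype=float))
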