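"""Calibrated height-map containers.

A :class:`HeightFrame` is a single AFM topograph: a rectangular raster of
surface heights in nanometres over square pixels of known physical size.
A :class:`Movie` is a time-ordered sequence of frames sharing one
calibration, the raw input of every analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = ["HeightFrame", "Movie"]


@dataclass
class HeightFrame:
    """A single calibrated 2D height raster.

    Parameters
    ----------
    grid : ndarray, shape (rows, cols)
        Heights in nm. Row index maps to physical y, column index to x,
        with ``x = col * pixel_size_nm`` (0-based pixel indices).
    pixel_size_nm : float
        Edge length of a (square) pixel, nm.
    t_s : float
        Acquisition timestamp, seconds.
    """

    grid: np.ndarray
    pixel_size_nm: float
    t_s: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2D (rows, cols)")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("heights must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def copy_with(self, grid: np.ndarray) -> "HeightFrame":
        """A new frame with the same calibration and a replaced grid."""
        return replace(self, grid=np.asarray(grid, dtype=float))


@dataclass
class Movie:
    """Time-ordered frames with uniform pixel size.

    Invariants checked at construction: at least one frame, strictly
    increasing timestamps, one common pixel size.
    """

    frames: list[HeightFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a movie needs at least one frame")
        px = {f.pixel_size_nm for f in self.frames}
        if len(px) != 1:
            raise ValueError("all frames must share one pixel size")
        times = [f.t_s for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def pixel_size_nm(self) -> float:
        return self.frames[0].pixel_size_nm

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_interval_s(self) -> float:
        """Median frame spacing (exact spacing for uniformly timed movies)."""
        if len(self.frames) == 1:
            return 0.0
        times = np.array([f.t_s for f in self.frames])
        return float(np.median(np.diff(times)))

    def __iter__(self) -> Iterator[HeightFrame]:
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> HeightFrame:
        return self.frames[i]

    @classmethod
    def from_arrays(
        cls,
        grids: Sequence[np.ndarray],
        pixel_size_nm: float,
        frame_interval_s: float = 0.5,
        t0_s: float = 0.0,
    ) -> "Movie":
        frames = [
            HeightFrame(g, pixel_size_nm, t0_s + i * frame_interval_s)
            for i, g in enumerate(grids)
        ]
        return cls(frames)
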