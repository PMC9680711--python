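"""Movie container and multi-page TIFF I/O.

A movie is a ``T x H x W`` stack of camera frames: the raw input to every
SOFI reconstruction. Frames are promoted to double precision on load so
that high-order powered deviations do not overflow integer camera types.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["Movie", "as_movie", "resolve_frame_range", "write_tiff"]


@dataclass
class Movie:
    """A ``T x H x W`` fluorescence movie.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``; any real dtype, converted to float64.
        All values must be finite.
    """

    frames: np.ndarray
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=np.float64)
        if arr.ndim == 2:  # single frame is a 1-frame movie
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"movie must be T x H x W, got shape {arr.shape}")
        if arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError(f"movie frames must be at least 1x1, got {arr.shape[1:]}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("movie contains non-finite values")
        self.frames = arr

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def T(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @classmethod
    def from_tiff(cls, path: str | os.PathLike) -> "Movie":
        """Read a multi-page grayscale TIFF stack (frames along first axis)."""
        path = os.fspath(path)
        if not os.path.exists(path):
            raise FileNotFoundError(f"no such movie file: {path}")
        arr = tifffile.imread(path)
        return cls(np.asarray(arr, dtype=np.float64), source=path)

    def to_tiff(self, path: str | os.PathLike, dtype=np.float32) -> str:
        """Write the movie as a multi-page TIFF with the given sample dtype."""
        path = os.fspath(path)
        tifffile.imwrite(path, np.asarray(self.frames, dtype=dtype))
        return path

    def select(self, frame_range: tuple[int, int] | None) -> np.ndarray:
        """Frames of the half-open interval ``[start, end)`` (view, not copy)."""
        sl = resolve_frame_range(self.T, frame_range)
        return self.frames[sl]


def as_movie(movie) -> Movie:
    """Coerce a ``Movie``, array, or TIFF path into a :class:`Movie`."""
    if isinstance(movie, Movie):
        return movie
    if isinstance(movie, (str, os.PathLike)):
        return Movie.from_tiff(movie)
    return Movie(np.asarray(movie))


def resolve_frame_range(n_frames: int, frame_range: tuple[int, int] | None) -> slice:
    """Validate a half-open, 0-based ``[start, end)`` frame interval.

    ``None`` selects all frames. The selection must be non-empty and lie
    within ``[0, n_frames)``.
    """
    if frame_range is None:
        return slice(0, n_frames)
    start, end = int(frame_range[0]), int(frame_range[1])
    if start < 0 or end > n_frames or start >= end:
        raise ValueError(
            f"frame range [{start}, {end}) is empty or outside [0, {n_frames})"
        )
    return slice(start, end)


def write_tiff(path: str | os.PathLike, image: np.ndarray, dtype=np.float32) -> str:
    """Write an image (or stack) as TIFF, 32-bit float by default."""
    path = os.fspath(path)
    tifffile.imwrite(path, np.asarray(image, dtype=dtype))
    return path
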