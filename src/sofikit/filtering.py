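"""Gaussian kernels and pixel-wise temporal noise filtering.

High-order reconstruction images computed from consecutive time blocks of
one acquisition fluctuate from block to block because each block is a
short, noisy sample. Filtering each pixel's block-series with a unit-sum
Gaussian kernel along the time (block) axis suppresses that noise without
mixing spatial neighbors, which would blur the super-resolved structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

__all__ = ["KernelSpec", "ImageSeries", "gauss1d_kernel", "gauss2d_kernel", "noise_filter1d"]


@dataclass
class KernelSpec:
    """A normalized Gaussian kernel: non-negative weights summing to 1,
    symmetric about the center, peaked at the center."""

    shape: tuple[int, ...]
    sigma: float
    weights: np.ndarray

    @property
    def length(self) -> int:
        """Flat length, for 1-D kernels."""
        return int(np.prod(self.shape))


@dataclass
class ImageSeries:
    """Ordered, equally-shaped images keyed by time-block identifier."""

    keys: list
    images: np.ndarray  # (M, H, W)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError(f"image series must be M x H x W, got {self.images.shape}")
        if len(self.keys) != self.images.shape[0]:
            raise ValueError(
                f"{len(self.keys)} keys for {self.images.shape[0]} images"
            )

    @classmethod
    def from_dict(cls, mapping: dict) -> "ImageSeries":
        keys = list(mapping)
        return cls(keys=keys, images=np.stack([mapping[k] for k in keys]))

    def to_dict(self) -> dict:
        return {k: self.images[i] for i, k in enumerate(self.keys)}

    def __len__(self) -> int:
        return self.images.shape[0]

    def __getitem__(self, key) -> np.ndarray:
        return self.images[self.keys.index(key)]


def gauss1d_kernel(length: int, sigma: float) -> KernelSpec:
    """1-D Gaussian kernel sampled at integer offsets, normalized to sum 1."""
    if length < 1 or length % 2 == 0:
        raise ValueError(f"kernel length must be a positive odd integer, got {length}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    offsets = np.arange(length) - length // 2
    w = np.exp(-(offsets**2) / (2.0 * sigma**2))
    w /= w.sum()
    return KernelSpec(shape=(1, length), sigma=float(sigma), weights=w)


def gauss2d_kernel(shape: tuple[int, int], sigma: float) -> KernelSpec:
    """Separable 2-D Gaussian kernel (outer product of 1-D kernels), sum 1."""
    rows, cols = shape
    if rows % 2 == 0 or cols % 2 == 0 or rows < 1 or cols < 1:
        raise ValueError(f"kernel dimensions must be positive odd integers, got {shape}")
    wr = gauss1d_kernel(rows, sigma).weights
    wc = gauss1d_kernel(cols, sigma).weights
    return KernelSpec(shape=(rows, cols), sigma=float(sigma), weights=np.outer(wr, wc))


def noise_filter1d(series: ImageSeries | dict, kernel: KernelSpec) -> ImageSeries:
    """Convolve each pixel's block-series with a 1-D kernel along time.

    Boundaries use reflect padding that mirrors about the edge sample
    without repeating it (``... s2 s1 | s0 s1 s2 ...``), so a kernel of
    length L needs a series of at least ``(L+1)/2`` blocks. Keys and order
    are preserved; a constant series is a fixed point of any unit-sum
    kernel.
    """
    if isinstance(series, dict):
        series = ImageSeries.from_dict(series)
    w = np.ravel(kernel.weights)
    if kernel.shape[0] != 1 and len(kernel.shape) > 1:
        raise ValueError(f"temporal filtering needs a 1-D kernel, got shape {kernel.shape}")
    m = len(series)
    if w.size > 2 * m - 1:
        raise ValueError(
            f"kernel length {w.size} exceeds 2M-1 = {2 * m - 1} for M = {m} blocks"
        )
    if w.size == 1:
        filtered = series.images * w[0]
    else:
        filtered = convolve1d(series.images, w, axis=0, mode="mirror")
    return ImageSeries(keys=list(series.keys), images=filtered)
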