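"""Temporal moment and cumulant reconstruction, and photobleaching correction.

The pixel intensity of a blinking-emitter movie is modelled as

    F(r, t) = sum_k  eps_k * b_k(t) * U(r - r_k)

where ``b_k`` is the on/off blinking trace of emitter ``k``, ``eps_k`` its
on-state brightness and ``U`` the point spread function. SOFI reconstructs
per-pixel temporal cumulants of the fluctuation ``dF = F - <F>_t``: the
n-th order cumulant image carries the PSF raised to the n-th power, i.e. a
sqrt(n)-fold narrower Gaussian, and per-emitter "virtual brightnesses"
``eps_k**n * omega_n(rho_k)`` that can be negative.

Moments are *centered* (computed on ``dF``) and use population-style time
averages (divide by the number of frames, no bias correction). Cumulant
images are obtained from moment images with the recursion

    Cum_n = G_n - sum_{i=1}^{n-1} C(n-1, i) * Cum_{n-i} * G_i

evaluated pixel-wise in ascending order, where ``G_n`` is the n-th centered
moment image and ``C(n-1, i)`` a binomial coefficient. The recursion is
algebraically invertible, which :func:`moments_from_cumulants` implements.

Photobleaching correction (BC) splits the movie into blocks of equal
fractional total-signal decay, reconstructs each block independently (each
block is centered on its own mean, removing most of the bleaching trend)
and averages the per-order images over blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from .movie import Movie, as_movie, resolve_frame_range

__all__ = [
    "MomentSet",
    "CumulantSet",
    "BleachSchedule",
    "average_image",
    "moment_image",
    "calc_moments_set",
    "cumulants_from_moments",
    "moments_from_cumulants",
    "total_signal",
    "smooth_monotone",
    "bleach_blocks",
    "correct_bleaching",
]


@dataclass
class MomentSet:
    """Centered temporal moment images ``G_n`` for n = 1..highest_order.

    ``order_to_image[1]`` is identically zero (first centered moment);
    ``average`` is the temporal mean image ``<F>_t``.
    """

    order_to_image: dict[int, np.ndarray]
    average: np.ndarray
    highest_order: int

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.order_to_image.values()}
        shapes.add(self.average.shape)
        if len(shapes) != 1:
            raise ValueError(f"moment images disagree in shape: {shapes}")

    def __getitem__(self, order: int) -> np.ndarray:
        return self.order_to_image[order]


@dataclass
class CumulantSet:
    """Cumulant images ``Cum_n`` for n = 1..highest_order."""

    order_to_image: dict[int, np.ndarray]
    highest_order: int

    def __getitem__(self, order: int) -> np.ndarray:
        return self.order_to_image[order]


@dataclass
class BleachSchedule:
    """Total-intensity bleaching profile and the derived frame blocks.

    ``blocks`` are half-open ``[start, end)`` frame ranges that are
    contiguous, non-empty and cover ``[0, T)``.
    """

    total_signal: np.ndarray
    smoothed: np.ndarray
    fbc: float
    blocks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def _check_orders(order_to_image: dict[int, np.ndarray], highest_order: int) -> None:
    for n in range(1, highest_order + 1):
        if n not in order_to_image:
            raise ValueError(f"missing order {n} (need all orders 1..{highest_order})")


def average_image(movie, frame_range: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel arithmetic mean over the selected frames."""
    mov = as_movie(movie)
    return mov.select(frame_range).mean(axis=0)


def moment_image(movie, order: int, frame_range: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel centered temporal moment ``<(F - <F>)^order>``.

    Order 1 returns the zero image by construction. Orders >= 2 require at
    least 2 selected frames.
    """
    if order < 1:
        raise ValueError(f"moment order must be >= 1, got {order}")
    mov = as_movie(movie)
    frames = mov.select(frame_range)
    if order == 1:
        return np.zeros(frames.shape[1:], dtype=np.float64)
    if frames.shape[0] < 2:
        raise ValueError(
            f"moment of order {order} needs >= 2 frames, got {frames.shape[0]}"
        )
    # two-pass: mean first, then powered deviations, in double precision;
    # iterated products so per-order results match calc_moments_set exactly
    delta = frames - frames.mean(axis=0)
    power = delta.copy()
    for _ in range(order - 1):
        power *= delta
    return power.mean(axis=0)


def calc_moments_set(movie, highest_order: int,
                     frame_range: tuple[int, int] | None = None) -> MomentSet:
    """Centered moment images for all orders ``1..highest_order`` plus the mean.

    Single pass over the powered deviations; equal (to rounding) to calling
    :func:`moment_image` per order.
    """
    if highest_order < 1:
        raise ValueError(f"highest_order must be >= 1, got {highest_order}")
    mov = as_movie(movie)
    frames = mov.select(frame_range)
    avg = frames.mean(axis=0)
    images: dict[int, np.ndarray] = {1: np.zeros_like(avg)}
    if highest_order >= 2:
        if frames.shape[0] < 2:
            raise ValueError(
                f"moments of order >= 2 need >= 2 frames, got {frames.shape[0]}"
            )
        delta = frames - avg
        power = delta.copy()
        for n in range(2, highest_order + 1):
            power *= delta
            images[n] = power.mean(axis=0)
    return MomentSet(order_to_image=images, average=avg, highest_order=highest_order)


def cumulants_from_moments(moments: MomentSet) -> CumulantSet:
    """Cumulant images from moment images via the ascending recursion.

    ``Cum_n = G_n - sum_{i=1}^{n-1} C(n-1, i) Cum_{n-i} G_i`` pixel-wise.
    With centered moments (``G_1 = 0``) the order-2 and order-3 cumulants
    equal the moments exactly.
    """
    _check_orders(moments.order_to_image, moments.highest_order)
    cums: dict[int, np.ndarray] = {}
    for n in range(1, moments.highest_order + 1):
        total = moments.order_to_image[n].copy()
        for i in range(1, n):
            total -= comb(n - 1, i, exact=True) * cums[n - i] * moments.order_to_image[i]
        cums[n] = total
    return CumulantSet(order_to_image=cums, highest_order=moments.highest_order)


def moments_from_cumulants(cumulants: CumulantSet) -> MomentSet:
    """Moment images from cumulant images (the inverse recursion).

    ``G_n = Cum_n + sum_{i=1}^{n-1} C(n-1, i) Cum_{n-i} G_i`` in ascending n.
    """
    _check_orders(cumulants.order_to_image, cumulants.highest_order)
    moms: dict[int, np.ndarray] = {}
    for n in range(1, cumulants.highest_order + 1):
        total = cumulants.order_to_image[n].copy()
        for i in range(1, n):
            total += comb(n - 1, i, exact=True) * cumulants.order_to_image[n - i] * moms[i]
        moms[n] = total
    avg = moms[1]  # the first raw moment; zero for centered sets
    return MomentSet(order_to_image=moms, average=avg.copy(),
                     highest_order=cumulants.highest_order)


def total_signal(movie) -> np.ndarray:
    """Per-frame sum over all pixels: the total-intensity series I(t)."""
    mov = as_movie(movie)
    return mov.frames.sum(axis=(1, 2))


def smooth_monotone(signal: np.ndarray, smooth_kernel: int) -> np.ndarray:
    """Moving-average smoothing followed by a running minimum.

    The moving average uses edge-shortened windows at the boundaries (the
    window is clipped to the series, and the divisor is the actual window
    size), so constants are fixed points. The running minimum then enforces
    a monotonically non-increasing bleaching-profile estimate.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n = signal.shape[0]
    if smooth_kernel < 1 or smooth_kernel % 2 == 0:
        raise ValueError(f"smooth_kernel must be a positive odd integer, got {smooth_kernel}")
    if smooth_kernel > n:
        raise ValueError(f"smooth_kernel {smooth_kernel} exceeds series length {n}")
    kernel = np.ones(smooth_kernel)
    sums = np.convolve(signal, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return np.minimum.accumulate(sums / counts)


def bleach_blocks(smoothed: np.ndarray, fbc: float,
                  total: np.ndarray | None = None) -> BleachSchedule:
    """Split frames into blocks of equal fractional signal decay.

    Each block ends at the first frame where the smoothed total signal
    falls below ``(1 - fbc)`` times its value at the block start (a
    geometric threshold per block). The final partial block is kept if it
    has at least 2 frames, otherwise merged into the previous block.
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    if not 0.0 < fbc < 1.0:
        raise ValueError(f"fbc must lie in (0, 1), got {fbc}")
    if np.any(np.diff(smoothed) > 1e-9 * max(1.0, np.abs(smoothed).max())):
        raise ValueError("smoothed signal must be non-increasing")
    n = smoothed.shape[0]
    blocks: list[tuple[int, int]] = []
    start = 0
    while start < n:
        threshold = smoothed[start] * (1.0 - fbc)
        below = np.nonzero(smoothed[start + 1:] < threshold)[0]
        end = start + 1 + below[0] if below.size else n
        blocks.append((start, end))
        start = end
    if len(blocks) > 1 and blocks[-1][1] - blocks[-1][0] < 2:
        tail = blocks.pop()
        prev = blocks.pop()
        blocks.append((prev[0], tail[1]))
    if total is None:
        total = smoothed.copy()
    return BleachSchedule(total_signal=np.asarray(total, dtype=np.float64),
                          smoothed=smoothed, fbc=float(fbc), blocks=blocks)


def correct_bleaching(movie, fbc: float, smooth_kernel: int,
                      highest_order: int) -> CumulantSet:
    """Bleaching-corrected cumulant images.

    Splits the movie per :func:`bleach_blocks`, computes centered moments
    and cumulants independently per block, and returns the unweighted
    per-order average over blocks. Per-block centering removes the local
    bleaching trend that contaminates a whole-movie reconstruction.
    """
    mov = as_movie(movie)
    schedule = bleach_schedule(mov, fbc=fbc, smooth_kernel=smooth_kernel)
    return cumulants_over_blocks(mov, schedule.blocks, highest_order)


def bleach_schedule(movie, fbc: float, smooth_kernel: int) -> BleachSchedule:
    """Total signal -> monotone smoothing -> block boundaries, in one call."""
    mov = as_movie(movie)
    total = total_signal(mov)
    smoothed = smooth_monotone(total, smooth_kernel)
    return bleach_blocks(smoothed, fbc, total=total)


def cumulants_over_blocks(movie, blocks: list[tuple[int, int]],
                          highest_order: int) -> CumulantSet:
    """Per-block cumulant images averaged (unweighted) over blocks."""
    mov = as_movie(movie)
    if not blocks:
        raise ValueError("no blocks to reconstruct")
    for idx, (start, end) in enumerate(blocks):
        if end - start < 2:
            raise ValueError(
                f"block {idx} ([{start}, {end})) has fewer than 2 frames"
            )
    acc: dict[int, np.ndarray] = {}
    for start, end in blocks:
        cums = cumulants_from_moments(
            calc_moments_set(mov, highest_order, frame_range=(start, end))
        )
        for n, im in cums.order_to_image.items():
            acc[n] = acc.get(n, 0.0) + im
    images = {n: im / len(blocks) for n, im in acc.items()}
    return CumulantSet(order_to_image=images, highest_order=highest_order)
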