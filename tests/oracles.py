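"""Independent reference implementations used to pin the library's numerics.

Each oracle takes a deliberately different computational route from the
implementation it checks: cumulants via the logarithm of the exponential
generating function (not the binomial recursion), convolution and window
scans as explicit index loops, and trigonometric interpolation via
spectrum zero-padding.
"""

from __future__ import annotations

import math

import numpy as np


def bell_cumulants_from_moments(moments: np.ndarray) -> np.ndarray:
    """Cumulants from moments via the formal log of the moment EGF.

    ``moments[n-1]`` is the n-th (possibly centered) moment, with any
    trailing shape. Builds the series p(t) = sum m_n t^n / n!, expands
    log(1 + p) = sum_k (-1)^(k+1) p^k / k truncated at the highest order,
    and reads kappa_n = n! * [t^n] log(1 + p).
    """
    moments = np.asarray(moments, dtype=np.float64)
    n_max = moments.shape[0]
    tail = moments.shape[1:]
    a = np.zeros((n_max + 1,) + tail)
    for n in range(1, n_max + 1):
        a[n] = moments[n - 1] / math.factorial(n)

    def mul_trunc(p, q):
        out = np.zeros_like(p)
        for n in range(n_max + 1):
            for i in range(n + 1):
                out[n] += p[i] * q[n - i]
        return out

    log_series = np.zeros_like(a)
    p_power = a.copy()
    for k in range(1, n_max + 1):
        log_series += ((-1) ** (k + 1)) * p_power / k
        if k < n_max:
            p_power = mul_trunc(p_power, a)
    return np.stack([log_series[n] * math.factorial(n) for n in range(1, n_max + 1)])


def brute_central_moment(series: np.ndarray, order: int) -> float:
    """Frame-by-frame loop: mean, then averaged powered deviations."""
    total = 0.0
    for v in series:
        total += v
    mean = total / len(series)
    acc = 0.0
    for v in series:
        acc += (v - mean) ** order
    return acc / len(series)


def reflect_convolve(series: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """1-D convolution with mirror padding (edge sample not repeated),
    element by element."""
    m = len(series)
    half = len(weights) // 2
    out = np.zeros_like(np.asarray(series, dtype=np.float64))
    for t in range(m):
        acc = 0.0
        for j, w in enumerate(weights):
            idx = t + j - half
            if idx < 0:
                idx = -idx
            elif idx >= m:
                idx = 2 * (m - 1) - idx
            acc += w * series[idx]
        out[t] = acc
    return out


def ldrc_oracle(input_im: np.ndarray, mask_im: np.ndarray,
                window: tuple[int, int]) -> np.ndarray:
    """Per-pixel gathering form of ldrc: for every pixel, enumerate all
    windows covering it, rescale that window from scratch, and average the
    pixel's rescaled values."""
    input_im = np.asarray(input_im, dtype=np.float64)
    mask_im = np.asarray(mask_im, dtype=np.float64)
    h, w = input_im.shape
    wr, wc = window
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            values = []
            for i in range(max(0, r - wr + 1), min(r, h - wr) + 1):
                for j in range(max(0, c - wc + 1), min(c, w - wc) + 1):
                    win = input_im[i:i + wr, j:j + wc]
                    ref = mask_im[i:i + wr, j:j + wc]
                    mn, mx = win.min(), win.max()
                    rmn, rmx = ref.min(), ref.max()
                    if mx > mn:
                        val = (input_im[r, c] - mn) / (mx - mn) * (rmx - rmn) + rmn
                    else:
                        val = rmn
                    values.append(val)
            out[r, c] = sum(values) / len(values)
    return out


def ldrc_coverage(shape: tuple[int, int], window: tuple[int, int]) -> np.ndarray:
    """Number of fully-interior windows covering each pixel."""
    h, w = shape
    wr, wc = window
    cov = np.zeros((h, w))
    for i in range(h - wr + 1):
        for j in range(w - wc + 1):
            cov[i:i + wr, j:j + wc] += 1
    return cov


def zero_pad_interp(vector: np.ndarray, factor: int) -> np.ndarray:
    """Trigonometric interpolation of an odd-length vector by FFT
    zero-padding; returns the ``factor*(n-1)+1`` samples at x = p/factor."""
    v = np.asarray(vector, dtype=np.float64)
    n = len(v)
    assert n % 2 == 1, "zero-padding interpolant is unambiguous only for odd n"
    spec = np.fft.fft(v)
    half = (n - 1) // 2
    padded = np.zeros(n * factor, dtype=complex)
    padded[: half + 1] = spec[: half + 1]
    padded[-half:] = spec[-half:]
    fine = np.fft.ifft(padded).real * factor
    return fine[: factor * (n - 1) + 1]
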