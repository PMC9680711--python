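"""Local dynamic range compression (ldrc).

High-order moment/cumulant images have an enormous pixel-intensity dynamic
range (bright emitters are raised to the n-th power), which makes dim
structure imperceptible on a linear display. ldrc rescales the image to
the *local* dynamic range of a reference image (typically the time-average
or the second-order image, which shares the structure but has a confined
range): a window scans the image with stride 1; in each window the input
intensities are linearly mapped onto the reference window's [min, max]
range; each pixel's final value is the average of its rescaled values over
all windows covering it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ldrc"]


def ldrc(input_im: np.ndarray, mask_im: np.ndarray,
         window: tuple[int, int] = (20, 20)) -> np.ndarray:
    """Compress ``input_im`` to the local dynamic range of ``mask_im``.

    Windows are evaluated only fully inside the image (stride 1); edge
    pixels are covered by fewer windows but always by at least one. A
    constant input window carries no contrast and maps to the reference
    window's minimum. Output = accumulated rescalings / coverage counts,
    in double precision.
    """
    input_im = np.asarray(input_im, dtype=np.float64)
    mask_im = np.asarray(mask_im, dtype=np.float64)
    if input_im.shape != mask_im.shape:
        raise ValueError(
            f"input {input_im.shape} and reference {mask_im.shape} shapes differ"
        )
    h, w = input_im.shape
    wr, wc = int(window[0]), int(window[1])
    if wr < 1 or wc < 1 or wr > h or wc > w:
        raise ValueError(f"window {window} does not fit inside image {input_im.shape}")

    acc = np.zeros_like(input_im)
    coverage = np.zeros_like(input_im)
    for i in range(h - wr + 1):
        for j in range(w - wc + 1):
            win = input_im[i:i + wr, j:j + wc]
            ref = mask_im[i:i + wr, j:j + wc]
            mn, mx = win.min(), win.max()
            rmn, rmx = ref.min(), ref.max()
            if mx > mn:
                rescaled = (win - mn) / (mx - mn) * (rmx - rmn) + rmn
            else:
                rescaled = np.full_like(win, rmn)
            acc[i:i + wr, j:j + wc] += rescaled
            coverage[i:i + wr, j:j + wc] += 1.0
    return acc / coverage
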