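"""Workflow orchestration: the :class:`SofiDataset` class and the SOFI 2.0 chain.

:class:`SofiDataset` bundles a TIFF movie, the user parameters and every
intermediate result (average image, moment/cumulant sets, filtered and
ldrc images) as attributes, with the processing steps as methods — the
same result is always obtainable by calling the function modules
directly. Results are cached per parameter set and logged in a provenance
list; frames are streamed from disk in chunks so high-order moment
computation never holds the full movie in memory.

The SOFI 2.0 chain processes consecutive time blocks of one acquisition:
(optional Fourier interpolation) -> per-block high-order moment images ->
pixel-wise temporal noise filtering across blocks -> (optional
deconvolution hook) -> local dynamic range compression per block.
"""

from __future__ import annotations

import datetime
import os
import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Callable

import numpy as np
import tifffile

from . import finterp as _finterp
from .ldrc import ldrc as _ldrc_fn
from .filtering import ImageSeries, gauss1d_kernel, noise_filter1d
from .movie import Movie, resolve_frame_range, write_tiff
from .reconstruction import (
    CumulantSet,
    MomentSet,
    bleach_schedule,
    cumulants_from_moments,
    cumulants_over_blocks,
    moment_image,
)

__all__ = ["SofiDataset", "Sofi2Config", "load_dataset", "run_sofi2", "save_intermediate"]


@dataclass
class Sofi2Config:
    """Parameters of the SOFI 2.0 block-series chain.

    ``order`` is the moment order per block; ``interp_factor`` enables
    frame-wise Fourier interpolation before the moment step (None = off);
    the temporal noise filter is a 1-D Gaussian of ``kernel_length`` taps
    and width ``kernel_sigma`` (in blocks); ``window`` is the ldrc scan
    window; ``reference`` selects the ldrc reference per block ("mean",
    "m2", or an explicit image); ``deconvolver`` is an optional hook
    applied to each filtered image before ldrc (identity when None).
    """

    order: int = 6
    interp_factor: int | None = None
    kernel_length: int = 21
    kernel_sigma: float = 2.0
    window: tuple[int, int] = (20, 20)
    reference: str | np.ndarray = "mean"
    deconvolver: Callable[[np.ndarray], np.ndarray] | None = None
    save_intermediates: bool = False
    out_dir: str | None = None


class SofiDataset:
    """A movie on disk plus cached reconstruction results.

    Parameters
    ----------
    filepath
        Directory containing the movie, or the full path when ``filename``
        is omitted.
    filename
        Movie file name within ``filepath``.
    chunk_size
        Number of frames read per chunk when streaming.
    """

    def __init__(self, filepath: str, filename: str | None = None,
                 chunk_size: int = 200) -> None:
        path = os.path.join(filepath, filename) if filename else filepath
        if not os.path.exists(path):
            raise FileNotFoundError(f"no such movie file: {path}")
        self.path = path
        self.stem = os.path.splitext(os.path.basename(path))[0]
        self.chunk_size = int(chunk_size)
        try:
            with tifffile.TiffFile(path) as tif:
                series = tif.series[0]
                shape = series.shape
                self.dtype = np.dtype(series.dtype)
        except Exception as exc:  # corrupt / not a TIFF
            raise ValueError(f"cannot read TIFF movie {path}: {exc}") from exc
        if len(shape) == 2:
            self.frame_count, self.shape = 1, (shape[0], shape[1])
        else:
            self.frame_count, self.shape = int(shape[0]), (shape[1], shape[2])
        if self.frame_count < 2:
            warnings.warn(
                f"{path} has a single frame; moments of order >= 2 are unavailable",
                stacklevel=2,
            )
        self.ave: np.ndarray | None = None
        self.moments_set: dict[int, np.ndarray] = {}
        self.cumulants_set: dict[int, np.ndarray] = {}
        self.filtered: dict = {}
        self.ldrc_result: np.ndarray | None = None
        self.provenance: list[tuple[str, dict, str]] = []
        self._cache: dict = {}

    # -- frame access -----------------------------------------------------

    def frames(self, frame_range: tuple[int, int] | None = None) -> np.ndarray:
        """Materialize the selected frames as a float64 stack."""
        sl = resolve_frame_range(self.frame_count, frame_range)
        chunks = [chunk for _, chunk in self._iter_chunks(sl.start, sl.stop)]
        return np.concatenate(chunks) if len(chunks) > 1 else chunks[0]

    def movie(self, frame_range: tuple[int, int] | None = None) -> Movie:
        return Movie(self.frames(frame_range), source=self.path)

    def _iter_chunks(self, start: int, stop: int):
        """Yield ``(chunk_start, frames)`` reading chunk_size frames at a time."""
        with tifffile.TiffFile(self.path) as tif:
            pages = tif.series[0].pages
            for a in range(start, stop, self.chunk_size):
                b = min(a + self.chunk_size, stop)
                chunk = np.stack(
                    [np.asarray(pages[i].asarray(), dtype=np.float64)
                     for i in range(a, b)]
                )
                yield a, chunk

    # -- bookkeeping ------------------------------------------------------

    def _log(self, step: str, params: dict) -> None:
        self.provenance.append(
            (step, dict(params), datetime.datetime.now().isoformat())
        )

    def _cached(self, step: str, params: dict, compute: Callable):
        key = (step, tuple(sorted(params.items())))
        if key not in self._cache:
            self._cache[key] = compute()
            self._log(step, params)
        return self._cache[key]

    # -- reconstructions --------------------------------------------------

    def average_image(self, frame_range: tuple[int, int] | None = None) -> np.ndarray:
        """Temporal mean image (streamed); cached per frame range."""
        def compute():
            sl = resolve_frame_range(self.frame_count, frame_range)
            total = np.zeros(self.shape)
            for _, chunk in self._iter_chunks(sl.start, sl.stop):
                total += chunk.sum(axis=0)
            ave = total / (sl.stop - sl.start)
            self.ave = ave
            return ave

        return self._cached("average_image", {"frame_range": frame_range}, compute)

    def moment_image(self, order: int, frame_range: tuple[int, int] | None = None,
                     finterp: bool = False, interp_num: int = 2) -> np.ndarray:
        """Centered moment image of one order, optionally on
        Fourier-interpolated frames (streamed two-pass computation)."""
        params = {"order": order, "frame_range": frame_range,
                  "finterp": finterp, "interp_num": interp_num}

        def compute():
            factor = interp_num if finterp else None
            mset = self._streamed_moments(order, frame_range, factor)
            im = mset.order_to_image[order]
            self.moments_set[order] = im
            return im

        return self._cached("moment_image", params, compute)

    def calc_moments(self, highest_order: int,
                     frame_range: tuple[int, int] | None = None) -> MomentSet:
        """Centered moment images for all orders ``1..highest_order``."""
        params = {"highest_order": highest_order, "frame_range": frame_range}

        def compute():
            mset = self._streamed_moments(highest_order, frame_range, None)
            self.ave = mset.average
            self.moments_set.update(mset.order_to_image)
            return mset

        return self._cached("calc_moments", params, compute)

    def cumulants_images(self, highest_order: int, bleach_correction: bool = False,
                         smooth_kernel: int = 251, fbc: float = 0.04,
                         frame_range: tuple[int, int] | None = None) -> CumulantSet:
        """Cumulant images up to ``highest_order``, optionally with
        photobleaching correction (block splitting at BC factor ``fbc``)."""
        params = {"highest_order": highest_order,
                  "bleach_correction": bleach_correction,
                  "smooth_kernel": smooth_kernel, "fbc": fbc,
                  "frame_range": frame_range}

        def compute():
            if bleach_correction:
                mov = self.movie(frame_range)
                schedule = bleach_schedule(mov, fbc=fbc, smooth_kernel=smooth_kernel)
                cset = cumulants_over_blocks(mov, schedule.blocks, highest_order)
            else:
                cset = cumulants_from_moments(
                    self.calc_moments(highest_order, frame_range)
                )
            self.cumulants_set.update(cset.order_to_image)
            return cset

        return self._cached("cumulants_images", params, compute)

    def _streamed_moments(self, highest_order: int,
                          frame_range: tuple[int, int] | None,
                          interp_factor: int | None) -> MomentSet:
        """Two-pass chunked moments, optionally on interpolated frames."""
        sl = resolve_frame_range(self.frame_count, frame_range)
        n = sl.stop - sl.start
        if highest_order >= 2 and n < 2:
            raise ValueError(f"moments of order >= 2 need >= 2 frames, got {n}")

        def transform(chunk):
            if interp_factor is None or interp_factor == 1:
                return chunk
            return np.stack(
                [_finterp.fourier_interp_image(f, interp_factor) for f in chunk]
            )

        total = None
        for _, chunk in self._iter_chunks(sl.start, sl.stop):
            chunk = transform(chunk)
            total = chunk.sum(axis=0) if total is None else total + chunk.sum(axis=0)
        ave = total / n
        images: dict[int, np.ndarray] = {1: np.zeros_like(ave)}
        if highest_order >= 2:
            sums = {k: np.zeros_like(ave) for k in range(2, highest_order + 1)}
            for _, chunk in self._iter_chunks(sl.start, sl.stop):
                delta = transform(chunk) - ave
                power = delta.copy()
                for k in range(2, highest_order + 1):
                    power *= delta
                    sums[k] += power.sum(axis=0)
            for k in range(2, highest_order + 1):
                images[k] = sums[k] / n
        return MomentSet(order_to_image=images, average=ave,
                         highest_order=highest_order)

    # -- Fourier interpolation -------------------------------------------

    def finterp_tiffstack(self, interp_num_lst: list[int],
                          frames: tuple[int, int] | None = None,
                          save_option: bool = True,
                          return_option: bool = False,
                          out_dir: str | None = None):
        """Frame-wise Fourier interpolation; writes one
        ``<stem>_InterpNum<k>.tiff`` per factor when saving."""
        result = _finterp.fourier_interp_movie(
            self.movie(), interp_num_lst, frame_range=frames, save=save_option,
            out_dir=out_dir or os.path.dirname(self.path), stem=self.stem,
        )
        self._log("finterp_tiffstack",
                  {"interp_num_lst": tuple(interp_num_lst), "frames": frames})
        return result if return_option else None

    # -- ldrc -------------------------------------------------------------

    def ldrc(self, mask_im: np.ndarray, input_im: np.ndarray,
             window_size: tuple[int, int] = (20, 20)) -> np.ndarray:
        """Local dynamic range compression of ``input_im`` against
        ``mask_im``; stores the result on the dataset."""
        out = _ldrc_fn(input_im, mask_im, window=tuple(window_size))
        self.ldrc_result = out
        self._log("ldrc", {"window_size": tuple(window_size)})
        return out

    # -- persistence ------------------------------------------------------

    def available_results(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if self.ave is not None:
            out["mean"] = self.ave
        for n, im in self.moments_set.items():
            out[f"m{n}"] = im
        for n, im in self.cumulants_set.items():
            out[f"k{n}"] = im
        if self.filtered:
            out["filtered"] = np.stack(list(self.filtered.values()))
        if self.ldrc_result is not None:
            out["ldrc"] = self.ldrc_result
        return out

    def save_intermediate(self, which: str, out_dir: str | None = None) -> str:
        """Write one named intermediate as 32-bit float TIFF, suffixing the
        result name (e.g. ``_m6``, ``_k4``, ``_bc``, ``_filtered``,
        ``_ldrc``) to the movie stem."""
        available = self.available_results()
        if which not in available:
            raise ValueError(
                f"unknown result {which!r}; available: {sorted(available)}"
            )
        name = f"{self.stem}_{which}.tiff"
        target = os.path.join(out_dir or os.path.dirname(self.path) or ".", name)
        write_tiff(target, available[which])
        self._log("save_intermediate", {"which": which, "path": target})
        return target


def load_dataset(filepath: str, filename: str | None = None,
                 chunk_size: int = 200) -> SofiDataset:
    """Open a multi-page TIFF movie as a :class:`SofiDataset` without
    materializing any frames."""
    return SofiDataset(filepath, filename, chunk_size=chunk_size)


def save_intermediate(dataset: SofiDataset, which: str,
                      out_dir: str | None = None) -> str:
    """Function-module twin of :meth:`SofiDataset.save_intermediate`."""
    return dataset.save_intermediate(which, out_dir)


def run_sofi2(datasets: list[SofiDataset], config: Sofi2Config | None = None
              ) -> dict[str, dict[str, np.ndarray]]:
    """SOFI 2.0 chain over consecutive time blocks.

    Per block: (optional FI) -> order-n moment image; then temporal noise
    filtering across blocks, the optional deconvolution hook, and ldrc of
    each filtered image against the configured reference. Returns
    ``{"moments": .., "filtered": .., "ldrc": ..}``, each keyed by block
    stem in acquisition order. Intermediates are written as TIFF when
    ``config.save_intermediates`` is on.
    """
    if not datasets:
        raise ValueError("need at least one dataset block")
    config = config or Sofi2Config()
    shapes = {d.shape for d in datasets}
    if len(shapes) != 1:
        raise ValueError(f"blocks disagree in frame shape: {shapes}")

    use_fi = config.interp_factor is not None and config.interp_factor > 1
    moments: dict[str, np.ndarray] = {}
    references: dict[str, np.ndarray] = {}
    for d in datasets:
        moments[d.stem] = d.moment_image(
            config.order, finterp=use_fi, interp_num=config.interp_factor or 1
        )
        references[d.stem] = _block_reference(d, config, use_fi)

    kernel = gauss1d_kernel(config.kernel_length, config.kernel_sigma)
    filtered = noise_filter1d(ImageSeries.from_dict(moments), kernel)

    deconv = config.deconvolver or (lambda im: im)
    ldrc_images: dict[str, np.ndarray] = {}
    for d in datasets:
        im = deconv(filtered[d.stem])
        d.filtered[d.stem] = im
        ldrc_images[d.stem] = d.ldrc(references[d.stem], im,
                                     window_size=config.window)

    if config.save_intermediates:
        out_dir = config.out_dir
        for d in datasets:
            write_tiff(_out_path(d, f"m{config.order}_filtered", out_dir),
                       d.filtered[d.stem])
            write_tiff(_out_path(d, "ldrc", out_dir), ldrc_images[d.stem])

    return {"moments": moments, "filtered": filtered.to_dict(), "ldrc": ldrc_images}


def _block_reference(d: SofiDataset, config: Sofi2Config, use_fi: bool) -> np.ndarray:
    if isinstance(config.reference, np.ndarray):
        return config.reference
    if config.reference == "mean":
        ave = d.average_image()
        if use_fi:
            ave = _finterp.fourier_interp_image(ave, config.interp_factor)
        return ave
    if config.reference == "m2":
        return d.moment_image(2, finterp=use_fi,
                              interp_num=config.interp_factor or 1)
    raise ValueError(f"unknown ldrc reference {config.reference!r}")


def _out_path(d: SofiDataset, suffix: str, out_dir: str | None) -> str:
    name = f"{d.stem}_{suffix}.tiff"
    return os.path.join(out_dir or os.path.dirname(d.path) or ".", name)
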