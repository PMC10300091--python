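"""Laplacian/Gaussian pyramid fusion.

Classic Burt–Adelson pyramid with the binomial 5-tap kernel and symmetric
border handling. Detail levels merge by per-coefficient maximum absolute
value; the approximation (coarsest) layer merges block-wise, each block
taken from the source with higher local variance. Exact ties average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class PyramidStack:
    """Detail rasters (fine → coarse) plus the coarsest approximation.

    Collapsing an unmodified stack reproduces the source image to floating
    point precision.
    """

    details: list[np.ndarray]
    approximation: np.ndarray

    @property
    def level_count(self) -> int:
        return len(self.details)


def _blur(img: np.ndarray) -> np.ndarray:
    out = ndi.correlate1d(img, _KERNEL, axis=0, mode="reflect")
    return ndi.correlate1d(out, _KERNEL, axis=1, mode="reflect")


def _reduce(img: np.ndarray) -> np.ndarray:
    return _blur(img)[::2, ::2]


def _expand(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    up = np.zeros(shape, dtype=img.dtype)
    up[::2, ::2] = img
    return _blur(up) * 4.0


def build_laplacian_pyramid(img: np.ndarray, levels: int) -> PyramidStack:
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if min(img.shape) < 2**levels:
        raise ValueError(f"image {img.shape} too small for {levels} pyramid levels")
    details = []
    current = np.asarray(img, dtype=float)
    for _ in range(levels):
        low = _reduce(current)
        details.append(current - _expand(low, current.shape))
        current = low
    return PyramidStack(details=details, approximation=current)


def reconstruct_pyramid(stack: PyramidStack) -> np.ndarray:
    img = stack.approximation
    for detail in reversed(stack.details):
        img = detail + _expand(img, detail.shape)
    return img


def _max_abs_merge(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    take_a = np.abs(da) > np.abs(db)
    take_b = np.abs(db) > np.abs(da)
    return np.where(take_a, da, np.where(take_b, db, 0.5 * (da + db)))


def _blockwise_variance_merge(a: np.ndarray, b: np.ndarray, block: int) -> np.ndarray:
    h, w = a.shape
    ph, pw = (-h) % block, (-w) % block
    pad = ((0, ph), (0, pw))
    ap = np.pad(a, pad, mode="reflect" if max(ph, pw) < min(h, w) else "edge")
    bp = np.pad(b, pad, mode="reflect" if max(ph, pw) < min(h, w) else "edge")
    hh, ww = ap.shape
    av = ap.reshape(hh // block, block, ww // block, block).swapaxes(1, 2)
    bv = bp.reshape(hh // block, block, ww // block, block).swapaxes(1, 2)
    var_a = av.var(axis=(2, 3))
    var_b = bv.var(axis=(2, 3))
    take_a = (var_a > var_b)[:, :, None, None]
    take_b = (var_b > var_a)[:, :, None, None]
    merged = np.where(take_a, av, np.where(take_b, bv, 0.5 * (av + bv)))
    out = merged.swapaxes(1, 2).reshape(hh, ww)
    return out[:h, :w]


def fuse_laplacian(a: np.ndarray, b: np.ndarray, levels: int = 4, block: int = 8) -> np.ndarray:
    """Pyramid fusion: max-abs details, higher-local-variance approximation blocks."""
    pa = build_laplacian_pyramid(a, levels)
    pb = build_laplacian_pyramid(b, levels)
    fused = PyramidStack(
        details=[_max_abs_merge(da, db) for da, db in zip(pa.details, pb.details)],
        approximation=_blockwise_variance_merge(pa.approximation, pb.approximation, block),
    )
    return np.clip(reconstruct_pyramid(fused), 0.0, 1.0)
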