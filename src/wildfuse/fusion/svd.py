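"""Block-wise SVD fusion.

Each non-overlapping block is scored by its singular-value energy (the sum
of squared singular values); the fused block is the higher-energy source
block, or the mean of the two on an exact tie. The output is therefore a
block-wise selection from the sources.
"""

from __future__ import annotations

import numpy as np


def fuse_svd(a: np.ndarray, b: np.ndarray, block: int = 8) -> np.ndarray:
    if block < 1:
        raise ValueError("block must be >= 1")
    h, w = a.shape
    ph, pw = (-h) % block, (-w) % block
    ap = np.pad(a, ((0, ph), (0, pw)), mode="reflect")
    bp = np.pad(b, ((0, ph), (0, pw)), mode="reflect")
    hh, ww = ap.shape
    av = ap.reshape(hh // block, block, ww // block, block).swapaxes(1, 2)
    bv = bp.reshape(hh // block, block, ww // block, block).swapaxes(1, 2)
    # sum of squared singular values per block
    ea = (np.linalg.svd(av, compute_uv=False) ** 2).sum(axis=-1)
    eb = (np.linalg.svd(bv, compute_uv=False) ** 2).sum(axis=-1)
    take_a = (ea > eb)[:, :, None, None]
    take_b = (eb > ea)[:, :, None, None]
    merged = np.where(take_a, av, np.where(take_b, bv, 0.5 * (av + bv)))
    out = merged.swapaxes(1, 2).reshape(hh, ww)[:h, :w]
    return np.clip(out, 0.0, 1.0)
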