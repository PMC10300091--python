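"""Hybrid wavelet fusion: multi-resolution transform plus an optimization
merge in transform space.

``wl_tvm`` fuses detail subbands by maximum absolute coefficient and the
approximation subband by the total-variation gradient-transfer objective.
``wl_swarm`` assigns each subband a convex weight optimized by particle
swarm to maximize the entropy of the reconstructed image.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..quality import region_entropy
from .variational import _tvm_minimize

_WAVEDEC_MODE = "symmetric"


def _max_abs(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    take_a = np.abs(da) > np.abs(db)
    take_b = np.abs(db) > np.abs(da)
    return np.where(take_a, da, np.where(take_b, db, 0.5 * (da + db)))


def _decompose(img: np.ndarray, wavelet: str, levels: int):
    if levels < 1:
        raise ValueError("levels must be >= 1")
    max_level = pywt.dwtn_max_level(img.shape, wavelet)
    if levels > max_level:
        raise ValueError(f"image {img.shape} too small for {levels} '{wavelet}' levels")
    return pywt.wavedec2(img, wavelet, mode=_WAVEDEC_MODE, level=levels)


def _reconstruct(coeffs, wavelet: str, shape: tuple[int, int]) -> np.ndarray:
    out = pywt.waverec2(coeffs, wavelet, mode=_WAVEDEC_MODE)
    return out[: shape[0], : shape[1]]


def fuse_wl_tvm(
    a: np.ndarray,
    b: np.ndarray,
    wavelet: str = "db2",
    levels: int = 3,
    lam: float = 4.0,
    iters: int = 60,
    tol: float = 1e-6,
) -> np.ndarray:
    ca = _decompose(a, wavelet, levels)
    cb = _decompose(b, wavelet, levels)
    approx, _ = _tvm_minimize(ca[0], cb[0], lam=lam, iters=iters, tol=tol)
    fused = [approx] + [
        tuple(_max_abs(da, db) for da, db in zip(ta, tb)) for ta, tb in zip(ca[1:], cb[1:])
    ]
    return np.clip(_reconstruct(fused, wavelet, a.shape), 0.0, 1.0)


def _weighted_coeffs(ca, cb, weights: np.ndarray):
    """weights: approximation weight followed by one weight per detail subband
    (three per level: horizontal, vertical, diagonal)."""
    out = [weights[0] * ca[0] + (1.0 - weights[0]) * cb[0]]
    k = 1
    for ta, tb in zip(ca[1:], cb[1:]):
        merged = []
        for da, db in zip(ta, tb):
            w = weights[k]
            merged.append(w * da + (1.0 - w) * db)
            k += 1
        out.append(tuple(merged))
    return out


def fuse_wl_swarm(
    a: np.ndarray,
    b: np.ndarray,
    wavelet: str = "db2",
    levels: int = 3,
    swarm_size: int = 20,
    pso_iters: int = 40,
    seed: int = 0,
    inertia: float = 0.7,
    c1: float = 1.5,
    c2: float = 1.5,
    return_details: bool = False,
):
    """Per-subband convex weights optimized by particle swarm, maximizing the
    entropy of the fused image. Deterministic for a fixed seed; the global
    best objective is non-decreasing across iterations by construction."""
    if swarm_size < 2:
        raise ValueError("swarm_size must be >= 2")
    ca = _decompose(a, wavelet, levels)
    cb = _decompose(b, wavelet, levels)
    dim = 3 * levels + 1  # approximation weight + one per detail subband

    def objective(weights: np.ndarray) -> float:
        fused = _reconstruct(_weighted_coeffs(ca, cb, weights), wavelet, a.shape)
        return region_entropy(np.clip(fused, 0.0, 1.0))

    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(swarm_size, dim))
    pos[0] = 0.5  # include the even-blend starting point
    vel = rng.uniform(-0.1, 0.1, size=(swarm_size, dim))
    pbest = pos.copy()
    pbest_val = np.array([objective(p) for p in pos])
    g_idx = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g_idx].copy(), float(pbest_val[g_idx])
    trace = [gbest_val]
    for _ in range(pso_iters):
        r1 = rng.uniform(size=(swarm_size, dim))
        r2 = rng.uniform(size=(swarm_size, dim))
        vel = inertia * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
        pos = np.clip(pos + vel, 0.0, 1.0)
        for i in range(swarm_size):
            v = objective(pos[i])
            if v > pbest_val[i]:
                pbest_val[i] = v
                pbest[i] = pos[i].copy()
                if v > gbest_val:
                    gbest_val = v
                    gbest = pos[i].copy()
        trace.append(gbest_val)
    fused = np.clip(_reconstruct(_weighted_coeffs(ca, cb, gbest), wavelet, a.shape), 0.0, 1.0)
    if return_details:
        return fused, gbest, trace
    return fused
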