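"""Visible–thermal image fusion.

Eight fusion methods under a common transform → merge → reconstruct scheme:

* multi-resolution: ``guided_filter``, ``laplacian``, ``svd``, ``sparse``
* optimization-based (pixel level, no transform): ``gradient``, ``tvm``
* hybrid (wavelet transform + optimization merge): ``wl_tvm``, ``wl_swarm``

All methods take two co-registered single-channel rasters in [0, 1] — the
visible luminance and the normalized thermal image — and return a fused
raster of the same size, clipped to [0, 1]. Every method is deterministic
for fixed inputs, parameters and (where applicable) seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .guided import fuse_guided_filter
from .pyramid import PyramidStack, build_laplacian_pyramid, fuse_laplacian, reconstruct_pyramid
from .sparse import dct_dictionary, fuse_sparse, omp_code
from .svd import fuse_svd
from .variational import fuse_gradient, fuse_tvm, poisson_solve_neumann, tvm_energy
from .wavelet import fuse_wl_swarm, fuse_wl_tvm

__all__ = [
    "FusionInput",
    "FusionResult",
    "METHOD_NAMES",
    "DEFAULT_PARAMS",
    "fuse",
    "to_luminance",
    "normalize_intensity",
    "fuse_guided_filter",
    "fuse_laplacian",
    "fuse_svd",
    "fuse_sparse",
    "fuse_gradient",
    "fuse_tvm",
    "fuse_wl_tvm",
    "fuse_wl_swarm",
    "PyramidStack",
    "build_laplacian_pyramid",
    "reconstruct_pyramid",
    "poisson_solve_neumann",
    "tvm_energy",
    "dct_dictionary",
    "omp_code",
]

#: canonical method names, dispatchable through :func:`fuse`
METHOD_NAMES = (
    "guided_filter",
    "laplacian",
    "svd",
    "sparse",
    "gradient",
    "tvm",
    "wl_tvm",
    "wl_swarm",
)

# Literature-standard defaults; every entry is overridable per call.
DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "guided_filter": dict(r_base=45, eps_base=0.3, r_detail=7, eps_detail=1e-6, blur=5.0),
    "laplacian": dict(levels=4, block=8),
    "svd": dict(block=8),
    "sparse": dict(patch=8, stride=2, atoms=256, max_atoms=8, tol=None),
    "gradient": dict(),
    "tvm": dict(lam=4.0, iters=200, tol=1e-5),
    "wl_tvm": dict(wavelet="db2", levels=3, lam=4.0, iters=60),
    "wl_swarm": dict(wavelet="db2", levels=3, swarm_size=20, pso_iters=40),
}


@dataclass(frozen=True)
class FusionInput:
    """Validated pair of co-registered single-channel rasters in [0, 1]."""

    a: np.ndarray  #: visible luminance
    b: np.ndarray  #: normalized thermal

    def __post_init__(self) -> None:
        a, b = np.asarray(self.a, float), np.asarray(self.b, float)
        if a.shape != b.shape or a.ndim != 2:
            raise ValueError(f"inputs must be 2-D with equal dims, got {a.shape} vs {b.shape}")
        for name, arr in (("a", a), ("b", b)):
            if not np.isfinite(arr).all():
                raise ValueError(f"input {name} contains non-finite values")
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValueError(f"input {name} outside [0, 1]")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def dims(self) -> tuple[int, int]:
        return self.a.shape  # (rows, cols)


@dataclass(frozen=True)
class FusionResult:
    fused: np.ndarray
    method: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None


def to_luminance(rgb: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luminance, 0.299 R + 0.587 G + 0.114 B, in [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) raster, got shape {rgb.shape}")
    if rgb.max() > 1.0:  # 8-bit input
        rgb = rgb / 255.0
    return rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114


def normalize_intensity(raster: np.ndarray) -> np.ndarray:
    """Min–max scale to [0, 1]; a constant raster maps to all zeros."""
    arr = np.asarray(raster, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("raster contains NaN or infinite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


_DISPATCH = {
    "guided_filter": fuse_guided_filter,
    "laplacian": fuse_laplacian,
    "svd": fuse_svd,
    "sparse": fuse_sparse,
    "gradient": fuse_gradient,
    "tvm": fuse_tvm,
    "wl_tvm": fuse_wl_tvm,
    "wl_swarm": fuse_wl_swarm,
}


def fuse(
    inp: FusionInput,
    method: str,
    params: dict[str, Any] | None = None,
    seed: int | None = None,
) -> FusionResult:
    """Run one named fusion method and record the parameters used."""
    if method not in _DISPATCH:
        raise ValueError(f"unknown fusion method {method!r}; choose from {METHOD_NAMES}")
    kwargs = dict(DEFAULT_PARAMS[method])
    kwargs.update(params or {})
    if method == "wl_swarm":
        if seed is None:
            raise ValueError("wl_swarm requires a seed")
        kwargs["seed"] = seed
    fused = _DISPATCH[method](inp.a, inp.b, **kwargs)
    return FusionResult(fused=fused, method=method, params=kwargs, seed=seed)
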