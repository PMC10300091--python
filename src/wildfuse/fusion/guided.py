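"""Two-scale guided-filter fusion.

Each source splits into a base layer (box-filter mean) and a detail residual.
Per-pixel saliency (Gaussian-smoothed absolute Laplacian) picks an initial
binary weight map, which is then refined by guided filtering with the
corresponding source as guide — a large radius / large epsilon filter for the
base weights and a small radius / small epsilon filter for the detail
weights. Refined weights are renormalized pixelwise before blending.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

_BASE_SPLIT_RADIUS = 15  # 31x31 averaging window for the base/detail split


def _box(img: np.ndarray, radius: int) -> np.ndarray:
    return ndi.uniform_filter(img, size=2 * radius + 1, mode="reflect")


def guided_filter(guide: np.ndarray, src: np.ndarray, radius: int, eps: float) -> np.ndarray:
    """Edge-preserving smoothing of ``src`` steered by ``guide``."""
    mean_i = _box(guide, radius)
    mean_p = _box(src, radius)
    corr_ip = _box(guide * src, radius)
    corr_ii = _box(guide * guide, radius)
    var_i = corr_ii - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p
    a = cov_ip / (var_i + eps)
    b = mean_p - a * mean_i
    return _box(a, radius) * guide + _box(b, radius)


def _saliency(img: np.ndarray, blur: float) -> np.ndarray:
    return ndi.gaussian_filter(np.abs(ndi.laplace(img, mode="reflect")), blur, mode="reflect")


def fuse_guided_filter(
    a: np.ndarray,
    b: np.ndarray,
    r_base: int = 45,
    eps_base: float = 0.3,
    r_detail: int = 7,
    eps_detail: float = 1e-6,
    blur: float = 5.0,
) -> np.ndarray:
    if min(r_base, r_detail) < 1 or min(eps_base, eps_detail) <= 0:
        raise ValueError("radii must be >= 1 and eps > 0")
    base_a, base_b = _box(a, _BASE_SPLIT_RADIUS), _box(b, _BASE_SPLIT_RADIUS)
    det_a, det_b = a - base_a, b - base_b

    sal_a, sal_b = _saliency(a, blur), _saliency(b, blur)
    p_a = np.where(sal_a > sal_b, 1.0, np.where(sal_b > sal_a, 0.0, 0.5))
    p_b = 1.0 - p_a

    def refined(p_src_a: np.ndarray, p_src_b: np.ndarray, r: int, eps: float):
        wa = np.clip(guided_filter(a, p_src_a, r, eps), 0.0, 1.0)
        wb = np.clip(guided_filter(b, p_src_b, r, eps), 0.0, 1.0)
        total = wa + wb
        flat = total < 1e-12
        wa = np.where(flat, 0.5, wa / np.where(flat, 1.0, total))
        return wa, 1.0 - wa

    wb_a, wb_b = refined(p_a, p_b, r_base, eps_base)
    wd_a, wd_b = refined(p_a, p_b, r_detail, eps_detail)
    fused = wb_a * base_a + wb_b * base_b + wd_a * det_a + wd_b * det_b
    return np.clip(fused, 0.0, 1.0)
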