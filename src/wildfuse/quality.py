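"""Object-level fusion-quality metrics.

Three metrics are computed inside annotated bounding boxes, never averaged
across methods: Shannon region entropy (bits per pixel), summed mutual
information between each source and the fused image (bits per pixel), and
the gradient-based Petrovic edge-preservation score in [0, 1].

Boxes use half-open pixel semantics and are clipped to the raster before
any histogram is formed. Intensities are assumed normalized to [0, 1];
histograms are binned over that fixed range so that entropies of 8-bit
content reach at most ``log2(bins)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .annotations import BoundingBox

ENTROPY_BINS = 256  #: default histogram resolution for entropy
MI_BINS = 64  #: default joint-histogram resolution for mutual information

# Sigmoid constants of the edge-preservation model (strength and orientation
# branches). The two sigmoids are normalized by their value at perfect
# preservation so that an exactly preserved edge scores 1.
_GAMMA_G, _KAPPA_G, _SIGMA_G = 0.9994, -15.0, 0.5
_GAMMA_A, _KAPPA_A, _SIGMA_A = 0.9879, -22.0, 0.8
_STRENGTH_EXPONENT = 1.0


@dataclass(frozen=True)
class QualityRecord:
    """All three metrics for one object under one method (or a raw source)."""

    object_id: str
    species: str
    method: str
    entropy: float
    mi_sum: float
    petrovic: float


def _region(img: np.ndarray, box: BoundingBox | None) -> np.ndarray:
    if box is None:
        return img
    h, w = img.shape
    b = box.clipped(w, h)
    r0, r1 = int(math.floor(b.y_min)), int(math.ceil(b.y_max))
    c0, c1 = int(math.floor(b.x_min)), int(math.ceil(b.x_max))
    region = img[r0:r1, c0:c1]
    if region.size == 0:
        raise ValueError(f"box {box} has zero area after clipping to {w}x{h}")
    return region


def region_entropy(img: np.ndarray, box: BoundingBox | None = None, bins: int = ENTROPY_BINS) -> float:
    """Shannon entropy of the intensity histogram inside ``box``, in bits/pixel."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    pix = _region(np.asarray(img, dtype=float), box)
    counts, _ = np.histogram(pix, bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / pix.size
    return float(-(p * np.log2(p)).sum())


def region_mutual_information(
    src: np.ndarray,
    fused: np.ndarray,
    box: BoundingBox | None = None,
    bins: int = MI_BINS,
) -> float:
    """Mutual information between a source and the fused image inside ``box``.

    Computed from the bins x bins joint histogram; symmetric and >= 0.
    """
    x = _region(np.asarray(src, dtype=float), box).ravel()
    y = _region(np.asarray(fused, dtype=float), box).ravel()
    if x.size != y.size:
        raise ValueError("source and fused regions differ in size")
    joint, _, _ = np.histogram2d(x, y, bins=bins, range=((0.0, 1.0), (0.0, 1.0)))
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = (pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])).sum()
    return float(max(mi, 0.0))


def mi_sum(
    a: np.ndarray,
    b: np.ndarray,
    fused: np.ndarray,
    box: BoundingBox | None = None,
    bins: int = MI_BINS,
) -> float:
    """MI(a, fused) + MI(b, fused): total information transferred into the
    fused image from the two sources; higher is better."""
    return region_mutual_information(a, fused, box, bins) + region_mutual_information(
        b, fused, box, bins
    )


def _sobel_strength_orientation(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = ndi.sobel(img, axis=1, mode="reflect")
    gy = ndi.sobel(img, axis=0, mode="reflect")
    strength = np.hypot(gx, gy)
    # fold direction into orientation in [-pi/2, pi/2): opposite-contrast
    # edges share an orientation
    alpha = np.mod(np.arctan2(gy, gx) + np.pi / 2, np.pi) - np.pi / 2
    return strength, alpha


def _sigmoid(x: np.ndarray, gamma: float, kappa: float, sigma: float) -> np.ndarray:
    return gamma / (1.0 + np.exp(kappa * (x - sigma)))


def _preservation(
    g_src: np.ndarray, a_src: np.ndarray, g_f: np.ndarray, a_f: np.ndarray
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(g_src > g_f, g_f / g_src, np.where(g_f > 0, g_src / g_f, 1.0))
    ratio = np.nan_to_num(ratio, nan=1.0)
    dalpha = np.abs(a_src - a_f)
    dalpha = np.minimum(dalpha, np.pi - dalpha)  # orientation distance on [0, pi/2]
    angle = 1.0 - dalpha / (np.pi / 2)
    q_g = _sigmoid(ratio, _GAMMA_G, _KAPPA_G, _SIGMA_G) / _sigmoid(
        np.float64(1.0), _GAMMA_G, _KAPPA_G, _SIGMA_G
    )
    q_a = _sigmoid(angle, _GAMMA_A, _KAPPA_A, _SIGMA_A) / _sigmoid(
        np.float64(1.0), _GAMMA_A, _KAPPA_A, _SIGMA_A
    )
    return q_g * q_a


def petrovic_metric(
    a: np.ndarray,
    b: np.ndarray,
    fused: np.ndarray,
    box: BoundingBox | None = None,
) -> float:
    """Edge-preservation score Q in [0, 1].

    Sobel edge strength and orientation are compared between each source and
    the fused image; relative strength and orientation agreement pass through
    sigmoid preservation models, and the per-pixel scores are averaged with
    source edge strength as weight. Pixels where a source has no gradient
    contribute no weight; if neither source has any gradient inside the box
    the score is 1 by convention (there was nothing to preserve).
    """
    a_r, b_r, f_r = (_region(np.asarray(x, dtype=float), box) for x in (a, b, fused))
    if not (a_r.shape == b_r.shape == f_r.shape):
        raise ValueError("inputs must share dimensions")
    g_a, al_a = _sobel_strength_orientation(a_r)
    g_b, al_b = _sobel_strength_orientation(b_r)
    g_f, al_f = _sobel_strength_orientation(f_r)
    q_af = _preservation(g_a, al_a, g_f, al_f)
    q_bf = _preservation(g_b, al_b, g_f, al_f)
    w_a = g_a**_STRENGTH_EXPONENT
    w_b = g_b**_STRENGTH_EXPONENT
    denom = (w_a + w_b).sum()
    if denom == 0:
        return 1.0
    return float((q_af * w_a + q_bf * w_b).sum() / denom)
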