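"""Thermal-to-visible registration by upscaling and translation.

The thermal sensor has a fixed, known magnification relative to the visible
camera, so the scale is taken from sensor geometry rather than estimated.
The residual translation is estimated by phase correlation between
gradient-magnitude images — gradients survive the modality change far better
than raw intensities — with subpixel quadratic refinement of the correlation
peak. The visible frame is cropped to the thermal field of view and both
rasters are resampled to a common working size.

Conventions: origin top-left, x rightward, y downward, 0-based. The recorded
transform maps raw thermal pixel coordinates into the visible frame:
``x_vis = scale * x_th + tx``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .fusion import to_luminance


class RegistrationError(RuntimeError):
    """Registration failed; carries the raw estimate when available."""

    def __init__(self, message: str, estimate: tuple[float, float] | None = None):
        super().__init__(message)
        self.estimate = estimate


class NoSignalError(ValueError):
    """Phase correlation is undefined on (near-)constant input."""


@dataclass(frozen=True)
class SimilarityTransform:
    """Scale plus translation mapping thermal coordinates into the visible frame."""

    scale: float
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if not (self.scale > 0 and np.isfinite([self.scale, self.tx, self.ty]).all()):
            raise ValueError(f"invalid transform: {self}")

    def apply(self, x: float, y: float) -> tuple[float, float]:
        return self.scale * x + self.tx, self.scale * y + self.ty

    def inverse(self, x: float, y: float) -> tuple[float, float]:
        return (x - self.tx) / self.scale, (y - self.ty) / self.scale


@dataclass
class RegisteredPair:
    visible_gray: np.ndarray
    thermal_reg: np.ndarray
    transform: SimilarityTransform
    target_dims: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        h, w = self.visible_gray.shape
        if (w, h) != self.target_dims or self.thermal_reg.shape != (h, w):
            raise ValueError("registered rasters must share target_dims exactly")


def _resample(img: np.ndarray, out_shape: tuple[int, int], sy: float, sx: float) -> np.ndarray:
    """Bicubic resampling with pixel-center alignment: output pixel (r, c)
    samples the input at (r / sy, c / sx). This matches the package-wide
    transform convention ``x_out = s * x_in`` on pixel centers."""
    rows = np.arange(out_shape[0], dtype=float) / sy
    cols = np.arange(out_shape[1], dtype=float) / sx
    return ndi.map_coordinates(
        img, np.meshgrid(rows, cols, indexing="ij"), order=3, mode="nearest"
    )


def upscale_thermal(thermal: np.ndarray, scale: float) -> np.ndarray:
    """Bicubic upscaling; output dims are ``round(input dims * scale)``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    thermal = np.asarray(thermal, dtype=float)
    h, w = thermal.shape
    out_shape = (int(round(h * scale)), int(round(w * scale)))
    if out_shape == (h, w):
        return thermal.copy()
    return np.clip(_resample(thermal, out_shape, scale, scale), 0.0, 1.0)


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndi.sobel(img, axis=1, mode="reflect")
    gy = ndi.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def _quadratic_refine(c_m1: float, c_0: float, c_p1: float) -> float:
    denom = c_m1 - 2.0 * c_0 + c_p1
    if denom >= -1e-300:  # not a proper maximum
        return 0.0
    return 0.5 * (c_m1 - c_p1) / denom


def estimate_translation(
    reference: np.ndarray,
    moving: np.ndarray,
    max_shift: float = 32.0,
) -> tuple[float, float]:
    """Translation ``(tx, ty)`` by which the moving raster is displaced
    relative to the reference: ``moving[r, c] ~ reference[r - ty, c - tx]``.

    Phase correlation on Hann-windowed gradient magnitudes with quadratic
    subpixel refinement; the peak search is restricted to ``|shift| <= max_shift``.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("rasters must share dims")
    if reference.std() < 1e-9 or moving.std() < 1e-9:
        raise NoSignalError("constant raster carries no registration signal")

    def windowed_gradient(img: np.ndarray) -> np.ndarray:
        g = _gradient_magnitude(img)
        win = np.outer(np.hanning(img.shape[0]), np.hanning(img.shape[1]))
        return (g - g.mean()) * win

    return _phase_correlation_shift(
        windowed_gradient(reference), windowed_gradient(moving), max_shift
    )


def _phase_correlation_shift(
    g_ref: np.ndarray, g_mov: np.ndarray, max_shift: float
) -> tuple[float, float]:
    h, w = g_ref.shape
    f_ref = np.fft.fft2(g_ref)
    f_mov = np.fft.fft2(g_mov)
    cross = f_ref * np.conj(f_mov)
    cross /= np.maximum(np.abs(cross), 1e-15)
    corr = np.fft.ifft2(cross).real

    # shift value represented by each correlation index
    sy = np.fft.fftfreq(h, d=1.0 / h)
    sx = np.fft.fftfreq(w, d=1.0 / w)
    mask = (np.abs(sy)[:, None] <= max_shift) & (np.abs(sx)[None, :] <= max_shift)
    masked = np.where(mask, corr, -np.inf)
    iy, ix = np.unravel_index(np.argmax(masked), corr.shape)
    gy, gx = np.unravel_index(np.argmax(corr), corr.shape)
    if not mask[gy, gx] and corr[gy, gx] > 1.2 * corr[iy, ix]:
        raise RegistrationError(
            f"dominant correlation peak at ({-sx[gx]:.1f}, {-sy[gy]:.1f}) "
            f"exceeds max_shift={max_shift}",
            (float(-sx[gx]), float(-sy[gy])),
        )

    dy = _quadratic_refine(corr[(iy - 1) % h, ix], corr[iy, ix], corr[(iy + 1) % h, ix])
    dx = _quadratic_refine(corr[iy, (ix - 1) % w], corr[iy, ix], corr[iy, (ix + 1) % w])
    ty = sy[iy] + dy
    tx = sx[ix] + dx
    # correlation peak at +s means the moving content sits at reference + s;
    # the sign convention below was fixed against injected shifts
    tx, ty = -tx, -ty
    if abs(tx) > max_shift or abs(ty) > max_shift:
        raise RegistrationError(f"estimated shift ({tx:.2f}, {ty:.2f}) exceeds max_shift", (tx, ty))
    return float(tx), float(ty)


def apply_transform(
    thermal: np.ndarray, transform: SimilarityTransform, target_dims: tuple[int, int]
) -> np.ndarray:
    """Render the raw thermal raster into the registered working frame."""
    up = upscale_thermal(thermal, transform.scale)
    w, h = target_dims
    if up.shape == (h, w):
        return up
    out = _resample(up, (h, w), h / up.shape[0], w / up.shape[1])
    return np.clip(out, 0.0, 1.0)


def register_pair(
    visible: np.ndarray,
    thermal: np.ndarray,
    nominal_scale: float,
    target_dims: tuple[int, int] | None = None,
    max_shift: float = 32.0,
) -> RegisteredPair:
    """Upscale thermal by the nominal sensor scale, locate it within the
    visible frame, crop the visible image to the thermal field of view, and
    resample both to ``target_dims`` (defaults to the upscaled thermal size)."""
    thermal = np.asarray(thermal, dtype=float)
    if visible.shape[0] < thermal.shape[0] or visible.shape[1] < thermal.shape[1]:
        raise ValueError("thermal raster must be strictly smaller than visible")
    lum = to_luminance(visible) if visible.ndim == 3 else np.asarray(visible, dtype=float)
    th_up = upscale_thermal(thermal, nominal_scale)
    hu, wu = th_up.shape
    hv, wv = lum.shape
    if hu > hv or wu > wv:
        raise ValueError("upscaled thermal exceeds the visible frame")

    # correlate against the same-size top-left visible window: identical
    # dims and windows, and no artificial padding edge in either raster
    sx, sy = estimate_translation(lum[:hu, :wu], th_up, max_shift=max_shift)
    # top-left-anchored thermal content displaced by (sx, sy) means its true
    # position in the visible frame is the opposite offset
    tx, ty = -sx, -sy
    x0, y0 = tx, ty
    # overhangs up to ~2 px (noise-level estimates on aligned pairs) are
    # clamped by the coordinate clip below; anything larger is an error
    if x0 < -2.0 or y0 < -2.0 or x0 + wu > wv + 2.0 or y0 + hu > hv + 2.0:
        raise RegistrationError(
            f"thermal field of view at ({x0:.2f}, {y0:.2f}) leaves the visible frame",
            (tx, ty),
        )
    # subpixel crop of the visible frame at the estimated offset
    rows = np.clip(np.arange(hu) + y0, 0, hv - 1)
    cols = np.clip(np.arange(wu) + x0, 0, wv - 1)
    crop = ndi.map_coordinates(
        lum, np.meshgrid(rows, cols, indexing="ij"), order=3, mode="nearest"
    )

    if target_dims is None:
        target_dims = (wu, hu)
    w, h = target_dims
    if crop.shape == (h, w):
        vis_out = np.clip(crop, 0.0, 1.0)
    else:
        vis_out = np.clip(_resample(crop, (h, w), h / crop.shape[0], w / crop.shape[1]), 0, 1)
    transform = SimilarityTransform(scale=nominal_scale, tx=float(tx), ty=float(ty))
    th_out = apply_transform(thermal, transform, target_dims)
    return RegisteredPair(
        visible_gray=vis_out,
        thermal_reg=th_out,
        transform=transform,
        target_dims=target_dims,
    )


def write_registered_pair(pair: RegisteredPair, out_dir: str | Path, stem: str) -> None:
    """Two 32-bit float TIFFs plus a JSON sidecar with the transform."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{stem}_visible.tif", pair.visible_gray.astype(np.float32))
    tifffile.imwrite(out / f"{stem}_thermal.tif", pair.thermal_reg.astype(np.float32))
    sidecar = {"transform": asdict(pair.transform), "target_dims": list(pair.target_dims)}
    (out / f"{stem}_transform.json").write_text(json.dumps(sidecar, indent=1))
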