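"""Seeded synthetic paired visible/thermal scenes with ground truth.

The generator emulates nadir drone imagery of animals on pasture: a large
visible frame and a smaller thermal frame related by a known similarity
misregistration, animal objects rendered as oriented body-plus-head ellipse
pairs, per-species visible conspicuousness (cryptic deer-like targets have
near-zero visible contrast and frequently sit in shadow patches; cow- and
horse-like targets contrast strongly), and warm-body thermal contrast
against a cooler ambient background. The visible and thermal backgrounds
are independent draws of Gaussian-smoothed noise, so any cross-modal
structure comes from the objects alone. A simulated detector with
controllable false-negative / false-positive / localization /
misclassification error provides detection sets with known expected
statistics.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .annotations import AnnotationSet, BoundingBox, write_coco, write_yolo
from .registration import SimilarityTransform


class PlacementError(RuntimeError):
    """Scene too small to place the requested objects without overlap."""


@dataclass(frozen=True)
class SpeciesProfile:
    """Rendering profile controlling how conspicuous a species is."""

    name: str
    visible_contrast: float  #: luminance offset vs background, in [-1, 1]
    thermal_contrast: float  #: warm-body offset in normalized units [0, 1]
    size_range: tuple[float, float]  #: body semi-axis range, visible-frame px
    shadow_prob: float  #: probability the object sits in a shadow patch
    count_range: tuple[int, int]  #: objects per image (inclusive range)

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError("size_range must satisfy 0 < min <= max")
        if not (-1 <= self.visible_contrast <= 1 and 0 <= self.thermal_contrast <= 1):
            raise ValueError("contrasts out of range")
        if not 0 <= self.shadow_prob <= 1:
            raise ValueError("shadow_prob must lie in [0, 1]")


# Default profiles: a cryptic deer-like class (low visible contrast, shadowed
# about 60% of the time) and two conspicuous classes.
DEER_LIKE = SpeciesProfile("deer", 0.02, 0.5, (14.0, 24.0), 0.6, (1, 3))
COW_LIKE = SpeciesProfile("cow", 0.35, 0.5, (16.0, 28.0), 0.05, (1, 5))
HORSE_LIKE = SpeciesProfile("horse", 0.30, 0.5, (18.0, 30.0), 0.05, (1, 4))

#: image-count mix of the reference survey dataset (cow : deer : horse)
REFERENCE_IMAGE_MIX = {"cow": 68, "deer": 53, "horse": 43}


@dataclass(frozen=True)
class SceneConfig:
    visible_dims: tuple[int, int] = (448, 358)  #: (width, height)
    thermal_dims: tuple[int, int] = (160, 128)
    species: tuple[SpeciesProfile, ...] = (DEER_LIKE, COW_LIKE, HORSE_LIKE)
    misregistration: SimilarityTransform = SimilarityTransform(scale=2.8, tx=0.0, ty=0.0)
    background_smoothness: float = 8.0  #: Gaussian blur radius, px
    noise_sigma: float = 0.01
    thermal_background_level: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        wv, hv = self.visible_dims
        wt, ht = self.thermal_dims
        if min(wv, hv, wt, ht) <= 0:
            raise ValueError("dims must be positive")
        if not (wt < wv and ht < hv):
            raise ValueError("thermal_dims must be strictly smaller than visible_dims")


@dataclass(frozen=True)
class DetectorErrorModel:
    """Controls for a simulated detector standing in for a trained network."""

    fn_rate: float = 0.0  #: probability a true object yields no detection
    fp_rate: float = 0.0  #: expected spurious detections per image
    loc_jitter_sigma: float = 0.0  #: box-corner perturbation, px
    misclass_rate: float = 0.0  #: probability of a wrong class label
    confidence_model: Callable[[float], float] | None = None
    """Maps the mean absolute corner displacement (px) to a score in (0, 1];
    the default is ``1 / (1 + displacement)`` so exact boxes score 1.0."""

    def __post_init__(self) -> None:
        for r in (self.fn_rate, self.fp_rate, self.misclass_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.loc_jitter_sigma < 0:
            raise ValueError("loc_jitter_sigma must be >= 0")

    def confidence(self, displacement: float) -> float:
        if self.confidence_model is not None:
            return self.confidence_model(displacement)
        return 1.0 / (1.0 + displacement)


def _smooth_noise(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    field_ = ndi.gaussian_filter(rng.uniform(size=shape), smoothness, mode="reflect")
    lo, hi = field_.min(), field_.max()
    return (field_ - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _object_masks(
    rng: np.random.Generator, cx: float, cy: float, semi: float, shape
) -> tuple[tuple, tuple, tuple]:
    """Body ellipse with a smaller head ellipse at one end; returns the
    object mask and the shadow-patch indices. The head overlaps the body end
    so the bounding box stays snug around the warm mass."""
    theta = rng.uniform(0.0, np.pi)
    minor = semi * rng.uniform(0.55, 0.7)
    hx = cx + np.cos(theta) * semi * 0.75
    hy = cy - np.sin(theta) * semi * 0.75
    body = draw_ellipse(cy, cx, minor, semi, shape=shape, rotation=theta)
    head = draw_ellipse(hy, hx, minor * 0.5, semi * 0.3, shape=shape, rotation=theta)
    mask = (
        np.concatenate([body[0], head[0]]),
        np.concatenate([body[1], head[1]]),
    )
    shadow = draw_ellipse(
        cy + minor * 0.8, cx + semi * 0.4, minor * 1.6, semi * 1.4, shape=shape, rotation=theta
    )
    return mask, shadow


def make_scene(
    config: SceneConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, AnnotationSet]:
    """Render one paired scene.

    Returns the visible raster (H, W, 3) in [0, 1], the thermal raster
    (h, w) in [0, 1] sampled under the inverse of the configured
    misregistration, and ground-truth boxes in visible-frame coordinates.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wv, hv = config.visible_dims
    wt, ht = config.thermal_dims

    vis_lum = 0.35 + 0.3 * _smooth_noise(rng, (hv, wv), config.background_smoothness)
    therm = config.thermal_background_level - 0.05 + 0.1 * _smooth_noise(
        rng, (hv, wv), config.background_smoothness
    )

    boxes: list[BoundingBox] = []
    occupancy = np.zeros((hv, wv), dtype=bool)
    shadow_flags: list[bool] = []
    for profile in config.species:
        lo, hi = profile.count_range
        count = int(rng.integers(lo, hi + 1))
        for _ in range(count):
            placed = False
            for _attempt in range(100):
                semi = rng.uniform(*profile.size_range)
                margin = semi * 1.6 + 2
                if 2 * margin >= min(wv, hv):
                    continue
                cx = rng.uniform(margin, wv - margin)
                cy = rng.uniform(margin, hv - margin)
                mask, shadow = _object_masks(rng, cx, cy, semi, (hv, wv))
                if mask[0].size == 0:
                    continue
                r0, r1 = mask[0].min(), mask[0].max() + 1
                c0, c1 = mask[1].min(), mask[1].max() + 1
                if occupancy[r0:r1, c0:c1].any():
                    continue
                shadowed = bool(rng.random() < profile.shadow_prob)
                if shadowed:
                    vis_lum[shadow] *= 0.4
                vis_lum[mask] = np.clip(vis_lum[mask] + profile.visible_contrast, 0, 1)
                therm[mask] = np.clip(therm[mask] + profile.thermal_contrast, 0, 1)
                occupancy[r0:r1, c0:c1] = True
                boxes.append(
                    BoundingBox(float(c0), float(r0), float(c1), float(r1), profile.name)
                )
                shadow_flags.append(shadowed)
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {profile.name} object in a "
                    f"{wv}x{hv} scene after bounded retries"
                )

    vis_lum = np.clip(vis_lum + rng.normal(0, config.noise_sigma, vis_lum.shape), 0, 1)
    # mild fixed channel tints keep luminance equal to the rendered field
    visible = np.stack([vis_lum, vis_lum, vis_lum], axis=-1)

    t = config.misregistration
    rr, cc = np.meshgrid(np.arange(ht, dtype=float), np.arange(wt, dtype=float), indexing="ij")
    thermal = ndi.map_coordinates(
        therm, [t.scale * rr + t.ty, t.scale * cc + t.tx], order=1, mode="nearest"
    )
    thermal = np.clip(thermal + rng.normal(0, config.noise_sigma, thermal.shape), 0, 1)

    aset = AnnotationSet(boxes=boxes, image_size=(wv, hv), image_id="")
    aset.shadow_flags = shadow_flags  # type: ignore[attr-defined]
    return visible, thermal, aset


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------


def split_counts(n_images: int, split: tuple[float, float, float]) -> tuple[int, int, int]:
    """Floor the train and validation counts; the remainder goes to test."""
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(np.floor(n_images * split[0]))
    n_val = int(np.floor(n_images * split[1]))
    return n_train, n_val, n_images - n_train - n_val


def _config_digest(config: SceneConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def make_dataset(
    config: SceneConfig,
    n_images: int,
    split: tuple[float, float, float] = (0.7, 0.1, 0.2),
    out_dir: str | Path = ".",
    seed: int = 0,
) -> dict:
    """Write image pairs and annotations for all splits; returns the manifest.

    Visible images are 8-bit PNG, thermal images 16-bit single-channel TIFF;
    annotations are written both as YOLO text and COCO JSON. The manifest
    (also written to ``manifest.json``) records per-image seeds so any entry
    can be regenerated independently.
    """
    out = Path(out_dir)
    class_names = [p.name for p in config.species]
    counts = split_counts(n_images, split)
    seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2**31)
    manifest: dict = {
        "seed": seed,
        "config_digest": _config_digest(config),
        "config": asdict(config),
        "class_names": class_names,
        "splits": {},
    }
    idx = 0
    for split_name, n_split in zip(("train", "val", "test"), counts):
        entries = []
        split_dir = out / split_name
        split_dir.mkdir(parents=True, exist_ok=True)
        for _ in range(n_split):
            img_seed = int(seeds[idx])
            visible, thermal, truth = make_scene(config, seed=img_seed)
            stem = f"scene_{idx:05d}"
            Image.fromarray((visible * 255).round().astype(np.uint8)).save(
                split_dir / f"{stem}_visible.png"
            )
            tifffile.imwrite(
                split_dir / f"{stem}_thermal.tif",
                (thermal * 65535).round().astype(np.uint16),
            )
            write_yolo(truth, split_dir / f"{stem}.txt", class_names)
            write_coco(truth, split_dir / f"{stem}.json", class_names)
            entries.append(
                {
                    "stem": stem,
                    "seed": img_seed,
                    "n_objects": len(truth),
                    "visible": f"{split_name}/{stem}_visible.png",
                    "thermal": f"{split_name}/{stem}_thermal.tif",
                    "yolo": f"{split_name}/{stem}.txt",
                    "coco": f"{split_name}/{stem}.json",
                }
            )
            idx += 1
        manifest["splits"][split_name] = entries
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    # return the JSON-canonical form so it round-trips with the written file
    return json.loads(json.dumps(manifest))


def reference_mix_counts(n_images: int) -> dict[str, int]:
    """Partition ``n_images`` in the reference survey's cow:deer:horse
    image proportions (largest-remainder rounding)."""
    total = sum(REFERENCE_IMAGE_MIX.values())
    raw = {k: n_images * v / total for k, v in REFERENCE_IMAGE_MIX.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    leftovers = sorted(raw, key=lambda k: raw[k] - base[k], reverse=True)
    for k in leftovers[: n_images - sum(base.values())]:
        base[k] += 1
    return base


# ---------------------------------------------------------------------------
# Simulated detector
# ---------------------------------------------------------------------------


def simulate_detections(
    truth: AnnotationSet,
    model: DetectorErrorModel,
    seed: int = 0,
    class_names: Sequence[str] | None = None,
) -> AnnotationSet:
    """Detector output with known expected error statistics.

    Each truth box independently survives with probability ``1 - fn_rate``
    and yields one corner-jittered detection; spurious detections (expected
    count ``fp_rate``) are placed uniformly with a random class drawn from
    the known classes.
    """
    rng = np.random.default_rng(seed)
    w, h = truth.image_size
    names = list(class_names) if class_names else (truth.labels() or ["object"])
    detections: list[BoundingBox] = []
    for box in truth:
        if rng.random() < model.fn_rate:
            continue
        jitter = rng.normal(0.0, model.loc_jitter_sigma, size=4) if model.loc_jitter_sigma else np.zeros(4)
        x0, y0 = box.x_min + jitter[0], box.y_min + jitter[1]
        x1, y1 = box.x_max + jitter[2], box.y_max + jitter[3]
        if x1 <= x0 + 1e-6:
            x0, x1 = box.x_min, box.x_max
        if y1 <= y0 + 1e-6:
            y0, y1 = box.y_min, box.y_max
        label = box.class_label
        if model.misclass_rate and rng.random() < model.misclass_rate:
            others = [n for n in names if n != label]
            if others:
                label = others[int(rng.integers(len(others)))]
        conf = float(np.clip(model.confidence(float(np.abs(jitter).mean())), 1e-6, 1.0))
        detections.append(BoundingBox(x0, y0, x1, y1, label, conf))
    n_fp = int(rng.poisson(model.fp_rate))
    for _ in range(n_fp):
        bw = rng.uniform(8, max(9.0, w / 8))
        bh = rng.uniform(8, max(9.0, h / 8))
        x0 = rng.uniform(0, w - bw)
        y0 = rng.uniform(0, h - bh)
        label = names[int(rng.integers(len(names)))]
        detections.append(
            BoundingBox(x0, y0, x0 + bw, y0 + bh, label, float(rng.uniform(0.1, 0.5)))
        )
    return AnnotationSet(boxes=detections, image_size=truth.image_size, image_id=truth.image_id)


def cryptic_scene_config(seed: int = 0, **overrides) -> SceneConfig:
    """A deer-only cryptic-target configuration: near-zero visible contrast,
    strong warm-body thermal contrast — the hard case for visible imagery."""
    cryptic = replace(DEER_LIKE, visible_contrast=0.02, thermal_contrast=0.5, count_range=(2, 4))
    return SceneConfig(species=(cryptic,), seed=seed, **overrides)
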