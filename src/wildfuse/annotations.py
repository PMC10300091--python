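"""Bounding-box annotations and interchange between YOLO text and COCO JSON.

Coordinate convention throughout the package: origin at the top-left corner,
x increases rightward (columns), y increases downward (rows), 0-based pixel
coordinates, boxes half-open ``[min, max)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence


class AnnotationError(ValueError):
    """Raised for malformed annotation files; carries the offending line."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, half-open on both axes."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_label: str = ""
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box: {self}")
        if self.confidence is not None and not (0.0 < self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in (0, 1]: {self.confidence}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def clipped(self, width: int, height: int) -> "BoundingBox":
        """Clip to image bounds; raises if nothing remains."""
        return replace(
            self,
            x_min=max(0.0, self.x_min),
            y_min=max(0.0, self.y_min),
            x_max=min(float(width), self.x_max),
            y_max=min(float(height), self.y_max),
        )


@dataclass
class AnnotationSet:
    """Boxes attached to one image of known size (width, height)."""

    boxes: list[BoundingBox] = field(default_factory=list)
    image_size: tuple[int, int] = (0, 0)
    image_id: str = ""

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self) -> Iterator[BoundingBox]:
        return iter(self.boxes)

    def labels(self) -> list[str]:
        return sorted({b.class_label for b in self.boxes})


# ---------------------------------------------------------------------------
# YOLO text format: one line per object,
#   class_index x_center y_center width height   (all normalized to [0, 1])
# ---------------------------------------------------------------------------


def write_yolo(aset: AnnotationSet, path: str | Path, class_names: Sequence[str]) -> None:
    w, h = aset.image_size
    lines = []
    index = {name: i for i, name in enumerate(class_names)}
    for b in aset.boxes:
        cx = (b.x_min + b.x_max) / 2.0 / w
        cy = (b.y_min + b.y_max) / 2.0 / h
        lines.append(
            f"{index[b.class_label]} {cx:.10f} {cy:.10f} {b.width / w:.10f} {b.height / h:.10f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo(
    path: str | Path,
    image_size: tuple[int, int],
    class_names: Sequence[str],
    image_id: str = "",
) -> AnnotationSet:
    w, h = image_size
    boxes: list[BoundingBox] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise AnnotationError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        try:
            ci = int(parts[0])
            cx, cy, bw, bh = (float(p) for p in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else None
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
        if not 0 <= ci < len(class_names):
            raise AnnotationError(f"{path}:{lineno}: class index {ci} out of range")
        boxes.append(
            BoundingBox(
                x_min=(cx - bw / 2) * w,
                y_min=(cy - bh / 2) * h,
                x_max=(cx + bw / 2) * w,
                y_max=(cy + bh / 2) * h,
                class_label=class_names[ci],
                confidence=conf,
            )
        )
    return AnnotationSet(boxes=boxes, image_size=image_size, image_id=image_id)


# ---------------------------------------------------------------------------
# COCO-style JSON: absolute [x, y, width, height] boxes.
# ---------------------------------------------------------------------------


def write_coco(aset: AnnotationSet, path: str | Path, class_names: Sequence[str]) -> None:
    w, h = aset.image_size
    index = {name: i for i, name in enumerate(class_names)}
    doc = {
        "images": [{"id": 0, "file_name": aset.image_id, "width": w, "height": h}],
        "categories": [{"id": i, "name": n} for i, n in enumerate(class_names)],
        "annotations": [
            {
                "id": j,
                "image_id": 0,
                "category_id": index[b.class_label],
                "bbox": [b.x_min, b.y_min, b.width, b.height],
                **({"score": b.confidence} if b.confidence is not None else {}),
            }
            for j, b in enumerate(aset.boxes)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path: str | Path) -> AnnotationSet:
    doc = json.loads(Path(path).read_text())
    try:
        img = doc["images"][0]
        names = {c["id"]: c["name"] for c in doc["categories"]}
        boxes = [
            BoundingBox(
                x_min=a["bbox"][0],
                y_min=a["bbox"][1],
                x_max=a["bbox"][0] + a["bbox"][2],
                y_max=a["bbox"][1] + a["bbox"][3],
                class_label=names[a["category_id"]],
                confidence=a.get("score"),
            )
            for a in doc["annotations"]
        ]
    except (KeyError, IndexError, TypeError) as exc:
        raise AnnotationError(f"{path}: malformed COCO document ({exc})") from exc
    return AnnotationSet(
        boxes=boxes,
        image_size=(img["width"], img["height"]),
        image_id=img.get("file_name", ""),
    )


def read_annotations(path: str | Path, format: str, **kwargs) -> AnnotationSet:
    """Dispatch on format name: ``"yolo"`` or ``"coco"``."""
    if format == "yolo":
        return read_yolo(path, **kwargs)
    if format == "coco":
        return read_coco(path)
    raise ValueError(f"unrecognized annotation format: {format!r}")
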