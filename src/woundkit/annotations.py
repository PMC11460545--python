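"""Bounding-box annotation I/O: YOLO-txt and COCO-JSON.

YOLO-txt rows are ``class cx cy w h`` with center/size normalized by the
image dimensions; an optional sixth column carries a confidence.  COCO boxes
are ``[x, y, width, height]`` in absolute pixels.  Both round-trip
losslessly through :class:`~woundkit.detect.Detection`.
"""

from __future__ import annotations

import json
from pathlib import Path

from .detect import BoundingBox, Detection

__all__ = [
    "load_yolo_txt",
    "save_yolo_txt",
    "load_coco_json",
    "save_coco_json",
]


def load_yolo_txt(path, image_width: int, image_height: int) -> list[Detection]:
    dets = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cls = int(parts[0])
        cx, cy, w, h = (float(v) for v in parts[1:5])
        conf = float(parts[5]) if len(parts) > 5 else 1.0
        box = BoundingBox(
            (cx - w / 2) * image_width,
            (cy - h / 2) * image_height,
            (cx + w / 2) * image_width,
            (cy + h / 2) * image_height,
        )
        dets.append(Detection(box, conf, label=cls))
    return dets


def save_yolo_txt(path, detections: list[Detection], image_width: int, image_height: int) -> None:
    lines = []
    for d in detections:
        b = d.box
        cx = (b.x_min + b.x_max) / 2 / image_width
        cy = (b.y_min + b.y_max) / 2 / image_height
        w = b.width / image_width
        h = b.height / image_height
        lines.append(f"{d.label} {cx!r} {cy!r} {w!r} {h!r} {d.confidence!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def save_coco_json(
    path,
    per_image: dict[str, list[Detection]],
    image_sizes: dict[str, tuple[int, int]] | None = None,
    category_name: str = "wound",
) -> None:
    """Write detections as a COCO-style dict of images/annotations/categories.

    ``image_sizes`` maps file name to ``(width, height)``.
    """
    images = []
    annotations = []
    name_to_id = {}
    for i, name in enumerate(sorted(per_image), start=1):
        name_to_id[name] = i
        entry = {"id": i, "file_name": name}
        if image_sizes and name in image_sizes:
            entry["width"], entry["height"] = image_sizes[name]
        images.append(entry)
    ann_id = 1
    for name in sorted(per_image):
        for d in per_image[name]:
            b = d.box
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": name_to_id[name],
                    "category_id": 1,
                    "bbox": [b.x_min, b.y_min, b.width, b.height],
                    "area": b.area,
                    "score": d.confidence,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": category_name}],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_coco_json(path) -> dict[str, list[Detection]]:
    doc = json.loads(Path(path).read_text())
    id_to_name = {im["id"]: im["file_name"] for im in doc["images"]}
    out: dict[str, list[Detection]] = {name: [] for name in id_to_name.values()}
    for ann in doc["annotations"]:
        x, y, w, h = ann["bbox"]
        box = BoundingBox(x, y, x + w, y + h)
        conf = float(ann.get("score", 1.0))
        out[id_to_name[ann["image_id"]]].append(Detection(box, conf))
    return out
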