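"""Pascal-VOC XML annotation I/O, dataset manifests and detection dumps.

On disk the VOC dialect (the LabelImg convention) stores 1-based *inclusive*
pixel coordinates; in memory the package uses 0-based half-open boxes.  The
conversion is ``x1 = xmin - 1`` and ``x2 = xmax`` (widths are preserved), and
``write_voc_xml`` is the exact inverse of ``read_voc_xml``.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .boxes import BoxSet


@dataclass
class ImageMeta:
    filename: str
    width: int
    height: int
    depth: int = 3
    folder: str = "images"


@dataclass
class ManifestEntry:
    image_path: str
    xml_path: str
    split: str            # "train" or "test"
    class_id: int


@dataclass
class DatasetManifest:
    class_names: list[str]
    entries: list[ManifestEntry]
    seed: int
    image_size: tuple[int, int] = (800, 600)

    def paths(self, split: str | None = None) -> list[ManifestEntry]:
        return [e for e in self.entries if split is None or e.split == split]

    def save(self, path):
        payload = {
            "class_names": self.class_names,
            "seed": self.seed,
            "image_size": list(self.image_size),
            "entries": [vars(e) for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def load(path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        entries = [ManifestEntry(**e) for e in payload["entries"]]
        return DatasetManifest(payload["class_names"], entries,
                               payload["seed"], tuple(payload["image_size"]))


def read_voc_xml(path, class_names: list[str]) -> tuple[ImageMeta, BoxSet]:
    """Parse one VOC XML file into image metadata and a BoxSet.

    Boxes are converted to the internal 0-based half-open convention and
    clipped to the image bounds; degenerate boxes or unknown class names
    raise a ``ValueError`` naming the file.
    """
    path = Path(path)
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML in {path}: {exc}") from exc
    size = root.find("size")
    if size is None:
        raise ValueError(f"missing <size> element in {path}")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    depth = int(size.findtext("depth", "3"))
    meta = ImageMeta(root.findtext("filename", path.stem + ".png"),
                     width, height, depth,
                     root.findtext("folder", "images"))

    boxes, labels = [], []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name not in class_names:
            raise ValueError(f"unknown class {name!r} in {path}")
        bb = obj.find("bndbox")
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"degenerate box for {name!r} in {path}")
        x1, y1, x2, y2 = xmin - 1.0, ymin - 1.0, xmax, ymax
        x1, x2 = max(0.0, x1), min(float(width), x2)
        y1, y2 = max(0.0, y1), min(float(height), y2)
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"degenerate box for {name!r} in {path}")
        boxes.append([x1, y1, x2, y2])
        labels.append(class_names.index(name) + 1)
    if boxes:
        return meta, BoxSet(np.array(boxes), np.array(labels))
    return meta, BoxSet.empty()


def write_voc_xml(meta: ImageMeta, boxes: BoxSet, class_names: list[str],
                  path) -> None:
    """Write a VOC XML file; exact inverse of :func:`read_voc_xml`."""
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = meta.folder
    ET.SubElement(root, "filename").text = meta.filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(meta.width)
    ET.SubElement(size, "height").text = str(meta.height)
    ET.SubElement(size, "depth").text = str(meta.depth)
    for b, lab in zip(boxes.boxes, boxes.labels):
        # widths must exceed 1 px: the on-disk 1-based inclusive coding cannot
        # represent anything narrower without degenerating (xmax <= xmin)
        if b[2] <= b[0] + 1 or b[3] <= b[1] + 1:
            raise ValueError("refusing to write a box narrower than 2 px")
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = class_names[int(lab) - 1]
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = _fmt(b[0] + 1.0)
        ET.SubElement(bb, "ymin").text = _fmt(b[1] + 1.0)
        ET.SubElement(bb, "xmax").text = _fmt(b[2])
        ET.SubElement(bb, "ymax").text = _fmt(b[3])
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), encoding="unicode")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# detection dumps: one JSON object per line
# ---------------------------------------------------------------------------

def write_detections(dets: dict[str, BoxSet], path) -> None:
    """Dump per-image detections as JSON lines (image id, label, score, box)."""
    with open(path, "w") as fh:
        for image_id, bs in dets.items():
            for b, lab, sc in zip(bs.boxes, bs.labels,
                                  bs.scores if bs.scores is not None
                                  else np.ones(len(bs))):
                fh.write(json.dumps({
                    "image_id": image_id, "label": int(lab),
                    "score": float(sc), "box": [float(v) for v in b],
                }) + "\n")


def read_detections(path) -> dict[str, BoxSet]:
    rows: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            rows.setdefault(rec["image_id"], []).append(rec)
    out = {}
    for image_id, recs in rows.items():
        out[image_id] = BoxSet(np.array([r["box"] for r in recs]),
                               np.array([r["label"] for r in recs]),
                               np.array([r["score"] for r in recs]))
    return out
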