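"""PASCAL-VOC style annotation I/O and keep-ratio resizing.

Boxes are stored internally with 0-based corner coordinates in floating
point, using the continuous convention ``width = xmax - xmin`` for all
overlap arithmetic.  On disk the VOC dialect is 1-based and integer; the
offset is applied on read/write so that a write/read roundtrip is the
identity on valid records.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "BoxAnnotation", "ImageRecord", "DatasetIndex",
    "read_voc_xml", "write_voc_xml", "resize_with_boxes", "summarize_dataset",
    "VocFormatError",
]


class VocFormatError(ValueError):
    """Raised for malformed or structurally invalid annotation files."""


@dataclass
class BoxAnnotation:
    """A single labelled box; corners 0-based, ``xmax > xmin``."""

    label: str
    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def validate(self):
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_array(self) -> np.ndarray:
        return np.array([self.xmin, self.ymin, self.xmax, self.ymax],
                        dtype=np.float64)


@dataclass
class ImageRecord:
    """An image (path or in-memory array) plus its annotations."""

    width: int
    height: int
    annotations: list[BoxAnnotation] = field(default_factory=list)
    path: str | None = None
    image: np.ndarray | None = None   # HxWx3 uint8 when in memory
    scale: float = 1.0                # resize factor applied so far

    def validate(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        for a in self.annotations:
            a.validate()
            if a.xmin < 0 or a.ymin < 0 or a.xmax > self.width or a.ymax > self.height:
                raise ValueError(f"annotation {a} outside {self.width}x{self.height}")

    def boxes(self) -> np.ndarray:
        if not self.annotations:
            return np.zeros((0, 4), dtype=np.float64)
        return np.stack([a.as_array() for a in self.annotations])

    def labels(self) -> list[str]:
        return [a.label for a in self.annotations]


@dataclass
class DatasetIndex:
    records: list[ImageRecord]
    class_names: list[str]
    split: str = "train"

    def __post_init__(self):
        if not self.class_names:
            raise ValueError("class_names must be non-empty")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names contains duplicates")
        known = set(self.class_names)
        for r in self.records:
            for a in r.annotations:
                if a.label not in known:
                    raise ValueError(
                        f"unknown class {a.label!r}; expected one of {sorted(known)}"
                    )

    def class_id(self, label: str) -> int:
        return self.class_names.index(label)

    def __len__(self):
        return len(self.records)


def read_voc_xml(path: str | Path) -> ImageRecord:
    """Parse one VOC annotation file into an :class:`ImageRecord`.

    Unknown class names are preserved verbatim; they are rejected later at
    :class:`DatasetIndex` construction so that bad label maps fail loudly.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise VocFormatError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise VocFormatError(f"{path}: missing <size> node")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    annotations = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        bb = obj.find("bndbox")
        if name is None or bb is None:
            raise VocFormatError(f"{path}: object without name/bndbox")
        # VOC is 1-based; shift to the internal 0-based convention
        annotations.append(BoxAnnotation(
            label=name,
            xmin=float(bb.findtext("xmin")) - 1.0,
            ymin=float(bb.findtext("ymin")) - 1.0,
            xmax=float(bb.findtext("xmax")) - 1.0,
            ymax=float(bb.findtext("ymax")) - 1.0,
        ))
    fname = root.findtext("filename")
    return ImageRecord(width=width, height=height, annotations=annotations,
                       path=fname)


def write_voc_xml(record: ImageRecord, path: str | Path):
    """Emit ``record`` as a VOC annotation file (re-readable losslessly)."""
    record.validate()
    lines = ["<annotation>"]
    if record.path:
        lines.append(f"  <filename>{record.path}</filename>")
    lines += [
        "  <size>",
        f"    <width>{record.width}</width>",
        f"    <height>{record.height}</height>",
        "    <depth>3</depth>",
        "  </size>",
    ]
    for a in record.annotations:
        lines += [
            "  <object>",
            f"    <name>{a.label}</name>",
            "    <bndbox>",
            f"      <xmin>{_fmt(a.xmin + 1.0)}</xmin>",
            f"      <ymin>{_fmt(a.ymin + 1.0)}</ymin>",
            f"      <xmax>{_fmt(a.xmax + 1.0)}</xmax>",
            f"      <ymax>{_fmt(a.ymax + 1.0)}</ymax>",
            "    </bndbox>",
            "  </object>",
        ]
    lines.append("</annotation>")
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(v: float) -> str:
    """Stable numeric formatting: integers stay integers."""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def resize_with_boxes(record: ImageRecord, max_long: int, max_short: int) -> ImageRecord:
    """Keep-ratio resize so the long/short sides fit (max_long, max_short).

    The scale is ``min(max_long/long_side, max_short/short_side)`` — the
    COCO-style convention; box coordinates stay in floating point while the
    image size is rounded half-away-from-zero to whole pixels.
    """
    if not (max_long >= max_short > 0):
        raise ValueError("require max_long >= max_short > 0")
    record.validate()
    long_side = max(record.width, record.height)
    short_side = min(record.width, record.height)
    scale = min(max_long / long_side, max_short / short_side)
    new_w = max(1, _round_half_away(record.width * scale))
    new_h = max(1, _round_half_away(record.height * scale))
    if new_w == record.width and new_h == record.height:
        return record
    annotations = [
        BoxAnnotation(a.label,
                      min(a.xmin * scale, new_w), min(a.ymin * scale, new_h),
                      min(a.xmax * scale, new_w), min(a.ymax * scale, new_h))
        for a in record.annotations
    ]
    image = None
    if record.image is not None:
        image = _resize_image(record.image, new_h, new_w)
    return replace(record, width=new_w, height=new_h, annotations=annotations,
                   image=image, scale=record.scale * scale)


def _resize_image(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    from PIL import Image

    pil = Image.fromarray(img)
    return np.asarray(pil.resize((out_w, out_h), Image.BILINEAR))


def load_voc_dir(path: str | Path, class_names: list[str],
                 split: str = "train") -> DatasetIndex:
    """Load a directory of images + VOC XML written by this package.

    Reads ``manifest_<split>.txt`` when present, otherwise pairs every
    ``*.xml`` with its same-stem image.  Images are loaded into memory.
    """
    from PIL import Image

    path = Path(path)
    manifest = path / f"manifest_{split}.txt"
    if manifest.exists():
        pairs = [line.split() for line in manifest.read_text().splitlines()
                 if line.strip()]
    else:
        pairs = []
        for xml in sorted(path.glob("*.xml")):
            for ext in (".png", ".jpg", ".jpeg"):
                img = xml.with_suffix(ext)
                if img.exists():
                    pairs.append([img.name, xml.name])
                    break
    records = []
    for img_name, xml_name in pairs:
        rec = read_voc_xml(path / xml_name)
        rec.image = np.asarray(Image.open(path / img_name).convert("RGB"))
        rec.path = img_name
        records.append(rec)
    return DatasetIndex(records=records, class_names=list(class_names),
                        split=split)


def summarize_dataset(index: DatasetIndex) -> dict:
    """Per-class image and object counts plus totals.

    An image containing k classes is counted once in each of those classes'
    image counts; object counts sum to the total number of annotations.
    """
    images = {c: 0 for c in index.class_names}
    objects = {c: 0 for c in index.class_names}
    for r in index.records:
        present = set()
        for a in r.annotations:
            objects[a.label] += 1
            present.add(a.label)
        for c in present:
            images[c] += 1
    total_objects = sum(objects.values())
    return {
        "images_per_class": images,
        "objects_per_class": objects,
        "total_images": len(index.records),
        "total_objects": total_objects,
        "mean_objects_per_image": (total_objects / len(index.records)
                                   if index.records else 0.0),
    }
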