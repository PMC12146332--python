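"""Pascal VOC XML annotation I/O and deterministic dataset splitting.

Coordinate conventions
----------------------
Internally every box is 0-based and half-open: a box ``(xmin, ymin, xmax,
ymax)`` covers the pixel columns ``xmin..xmax-1`` and rows ``ymin..ymax-1``,
so ``width == xmax - xmin``.  VOC XML files use the classic 1-based,
boundary-inclusive dialect: on write ``xmin``/``ymin`` gain 1 while
``xmax``/``ymax`` are stored as-is, and reading inverts that.

A non-standard ``<time_h>`` element records the frame's acquisition time in
hours; VOC consumers that do not know it simply ignore it.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default label vocabulary.  The map is configurable because upstream
#: datasets are free to use their own class strings.
DEFAULT_LABELS = frozenset({"germinated", "ungerminated"})


class VocParseError(ValueError):
    """Raised when a VOC XML file cannot be parsed."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in 0-based half-open pixel coordinates."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int
    label: str

    def __post_init__(self) -> None:
        if self.xmin < 0 or self.ymin < 0:
            raise ValueError(f"box coordinates must be non-negative, got {self}")
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"degenerate box (need xmin < xmax and ymin < ymax): {self}")

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    def clip(self, height: int, width: int) -> "BoundingBox":
        """Clip the box to an image extent; raises if no overlap remains."""
        xmin = max(self.xmin, 0)
        ymin = max(self.ymin, 0)
        xmax = min(self.xmax, width)
        ymax = min(self.ymax, height)
        if xmin >= xmax or ymin >= ymax:
            raise ValueError(f"box {self} does not overlap a {height}x{width} image")
        return replace(self, xmin=xmin, ymin=ymin, xmax=xmax, ymax=ymax)


@dataclass
class AnnotatedFrame:
    """One time point: an image identifier, its acquisition time and boxes."""

    image_id: str
    time_h: float = 0.0
    boxes: list[BoundingBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"time_h must be non-negative, got {self.time_h}")


@dataclass(frozen=True)
class SplitCounts:
    n_train: int
    n_test: int
    n_val: int

    @property
    def total(self) -> int:
        return self.n_train + self.n_test + self.n_val


def read_voc(
    xml_path: str | Path,
    labels: Iterable[str] = DEFAULT_LABELS,
    strict: bool = False,
) -> AnnotatedFrame:
    """Parse one VOC XML file into an :class:`AnnotatedFrame`.

    Objects whose ``<name>`` is not in ``labels`` are skipped with a warning,
    or rejected when ``strict`` is true.
    """
    xml_path = Path(xml_path)
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise VocParseError(f"malformed VOC XML in {xml_path}: {exc}") from exc

    filename = root.findtext("filename", default=xml_path.stem)
    image_id = Path(filename).stem
    time_el = root.findtext("time_h")
    time_h = float(time_el) if time_el is not None else 0.0

    known = frozenset(labels)
    boxes: list[BoundingBox] = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        if name not in known:
            if strict:
                raise ValueError(f"unrecognized label {name!r} in {xml_path}")
            logger.warning("skipping object with unrecognized label %r in %s", name, xml_path)
            continue
        bnd = obj.find("bndbox")
        if bnd is None:
            raise VocParseError(f"<object> without <bndbox> in {xml_path}")
        # 1-based inclusive file coordinates -> 0-based half-open.
        xmin = int(round(float(bnd.findtext("xmin")))) - 1
        ymin = int(round(float(bnd.findtext("ymin")))) - 1
        xmax = int(round(float(bnd.findtext("xmax"))))
        ymax = int(round(float(bnd.findtext("ymax"))))
        boxes.append(BoundingBox(xmin, ymin, xmax, ymax, name))
    return AnnotatedFrame(image_id=image_id, time_h=time_h, boxes=boxes)


def write_voc(
    frame: AnnotatedFrame,
    xml_path: str | Path,
    image_size: tuple[int, int] | None = None,
) -> None:
    """Write a frame as VOC XML; ``read_voc`` inverts this exactly.

    ``image_size`` is ``(height, width)`` for the optional ``<size>`` block.
    """
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{frame.image_id}.png"
    ET.SubElement(root, "time_h").text = repr(float(frame.time_h))
    if image_size is not None:
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "height").text = str(image_size[0])
        ET.SubElement(size, "width").text = str(image_size[1])
        ET.SubElement(size, "depth").text = "1"
    for box in frame.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.label
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(box.xmin + 1)
        ET.SubElement(bnd, "ymin").text = str(box.ymin + 1)
        ET.SubElement(bnd, "xmax").text = str(box.xmax)
        ET.SubElement(bnd, "ymax").text = str(box.ymax)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(xml_path, encoding="unicode")


def split_dataset(
    n_items: int,
    ratios: Sequence[int] = (7, 2, 1),
    seed: int = 0,
) -> tuple[SplitCounts, dict[str, np.ndarray]]:
    """Deterministically split ``n_items`` indices into train/test/val.

    The train share is ``floor(n * r_train / sum(ratios))``; the remainder is
    split test:val in the exact remaining ratio with any leftover item going
    to the test set (this reproduces 8148 -> 5703/1630/815 at 7:2:1).
    Returns the counts and the seeded shuffle assignment.
    """
    if n_items < 0:
        raise ValueError(f"n_items must be non-negative, got {n_items}")
    if len(ratios) != 3 or any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise ValueError(f"ratios must be three non-negative integers with positive sum, got {ratios}")

    r_train, r_test, r_val = ratios
    total = r_train + r_test + r_val
    n_train = n_items * r_train // total  # exact floor(N * r_train / total)
    remainder = n_items - n_train
    if r_test + r_val > 0:
        n_val = remainder * r_val // (r_test + r_val)
    else:
        n_val = 0
    n_test = remainder - n_val
    counts = SplitCounts(n_train=n_train, n_test=n_test, n_val=n_val)

    perm = np.random.default_rng(seed).permutation(n_items)
    assignment = {
        "train": np.sort(perm[:n_train]),
        "test": np.sort(perm[n_train : n_train + n_test]),
        "val": np.sort(perm[n_train + n_test :]),
    }
    return counts, assignment


def write_split_manifests(
    names: Sequence[str],
    assignment: dict[str, np.ndarray],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one plain-text file list per split subset."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for subset, indices in assignment.items():
        path = out_dir / f"{subset}.txt"
        path.write_text("".join(f"{names[i]}\n" for i in indices))
        paths[subset] = path
    return paths
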