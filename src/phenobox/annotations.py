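"""Reading, writing and geometry of YOLO-format bounding-box labels.

A label file holds one object per line: ``class_id cx cy w h`` with all
coordinates normalized to the image dimensions; detector output appends a
sixth confidence column.  Ground-truth files therefore have 5 columns and
detection files 5 or 6.  These files, plus the image dimensions, are the
universal currency of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigError,
    DegenerateBoxError,
    LabelParseError,
    UnknownClassError,
)

#: Canonical trait-class names.  "leaf", "petiole" and "height" are the
#: annotated plant structures; "calibration" is the reference board of known
#: physical height used for pixel-to-centimeter conversion.
CLASS_NAMES = ("leaf", "petiole", "height", "calibration")

#: Default id -> name map (ids are configurable; datasets with only the three
#: plant classes simply omit "calibration").
DEFAULT_CLASS_MAP: dict[int, str] = {i: n for i, n in enumerate(CLASS_NAMES)}

_PRECISION = 6  # decimal places written by write_label_file


def validate_class_map(class_map: Mapping[int, str]) -> dict[int, str]:
    """Check that a class map is a bijection onto known trait names."""
    names = list(class_map.values())
    if len(set(names)) != len(names):
        raise ConfigError(f"class map is not a bijection: {class_map}")
    for cid, name in class_map.items():
        if cid < 0 or int(cid) != cid:
            raise ConfigError(f"class id must be a small non-negative int: {cid}")
        if name not in CLASS_NAMES:
            raise ConfigError(f"unknown trait name {name!r}; expected one of {CLASS_NAMES}")
    return dict(class_map)


@dataclass(frozen=True)
class NormalizedBox:
    """A bounding box in normalized (fraction-of-image) coordinates.

    ``cx, cy`` locate the box center and ``w, h`` its extent, all as
    fractions of the image width/height.  ``confidence`` is present only for
    detector output.
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float | None = None

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise DegenerateBoxError(f"box has non-positive size w={self.w}, h={self.h}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ConfigError(f"confidence outside [0,1]: {self.confidence}")

    def clipped(self) -> "NormalizedBox":
        """Clip the box to the unit square, warning if anything changes.

        Annotation jitter routinely pushes edges slightly past the frame;
        clipping keeps those boxes rather than rejecting them.
        """
        rx0, ry0 = self.cx - self.w / 2, self.cy - self.h / 2
        rx1, ry1 = self.cx + self.w / 2, self.cy + self.h / 2
        if rx0 >= 0.0 and ry0 >= 0.0 and rx1 <= 1.0 and ry1 <= 1.0:
            return self
        x0, y0 = max(rx0, 0.0), max(ry0, 0.0)
        x1, y1 = min(rx1, 1.0), min(ry1, 1.0)
        if x0 >= x1 or y0 >= y1:
            raise DegenerateBoxError("box lies entirely outside the image")
        warnings.warn("box extended past [0,1]^2 and was clipped", stacklevel=2)
        return replace(self, cx=(x0 + x1) / 2, cy=(y0 + y1) / 2, w=x1 - x0, h=y1 - y0)


@dataclass(frozen=True)
class PixelBox:
    """An axis-aligned box in continuous, 0-based pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise DegenerateBoxError(
                f"empty pixel box ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass
class LabeledImage:
    """One image's worth of boxes plus its pixel dimensions."""

    image_id: str
    width_px: int
    height_px: int
    boxes: list[NormalizedBox] = field(default_factory=list)

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigError("image dimensions must be positive")

    def boxes_of(self, class_id: int) -> list[NormalizedBox]:
        return [b for b in self.boxes if b.class_id == class_id]


def read_label_file(
    text: str, class_map: Mapping[int, str] = DEFAULT_CLASS_MAP
) -> list[NormalizedBox]:
    """Parse YOLO label text into boxes, preserving line order.

    Accepts 5 fields per line (ground truth) or 6 (detections with a
    trailing confidence).  Raises :class:`LabelParseError` with the 1-based
    line number on malformed lines and :class:`UnknownClassError` for class
    ids not in ``class_map``.
    """
    boxes: list[NormalizedBox] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise LabelParseError(line_no, f"expected 5 or 6 fields, got {len(fields)}")
        try:
            class_id = int(fields[0])
            values = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise LabelParseError(line_no, f"non-numeric field: {exc}") from None
        if class_id not in class_map:
            raise UnknownClassError(f"line {line_no}: class id {class_id} not in class map")
        conf = values[4] if len(values) == 5 else None
        box = NormalizedBox(class_id, *values[:4], confidence=conf)
        boxes.append(box.clipped())
    return boxes


def write_label_file(boxes: Iterable[NormalizedBox]) -> str:
    """Serialize boxes to YOLO label text (6 decimal places).

    Inverse of :func:`read_label_file` up to the declared precision; boxes
    with a confidence produce 6-field lines.
    """
    lines = []
    for b in boxes:
        parts = [str(b.class_id)] + [f"{v:.{_PRECISION}f}" for v in (b.cx, b.cy, b.w, b.h)]
        if b.confidence is not None:
            parts.append(f"{b.confidence:.{_PRECISION}f}")
        lines.append(" ".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")


def to_pixel_box(box: NormalizedBox, width_px: int, height_px: int) -> PixelBox:
    """Convert a normalized box to continuous pixel coordinates."""
    if width_px <= 0 or height_px <= 0:
        raise ConfigError("image dimensions must be positive")
    return PixelBox(
        x_min=(box.cx - box.w / 2) * width_px,
        y_min=(box.cy - box.h / 2) * height_px,
        x_max=(box.cx + box.w / 2) * width_px,
        y_max=(box.cy + box.h / 2) * height_px,
    )


def to_normalized_box(
    pbox: PixelBox,
    class_id: int,
    width_px: int,
    height_px: int,
    confidence: float | None = None,
) -> NormalizedBox:
    """Inverse of :func:`to_pixel_box`."""
    if width_px <= 0 or height_px <= 0:
        raise ConfigError("image dimensions must be positive")
    return NormalizedBox(
        class_id=class_id,
        cx=(pbox.x_min + pbox.x_max) / 2 / width_px,
        cy=(pbox.y_min + pbox.y_max) / 2 / height_px,
        w=pbox.width / width_px,
        h=pbox.height / height_px,
        confidence=confidence,
    )


def split_dataset(
    ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 42,
) -> dict[str, str]:
    """Partition image ids into train/val/test by shuffled-index slicing.

    Realized sizes follow largest-remainder apportionment, so they deviate
    from the exact ratios by at most one image; ties go to the larger ratio
    (a single id lands in train under the default 7:2:1).
    """
    if len(ratios) != 3:
        raise ConfigError("ratios must have three entries (train, val, test)")
    if any(r <= 0 for r in ratios):
        raise ConfigError(f"ratios must be positive: {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"ratios must sum to 1: {ratios}")
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate image ids")

    n = len(ids)
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    # hand out the remainder to the largest fractional parts, larger ratio first
    order = sorted(range(3), key=lambda i: (exact[i] - counts[i], ratios[i]), reverse=True)
    for i in order[: n - sum(counts)]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    names = ("train", "val", "test")
    assignment: dict[str, str] = {}
    start = 0
    for name, c in zip(names, counts):
        for idx in perm[start : start + c]:
            assignment[ids[idx]] = name
        start += c
    return assignment
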