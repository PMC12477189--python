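"""Phenotypic trait computation from detection boxes.

Plant height comes from a calibration-board scale conversion: the board has
a known physical height of 1.0 cm, so its pixel height Hs gives the image's
pixels-per-centimeter ratio r = Hs / 1.0.  The stem ("height"-class) box's
pixel height Hp then converts to the physical plant height PH = Hp / r.
Both Hs and Hp use the tallest box of their class when several are present.
Because calibration and stem boxes scale together, PH is invariant to
uniform image rescaling.

Petiole and leaf counts come from raw box counts; the per-petiole leaf
distribution comes from a geometric association rule: each petiole box is
expanded by a margin into an association rectangle, and a leaf belongs to a
petiole when the leaf's center point falls inside that rectangle (nearest
petiole center wins when rectangles overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    DEFAULT_CLASS_MAP,
    LabeledImage,
    NormalizedBox,
    to_pixel_box,
)
from .errors import (
    ConfigError,
    DegenerateBoxError,
    MissingCalibrationError,
    MissingTraitError,
    PhenoboxError,
)


@dataclass(frozen=True)
class ScaleFactor:
    """Pixels per centimeter, derived from a calibration box."""

    r: float
    source: str = ""

    def __post_init__(self):
        if not self.r > 0:
            raise ConfigError(f"scale factor must be positive, got {self.r}")


@dataclass(frozen=True)
class AssociationRule:
    """Geometry of the petiole-leaf association.

    ``margin_frac`` expands the petiole rectangle by that fraction of its
    own width (horizontally) and height (vertically) on each side.  Leaves
    whose center falls in several expanded rectangles go to the petiole with
    the nearest center; remaining ties go to the lower petiole index.
    """

    margin_frac: float = 0.10

    def __post_init__(self):
        if self.margin_frac < 0:
            raise ConfigError("margin_frac must be non-negative")


@dataclass
class TraitRecord:
    """Extracted phenotype of one plant."""

    plant_id: str
    treatment: str | None
    height_cm: float
    petiole_count: int
    leaf_count: int
    leaves_per_petiole: list[int] = field(default_factory=list)
    unassigned_leaves: int = 0

    def __post_init__(self):
        if self.petiole_count != len(self.leaves_per_petiole):
            raise PhenoboxError("petiole_count inconsistent with leaves_per_petiole")
        if self.leaf_count != sum(self.leaves_per_petiole) + self.unassigned_leaves:
            raise PhenoboxError("leaf_count inconsistent with assignment totals")


def _name_to_id(class_map: Mapping[int, str]) -> dict[str, int]:
    return {name: cid for cid, name in class_map.items()}


def pixels_per_cm(
    calibration_boxes: Sequence[NormalizedBox],
    image_height_px: int,
    board_height_cm: float = 1.0,
    source: str = "",
) -> ScaleFactor:
    """Scale conversion from the calibration board.

    Hs = max(normalized box height) * image height in pixels;
    r = Hs / board height in cm.  The tallest calibration box wins, which
    guards against partial detections of the board.
    """
    if not calibration_boxes:
        raise MissingCalibrationError("no calibration-board box in the image")
    if board_height_cm <= 0:
        raise ConfigError("board height must be positive")
    h_max = max(b.h for b in calibration_boxes)
    if h_max <= 0:
        raise DegenerateBoxError("calibration box has zero height")
    hs_px = h_max * image_height_px
    return ScaleFactor(r=hs_px / board_height_cm, source=source)


def estimate_plant_height(
    height_boxes: Sequence[NormalizedBox],
    scale: ScaleFactor,
    image_height_px: int,
) -> float:
    """Physical plant height PH (cm) from the tallest stem box: PH = Hp / r."""
    if not height_boxes:
        raise MissingTraitError("no height-class (stem) box in the image")
    hp_px = max(b.h for b in height_boxes) * image_height_px
    return hp_px / scale.r


def associate_leaves(
    petiole_boxes: Sequence[NormalizedBox],
    leaf_boxes: Sequence[NormalizedBox],
    rule: AssociationRule = AssociationRule(),
    image_dims: tuple[int, int] = (1, 1),
) -> list[int | None]:
    """Assign each leaf to a petiole (by index) or to None.

    A leaf is eligible for a petiole when its center lies inside the
    petiole's margin-expanded pixel rectangle; among eligible petioles the
    one with the nearest center wins, ties broken by lower index.  Each leaf
    is assigned at most once, so assigned + unassigned = total leaves.
    """
    W, H = image_dims
    pet_rects = []
    pet_centers = []
    for p in petiole_boxes:
        pb = to_pixel_box(p, W, H)
        mx, my = rule.margin_frac * pb.width, rule.margin_frac * pb.height
        pet_rects.append((pb.x_min - mx, pb.y_min - my, pb.x_max + mx, pb.y_max + my))
        pet_centers.append(pb.center)

    assignment: list[int | None] = []
    for leaf in leaf_boxes:
        cx, cy = to_pixel_box(leaf, W, H).center
        candidates = [
            j
            for j, (x0, y0, x1, y1) in enumerate(pet_rects)
            if x0 <= cx <= x1 and y0 <= cy <= y1
        ]
        if not candidates:
            assignment.append(None)
        elif len(candidates) == 1:
            assignment.append(candidates[0])
        else:
            dists = [np.hypot(cx - pet_centers[j][0], cy - pet_centers[j][1]) for j in candidates]
            assignment.append(candidates[int(np.argmin(dists))])
    return assignment


def extract_traits(
    image: LabeledImage,
    class_map: Mapping[int, str] = DEFAULT_CLASS_MAP,
    rule: AssociationRule = AssociationRule(),
    scale: ScaleFactor | None = None,
    board_height_cm: float = 1.0,
    treatment: str | None = None,
) -> TraitRecord:
    """Full per-plant phenotype from one labeled image.

    Composes the scale conversion, stem-height estimation and petiole-leaf
    association.  An externally supplied ``scale`` bypasses the need for a
    calibration box in this image.
    """
    ids = _name_to_id(class_map)
    if scale is None:
        cal = image.boxes_of(ids["calibration"]) if "calibration" in ids else []
        scale = pixels_per_cm(cal, image.height_px, board_height_cm, source=image.image_id)
    height_cm = estimate_plant_height(image.boxes_of(ids["height"]), scale, image.height_px)

    petioles = image.boxes_of(ids["petiole"])
    leaves = image.boxes_of(ids["leaf"])
    assignment = associate_leaves(
        petioles, leaves, rule, image_dims=(image.width_px, image.height_px)
    )
    per_petiole = [0] * len(petioles)
    unassigned = 0
    for a in assignment:
        if a is None:
            unassigned += 1
        else:
            per_petiole[a] += 1
    return TraitRecord(
        plant_id=image.image_id,
        treatment=treatment,
        height_cm=height_cm,
        petiole_count=len(petioles),
        leaf_count=len(leaves),
        leaves_per_petiole=per_petiole,
        unassigned_leaves=unassigned,
    )


def relative_error(measured: float, predicted: float) -> float:
    """Per-sample relative error in percent, reported to one decimal.

    100 * |predicted - measured| / measured, with the manual measurement as
    the denominator (the convention consistent with the petiole-count error
    column of the reference comparison table).
    """
    if measured <= 0:
        raise ConfigError(f"measured value must be positive, got {measured}")
    return round(100.0 * abs(predicted - measured) / measured, 1)


def traits_table(records: Sequence[TraitRecord]) -> pd.DataFrame:
    """Flatten trait records into the traits CSV layout."""
    return pd.DataFrame(
        {
            "plant_id": [r.plant_id for r in records],
            "treatment": [r.treatment for r in records],
            "height_cm": [r.height_cm for r in records],
            "petiole_count": [r.petiole_count for r in records],
            "leaf_count": [r.leaf_count for r in records],
            "unassigned_leaves": [r.unassigned_leaves for r in records],
        }
    )


def extract_cohort_traits(
    cohort,
    noise=None,
    seed: int = 0,
    rule: AssociationRule = AssociationRule(),
) -> pd.DataFrame:
    """Traits table for a synthetic cohort, optionally through detector noise.

    With a noise spec, each scene is corrupted into detections first, so the
    resulting traits carry realistic measurement error; scenes whose stem or
    calibration box was dropped by the noise cannot be measured and are
    skipped (a "skipped" attribute on the returned frame counts them).
    """
    from .scenes import corrupt_detections  # deferred: scenes imports annotations only

    records = []
    skipped = 0
    for i, s in enumerate(cohort):
        image = s.image
        if noise is not None:
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(7, i))
            image = corrupt_detections(image, noise, np.random.default_rng(ss))
        try:
            records.append(extract_traits(image, rule=rule, treatment=s.treatment))
        except (MissingCalibrationError, MissingTraitError):
            skipped += 1
    table = traits_table(records)
    table.attrs["skipped"] = skipped
    return table
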