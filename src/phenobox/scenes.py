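"""Synthetic labeled plant scenes with known ground truth.

Each scene is a box-level abstraction of a side-view image of a potted
tomato plant: one vertical stem box (the "height" class), petiole boxes
attached alternately left/right along the stem, 1-3 leaf boxes per petiole,
and one calibration board of exactly 1.0 cm physical height standing next to
the plant.  No raster image is rendered - the detector itself is out of
scope - but the boxes carry the full geometry that the trait-extraction
stage consumes, so every downstream computation can be tested against the
generator's ground truth.

Three water treatments are modeled: CK (well-watered, 90-100% of field
capacity), W1 (70-80%) and W2 (50-60%).  Stress shortens the plant and
reduces the petiole count; the default treatment parameters produce the
strong between-group effects (Cohen's d > 0.8) that motivate using these
two traits as stress indicators.

A separate noise model corrupts a ground-truth scene into plausible
detector output: positional/size jitter, dropped boxes, spurious boxes,
leaf/petiole label confusion, and confidence scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import LabeledImage, NormalizedBox, write_label_file
from .errors import ConfigError, SceneFitError

# geometry constants, in centimeters
_STEM_WIDTH_CM = 0.8
_PETIOLE_LENGTH_CM = 3.0
_PETIOLE_HEIGHT_CM = 0.8
_LEAF_WIDTH_CM = 1.5
_LEAF_HEIGHT_CM = 1.2
_BOARD_HEIGHT_CM = 1.0
_GROUND_FRAC = 0.95  # vertical position of the "ground" line in the frame

_LEAF_ID = 0
_PETIOLE_ID = 1
_HEIGHT_ID = 2
_CALIBRATION_ID = 3

DEFAULT_IMAGE_DIMS = (960, 1280)  # (width_px, height_px)
PIXELS_PER_CM_RANGE = (8.0, 20.0)


@dataclass(frozen=True)
class TreatmentSpec:
    """Trait distribution of one water treatment."""

    name: str
    height_mean_cm: float
    height_sd_cm: float
    petiole_count_range: tuple[int, int]
    leaves_per_petiole_range: tuple[int, int] = (1, 3)

    def __post_init__(self):
        if self.height_mean_cm <= 0 or self.height_sd_cm < 0:
            raise ConfigError("height parameters must be positive")
        for lo, hi in (self.petiole_count_range, self.leaves_per_petiole_range):
            if lo > hi or lo < 0:
                raise ConfigError(f"empty or negative range ({lo}, {hi})")


def default_treatments() -> dict[str, TreatmentSpec]:
    """The three water-stress conditions (CK well-watered, W1 moderate, W2 severe)."""
    return {
        "CK": TreatmentSpec("CK", 33.0, 3.0, (9, 11)),
        "W1": TreatmentSpec("W1", 27.0, 3.0, (7, 9)),
        "W2": TreatmentSpec("W2", 22.0, 3.0, (5, 7)),
    }


@dataclass(frozen=True)
class PetioleTruth:
    """One petiole box and the leaf boxes attached to it."""

    box: NormalizedBox
    leaves: tuple[NormalizedBox, ...]


@dataclass(frozen=True)
class SceneTruth:
    """Generator-side ground truth for one scene."""

    plant_height_cm: float
    pixels_per_cm: float
    stem_box: NormalizedBox
    calibration_box: NormalizedBox
    petioles: tuple[PetioleTruth, ...]
    treatment: str

    @property
    def petiole_count(self) -> int:
        return len(self.petioles)

    @property
    def leaf_count(self) -> int:
        return sum(len(p.leaves) for p in self.petioles)

    @property
    def leaves_per_petiole(self) -> list[int]:
        return [len(p.leaves) for p in self.petioles]


@dataclass(frozen=True)
class NoiseSpec:
    """Detector error model applied to a ground-truth scene.

    ``jitter_sd`` perturbs box centers and sizes as a fraction of each box's
    own extent; ``drop_prob`` omits true boxes; ``spurious_rate`` is the
    expected number of false boxes per scene (Poisson); ``confusion_prob``
    swaps leaf/petiole labels, emulating the morphological confusion between
    those two classes.  True boxes receive higher confidences than spurious
    ones; a null spec reproduces the input with confidence 1.
    """

    jitter_sd: float = 0.0
    drop_prob: float = 0.0
    spurious_rate: float = 0.0
    confusion_prob: float = 0.0

    def __post_init__(self):
        for name in ("drop_prob", "confusion_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} outside [0,1]: {v}")
        if self.jitter_sd < 0 or self.spurious_rate < 0:
            raise ConfigError("jitter_sd and spurious_rate must be non-negative")

    @property
    def is_null(self) -> bool:
        return (
            self.jitter_sd == 0
            and self.drop_prob == 0
            and self.spurious_rate == 0
            and self.confusion_prob == 0
        )

    @classmethod
    def default(cls) -> "NoiseSpec":
        """A moderate, realistic detector-error level."""
        return cls(jitter_sd=0.05, drop_prob=0.05, spurious_rate=1.0, confusion_prob=0.05)


def _norm_box(class_id, x0, y0, x1, y1, W, H):
    return NormalizedBox(
        class_id=class_id,
        cx=(x0 + x1) / 2 / W,
        cy=(y0 + y1) / 2 / H,
        w=(x1 - x0) / W,
        h=(y1 - y0) / H,
    )


def generate_scene(
    spec: TreatmentSpec,
    image_dims: tuple[int, int] = DEFAULT_IMAGE_DIMS,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    image_id: str = "scene",
    max_retries: int = 50,
) -> tuple[LabeledImage, SceneTruth]:
    """Sample one plant scene with exact construction identities.

    The calibration box's pixel height is exactly ``pixels_per_cm * 1.0``
    and the stem box's pixel height exactly ``plant_height_cm *
    pixels_per_cm``, so trait extraction on the uncorrupted scene recovers
    the truth to floating-point precision.  Petioles sit at distinct heights
    along the stem with enough vertical separation that every leaf center
    lies inside exactly one petiole's association rectangle.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W, H = image_dims
    if W <= 0 or H <= 0:
        raise ConfigError("image dimensions must be positive")

    for _ in range(max_retries):
        ppcm = rng.uniform(*PIXELS_PER_CM_RANGE)
        height_cm = rng.normal(spec.height_mean_cm, spec.height_sd_cm)
        n_pet = int(rng.integers(spec.petiole_count_range[0], spec.petiole_count_range[1] + 1))
        if height_cm < 5.0:
            continue
        stem_px = height_cm * ppcm
        if stem_px > 0.85 * H:
            continue
        # petioles occupy 20%..90% of the stem; require >= 1 cm of vertical
        # separation so association rectangles never capture a foreign leaf
        span_cm = 0.7 * height_cm
        if n_pet > 1 and span_cm / (n_pet - 1) < 1.0:
            continue
        break
    else:
        raise SceneFitError(
            f"could not fit a {spec.name} plant in a {W}x{H} frame after {max_retries} tries"
        )

    y_base = _GROUND_FRAC * H
    cx_stem = 0.5 * W

    stem_box = _norm_box(
        _HEIGHT_ID,
        cx_stem - _STEM_WIDTH_CM * ppcm / 2,
        y_base - stem_px,
        cx_stem + _STEM_WIDTH_CM * ppcm / 2,
        y_base,
        W,
        H,
    )
    board_px = _BOARD_HEIGHT_CM * ppcm
    cal_box = _norm_box(
        _CALIBRATION_ID,
        0.10 * W - board_px / 2,
        y_base - board_px,
        0.10 * W + board_px / 2,
        y_base,
        W,
        H,
    )

    if n_pet == 1:
        fractions = [0.55]
    else:
        fractions = list(np.linspace(0.2, 0.9, n_pet))

    petioles: list[PetioleTruth] = []
    for j, f in enumerate(fractions):
        side = 1 if j % 2 == 0 else -1
        y_c = y_base - f * stem_px
        half_h = _PETIOLE_HEIGHT_CM * ppcm / 2
        if side > 0:
            x0, x1 = cx_stem, cx_stem + _PETIOLE_LENGTH_CM * ppcm
        else:
            x0, x1 = cx_stem - _PETIOLE_LENGTH_CM * ppcm, cx_stem
        pet_box = _norm_box(_PETIOLE_ID, x0, y_c - half_h, x1, y_c + half_h, W, H)

        lo, hi = spec.leaves_per_petiole_range
        k = int(rng.integers(lo, hi + 1))
        leaves = []
        for i in range(k):
            # leaf centers along the outer part of the petiole, away from the
            # stem column shared by both sides, in disjoint slots
            u = 0.2 + 0.6 * (i + rng.uniform(0.15, 0.85)) / max(k, 1)
            x_leaf = cx_stem + side * u * _PETIOLE_LENGTH_CM * ppcm
            y_leaf = y_c + rng.uniform(-0.25, 0.25) * _PETIOLE_HEIGHT_CM * ppcm
            leaves.append(
                _norm_box(
                    _LEAF_ID,
                    x_leaf - _LEAF_WIDTH_CM * ppcm / 2,
                    y_leaf - _LEAF_HEIGHT_CM * ppcm / 2,
                    x_leaf + _LEAF_WIDTH_CM * ppcm / 2,
                    y_leaf + _LEAF_HEIGHT_CM * ppcm / 2,
                    W,
                    H,
                )
            )
        petioles.append(PetioleTruth(box=pet_box, leaves=tuple(leaves)))

    boxes = [cal_box, stem_box]
    for p in petioles:
        boxes.append(p.box)
        boxes.extend(p.leaves)
    image = LabeledImage(image_id=image_id, width_px=W, height_px=H, boxes=boxes)
    truth = SceneTruth(
        plant_height_cm=height_cm,
        pixels_per_cm=ppcm,
        stem_box=stem_box,
        calibration_box=cal_box,
        petioles=tuple(petioles),
        treatment=spec.name,
    )
    return image, truth


def corrupt_detections(
    scene: LabeledImage,
    noise: NoiseSpec,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> LabeledImage:
    """Turn ground-truth boxes into noisy 'detections' with confidences."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise.is_null:
        out = [replace(b, confidence=1.0) for b in scene.boxes]
        return LabeledImage(scene.image_id, scene.width_px, scene.height_px, out)

    out = []
    for b in scene.boxes:
        if rng.random() < noise.drop_prob:
            continue
        class_id = b.class_id
        if class_id in (_LEAF_ID, _PETIOLE_ID) and rng.random() < noise.confusion_prob:
            class_id = _PETIOLE_ID if class_id == _LEAF_ID else _LEAF_ID
        cx = b.cx + rng.normal(0, noise.jitter_sd) * b.w
        cy = b.cy + rng.normal(0, noise.jitter_sd) * b.h
        w = max(b.w * (1 + rng.normal(0, noise.jitter_sd)), 1e-4)
        h = max(b.h * (1 + rng.normal(0, noise.jitter_sd)), 1e-4)
        conf = rng.uniform(0.55, 0.99)
        box = NormalizedBox(class_id, float(cx), float(cy), float(w), float(h), confidence=conf)
        out.append(box.clipped())

    n_spurious = rng.poisson(noise.spurious_rate)
    for _ in range(n_spurious):
        class_id = int(rng.choice([_LEAF_ID, _PETIOLE_ID]))
        out.append(
            NormalizedBox(
                class_id,
                cx=float(rng.uniform(0.1, 0.9)),
                cy=float(rng.uniform(0.1, 0.9)),
                w=float(rng.uniform(0.02, 0.08)),
                h=float(rng.uniform(0.02, 0.08)),
                confidence=float(rng.uniform(0.05, 0.5)),
            )
        )
    return LabeledImage(scene.image_id, scene.width_px, scene.height_px, out)


@dataclass(frozen=True)
class CohortScene:
    image: LabeledImage
    truth: SceneTruth
    treatment: str


def generate_cohort(
    specs: Sequence[TreatmentSpec],
    n_per_treatment: int,
    seed: int = 0,
    image_dims: tuple[int, int] = DEFAULT_IMAGE_DIMS,
) -> list[CohortScene]:
    """Generate ``n_per_treatment`` scenes for each treatment.

    Per-scene generators are derived from the master seed with a
    counter-based spawn key, so the cohort is reproducible and each scene is
    independent of generation order.
    """
    if n_per_treatment < 1:
        raise ConfigError("n_per_treatment must be >= 1")
    scenes: list[CohortScene] = []
    for t_idx, spec in enumerate(specs):
        for i in range(n_per_treatment):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(t_idx, i))
            rng = np.random.default_rng(ss)
            image_id = f"{spec.name}_{i:04d}"
            image, truth = generate_scene(spec, image_dims, rng, image_id=image_id)
            scenes.append(CohortScene(image=image, truth=truth, treatment=spec.name))
    return scenes


def cohort_manifest(scenes: Sequence[CohortScene]) -> pd.DataFrame:
    """Tabular ground truth for a cohort (one row per scene)."""
    rows = []
    for s in scenes:
        rows.append(
            {
                "image_id": s.image.image_id,
                "treatment": s.treatment,
                "width_px": s.image.width_px,
                "height_px": s.image.height_px,
                "true_height_cm": s.truth.plant_height_cm,
                "pixels_per_cm": s.truth.pixels_per_cm,
                "petiole_count": s.truth.petiole_count,
                "leaf_count": s.truth.leaf_count,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(
    scenes: Sequence[CohortScene],
    out_dir: str | Path,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write YOLO label files (plus optional noisy detections) and a manifest CSV."""
    out = Path(out_dir)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    if noise is not None:
        (out / "detections").mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(scenes):
        (out / "labels" / f"{s.image.image_id}.txt").write_text(write_label_file(s.image.boxes))
        if noise is not None:
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(1, i))
            det = corrupt_detections(s.image, noise, np.random.default_rng(ss))
            (out / "detections" / f"{s.image.image_id}.txt").write_text(
                write_label_file(det.boxes)
            )
    manifest = cohort_manifest(scenes)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
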