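"""Synthetic phantoms and planted-structure slice tasks.

Two generators make every stage of the framework testable without any
external imaging data:

* :func:`make_phantom_cohort` builds miniature multi-modality brain
  volumes — Gaussian background plus a nested ellipsoidal lesion whose
  shells carry the segmentation labels 1 (necrotic core), 4 (enhancing
  rim) and 2 (edema) — with a grade-dependent lesion intensity so HGG
  and LGG phantoms are actually distinguishable from their slices.

* :func:`make_slice_task` builds a flat 2D classification task with a
  planted informativeness structure: a majority of "normal" samples from
  two separated class prototypes, a low-information "duplicate"
  subpopulation of near-copies of an archetypally easy class exemplar,
  and an "outlier" subpopulation of mislabeled samples whose class
  signal is attenuated to the point that pixel noise dominates the image
  — the easy and pathological tails an uncertainty ranking should push
  to opposite ends.

All randomness flows from the spec seed through per-patient/per-stage
``SeedSequence`` spawn keys, so regenerating a subset is stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pipeline import MODALITIES, PatientVolume, SliceDataset

#: per-pixel noise standard deviation of the slice task; class_sep is in these units
TASK_NOISE_SD = 1.0
#: outliers keep only this fraction of their class signal (noise then dominates)
OUTLIER_SIGNAL_SCALE = 0.5
#: duplicates copy an exaggerated, archetypally easy class exemplar
DUPLICATE_PROTOTYPE_SCALE = 1.8
DUPLICATE_NOISE_SD = 0.05

_MODALITY_FACTOR = {"T1": 0.5, "T1C": 1.5, "T2": 1.0, "FLAIR": 1.0}
_BASE_LEVEL = {"T1": 0.40, "T1C": 0.45, "T2": 0.50, "FLAIR": 0.50}
_GRADE_FACTOR = {"HGG": 1.0, "LGG": 0.4}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a phantom volumetric cohort."""

    n_hgg: int
    n_lgg: int
    shape: tuple[int, int, int] = (12, 12, 34)
    min_tumor_planes: int = 30
    intensity_contrast: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hgg < 0 or self.n_lgg < 0 or self.n_hgg + self.n_lgg == 0:
            raise ValidationError("need at least one patient")
        if len(self.shape) != 3 or any(s < 3 for s in self.shape):
            raise ValidationError(f"shape must be 3 dims of >= 3 voxels, got {self.shape}")
        if self.min_tumor_planes < 1 or self.min_tumor_planes > self.shape[2]:
            raise ValidationError(
                f"min_tumor_planes {self.min_tumor_planes} must be in [1, Z={self.shape[2]}]"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SliceTaskSpec:
    """Parameters of a planted-structure 2D slice task."""

    n: int = 400
    image_side: int = 8
    class_sep: float = 5.0
    outlier_frac: float = 0.10
    duplicate_frac: float = 0.10
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValidationError(f"n must be >= 10, got {self.n}")
        if self.image_side < 2:
            raise ValidationError("image_side must be >= 2")
        if self.class_sep < 0:
            raise ValidationError("class_sep must be >= 0")
        for name, f in (("outlier_frac", self.outlier_frac), ("duplicate_frac", self.duplicate_frac)):
            if not 0.0 <= f < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {f}")
        if self.outlier_frac + self.duplicate_frac >= 1.0:
            raise ValidationError("outlier_frac + duplicate_frac must be < 1")
        if not 0.0 < self.class_balance < 1.0:
            raise ValidationError("class_balance must be in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(math.floor(round(x, 9) + 0.5))


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# phantom volumes


def make_phantom_cohort(spec: PhantomSpec) -> list[PatientVolume]:
    """Generate ``n_hgg + n_lgg`` phantom patients, HGG first.

    Each lesion is an axis-aligned ellipsoid at an integer center; its
    axial half-span ``rz`` guarantees at least ``min_tumor_planes``
    tumor-bearing planes (the center column keeps every spanned plane
    non-empty). Raises if the requested span cannot fit in ``shape``.
    """
    x, y, z = spec.shape
    rz = (spec.min_tumor_planes - 1 + 1) // 2 + 1  # ceil((min-1)/2) + 1 margin
    if 2 * rz + 1 > z:
        raise ValidationError(
            f"lesion spanning {2 * rz + 1} planes cannot fit in Z={z}; "
            f"reduce min_tumor_planes or enlarge shape"
        )
    rx, ry = max(1.0, 0.38 * x), max(1.0, 0.38 * y)
    cohort: list[PatientVolume] = []
    grades = ["HGG"] * spec.n_hgg + ["LGG"] * spec.n_lgg
    for idx, grade in enumerate(grades):
        rng = _child_rng(spec.seed, idx)
        cx, cy = x // 2, y // 2
        lo, hi = rz, z - 1 - rz
        cz = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        xx, yy, zz = np.meshgrid(np.arange(x), np.arange(y), np.arange(z), indexing="ij")
        r = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2)
        seg = np.zeros(spec.shape, dtype=np.int16)
        seg[r <= 1.0] = 2          # edema (outermost shell)
        seg[r <= 0.7] = 4          # enhancing rim
        seg[r <= 0.35] = 1         # necrotic core
        lesion = r <= 1.0
        modalities = {}
        for m in MODALITIES:
            vol = _BASE_LEVEL[m] + rng.normal(0.0, spec.noise_sd, size=spec.shape)
            vol[lesion] += spec.intensity_contrast * _GRADE_FACTOR[grade] * _MODALITY_FACTOR[m]
            modalities[m] = np.clip(vol, 0.0, None).astype(np.float32)
        cohort.append(PatientVolume(f"P{idx:03d}", modalities, seg, grade))
    return cohort


# ---------------------------------------------------------------------------
# planted-structure slice task


def make_slice_task(spec: SliceTaskSpec) -> SliceDataset:
    """Generate a tagged 2D slice task with planted easy and outlier tails.

    The manifest carries ``tag`` in {normal, duplicate, outlier} alongside
    label and a stratified 70/15/15 train/val/test split. Tag counts are
    round-half-up of the spec fractions times ``n``. Duplicates and
    outliers are planted in the train split only, so held-out metrics
    reflect clean generalization; the spec fractions still refer to the
    full ``n``.
    """
    rng_pattern = _child_rng(spec.seed, 0)
    d = spec.image_side * spec.image_side * 3
    pattern = rng_pattern.normal(size=d)
    pattern /= np.linalg.norm(pattern)

    n = spec.n
    n_pos = _round_half_up(spec.class_balance * n)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng_assign = _child_rng(spec.seed, 1)
    rng_assign.shuffle(labels)

    # stratified split by class, largest-remainder on (0.70, 0.15, 0.15)
    split = np.empty(n, dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng_assign.shuffle(idx)
        quotas = np.array([0.70, 0.15, 0.15]) * len(idx)
        counts = np.floor(quotas).astype(int)
        for j in np.argsort(-(quotas - counts), kind="stable")[: len(idx) - counts.sum()]:
            counts[j] += 1
        start = 0
        for name, c in zip(("train", "val", "test"), counts):
            split[idx[start:start + c]] = name
            start += c

    n_out = _round_half_up(spec.outlier_frac * n)
    n_dup = _round_half_up(spec.duplicate_frac * n)
    train_idx = np.flatnonzero(split == "train")
    if n_out + n_dup > len(train_idx):
        raise ValidationError(
            f"{n_out} outliers + {n_dup} duplicates exceed the train split ({len(train_idx)} samples)"
        )
    special = rng_assign.choice(train_idx, size=n_out + n_dup, replace=False)
    tags = np.full(n, "normal", dtype=object)
    tags[special[:n_out]] = "outlier"
    tags[special[n_out:]] = "duplicate"

    def prototype(cls: int) -> np.ndarray:
        sign = 1.0 if cls == 1 else -1.0
        return sign * (spec.class_sep / 2.0) * pattern

    images = np.empty((n, spec.image_side, spec.image_side, 3), dtype=np.float32)
    emitted = labels.copy()
    for i in range(n):
        rng = _child_rng(spec.seed, 2, i)
        y = int(labels[i])
        if tags[i] == "duplicate":
            x = DUPLICATE_PROTOTYPE_SCALE * prototype(y) + rng.normal(0.0, DUPLICATE_NOISE_SD, size=d)
        elif tags[i] == "outlier":
            # noise-dominated image, wrong label: the class signal is
            # attenuated below the noise floor and the emitted label flipped
            x = OUTLIER_SIGNAL_SCALE * prototype(y) + rng.normal(0.0, TASK_NOISE_SD, size=d)
            emitted[i] = 1 - y
        else:
            x = prototype(y) + rng.normal(0.0, TASK_NOISE_SD, size=d)
        images[i] = x.reshape(spec.image_side, spec.image_side, 3)

    manifest = pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n)],
            "patient_id": [f"s{i:04d}" for i in range(n)],
            "z_index": np.zeros(n, dtype=int),
            "label": emitted,
            "split": split,
            "tag": tags,
        }
    )
    return SliceDataset(images, manifest)
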