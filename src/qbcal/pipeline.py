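"""Volumetric patient records to labeled 2D slice datasets.

Mirrors the BRATS-style preparation used for glioma grade classification:
each patient carries four co-registered MRI modalities (T1, T1C, T2,
FLAIR) plus a voxel-wise segmentation with labels {0, 1, 2, 4} (0 =
background; any non-zero label is tumor tissue). From each patient, k
axial planes containing tumor are sampled, the T1/T1C/T2 channels are
stacked into a 3-channel image, min-max normalized per channel, and
resized. HGG patients label their slices 1, LGG patients 0. Dataset
splits are assigned at the patient level (never the slice level) so that
no patient leaks across train/val/test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
from skimage.transform import resize

from .errors import ValidationError

MODALITIES = ("T1", "T1C", "T2", "FLAIR")
#: modalities stacked into slice channels, in channel order
SLICE_CHANNELS = ("T1", "T1C", "T2")
SEGMENTATION_LABELS = frozenset({0, 1, 2, 4})
TUMOR_LABELS = frozenset({1, 2, 4})
GRADES = ("HGG", "LGG")
GRADE_TO_LABEL = {"HGG": 1, "LGG": 0}
SPLITS = ("train", "val", "test")


@dataclass
class PatientVolume:
    """One patient's co-registered modality volumes, segmentation and grade."""

    patient_id: str
    modalities: Mapping[str, np.ndarray]
    segmentation: np.ndarray
    grade: str

    def __post_init__(self) -> None:
        self.grade = self.grade.upper()
        if self.grade not in GRADES:
            raise ValidationError(f"patient {self.patient_id!r}: grade must be HGG or LGG, got {self.grade!r}")
        missing = [m for m in MODALITIES if m not in self.modalities]
        if missing:
            raise ValidationError(f"patient {self.patient_id!r}: missing modalities {missing}")
        shapes = {m: np.asarray(self.modalities[m]).shape for m in MODALITIES}
        shapes["segmentation"] = np.asarray(self.segmentation).shape
        if len(set(shapes.values())) != 1:
            raise ValidationError(f"patient {self.patient_id!r}: arrays not co-registered: {shapes}")
        seg_vals = set(np.unique(np.asarray(self.segmentation)).astype(int).tolist())
        if not seg_vals <= SEGMENTATION_LABELS:
            raise ValidationError(
                f"patient {self.patient_id!r}: segmentation labels {sorted(seg_vals - SEGMENTATION_LABELS)} "
                f"outside {sorted(SEGMENTATION_LABELS)}"
            )

    @property
    def label(self) -> int:
        return GRADE_TO_LABEL[self.grade]


@dataclass
class SliceRecord:
    """A labeled 3-channel axial slice with its provenance."""

    patient_id: str
    z_index: int
    image: np.ndarray  # (S, S, 3), channels T1, T1C, T2
    label: int
    split: str | None = None

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}:z{self.z_index:03d}"


@dataclass
class SliceDataset:
    """Image stack plus manifest; the in-memory unit the classifiers consume.

    ``images`` is (N, S, S, C) float32; ``manifest`` has one row per image
    with at least ``sample_id``, ``patient_id``, ``z_index``, ``label``,
    ``split`` (label/split may be absent for unlabeled pools).
    """

    images: np.ndarray
    manifest: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 4:
            raise ValidationError(f"images must be (N, S, S, C), got shape {self.images.shape}")
        if len(self.manifest) != self.images.shape[0]:
            raise ValidationError(
                f"manifest has {len(self.manifest)} rows for {self.images.shape[0]} images"
            )
        if "sample_id" not in self.manifest.columns:
            raise ValidationError("manifest must contain a sample_id column")
        if self.manifest["sample_id"].duplicated().any():
            raise ValidationError("manifest sample_ids not unique")
        self.manifest = self.manifest.reset_index(drop=True)

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return self.manifest["sample_id"].astype(str).tolist()

    @property
    def labels(self) -> np.ndarray:
        if "label" not in self.manifest.columns:
            raise ValidationError("dataset has no labels")
        return self.manifest["label"].to_numpy(dtype=int)

    def features(self) -> np.ndarray:
        """Flattened pixel matrix (N, S*S*C), the classifier input."""
        return self.images.reshape(len(self), -1).astype(np.float64)

    def subset(self, sample_ids: Sequence[str]) -> "SliceDataset":
        """Rows for the given ids, in the given order."""
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample_ids (first few): {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return SliceDataset(self.images[rows], self.manifest.iloc[rows].reset_index(drop=True))

    def split_subset(self, split: str) -> "SliceDataset":
        mask = (self.manifest["split"] == split).to_numpy()
        if not mask.any():
            raise ValidationError(f"no samples in split {split!r}")
        return SliceDataset(self.images[mask], self.manifest.loc[mask].reset_index(drop=True))

    def without_labels(self) -> "SliceDataset":
        """Copy with the label column dropped (forward-pass pools need none)."""
        return SliceDataset(self.images.copy(), self.manifest.drop(columns=["label"], errors="ignore").copy())


# ---------------------------------------------------------------------------
# slice extraction


def find_tumor_slices(segmentation: np.ndarray) -> list[int]:
    """Ascending axial (third-axis) indices of planes containing tumor.

    A plane qualifies if any voxel carries a label in {1, 2, 4}.
    """
    seg = np.asarray(segmentation)
    vals = set(np.unique(seg).astype(int).tolist())
    if not vals <= SEGMENTATION_LABELS:
        raise ValidationError(f"segmentation labels {sorted(vals - SEGMENTATION_LABELS)} outside {{0,1,2,4}}")
    has_tumor = np.any(seg > 0, axis=(0, 1))
    return [int(z) for z in np.nonzero(has_tumor)[0]]


def _normalize_channel(plane: np.ndarray) -> np.ndarray:
    lo, hi = float(plane.min()), float(plane.max())
    if hi == lo:
        return np.zeros_like(plane, dtype=np.float64)
    return (plane.astype(np.float64) - lo) / (hi - lo)


def extract_patient_slices(
    patient: PatientVolume,
    k: int,
    target_size: int,
    seed: int,
    strict: bool = True,
) -> list[SliceRecord]:
    """Sample k tumor-bearing axial slices from one patient.

    Each slice stacks the T1, T1C, T2 planes (in that order), min-max
    normalizes each channel to [0, 1], and bilinearly resizes to
    ``target_size`` squared. In strict mode a patient with fewer than k
    tumor planes is an error; in permissive mode all available planes are
    taken with a warning.
    """
    if k < 1:
        raise ValidationError(f"k must be positive, got {k}")
    zs = find_tumor_slices(patient.segmentation)
    if len(zs) < k:
        msg = f"patient {patient.patient_id!r}: only {len(zs)} tumor planes for k={k}"
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg + "; taking all available", stacklevel=2)
        chosen = list(zs)
    else:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(zs, size=k, replace=False).tolist())
    records = []
    for z in chosen:
        channels = [_normalize_channel(np.asarray(patient.modalities[m])[:, :, z]) for m in SLICE_CHANNELS]
        img = np.stack(channels, axis=-1)
        if img.shape[0] != target_size or img.shape[1] != target_size:
            img = resize(img, (target_size, target_size, img.shape[2]),
                         order=1, anti_aliasing=False, preserve_range=True)
        records.append(SliceRecord(patient.patient_id, int(z), img.astype(np.float32), patient.label))
    return records


def build_dataset(
    cohort: Sequence[PatientVolume],
    k_hgg: int,
    k_lgg: int,
    target_size: int,
    seed: int,
    split_assignment: Mapping[str, str] | None = None,
    strict: bool = True,
) -> tuple[SliceDataset, pd.DataFrame]:
    """Concatenate per-patient slice extraction over a cohort.

    HGG patients contribute ``k_hgg`` slices each and LGG patients
    ``k_lgg`` (20/20 reproduces the imbalanced design; 10/30 the balanced
    one). Returns the dataset plus a manifest summary-checked copy. Each
    patient draws from its own seed stream, so adding patients does not
    reshuffle earlier ones.
    """
    if not cohort:
        raise ValidationError("build_dataset: empty cohort")
    records: list[SliceRecord] = []
    for i, patient in enumerate(cohort):
        child_seed = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        k = k_hgg if patient.grade == "HGG" else k_lgg
        recs = extract_patient_slices(patient, k, target_size, child_seed, strict=strict)
        if split_assignment is not None:
            split = split_assignment.get(patient.patient_id)
            for r in recs:
                r.split = split
        records.extend(recs)
    images = np.stack([r.image for r in records])
    manifest = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "z_index": [r.z_index for r in records],
            "label": [r.label for r in records],
            "split": [r.split for r in records],
        }
    )
    dataset = SliceDataset(images, manifest)
    return dataset, manifest.copy()


def _largest_remainder(total: int, shares: Sequence[float]) -> list[int]:
    """Integer apportionment of ``total`` by quotas; ties to earlier entries."""
    quotas = np.array([total * s for s in shares], dtype=float)
    base = np.floor(quotas).astype(int)
    leftover = total - int(base.sum())
    if leftover:
        order = np.argsort(-(quotas - base), kind="stable")
        for j in order[:leftover]:
            base[j] += 1
    return base.tolist()


def split_patients(
    cohort: Sequence[PatientVolume],
    sizes: tuple[int, int, int],
    seed: int,
) -> dict[str, str]:
    """Patient-level stratified train/val/test partition.

    Each split receives HGG and LGG counts by largest-remainder
    apportionment of its share of each grade, so all splits carry the
    cohort's grade ratio as closely as integers allow. Assignment within
    a grade is a seeded uniform shuffle.
    """
    n = len(cohort)
    if sum(sizes) != n:
        raise ValidationError(f"split sizes {sizes} sum to {sum(sizes)}, cohort has {n} patients")
    shares = [s / n for s in sizes]
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for grade in GRADES:
        ids = [p.patient_id for p in cohort if p.grade == grade]
        counts = _largest_remainder(len(ids), shares)
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        start = 0
        for split, c in zip(SPLITS, counts):
            for pid in shuffled[start:start + c]:
                assignment[pid] = split
            start += c
    return assignment


# ---------------------------------------------------------------------------
# on-disk formats


def save_cohort_nifti(cohort: Sequence[PatientVolume], out_dir: str | Path) -> Path:
    """Write one NIfTI file per modality + segmentation and a CSV index.

    Returns the path of the index, whose columns are patient_id, grade and
    the five file paths (relative to the index directory).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    affine = np.eye(4)
    for p in cohort:
        row: dict[str, str] = {"patient_id": p.patient_id, "grade": p.grade}
        for m in MODALITIES:
            fname = f"{p.patient_id}_{m.lower()}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(p.modalities[m], dtype=np.float32), affine), out_dir / fname)
            row[m.lower()] = fname
        seg_name = f"{p.patient_id}_seg.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(p.segmentation, dtype=np.int16), affine), out_dir / seg_name)
        row["seg"] = seg_name
        rows.append(row)
    index = out_dir / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def load_cohort_nifti(index_csv: str | Path) -> list[PatientVolume]:
    index_csv = Path(index_csv)
    if not index_csv.exists():
        raise ValidationError(f"cohort index not found: {index_csv}")
    base = index_csv.parent
    df = pd.read_csv(index_csv)
    cohort = []
    for row in df.itertuples():
        modalities = {m: np.asarray(nib.load(base / getattr(row, m.lower())).dataobj, dtype=np.float32)
                      for m in MODALITIES}
        seg = np.asarray(nib.load(base / row.seg).dataobj).astype(np.int16)
        cohort.append(PatientVolume(str(row.patient_id), modalities, seg, str(row.grade)))
    return cohort


def save_slice_dataset(dataset: SliceDataset, h5_path: str | Path, manifest_csv: str | Path | None = None) -> None:
    """HDF5 container (images/labels/ids) plus an optional CSV manifest."""
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("images", data=dataset.images)
        f.create_dataset("sample_ids", data=np.array(dataset.sample_ids, dtype=object), dtype=h5py.string_dtype())
        for col in ("label", "z_index"):
            if col in dataset.manifest.columns:
                f.create_dataset(col + "s", data=dataset.manifest[col].to_numpy(dtype=int))
        for col in ("patient_id", "split", "tag"):
            if col in dataset.manifest.columns:
                f.create_dataset(col + "s", data=np.array(dataset.manifest[col].astype(str), dtype=object),
                                 dtype=h5py.string_dtype())
    if manifest_csv is not None:
        dataset.manifest.to_csv(manifest_csv, index=False)


def load_slice_dataset(h5_path: str | Path) -> SliceDataset:
    h5_path = Path(h5_path)
    if not h5_path.exists():
        raise ValidationError(f"slice dataset not found: {h5_path}")
    with h5py.File(h5_path, "r") as f:
        images = np.asarray(f["images"][...], dtype=np.float32)
        data: dict[str, list] = {
            "sample_id": [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][...]]
        }
        for col in ("label", "z_index"):
            if col + "s" in f:
                data[col] = np.asarray(f[col + "s"][...], dtype=int).tolist()
        for col in ("patient_id", "split", "tag"):
            if col + "s" in f:
                data[col] = [s.decode() if isinstance(s, bytes) else str(s) for s in f[col + "s"][...]]
    return SliceDataset(images, pd.DataFrame(data))
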