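"""Data model and I/O for choroid OCT images, masks, and cohort manifests.

The region of interest throughout this package is the segmented choroid of a
2-D OCT image.  Two modalities are handled:

* ``horizontal`` -- a b-scan (depth x lateral cross-section); rows are the
  depth axis, 0-based, row-major.
* ``enface`` -- a plane parallel to the retinal surface, reconstructed from a
  b-scan volume at a fixed fraction of normalized choroid thickness.

Depth convention: depth fraction 0 is the choroid inner boundary (Bruch's
membrane side) and 1 the choroid-scleral boundary.  Boundary rows are
inclusive: ``outer`` is the last choroid row of a column, so a column with
thickness ``t`` spans rows ``inner .. inner + t - 1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Modality",
    "ImageSample",
    "EyeRecord",
    "CohortDataset",
    "BoundaryPair",
    "ValidationError",
    "build_enface_stack",
    "select_depth_window",
    "load_cohort",
    "save_cohort",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "eye_id",
    "patient_id",
    "group",
    "modality",
    "slice_index",
    "image_path",
    "mask_path",
]


class ValidationError(ValueError):
    """Raised when an image, mask, boundary, or manifest violates an invariant."""


class Group(str, enum.Enum):
    HEALTHY = "healthy"
    CSCR = "cscr"
    FELLOW = "fellow"


class Modality(str, enum.Enum):
    HORIZONTAL = "horizontal"
    ENFACE = "enface"


@dataclass
class ImageSample:
    """One 2-D intensity image with a binary ROI mask and eye-level metadata.

    Parameters
    ----------
    image
        2-D non-negative intensity array on an 8-bit scale.
    mask
        2-D boolean array of the same shape; True marks the choroid ROI.
    depth_fraction
        Normalized choroid depth of an en face slice, in [0, 1]; ``None`` for
        b-scans.
    """

    image: np.ndarray
    mask: np.ndarray
    eye_id: str
    patient_id: str
    group: Group
    modality: Modality
    depth_fraction: float | None = None
    slice_index: int | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.group = Group(self.group)
        self.modality = Modality(self.modality)
        if self.image.ndim != 2:
            raise ValidationError(f"{self.sample_id}: image must be 2-D")
        if self.image.shape != self.mask.shape:
            raise ValidationError(
                f"{self.sample_id}: image shape {self.image.shape} != mask shape "
                f"{self.mask.shape}"
            )
        if (self.modality is Modality.ENFACE) != (self.depth_fraction is not None):
            raise ValidationError(
                f"{self.sample_id}: depth_fraction must be present iff modality is enface"
            )
        if self.depth_fraction is not None and not 0.0 <= self.depth_fraction <= 1.0:
            raise ValidationError(f"{self.sample_id}: depth_fraction outside [0, 1]")

    @property
    def sample_id(self) -> str:
        return f"{self.eye_id}:{self.modality.value}:{self.slice_index}"

    @property
    def roi_pixels(self) -> np.ndarray:
        """Masked pixel values as a flat float array."""
        return self.image[self.mask].astype(float)


@dataclass
class EyeRecord:
    """All samples of one eye, b-scans and en face slices."""

    eye_id: str
    patient_id: str
    group: Group
    horizontal_samples: list[ImageSample] = field(default_factory=list)
    enface_samples: list[ImageSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        for s in self.horizontal_samples + self.enface_samples:
            if (s.eye_id, s.patient_id, s.group) != (self.eye_id, self.patient_id, self.group):
                raise ValidationError(
                    f"sample {s.sample_id} metadata disagrees with eye {self.eye_id}"
                )
        idx = [s.slice_index for s in self.enface_samples]
        if idx != list(range(len(idx))):
            raise ValidationError(
                f"eye {self.eye_id}: enface slice_index must be 0..n-1 without gaps"
            )

    @property
    def n_samples(self) -> int:
        return len(self.horizontal_samples) + len(self.enface_samples)

    def samples(self, modality: Modality | str | None = None) -> list[ImageSample]:
        if modality is None:
            return self.horizontal_samples + self.enface_samples
        modality = Modality(modality)
        if modality is Modality.HORIZONTAL:
            return list(self.horizontal_samples)
        return list(self.enface_samples)


@dataclass
class CohortDataset:
    """A full cohort: eyes grouped by patient with group labels."""

    eyes: list[EyeRecord]

    def __post_init__(self) -> None:
        ids = [e.eye_id for e in self.eyes]
        if len(set(ids)) != len(ids):
            raise ValidationError("eye_id values must be unique")
        counts: dict[str, int] = {}
        for e in self.eyes:
            counts[e.patient_id] = counts.get(e.patient_id, 0) + 1
        over = [p for p, c in counts.items() if c > 2]
        if over:
            raise ValidationError(f"patients with more than 2 eyes: {over}")

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "eye_id": e.eye_id,
                "patient_id": e.patient_id,
                "group": e.group.value,
                "n_horizontal": len(e.horizontal_samples),
                "n_enface": len(e.enface_samples),
            }
            for e in self.eyes
        ]
        return pd.DataFrame(rows)

    def eyes_in(self, groups: Iterable[Group | str]) -> list[EyeRecord]:
        wanted = {Group(g) for g in groups}
        return [e for e in self.eyes if e.group in wanted]

    def samples(self, modality: Modality | str | None = None) -> list[ImageSample]:
        out: list[ImageSample] = []
        for e in self.eyes:
            out.extend(e.samples(modality))
        return out


@dataclass
class BoundaryPair:
    """Per-column inner/outer choroid boundary rows of one b-scan.

    ``inner`` and ``outer`` are integer row indices, inclusive on both ends.
    A column without choroid carries the sentinel -1 in both arrays.
    """

    inner: np.ndarray
    outer: np.ndarray

    def __post_init__(self) -> None:
        self.inner = np.asarray(self.inner, dtype=int)
        self.outer = np.asarray(self.outer, dtype=int)
        if self.inner.shape != self.outer.shape or self.inner.ndim != 1:
            raise ValidationError("inner and outer must be 1-D arrays of equal length")
        valid = self.valid_columns
        if np.any(self.outer[valid] < self.inner[valid]):
            bad = np.where(valid & (self.outer < self.inner))[0]
            raise ValidationError(f"boundary crossing (outer < inner) at columns {bad.tolist()}")

    @property
    def valid_columns(self) -> np.ndarray:
        return (self.inner >= 0) & (self.outer >= 0)

    @property
    def thickness(self) -> np.ndarray:
        """Choroid thickness in rows per column (0 where invalid)."""
        t = np.where(self.valid_columns, self.outer - self.inner + 1, 0)
        return t


def build_enface_stack(
    bscan_volume: Sequence[ImageSample],
    boundaries: Sequence[BoundaryPair],
    n_slices: int,
) -> list[ImageSample]:
    """Reconstruct en face slices at fixed fractions of normalized choroid depth.

    Slice ``k`` (of ``n_slices``) collects, for every (b-scan, column), the
    intensity at fractional depth ``(k + 0.5) / n_slices`` between the inner
    (fraction 0) and outer (fraction 1) boundary, nearest-row sampling.  The
    en face image has one row per b-scan; its mask is True exactly where the
    column has valid choroid.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if len(bscan_volume) != len(boundaries):
        raise ValidationError("need exactly one BoundaryPair per b-scan")
    if not bscan_volume:
        raise ValidationError("empty b-scan volume")

    first = bscan_volume[0]
    n_b = len(bscan_volume)
    width = first.image.shape[1]
    dtype = first.image.dtype

    inner = np.stack([b.inner for b in boundaries])  # (n_b, width)
    outer = np.stack([b.outer for b in boundaries])
    valid = np.stack([b.valid_columns for b in boundaries])
    volume = np.stack([s.image for s in bscan_volume])  # (n_b, H, width)

    span = (outer - inner).astype(float)  # inclusive span in rows minus 1
    b_idx, c_idx = np.meshgrid(np.arange(n_b), np.arange(width), indexing="ij")

    out: list[ImageSample] = []
    for k in range(n_slices):
        frac = (k + 0.5) / n_slices
        rows = inner + np.rint(frac * span).astype(int)
        rows = np.where(valid, rows, 0)
        img = volume[b_idx, rows, c_idx]
        img = np.where(valid, img, 0).astype(dtype)
        out.append(
            ImageSample(
                image=img,
                mask=valid.copy(),
                eye_id=first.eye_id,
                patient_id=first.patient_id,
                group=first.group,
                modality=Modality.ENFACE,
                depth_fraction=frac,
                slice_index=k,
            )
        )
    return out


def select_depth_window(eye: EyeRecord, start_slice: int, count: int) -> list[ImageSample]:
    """Return ``count`` consecutive en face slices starting at ``start_slice``."""
    n = len(eye.enface_samples)
    if start_slice < 0 or count < 1 or start_slice + count > n:
        raise ValueError(
            f"depth window [{start_slice}, {start_slice + count}) out of range for "
            f"{n} slices (eye {eye.eye_id})"
        )
    return eye.enface_samples[start_slice : start_slice + count]


def save_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write every image/mask as 8-bit PNG plus a manifest CSV; return the manifest path."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for eye in dataset.eyes:
        for s in eye.samples():
            stem = f"{s.eye_id}_{s.modality.value}_{s.slice_index:04d}"
            image_path = f"images/{stem}.png"
            mask_path = f"images/{stem}_mask.png"
            iio.imwrite(out_dir / image_path, np.asarray(s.image, dtype=np.uint8))
            iio.imwrite(out_dir / mask_path, (s.mask.astype(np.uint8) * 255))
            rows.append(
                {
                    "eye_id": s.eye_id,
                    "patient_id": s.patient_id,
                    "group": s.group.value,
                    "modality": s.modality.value,
                    "slice_index": s.slice_index,
                    "image_path": image_path,
                    "mask_path": mask_path,
                }
            )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path


def load_cohort(manifest_path: str | Path, image_root: str | Path | None = None) -> CohortDataset:
    """Load a cohort from a manifest CSV referencing image/mask files.

    Missing files are collected and reported together before failing.  En face
    depth fractions are derived from the per-eye slice count as
    ``(slice_index + 0.5) / n_slices``.
    """
    manifest_path = Path(manifest_path)
    root = Path(image_root) if image_root is not None else manifest_path.parent
    try:
        table = pd.read_csv(manifest_path)
    except Exception as exc:  # pragma: no cover - pandas names the offending row
        raise ValidationError(f"malformed manifest {manifest_path}: {exc}") from exc
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"manifest missing columns {missing_cols}")

    missing_files = []
    for _, row in table.iterrows():
        for col in ("image_path", "mask_path"):
            p = root / str(row[col])
            if not p.exists():
                missing_files.append(str(p))
    if missing_files:
        raise ValidationError("missing files:\n" + "\n".join(missing_files))

    eyes: list[EyeRecord] = []
    for eye_id, sub in table.groupby("eye_id", sort=True):
        sub = sub.sort_values(["modality", "slice_index"])
        patient_id = str(sub["patient_id"].iloc[0])
        group = Group(str(sub["group"].iloc[0]))
        n_enface = int((sub["modality"] == Modality.ENFACE.value).sum())
        horizontal, enface = [], []
        for _, row in sub.iterrows():
            image = np.asarray(iio.imread(root / str(row["image_path"])))
            mask = np.asarray(iio.imread(root / str(row["mask_path"]))) > 0
            if image.shape != mask.shape:
                raise ValidationError(
                    f"sample {eye_id}:{row['modality']}:{row['slice_index']}: "
                    f"image/mask shape mismatch {image.shape} vs {mask.shape}"
                )
            modality = Modality(str(row["modality"]))
            k = int(row["slice_index"])
            sample = ImageSample(
                image=image,
                mask=mask,
                eye_id=str(eye_id),
                patient_id=patient_id,
                group=group,
                modality=modality,
                depth_fraction=(k + 0.5) / n_enface if modality is Modality.ENFACE else None,
                slice_index=k,
            )
            (horizontal if modality is Modality.HORIZONTAL else enface).append(sample)
        eyes.append(
            EyeRecord(
                eye_id=str(eye_id),
                patient_id=patient_id,
                group=group,
                horizontal_samples=horizontal,
                enface_samples=enface,
            )
        )
    return CohortDataset(eyes=eyes)
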