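"""Reading and writing binary segmentation masks and cohort tables.

Masks are exchanged as NIfTI-1 (``.nii``/``.nii.gz``, via nibabel) or NRRD
(``.nrrd``, via SimpleITK).  All geometry downstream operates on the mask's
own voxel grid with physical spacing attached; origin and orientation
metadata are carried through untouched because every shape feature computed
here is orientation-invariant.  Tabular data (cohorts, feature tables) use a
single dialect: UTF-8, comma-separated, header row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "VoxelMask",
    "CohortError",
    "MaskFormatError",
    "read_mask",
    "write_mask",
    "read_cohort",
    "write_cohort",
    "write_feature_table",
    "read_feature_table",
    "FEATURE_COLUMNS",
    "REQUIRED_COHORT_COLUMNS",
    "COVARIATE_COLUMNS",
]

#: Column order of the feature CSV emitted by :func:`write_feature_table`.
FEATURE_COLUMNS = (
    "log_volume",
    "surface_area_cm2",
    "sphericity",
    "discrete_compactness",
    "roundness",
)

REQUIRED_COHORT_COLUMNS = ("subject_id", "label")

#: Clinical covariates a full cohort carries (optional; absence is flagged).
COVARIATE_COLUMNS = (
    "age",
    "symptoms",
    "myasthenia",
    "cystic_change",
    "calcification",
    "diameter",
)


class MaskFormatError(ValueError):
    """Raised for unreadable, non-3D, or metadata-inconsistent mask files."""


class CohortError(ValueError):
    """Raised when a cohort table violates its schema."""


@dataclass
class VoxelMask:
    """A 3D binary occupancy grid with physical voxel spacing.

    Parameters
    ----------
    grid
        3D ``uint8`` array of {0, 1}; 1 marks tumor (foreground).
    spacing
        Physical edge lengths ``(sx, sy, sz)`` of one voxel, in mm.
    origin
        Physical offset in mm; carried through I/O but never interpreted.
    meta
        Free-form metadata (source path, original orientation, ...).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise MaskFormatError(
                f"mask grid must be 3D, got {self.grid.ndim}D"
            )
        vals = np.unique(self.grid)
        if not np.all(np.isin(vals, (0, 1))):
            raise MaskFormatError("mask grid must contain only 0/1 values")
        self.grid = self.grid.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MaskFormatError(
                f"spacing must be 3 positive components, got {self.spacing}"
            )
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelMask):
            return NotImplemented
        return (
            np.array_equal(self.grid, other.grid)
            and np.allclose(self.spacing, other.spacing, rtol=1e-5)
        )


def _binarize(data: np.ndarray) -> np.ndarray:
    """Any value > 0 is foreground; tolerates label maps (idempotent)."""
    return (np.asarray(data) > 0).astype(np.uint8)


def read_mask(path: str | os.PathLike) -> VoxelMask:
    """Read a binary mask from NIfTI (.nii/.nii.gz) or NRRD (.nrrd).

    The stored image is binarized (value > 0 -> 1) and spacing taken from
    the header.  Raises :class:`MaskFormatError` for missing files, non-3D
    images, or non-positive header spacing.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MaskFormatError(f"mask file not found: {path}")
    if path.endswith(".nrrd"):
        try:
            img = sitk.ReadImage(path)
        except Exception as exc:  # SimpleITK raises RuntimeError
            raise MaskFormatError(f"cannot read NRRD {path}: {exc}") from exc
        if img.GetDimension() != 3:
            raise MaskFormatError(
                f"expected 3D image, got {img.GetDimension()}D: {path}"
            )
        # GetArrayFromImage returns (z, y, x); transpose to (x, y, z).
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = img.GetSpacing()
        origin = img.GetOrigin()
        meta = {"source": path, "format": "nrrd",
                "direction": img.GetDirection()}
    elif path.endswith((".nii", ".nii.gz")):
        try:
            img = nib.load(path)
        except Exception as exc:
            raise MaskFormatError(f"cannot read NIfTI {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise MaskFormatError(
                f"expected 3D image, got {data.ndim}D: {path}"
            )
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) for z in zooms)
        origin = tuple(float(v) for v in img.affine[:3, 3])
        meta = {"source": path, "format": "nifti", "affine": img.affine}
    else:
        raise MaskFormatError(
            f"unsupported mask format (need .nii/.nii.gz/.nrrd): {path}"
        )
    if any(s <= 0 for s in spacing):
        raise MaskFormatError(f"non-positive header spacing {spacing}: {path}")
    return VoxelMask(_binarize(data), spacing=spacing, origin=origin,
                     meta=meta)


def write_mask(mask: VoxelMask, path: str | os.PathLike) -> None:
    """Write a mask so that ``read_mask`` round-trips grid and spacing."""
    path = os.fspath(path)
    if path.endswith(".nrrd"):
        img = sitk.GetImageFromArray(mask.grid.transpose(2, 1, 0))
        img.SetSpacing(mask.spacing)
        img.SetOrigin(mask.origin)
        sitk.WriteImage(img, path, useCompression=True)
    elif path.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(mask.spacing) + [1.0]).astype(float)
        affine[:3, 3] = mask.origin
        img = nib.Nifti1Image(mask.grid, affine)
        img.header.set_zooms(mask.spacing)
        nib.save(img, path)
    else:
        raise MaskFormatError(
            f"unsupported mask format (need .nii/.nii.gz/.nrrd): {path}"
        )


def read_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort CSV into a typed table.

    Requires ``subject_id`` and ``label`` columns; label is coerced to
    {0, 1} (0 = encapsulated, 1 = invasive).  Unknown columns pass through.
    Missing optional covariates are recorded in ``df.attrs['missing']``.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COHORT_COLUMNS:
        if col not in df.columns:
            raise CohortError(f"cohort is missing required column '{col}'")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortError(f"duplicated subject_id values: {dupes}")
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any() or not labels.isin((0, 1)).all():
        bad = df.loc[~labels.isin((0, 1)), "label"].unique().tolist()
        raise CohortError(f"label must be binary 0/1, found {bad}")
    df["label"] = labels.astype(int)
    missing = [c for c in COVARIATE_COLUMNS + FEATURE_COLUMNS
               if c not in df.columns]
    df.attrs["missing"] = missing
    return df


def write_cohort(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def write_feature_table(rows, path: str | os.PathLike) -> None:
    """Write per-subject shape features to CSV at full float precision.

    ``rows`` is an iterable of ``(subject_id, ShapeFeatures)`` pairs or of
    mappings already carrying the feature columns.
    """
    records = []
    for row in rows:
        if isinstance(row, tuple):
            sid, feats = row
            rec = {"subject_id": str(sid)}
            rec.update(feats.as_row())
        else:
            rec = dict(row)
        records.append(rec)
    cols = ["subject_id", *FEATURE_COLUMNS]
    df = pd.DataFrame(records, columns=cols if records else cols)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise CohortError("feature table is missing 'subject_id'")
    df["subject_id"] = df["subject_id"].astype(str)
    return df
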