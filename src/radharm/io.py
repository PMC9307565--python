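"""Core domain types and I/O: image studies, feature tables, resampling.

Conventions used throughout the package:

* arrays are indexed ``(slice, row, col)``; voxel spacing is reported per
  axis as ``(dz, dy, dx)`` is *not* used — spacing is ``(dx, dy, dz)`` in mm
  with ``dx``/``dy`` the in-plane pixel size and ``dz`` the slice thickness;
* segmentation masks are integer labelled: 0 background, 1 left-ventricular
  cavity (LV), 2 left-ventricular myocardium (MYO), 3 right-ventricular
  cavity (RV);
* feature tables are pandas-backed with a fixed canonical column order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

# ROI label codes and names
ROI_LABELS = {1: "LV", 2: "MYO", 3: "RV"}
ROI_NAMES = {v: k for k, v in ROI_LABELS.items()}
VALID_LABELS = frozenset({0, 1, 2, 3})

#: feature families in canonical order (first-order first, then the four
#: texture-matrix families alphabetically)
FAMILY_ORDER = ("firstorder", "GLCM", "GLDM", "GLRLM", "GLSZM")
ROI_ORDER = ("LV", "MYO", "RV")

#: metadata column prefix used in feature-table CSVs so feature names can
#: never collide with metadata
META_PREFIX = "meta:"
META_COLUMNS = ("subject_id", "centre", "pathology", "phase")


class ShapeMismatchError(ValueError):
    """Image and mask grids are incompatible."""


class UnknownLabelError(ValueError):
    """Mask contains labels outside {0, 1, 2, 3}."""


@dataclass
class ImageStudy:
    """One subject's grayscale volume, segmentation mask and metadata.

    ``voxels`` and ``mask`` share a ``(n_slices, n_rows, n_cols)`` grid.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # (dx, dy, dz) in mm
    mask: np.ndarray
    centre_id: str
    class_label: str  # "healthy" | "HCM"
    phase: str  # "ED" | "ES"
    subject_id: str
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if self.mask.shape != self.voxels.shape:
            raise ShapeMismatchError(
                f"mask shape {self.mask.shape} does not match "
                f"voxels shape {self.voxels.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        labels = set(np.unique(self.mask).tolist())
        unknown = labels - VALID_LABELS
        if unknown:
            raise UnknownLabelError(f"unknown label(s) in mask: {sorted(unknown)}")
        missing = [ROI_LABELS[l] for l in (1, 2, 3) if l not in labels]
        if missing:
            self.flags = list(self.flags) + [f"missing-roi:{r}" for r in missing]

    @property
    def study_id(self) -> str:
        return f"{self.subject_id}_{self.phase}"

    def roi_values(self, label: int) -> np.ndarray:
        """Voxel intensities inside one ROI label, as a flat array."""
        return self.voxels[self.mask == label]


@dataclass
class ROISample:
    """Flat vector of voxel intensities from a single ROI of one study."""

    intensities: np.ndarray
    roi: str
    source: str

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.intensities.size == 0:
            raise ValueError(f"empty ROI sample for {self.roi} of {self.source}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"non-finite intensities in {self.roi} of {self.source}")


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

def write_study(study: ImageStudy, image_path, mask_path) -> None:
    """Write a study's volume and mask as NIfTI-1 with spacing in the affine."""
    dx, dy, dz = study.spacing
    # array axes are (slice, row, col) -> voxel sizes (dz, dy, dx)
    affine = np.diag([dz, dy, dx, 1.0])
    nib.save(nib.Nifti1Image(study.voxels.astype(np.float64), affine), str(image_path))
    nib.save(nib.Nifti1Image(study.mask.astype(np.int16), affine), str(mask_path))


def read_study(image_path, mask_path, meta: dict) -> ImageStudy:
    """Load a NIfTI image/mask pair into an :class:`ImageStudy`.

    ``meta`` must provide ``subject_id``, ``centre``, ``pathology`` and
    ``phase``.  Intensities are preserved bit-exactly for float64 files.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    voxels = np.asarray(img.dataobj, dtype=np.float64)
    mask = np.rint(np.asarray(msk.dataobj)).astype(int)
    zooms = img.header.get_zooms()[:3]  # (dz, dy, dx) per our write convention
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ImageStudy(
        voxels=voxels,
        spacing=spacing,
        mask=mask,
        centre_id=str(meta["centre"]),
        class_label=str(meta["pathology"]),
        phase=str(meta["phase"]),
        subject_id=str(meta["subject_id"]),
    )


def write_cohort(studies: list[ImageStudy], out_dir) -> None:
    """Write a list of studies as NIfTI pairs plus a metadata CSV sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in studies:
        base = s.study_id
        write_study(s, out / f"{base}_img.nii.gz", out / f"{base}_mask.nii.gz")
        rows.append(
            {
                "subject_id": s.subject_id,
                "centre": s.centre_id,
                "pathology": s.class_label,
                "phase": s.phase,
                "image": f"{base}_img.nii.gz",
                "mask": f"{base}_mask.nii.gz",
            }
        )
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)


def read_cohort(in_dir) -> list[ImageStudy]:
    """Read a cohort written by :func:`write_cohort`."""
    from pathlib import Path

    root = Path(in_dir)
    meta = pd.read_csv(root / "metadata.csv", dtype=str)
    studies = []
    for _, row in meta.iterrows():
        studies.append(read_study(root / row["image"], root / row["mask"], row))
    return studies


# ---------------------------------------------------------------------------
# In-plane resampling
# ---------------------------------------------------------------------------

def resample_inplane(
    study: ImageStudy, target: tuple[float, float] = (1.0, 1.0)
) -> ImageStudy:
    """Resample each slice to ``target = (dx, dy)`` mm pixels.

    Slice count and slice thickness are unchanged.  The image is interpolated
    bilinearly, the mask by nearest neighbour (labels are categorical, so no
    new labels can appear).  Output pixel centres sit at
    ``x_out[i] = i * dx_target`` in the input's mm frame anchored at the
    first pixel centre; samples beyond the input extent clamp to the edge.
    """
    tx, ty = float(target[0]), float(target[1])
    if tx <= 0 or ty <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    dx, dy, dz = study.spacing
    if np.isclose(dx, tx) and np.isclose(dy, ty):
        return replace(study, voxels=study.voxels.copy(), mask=study.mask.copy())

    n_slices, n_rows, n_cols = study.voxels.shape
    new_rows = max(1, int(round(n_rows * dy / ty)))
    new_cols = max(1, int(round(n_cols * dx / tx)))
    # sample coordinates in input index units
    rr = np.arange(new_rows) * ty / dy
    cc = np.arange(new_cols) * tx / dx
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    coords = np.stack([grid_r.ravel(), grid_c.ravel()])

    vox = np.empty((n_slices, new_rows, new_cols), dtype=float)
    msk = np.empty((n_slices, new_rows, new_cols), dtype=study.mask.dtype)
    for k in range(n_slices):
        vox[k] = ndimage.map_coordinates(
            study.voxels[k], coords, order=1, mode="nearest"
        ).reshape(new_rows, new_cols)
        msk[k] = ndimage.map_coordinates(
            study.mask[k], coords, order=0, mode="nearest"
        ).reshape(new_rows, new_cols)
    return replace(
        study, voxels=vox, mask=msk, spacing=(tx, ty, dz), flags=list(study.flags)
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def feature_id(roi: str, family: str, name: str) -> str:
    return f"{roi}|{family}|{name}"


def parse_feature_id(col: str) -> tuple[str, str, str]:
    roi, family, name = col.split("|", 2)
    return roi, family, name


def canonical_column_order(columns) -> list[str]:
    """Sort feature ids: ROI (LV, MYO, RV), then family order
    (firstorder, GLCM, GLDM, GLRLM, GLSZM), then feature name alphabetically.
    """
    def key(col: str):
        roi, family, name = parse_feature_id(col)
        return (ROI_ORDER.index(roi), FAMILY_ORDER.index(family), name)

    return sorted(columns, key=key)


@dataclass
class FeatureTable:
    """Subjects-by-features matrix with row and column annotations.

    ``data`` is indexed by study id; ``row_meta`` (same index) carries
    subject_id/centre/pathology/phase; ``col_meta`` (indexed by feature id)
    carries roi/family/name/order with order ∈ {first, second}.
    """

    data: pd.DataFrame
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.row_meta.index):
            raise ValueError("data and row_meta indices differ")
        if list(self.data.columns) != list(self.col_meta.index):
            raise ValueError("data columns and col_meta index differ")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dups}")

    @classmethod
    def from_matrix(cls, data: pd.DataFrame, row_meta: pd.DataFrame) -> "FeatureTable":
        """Build a table from a feature matrix, deriving column metadata from
        ``roi|family|name`` column ids and enforcing canonical ordering."""
        cols = canonical_column_order(data.columns)
        data = data[cols]
        parsed = [parse_feature_id(c) for c in cols]
        col_meta = pd.DataFrame(
            {
                "roi": [p[0] for p in parsed],
                "family": [p[1] for p in parsed],
                "name": [p[2] for p in parsed],
                "order": ["first" if p[1] == "firstorder" else "second" for p in parsed],
            },
            index=pd.Index(cols, name="feature"),
        )
        return cls(data=data, row_meta=row_meta.loc[data.index], col_meta=col_meta)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def select(self, *, roi=None, order=None, family=None,
               pathology=None, phase=None, centre=None) -> "FeatureTable":
        """Subset rows by metadata and columns by annotation; returns a copy."""
        rows = pd.Series(True, index=self.data.index)
        if pathology is not None:
            rows &= self.row_meta["pathology"] == pathology
        if phase is not None:
            rows &= self.row_meta["phase"] == phase
        if centre is not None:
            rows &= self.row_meta["centre"] == centre
        cols = pd.Series(True, index=self.col_meta.index)
        if roi is not None:
            cols &= self.col_meta["roi"] == roi
        if order is not None:
            cols &= self.col_meta["order"] == order
        if family is not None:
            cols &= self.col_meta["family"] == family
        keep = cols[cols].index.tolist()
        return FeatureTable(
            data=self.data.loc[rows.values, keep].copy(),
            row_meta=self.row_meta.loc[rows.values].copy(),
            col_meta=self.col_meta.loc[keep].copy(),
        )

    def with_data(self, values: np.ndarray) -> "FeatureTable":
        """Same annotations, new matrix values."""
        data = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return FeatureTable(data=data, row_meta=self.row_meta.copy(),
                            col_meta=self.col_meta.copy())


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table to CSV (metadata columns prefixed ``meta:``)."""
    if table.data.isna().any().any():
        na = table.data.isna()
        r = na.any(axis=1).idxmax()
        c = na.any(axis=0).idxmax()
        raise ValueError(f"NaN in feature table at row {r!r}, column {c!r}")
    out = table.data.copy()
    for col in reversed(META_COLUMNS):
        out.insert(0, META_PREFIX + col, table.row_meta[col])
    out.index.name = "study_id"
    out.to_csv(path, float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    """Read a CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, index_col="study_id")
    df.index.name = None
    meta_cols = [c for c in df.columns if c.startswith(META_PREFIX)]
    row_meta = df[meta_cols].copy()
    row_meta.columns = [c[len(META_PREFIX):] for c in meta_cols]
    row_meta = row_meta.astype(str)
    data = df.drop(columns=meta_cols).astype(float)
    if data.shape[1] == 0:
        col_meta = pd.DataFrame(
            columns=["roi", "family", "name", "order"],
            index=pd.Index([], name="feature"),
        )
        return FeatureTable(data=data, row_meta=row_meta, col_meta=col_meta)
    return FeatureTable.from_matrix(data, row_meta)
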