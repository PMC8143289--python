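"""Readers and writers for volumes, masks, feature tables and JSON artifacts.

Conventions
-----------
* Voxel arrays are indexed ``(slice, row, col)``, 0-based, with the in-plane
  pixel spacing given as a ``(row, col)`` pair in millimetres.
* NIfTI is used for volumes; the affine is diagonal with zooms
  ``(slice_thickness, row_spacing, col_spacing)`` matching the array axes.
* Masks are voxel-aligned with their image (no resampling); any nonzero
  stored value is read as 1.
* Feature tables are CSV with columns ``patient_id,label[,partition]``
  followed by the feature columns, written with 17 significant digits so
  values round-trip exactly through text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError, SchemaError, ValidationError

META_COLUMNS = ("patient_id", "label")
PARTITION_VALUES = frozenset({"train", "test"})


# ---------------------------------------------------------------------------
# volumes and masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageVolume:
    """A scalar voxel grid in native signal units.

    Parameters
    ----------
    voxels
        3-D array indexed ``(slice, row, col)``.
    pixel_spacing_mm
        In-plane spacing ``(row, col)`` in mm.
    slice_thickness_mm
        Through-plane slice thickness in mm.
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValidationError(f"expected a 3-D voxel array, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise ValidationError("voxel array contains non-finite values")
        sp = tuple(float(s) for s in self.pixel_spacing_mm)
        if len(sp) != 2 or any(s <= 0 for s in sp) or self.slice_thickness_mm <= 0:
            raise ValidationError("pixel spacing and slice thickness must be positive")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "pixel_spacing_mm", sp)
        object.__setattr__(self, "slice_thickness_mm", float(self.slice_thickness_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class LesionMask:
    """A binary ROI congruent with an :class:`ImageVolume`."""

    voxels: np.ndarray

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValidationError(f"expected a 3-D mask array, got ndim={vox.ndim}")
        binary = (vox != 0).astype(np.uint8)
        object.__setattr__(self, "voxels", binary)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def check_congruent(volume: ImageVolume, mask: LesionMask) -> None:
    """Raise :class:`GeometryError` unless mask and volume share a grid."""
    if volume.shape != mask.shape:
        raise GeometryError(
            f"mask shape {mask.shape} does not match image shape {volume.shape}"
        )


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write an :class:`ImageVolume` as NIfTI, spacing encoded in the affine."""
    path = Path(path)
    thick = volume.slice_thickness_mm
    sp_r, sp_c = volume.pixel_spacing_mm
    affine = np.diag([thick, sp_r, sp_c, 1.0])
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float64), affine)
    nib.save(img, str(path))
    return path


def write_mask(mask: LesionMask, volume: ImageVolume, path: str | Path) -> Path:
    """Write a mask on its parent image's grid (uint8 NIfTI)."""
    check_congruent(volume, mask)
    path = Path(path)
    thick = volume.slice_thickness_mm
    sp_r, sp_c = volume.pixel_spacing_mm
    affine = np.diag([thick, sp_r, sp_c, 1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))
    return path


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path!s} as a NIfTI volume: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path!s}: expected a 3-D volume, got ndim={data.ndim}")
    return data, zooms


def read_patient(image_path: str | Path, mask_path: str | Path) -> tuple[ImageVolume, LesionMask]:
    """Load one patient's image and lesion mask.

    The mask is binarized (any stored value > 0 becomes 1). Shape or spacing
    disagreement between the two files raises :class:`GeometryError`.
    """
    img_data, img_zooms = _load_nifti(image_path)
    mask_data, mask_zooms = _load_nifti(mask_path)
    if img_data.shape != mask_data.shape:
        raise GeometryError(
            f"mask shape {mask_data.shape} does not match image shape {img_data.shape}"
        )
    if not np.allclose(img_zooms, mask_zooms, rtol=1e-4):
        raise GeometryError(
            f"mask zooms {mask_zooms} do not match image zooms {img_zooms}"
        )
    volume = ImageVolume(
        voxels=img_data,
        pixel_spacing_mm=(img_zooms[1], img_zooms[2]),
        slice_thickness_mm=img_zooms[0],
    )
    return volume, LesionMask(voxels=mask_data)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV; image/mask paths resolved against its folder."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"patient_id", "label", "image", "mask", "spacing_mm"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"manifest {path} is missing columns: {sorted(missing)}")
    base = path.parent
    for col in ("image", "mask"):
        df[col] = [str((base / p)) if not Path(p).is_absolute() else p for p in df[col]]
    return df


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Patients x features table with binary labels and optional partition.

    ``data`` holds ``patient_id``, ``label`` (0 = ncsPCa, 1 = csPCa), an
    optional ``partition`` column ({"train", "test"}) and one column per
    feature listed in ``feature_names``.
    """

    data: pd.DataFrame
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        df = self.data.reset_index(drop=True)
        for col in META_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"feature table is missing column '{col}'")
        if not self.feature_names:
            features = [c for c in df.columns if c not in META_COLUMNS and c != "partition"]
            self.feature_names = tuple(features)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature names are not unique")
        missing = [f for f in self.feature_names if f not in df.columns]
        if missing:
            raise SchemaError(f"feature table is missing feature columns: {missing}")
        ids = df["patient_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate patient_id values: {dupes}")
        labels = set(df["label"].tolist())
        if not labels <= {0, 1}:
            raise ValidationError(f"labels must be 0/1, got {sorted(labels)}")
        if "partition" in df.columns:
            bad = set(df["partition"]) - PARTITION_VALUES
            if bad:
                raise ValidationError(f"invalid partition values: {sorted(bad)}")
        df["patient_id"] = ids
        self.data = df

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_partition(self) -> bool:
        return "partition" in self.data.columns

    def _rows(self, partition: str | None) -> pd.DataFrame:
        if partition is None:
            return self.data
        if not self.has_partition:
            raise ValidationError("table has no partition assignment")
        return self.data[self.data["partition"] == partition]

    def ids(self, partition: str | None = None) -> np.ndarray:
        return self._rows(partition)["patient_id"].to_numpy()

    def X(self, partition: str | None = None) -> pd.DataFrame:
        rows = self._rows(partition)
        return rows.set_index("patient_id")[list(self.feature_names)].astype(float)

    def y(self, partition: str | None = None) -> np.ndarray:
        return self._rows(partition)["label"].to_numpy(dtype=int)

    def with_partition(self, train_ids: Iterable[str]) -> "CohortTable":
        """Return a copy with a partition column (listed ids -> train)."""
        train = {str(i) for i in train_ids}
        unknown = train - set(self.data["patient_id"])
        if unknown:
            raise ValidationError(f"unknown patient ids in partition: {sorted(unknown)}")
        df = self.data.copy()
        df["partition"] = ["train" if pid in train else "test" for pid in df["patient_id"]]
        cols = ["patient_id", "label", "partition"] + list(self.feature_names)
        return CohortTable(df[cols], self.feature_names)


def write_feature_table(table: CohortTable, path: str | Path) -> Path:
    """Write a :class:`CohortTable` as CSV (17 significant digits)."""
    path = Path(path)
    cols = ["patient_id", "label"]
    if table.has_partition:
        cols.append("partition")
    cols += list(table.feature_names)
    table.data[cols].to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(
    path: str | Path, required_features: Sequence[str] | None = None
) -> CohortTable:
    """Read a feature table CSV written by :func:`write_feature_table`.

    If ``required_features`` is given, every listed feature column must be
    present, otherwise :class:`SchemaError` is raised.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty and "patient_id" not in df.columns:
        raise SchemaError(f"{path}: not a feature table (missing header)")
    features = [c for c in df.columns if c not in META_COLUMNS and c != "partition"]
    if required_features is not None:
        missing = [f for f in required_features if f not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing feature columns {missing}")
        features = list(required_features)
    return CohortTable(df, tuple(features))


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")
    return path


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
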