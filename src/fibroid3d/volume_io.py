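"""Volume and label-map containers plus NIfTI/DICOM input-output.

The grid contract used throughout the package: voxels are addressed by
0-based indices ``(i, j, k)``; the world (mm) coordinate of a voxel center
is ``origin + index * spacing`` componentwise; axes are right-handed and
the third index ``k`` runs along the slice (sagittal-stack) direction.
Direction cosines beyond spacing/origin are accepted on read but
normalized to identity with a logged warning — the pipeline is
orientation-agnostic at desk scale.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: label codes shared by every module
BACKGROUND, BODY, ENDOMETRIUM, FIBROID = 0, 1, 2, 3
LABELS = (BACKGROUND, BODY, ENDOMETRIUM, FIBROID)
STRUCTURE_NAMES = {BODY: "body", ENDOMETRIUM: "endometrium", FIBROID: "fibroid"}


class VolumeFormatError(ValueError):
    """File could not be parsed as the requested volume format."""


class DimensionalityError(ValueError):
    """Input data is not a 3D scalar grid."""


class LabelValidationError(ValueError):
    """Label map contains values outside the declared label set."""


def _check_geometry(data: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    if data.ndim != 3:
        raise DimensionalityError(f"expected a 3D grid, got {data.ndim}D data")
    if any(s < 1 for s in data.shape):
        raise DimensionalityError(f"degenerate grid shape {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must have 3 components")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be strictly positive, got {spacing}")
    if any(not np.isfinite(o) for o in origin):
        raise ValueError(f"origin components must be finite, got {origin}")
    return spacing, origin


@dataclass
class Volume3D:
    """A 3D scalar voxel grid with per-axis spacing (mm) and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing, self.origin = _check_geometry(self.data, self.spacing, self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel centers for an (N, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class LabelMap:
    """Integer segmentation grid over the same geometry as its source volume.

    Codes: 0 background, 1 uterine body, 2 endometrium, 3 fibroid.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing, self.origin = _check_geometry(self.labels, self.spacing, self.origin)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise LabelValidationError("label map contains non-integer values")
            self.labels = self.labels.astype(np.int16)
        validate_labels(self.labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one structure."""
        return self.labels == label

    def matches_grid(self, other: "Volume3D | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def validate_labels(labels: np.ndarray, allowed: Iterable[int] = LABELS) -> None:
    present = np.unique(labels)
    bad = np.setdiff1d(present, np.asarray(sorted(allowed)))
    if bad.size:
        raise LabelValidationError(
            f"label values {bad.tolist()} outside declared set {sorted(allowed)}"
        )


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    return affine


def _geometry_from_nifti(img) -> tuple[tuple, tuple]:
    affine = img.affine
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in affine[:3, 3])
    rotation = affine[:3, :3] / np.asarray(spacing)[None, :]
    if not np.allclose(rotation, np.eye(3), atol=1e-3):
        logger.warning(
            "non-identity direction cosines in %s normalized to identity",
            getattr(img, "file_map", None) and img.get_filename(),
        )
    return spacing, origin


def read_volume(path: str | os.PathLike, format: str | None = None) -> Volume3D:
    """Read a 3D volume from NIfTI (.nii/.nii.gz) or a DICOM series directory.

    ``format`` is ``"nifti"``, ``"dicom-dir"`` or None (inferred: directories
    are treated as DICOM series, files as NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom-dir" if path.is_dir() else "nifti"
    if format == "nifti":
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several unrelated types
            raise VolumeFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise DimensionalityError(f"{path} holds {data.ndim}D data, expected 3D")
        spacing, origin = _geometry_from_nifti(img)
        return Volume3D(np.ascontiguousarray(data.astype(np.float64)), spacing, origin)
    if format == "dicom-dir":
        return _read_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}; use 'nifti' or 'dicom-dir'")


def _read_dicom_dir(path: Path) -> Volume3D:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise VolumeFormatError(f"no readable DICOM image files in {path}")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    arrays = [ds.pixel_array.T for ds in slices]  # (col, row) -> (i, j)
    if len({a.shape for a in arrays}) != 1:
        raise VolumeFormatError("DICOM series has inconsistent slice shapes")
    data = np.stack(arrays, axis=-1).astype(np.float64)
    if data.ndim != 3 or data.shape[2] < 1:
        raise DimensionalityError("DICOM series did not form a 3D stack")
    first = slices[0]
    px = getattr(first, "PixelSpacing", [1.0, 1.0])
    if len(slices) > 1:
        positions = [sort_key(ds) for ds in slices]
        dz = float(np.median(np.diff(positions)))
        if not np.isfinite(dz) or dz <= 0:
            dz = float(getattr(first, "SliceThickness", 1.0))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    spacing = (float(px[1]), float(px[0]), dz)
    pos = getattr(first, "ImagePositionPatient", [0.0, 0.0, 0.0])
    origin = (float(pos[0]), float(pos[1]), float(pos[2]))
    logger.warning("DICOM orientation normalized to identity (spacing/origin kept)")
    return Volume3D(data, spacing, origin)


def write_volume(volume: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; spacing/origin go into the affine."""
    img = nib.Nifti1Image(
        np.asarray(volume.data, dtype=np.float32),
        _affine_from_geometry(volume.spacing, volume.origin),
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_labelmap(labelmap: LabelMap, path: str | os.PathLike) -> None:
    """Write a label map as integer NIfTI-1 (lossless round-trip)."""
    validate_labels(labelmap.labels)
    img = nib.Nifti1Image(
        np.asarray(labelmap.labels, dtype=np.int16),
        _affine_from_geometry(labelmap.spacing, labelmap.origin),
    )
    img.header.set_zooms(labelmap.spacing)
    nib.save(img, str(path))


def read_labelmap(path: str | os.PathLike) -> LabelMap:
    """Read a label map from NIfTI and validate the label set."""
    vol = read_volume(path, format="nifti")
    data = vol.data
    if np.any(data != np.round(data)):
        raise LabelValidationError(f"{path} holds non-integer data")
    return LabelMap(data.astype(np.int16), vol.spacing, vol.origin)
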