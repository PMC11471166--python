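"""Volumetric image containers and NIfTI / DICOM-series input-output.

A probability volume is the per-voxel softmax output of a segmentation
network; a binary mask is a thresholded segmentation. Both carry a 4x4
voxel-to-world affine from which physical voxel spacing (mm) and voxel
volume (mm^3) are derived, so downstream volumetry is always in physical
units regardless of acquisition resolution.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "ProbabilityVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "dicom_series_to_volume",
]

#: tolerance for probabilities marginally outside [0, 1] (float32 rounding)
PROB_TOL = 1e-6


@dataclass
class Volume:
    """A 3D scalar field with physical geometry.

    Parameters
    ----------
    data : ndarray
        3D array of voxel values.
    affine : ndarray
        4x4 voxel-index to world-coordinate map (mm).
    case_id : str
        Examination identifier.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    case_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D image, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.abs(np.linalg.det(self.affine[:3, :3])) <= 0:
            raise ValueError("affine is singular: voxel volume would be 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing in mm along each array axis (affine column norms)."""
        return tuple(np.linalg.norm(self.affine[:3, i]) for i in range(3))

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3.

        Uses |det| of the affine's linear part, which equals the product
        of spacings for axis-aligned affines and stays correct for
        oblique ones.
        """
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class ProbabilityVolume(Volume):
    """Per-voxel probabilities in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        data = np.asarray(self.data, dtype=np.float64)
        lo, hi = float(data.min(initial=0.0)), float(data.max(initial=0.0))
        if lo < -PROB_TOL or hi > 1.0 + PROB_TOL:
            raise ValueError(
                f"probabilities outside [0, 1]: range [{lo:.6g}, {hi:.6g}]"
            )
        self.data = np.clip(data, 0.0, 1.0)


@dataclass
class BinaryMask(Volume):
    """Segmentation mask with values exactly {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        data = np.asarray(self.data)
        rounded = np.rint(data)
        if np.any(np.abs(data - rounded) > PROB_TOL) or not np.isin(
            np.unique(rounded), (0.0, 1.0)
        ).all():
            bad = np.unique(data)[:5]
            raise ValueError(f"non-binary mask: values include {bad}")
        self.data = rounded.astype(np.uint8)


def read_volume(path: str | os.PathLike, kind: str = "probability") -> Volume:
    """Read a 3D NIfTI image as a probability volume or binary mask.

    Parameters
    ----------
    path : path-like
        A ``.nii`` or ``.nii.gz`` file containing a 3D image.
    kind : {"probability", "mask"}
        Validation contract to apply.

    Returns
    -------
    ProbabilityVolume or BinaryMask
        Spacing and voxel volume come from the image affine. Probability
        values are clipped into [0, 1] only when within 1e-6 of the
        bounds; anything further out raises ``ValueError``.
    """
    if kind not in ("probability", "mask"):
        raise ValueError(f"kind must be 'probability' or 'mask', got {kind!r}")
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    case_id = Path(path).name.removesuffix(".gz").removesuffix(".nii")
    cls = ProbabilityVolume if kind == "probability" else BinaryMask
    return cls(data=data, affine=np.asarray(img.affine), case_id=case_id)


def write_volume(vol: Volume, path: str | os.PathLike) -> Path:
    """Write a volume to NIfTI. Masks are stored as uint8, else float32."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, os.fspath(path))
    return path


def _read_series(series_dir: str | os.PathLike):
    import pydicom

    files = sorted(Path(series_dir).iterdir())
    slices = []
    for f in files:
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(os.fspath(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {series_dir}")
    return slices


def dicom_series_to_volume(series_dir: str | os.PathLike) -> Volume:
    """Convert a single-series axial DICOM stack to a HU volume.

    Slices are sorted by the projection of ImagePositionPatient onto the
    slice normal (cross product of the row/column direction cosines), so
    the result is independent of file naming. Rescale slope/intercept are
    applied to produce Hounsfield units. The affine maps array indices
    (row, column, slice) to the patient coordinate frame.

    Raises
    ------
    ValueError
        On mixed SeriesInstanceUIDs, inconsistent in-plane spacing or
        orientation, variable inter-slice spacing, or missing geometry
        tags. Variable slice spacing is rejected rather than resampled.
    """
    slices = _read_series(series_dir)

    uids = {str(getattr(s, "SeriesInstanceUID", "")) for s in slices}
    if len(uids) != 1:
        raise ValueError(f"mixed series in directory: {len(uids)} SeriesInstanceUIDs")

    for tag in ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing"):
        if any(getattr(s, tag, None) is None for s in slices):
            raise ValueError(f"missing geometry tag {tag}")

    orient = np.array(slices[0].ImageOrientationPatient, dtype=float)
    spacing_rc = np.array(slices[0].PixelSpacing, dtype=float)  # (row, col) mm
    for s in slices[1:]:
        if not np.allclose(s.ImageOrientationPatient, orient, atol=1e-4):
            raise ValueError("inconsistent ImageOrientationPatient across slices")
        if not np.allclose(np.array(s.PixelSpacing, float), spacing_rc, atol=1e-4):
            raise ValueError("inconsistent in-plane PixelSpacing across slices")

    row_dir, col_dir = orient[:3], orient[3:]
    normal = np.cross(row_dir, col_dir)
    positions = np.array([s.ImagePositionPatient for s in slices], dtype=float)
    order = np.argsort(positions @ normal)
    slices = [slices[i] for i in order]
    positions = positions[order]

    if len(slices) > 1:
        steps = np.diff(positions @ normal)
        if np.any(steps <= 0):
            raise ValueError("duplicate or non-monotone slice positions")
        if not np.allclose(steps, steps[0], atol=1e-3):
            raise ValueError(
                f"variable inter-slice spacing ({steps.min():.3f}-{steps.max():.3f} mm)"
            )
        slice_step = float(steps[0])
    else:
        slice_step = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)

    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(s, "RescaleIntercept", 0.0) or 0.0)
        planes.append(arr * slope + intercept)
    data = np.stack(planes, axis=-1)  # (rows, cols, slices)

    affine = np.eye(4)
    affine[:3, 0] = col_dir * spacing_rc[0]  # row index step
    affine[:3, 1] = row_dir * spacing_rc[1]  # column index step
    affine[:3, 2] = normal * slice_step
    affine[:3, 3] = positions[0]
    case_id = str(getattr(slices[0], "SeriesInstanceUID", ""))
    return Volume(data=data, affine=affine, case_id=case_id)
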