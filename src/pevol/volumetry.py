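"""Thresholding, connected-component labeling, and physical volumetry.

Every classification rule in the pipeline ultimately consumes a physical
embolus volume in mm^3 produced here. Binarization keeps voxels at or
above the probability threshold; component labeling defaults to
26-connectivity in 3D and 8-connectivity within an axial slice, the
common convention for blob-like radiological segmentations (both are
configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, ProbabilityVolume, Volume

__all__ = [
    "EmbolusComponent",
    "ComponentReport",
    "binarize",
    "total_volume",
    "label_components_3d",
    "component_report",
    "volume_profile",
]

_STRUCTS_3D = {6: 1, 18: 2, 26: 3}
_STRUCTS_2D = {4: 1, 8: 2}


@dataclass(frozen=True)
class EmbolusComponent:
    """One 3D connected component of a binary segmentation.

    ``volume_mm3`` is exactly ``voxel_count * voxel_volume``;
    ``slice_count`` is the number of axial (third-axis) slices spanned.
    """

    component_id: int
    voxel_count: int
    volume_mm3: float
    bounding_box: tuple[tuple[int, int], ...]
    slice_count: int


@dataclass(frozen=True)
class ComponentReport:
    """Decomposition of a mask into 3D, 2D (per-axial-slice), and 1D
    (single-voxel) components, with volume statistics of the 3D ones.

    Statistics are ``None`` for an empty mask — PE-negative examinations
    are the common path and must not error.
    """

    n_3d: int
    n_2d: int
    n_1d: int
    mean_volume_mm3: float | None
    min_volume_mm3: float | None
    max_volume_mm3: float | None
    total_volume_mm3: float

    def to_dict(self) -> dict:
        return {
            "n_3d": self.n_3d,
            "n_2d": self.n_2d,
            "n_1d": self.n_1d,
            "mean_volume_mm3": self.mean_volume_mm3,
            "min_volume_mm3": self.min_volume_mm3,
            "max_volume_mm3": self.max_volume_mm3,
            "total_volume_mm3": self.total_volume_mm3,
        }


def binarize(vol: ProbabilityVolume, p: float) -> BinaryMask:
    """Threshold a probability volume at ``p`` (voxels with value >= p kept).

    The >= comparison keeps ``p = 1.0`` meaningful and makes nested
    thresholds strictly monotone: raising ``p`` can only shrink the mask.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability threshold must be in [0, 1], got {p}")
    return BinaryMask(
        data=(vol.data >= p).astype(np.uint8),
        affine=vol.affine,
        case_id=vol.case_id,
    )


def total_volume(mask: BinaryMask | Volume) -> float:
    """Total foreground volume in mm^3: set voxels times voxel volume."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    table = _STRUCTS_3D if ndim == 3 else _STRUCTS_2D
    if connectivity not in table:
        raise ValueError(
            f"connectivity must be one of {sorted(table)} in {ndim}D, got {connectivity}"
        )
    return ndimage.generate_binary_structure(ndim, table[connectivity])


def label_components_3d(
    mask: BinaryMask, connectivity: int = 26
) -> list[EmbolusComponent]:
    """Label maximal 3D connected components of a binary mask.

    Components are returned in deterministic order: sorted by their
    lexicographically smallest voxel index (row-major raster order).
    """
    struct = _structure(3, connectivity)
    labeled, n = ndimage.label(mask.data, structure=struct)
    if n == 0:
        return []
    # first raster-order occurrence of each label = its minimum voxel index
    flat = labeled.ravel()
    values, first_idx = np.unique(flat, return_index=True)
    first_of = dict(zip(values.tolist(), first_idx.tolist()))
    order = sorted(range(1, n + 1), key=lambda lab: first_of[lab])

    objects = ndimage.find_objects(labeled)
    counts = np.bincount(flat, minlength=n + 1)
    vv = mask.voxel_volume
    components = []
    for new_id, lab in enumerate(order, start=1):
        sl = objects[lab - 1]
        region = labeled[sl] == lab
        slice_count = int(np.count_nonzero(region.any(axis=(0, 1))))
        components.append(
            EmbolusComponent(
                component_id=new_id,
                voxel_count=int(counts[lab]),
                volume_mm3=float(counts[lab]) * vv,
                bounding_box=tuple((s.start, s.stop) for s in sl),
                slice_count=slice_count,
            )
        )
    return components


def component_report(
    mask: BinaryMask, connectivity_3d: int = 26, connectivity_2d: int = 8
) -> ComponentReport:
    """Count 3D, 2D, and 1D components and summarize 3D component volumes.

    2D components are in-plane connected components counted separately on
    every axial slice (the third array axis, the plane in which clots are
    annotated); 1D components are single foreground voxels, so ``n_1d``
    is the total foreground voxel count.
    """
    comps = label_components_3d(mask, connectivity_3d)
    struct2 = _structure(2, connectivity_2d)
    n_2d = 0
    for k in range(mask.data.shape[2]):
        _, n = ndimage.label(mask.data[:, :, k], structure=struct2)
        n_2d += int(n)
    volumes = np.array([c.volume_mm3 for c in comps])
    n_1d = int(sum(c.voxel_count for c in comps))
    return ComponentReport(
        n_3d=len(comps),
        n_2d=n_2d,
        n_1d=n_1d,
        mean_volume_mm3=float(volumes.mean()) if len(comps) else None,
        min_volume_mm3=float(volumes.min()) if len(comps) else None,
        max_volume_mm3=float(volumes.max()) if len(comps) else None,
        total_volume_mm3=float(volumes.sum()) if len(comps) else 0.0,
    )


def volume_profile(
    vol: ProbabilityVolume, p_grid: Sequence[float]
) -> dict[float, float]:
    """Total mask volume (mm^3) at each probability threshold.

    Equivalent to ``total_volume(binarize(vol, p))`` per threshold, but
    computed from one sort of the voxel values so a whole threshold grid
    costs a single pass over the volume. Volumes are non-increasing in p.
    """
    p_grid = list(p_grid)
    if not p_grid:
        raise ValueError("empty probability grid")
    for p in p_grid:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability threshold must be in [0, 1], got {p}")
    vals = np.sort(vol.data.ravel())
    n = vals.size
    vv = vol.voxel_volume
    return {
        float(p): float(n - np.searchsorted(vals, p, side="left")) * vv
        for p in p_grid
    }
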