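"""Synthetic CTPA-like probability phantoms and labeled cohorts.

Real probability volumes come from a trained segmentation network on
patient data; neither is needed to exercise the pipeline. The phantoms
planted here emulate the two features the post-processing actually
consumes:

* emboli: ellipsoidal blobs whose interior softmax probability is at
  its peak in the center and tapers radially toward the surface, so
  raising the probability threshold shrinks the measured volume — the
  mechanism threshold calibration exploits;
* distractors: low-peak-probability blobs standing in for typical
  false-positive sources (flow artifacts, veins, low contrast), plus
  sparse sub-threshold background noise.

No anatomical or HU realism is claimed. Every random draw flows from
the spec's seed, so a given spec reproduces byte-identical cohorts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import volumetry
from .volume_io import BinaryMask, ProbabilityVolume, write_volume

__all__ = [
    "Embolus",
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
]

#: fractional probability drop from blob center to surface
DEFAULT_TAPER = 0.15
#: radial exponent of the taper profile (quartic keeps most of the blob
#: above thresholds near the peak)
TAPER_EXPONENT = 4


@dataclass(frozen=True)
class Embolus:
    """An ellipsoidal planted blob.

    ``center`` is in voxel index coordinates (may be fractional),
    ``semi_axes`` in mm. Interior probability is
    ``peak * (1 - taper * r**4)`` with r the normalized ellipsoidal
    radius, so the surface sits at ``peak * (1 - taper)``.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    peak_probability: float
    taper: float = DEFAULT_TAPER

    def __post_init__(self) -> None:
        if not 0.0 < self.peak_probability <= 1.0:
            raise ValueError("peak_probability must be in (0, 1]")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if not 0.0 <= self.taper < 1.0:
            raise ValueError("taper must be in [0, 1)")

    def analytic_volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class PhantomSpec:
    """One synthetic examination."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    emboli: tuple[Embolus, ...] = ()
    distractors: tuple[Embolus, ...] = ()
    noise_density: float = 0.01
    noise_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    case_id: str = "phantom"


def _render_blob(
    prob: np.ndarray, emb: Embolus, spacing: Sequence[float]
) -> np.ndarray:
    """Paint one blob into ``prob`` (in place); return its interior mask."""
    shape = prob.shape
    lo, hi = [], []
    for ax in range(3):
        half = emb.semi_axes[ax] / spacing[ax]
        lo.append(int(np.floor(emb.center[ax] - half)) - 1)
        hi.append(int(np.ceil(emb.center[ax] + half)) + 2)
        if lo[-1] < -1 or hi[-1] > shape[ax] + 1:
            raise ValueError(
                f"embolus at {emb.center} with semi-axes {emb.semi_axes} mm "
                f"exceeds volume bounds {shape}"
            )
    lo = [max(l, 0) for l in lo]
    hi = [min(h, s) for h, s in zip(hi, shape)]
    grids = np.meshgrid(
        *[np.arange(lo[ax], hi[ax]) for ax in range(3)], indexing="ij"
    )
    r2 = sum(
        ((grids[ax] - emb.center[ax]) * spacing[ax] / emb.semi_axes[ax]) ** 2
        for ax in range(3)
    )
    inside = r2 <= 1.0
    r = np.sqrt(np.clip(r2, 0.0, 1.0))
    values = emb.peak_probability * (1.0 - emb.taper * r**TAPER_EXPONENT)
    region = tuple(slice(lo[ax], hi[ax]) for ax in range(3))
    prob[region] = np.where(inside, np.maximum(prob[region], values), prob[region])
    mask = np.zeros(shape, dtype=bool)
    mask[region] = inside
    return mask


def make_phantom(
    spec: PhantomSpec,
) -> tuple[ProbabilityVolume, BinaryMask, list[float]]:
    """Render a phantom probability volume.

    Returns
    -------
    (volume, truth, embolus_volumes)
        ``truth`` is the union of the emboli interiors (distractors and
        noise are excluded — they are not disease). ``embolus_volumes``
        are the voxelized per-embolus volumes in mm^3, measured through
        the same voxel-counting path used everywhere else.
    """
    rng = np.random.default_rng(spec.seed)
    prob = np.zeros(spec.shape, dtype=np.float64)

    # sub-threshold background speckle first, blobs paint over it
    if spec.noise_density > 0:
        speckle = rng.random(spec.shape) < spec.noise_density
        prob[speckle] = rng.uniform(*spec.noise_range, size=int(speckle.sum()))

    voxel_volume = float(np.prod(spec.spacing))
    truth = np.zeros(spec.shape, dtype=bool)
    embolus_volumes: list[float] = []
    for emb in spec.emboli:
        interior = _render_blob(prob, emb, spec.spacing)
        truth |= interior
        embolus_volumes.append(float(interior.sum()) * voxel_volume)
    for d in spec.distractors:
        _render_blob(prob, d, spec.spacing)

    affine = np.diag([*spec.spacing, 1.0])
    vol = ProbabilityVolume(data=prob, affine=affine, case_id=spec.case_id)
    mask = BinaryMask(
        data=truth.astype(np.uint8), affine=affine, case_id=spec.case_id
    )
    return vol, mask, embolus_volumes


@dataclass(frozen=True)
class CohortSpec:
    """A labeled synthetic cohort.

    Positive cases carry one or more emboli with volumes drawn from a
    log-normal distribution (default median 150 mm^3, sigma 0.8,
    clipped to 60-1000 mm^3) at peak probability 0.95. Negatives carry
    only distractors — small blobs (2-10 mm^3) at peak probability 0.8
    — and background noise, spanning with the emboli the volume range
    over which the decision thresholds operate (~10-1000 mm^3).
    """

    n_positive: int = 20
    n_negative: int = 20
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    volume_lognormal: tuple[float, float] = (float(np.log(150.0)), 0.8)
    volume_bounds: tuple[float, float] = (60.0, 1000.0)
    embolus_peak: float = 0.95
    extra_embolus_prob: float = 0.3
    distractor_volume_range: tuple[float, float] = (2.0, 10.0)
    distractor_peak: float = 0.8
    max_distractors: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("case counts must be >= 0")


def _random_embolus(
    rng: np.random.Generator,
    spec: CohortSpec,
    volume_mm3: float,
    peak: float,
) -> Embolus:
    # sphere-equivalent radius, mildly anisotropic axes with fixed product
    r = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratios = np.exp(rng.normal(0.0, 0.15, size=3))
    ratios /= ratios.prod() ** (1.0 / 3.0)
    semi = r * ratios
    center = []
    for ax in range(3):
        margin = semi[ax] / spec.spacing[ax] + 2.0
        hi = spec.shape[ax] - 1 - margin
        if hi <= margin:
            raise ValueError(
                f"embolus of {volume_mm3:.0f} mm^3 does not fit in shape {spec.shape}"
            )
        center.append(float(rng.uniform(margin, hi)))
    return Embolus(
        center=tuple(center),
        semi_axes=tuple(float(s) for s in semi),
        peak_probability=peak,
    )


def _case_spec(rng: np.random.Generator, spec: CohortSpec, positive: bool,
               case_id: str) -> PhantomSpec:
    emboli: list[Embolus] = []
    if positive:
        n_emb = 1 + int(rng.random() < spec.extra_embolus_prob)
        mu, sigma = spec.volume_lognormal
        for _ in range(n_emb):
            v = float(np.clip(rng.lognormal(mu, sigma), *spec.volume_bounds))
            emboli.append(_random_embolus(rng, spec, v, spec.embolus_peak))
    distractors = []
    for _ in range(int(rng.integers(0, spec.max_distractors + 1))):
        v = float(rng.uniform(*spec.distractor_volume_range))
        distractors.append(_random_embolus(rng, spec, v, spec.distractor_peak))
    return PhantomSpec(
        shape=spec.shape,
        spacing=spec.spacing,
        emboli=tuple(emboli),
        distractors=tuple(distractors),
        seed=int(rng.integers(0, 2**31 - 1)),
        case_id=case_id,
    )


def make_cohort(
    spec: CohortSpec, out_dir: str | os.PathLike | None = None
) -> tuple[pd.DataFrame, dict[str, ProbabilityVolume], pd.DataFrame]:
    """Generate a labeled cohort of phantom examinations.

    Returns
    -------
    (manifest, volumes, truth)
        ``manifest`` has columns case_id, path, label, annotation_path;
        ``volumes`` maps case_id to the in-memory probability volume;
        ``truth`` records each case's ground-truth total volume (mm^3,
        measured from the generated annotation mask) and embolus count.
        With ``out_dir`` set, volumes, annotation masks, manifest.csv
        and truth.csv are also written there; the run is deterministic
        under the spec seed either way.
    """
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        if not out.parent.exists():
            raise FileNotFoundError(f"cannot create {out}: parent missing")
        out.mkdir(exist_ok=True)

    manifest_rows, truth_rows = [], []
    volumes: dict[str, ProbabilityVolume] = {}
    labels = [1] * spec.n_positive + [0] * spec.n_negative
    for i, label in enumerate(labels):
        case_id = f"case{i:04d}"
        pspec = _case_spec(rng, spec, positive=bool(label), case_id=case_id)
        vol, mask, emb_volumes = make_phantom(pspec)
        gt_volume = volumetry.total_volume(mask)
        path, ann_path = "", ""
        if out is not None:
            path = str(out / f"{case_id}_prob.nii.gz")
            ann_path = str(out / f"{case_id}_annot.nii.gz")
            write_volume(vol, path)
            write_volume(mask, ann_path)
        volumes[case_id] = vol
        manifest_rows.append(
            {"case_id": case_id, "path": path, "label": label,
             "annotation_path": ann_path}
        )
        truth_rows.append(
            {"case_id": case_id, "label": label,
             "gt_volume_mm3": gt_volume, "n_emboli": len(emb_volumes)}
        )
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    return manifest, volumes, truth
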