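"""Cohort manifests, the small-PE exclusion filter, and fold splitting.

A cohort manifest is a CSV with one row per examination: ``case_id``,
``path`` (probability volume or mask NIfTI), ``label`` (1 PE positive,
0 negative), optional ``annotation_path`` (ground-truth mask) and an
optional ``dataset`` tag for stratified reporting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import volumetry
from .volume_io import BinaryMask, read_volume

__all__ = [
    "read_manifest",
    "validate_manifest",
    "apply_small_pe_exclusion",
    "split_train_validation",
    "SMALL_PE_CUTOFF_MM3",
]

#: default ground-truth volume (mm^3) below which a positive exam is excluded;
#: roughly the volume of a cylinder 4 mm in diameter and height
SMALL_PE_CUTOFF_MM3 = 50.0

_REQUIRED = ("case_id", "path", "label")


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Check manifest invariants: required columns, unique case ids,
    labels in {0, 1}."""
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df["case_id"].duplicated().any():
        dups = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case_ids in manifest: {dups[:5]}")
    labels = set(df["label"].unique().tolist())
    if not labels <= {0, 1}:
        raise ValueError(f"labels must be 0/1, got {sorted(labels)}")
    return df


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV."""
    df = pd.read_csv(path, dtype={"case_id": str})
    df["label"] = df["label"].astype(int)
    return validate_manifest(df)


def _annotation_volume(row) -> float:
    mask = read_volume(row.annotation_path, kind="mask")
    return volumetry.total_volume(mask)


def apply_small_pe_exclusion(
    manifest: pd.DataFrame,
    annotation_volumes: Mapping[str, float] | None = None,
    cutoff: float = SMALL_PE_CUTOFF_MM3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop PE-positive cases whose ground-truth embolus volume is below
    the cutoff.

    Very small emboli are subject to high inter-observer variability and
    debatable clinical relevance, so positives with total annotated
    volume strictly less than ``cutoff`` mm^3 are removed from the
    evaluation cohort. Negatives are never touched.

    Parameters
    ----------
    manifest : DataFrame
        Validated cohort manifest. Positive rows need either an entry in
        ``annotation_volumes`` or an ``annotation_path`` column from
        which the ground-truth mask volume is computed (with the same
        volumetry path used for predictions).
    annotation_volumes : mapping, optional
        Precomputed ``case_id -> ground-truth volume mm^3``.
    cutoff : float
        Exclusion threshold in mm^3 (strict ``<``).

    Returns
    -------
    (kept, report)
        ``kept`` is the filtered manifest. ``report`` lists every
        positive case with its ground-truth volume and an ``excluded``
        flag; positives whose volume cannot be resolved are excluded and
        flagged ``unresolvable`` rather than silently kept.
    """
    validate_manifest(manifest)
    rows = []
    keep_ids = set(manifest.loc[manifest["label"] == 0, "case_id"])
    for row in manifest[manifest["label"] == 1].itertuples(index=False):
        cid = str(row.case_id)
        vol: float | None = None
        if annotation_volumes is not None and cid in annotation_volumes:
            vol = float(annotation_volumes[cid])
        elif getattr(row, "annotation_path", None) and not (
            isinstance(getattr(row, "annotation_path"), float)
            and np.isnan(getattr(row, "annotation_path"))
        ):
            try:
                vol = _annotation_volume(row)
            except Exception:
                vol = None
        if vol is None:
            rows.append(
                {"case_id": cid, "gt_volume_mm3": np.nan, "excluded": True,
                 "reason": "unresolvable"}
            )
            continue
        excluded = vol < cutoff
        rows.append(
            {"case_id": cid, "gt_volume_mm3": vol, "excluded": excluded,
             "reason": "small_pe" if excluded else ""}
        )
        if not excluded:
            keep_ids.add(cid)
    report = pd.DataFrame(
        rows, columns=["case_id", "gt_volume_mm3", "excluded", "reason"]
    )
    kept = manifest[manifest["case_id"].isin(keep_ids)].reset_index(drop=True)
    return kept, report


def split_train_validation(
    manifest: pd.DataFrame, folds: int = 5, seed: int = 0
) -> pd.Series:
    """Assign cases to cross-validation folds.

    Folds are disjoint, cover the cohort, differ in size by at most one,
    and are deterministic under the seed. Returns a Series of fold
    indices (0-based) aligned with the manifest.
    """
    if folds < 2:
        raise ValueError(f"need at least 2 folds, got {folds}")
    n = len(manifest)
    if n < folds:
        raise ValueError(f"cannot split {n} cases into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    # block sizes differ by <= 1: first (n % folds) folds get the extra case
    sizes = [n // folds + (1 if i < n % folds else 0) for i in range(folds)]
    start = 0
    for fold, size in enumerate(sizes):
        assignment[perm[start : start + size]] = fold
        start += size
    return pd.Series(assignment, index=manifest.index, name="fold")
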