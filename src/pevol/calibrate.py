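"""Operating-point calibration by grid search over (probability, volume)
thresholds.

The calibrator is shaped like a statsmodels model: construct it from a
cohort (probability volumes plus ground-truth labels, or precomputed
volume profiles), call :meth:`ThresholdCalibrator.fit`, and receive a
:class:`CalibrationResult` carrying the full per-grid-point metric
table, the two selected operating points, and a ``summary()``.

The default grid is softmax thresholds 0.75-0.95 in steps of 0.05
crossed with volume thresholds 0-200 mm^3 in steps of 10 (105 points).
Strategy 1 is the MCC argmax (best sensitivity/specificity trade-off);
strategy 2 is the specificity argmax, optionally subject to a
sensitivity floor. Ties are broken toward higher sensitivity, then
lower volume threshold, then lower probability threshold — the
clinically safer, simpler operating point.

Volume profiles are computed once per (case, p); the volume-threshold
sweep then costs no further image passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import volumetry
from .classify import AtomicRule, StrategyConfig
from .metrics import ConfusionMatrix, mcc as _mcc
from .volume_io import ProbabilityVolume

__all__ = [
    "GridSpec",
    "ThresholdCalibrator",
    "CalibrationResult",
    "grid_search",
    "select_strategy1",
    "select_strategy2",
]


@dataclass(frozen=True)
class GridSpec:
    """The calibration grid: softmax thresholds x volume thresholds (mm^3)."""

    p_values: tuple[float, ...] = (0.75, 0.80, 0.85, 0.90, 0.95)
    v_values: tuple[float, ...] = tuple(float(v) for v in range(0, 201, 10))

    def __post_init__(self) -> None:
        if not self.p_values or not self.v_values:
            raise ValueError("grid must contain at least one p and one V value")
        for p in self.p_values:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"grid p must be in [0, 1], got {p}")
        for v in self.v_values:
            if v < 0:
                raise ValueError(f"grid V must be >= 0, got {v}")

    @property
    def size(self) -> int:
        return len(self.p_values) * len(self.v_values)


def _metric_table(
    profiles: Sequence[Mapping[float, float]],
    labels: Sequence[int],
    grid: GridSpec,
) -> pd.DataFrame:
    labels_arr = np.asarray(labels, dtype=int)
    n_pos = int((labels_arr == 1).sum())
    n_neg = int((labels_arr == 0).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise ValueError(f"calibration cohort has no {missing} cases")
    rows = []
    v_arr = np.asarray(grid.v_values, dtype=float)
    for p in grid.p_values:
        scores = np.array([prof[p] for prof in profiles], dtype=float)
        pred = scores[:, None] > v_arr[None, :]  # (cases, V)
        pos = labels_arr == 1
        tp = pred[pos].sum(axis=0)
        fp = pred[~pos].sum(axis=0)
        for j, V in enumerate(grid.v_values):
            cm = ConfusionMatrix(
                tp=int(tp[j]),
                fp=int(fp[j]),
                tn=n_neg - int(fp[j]),
                fn=n_pos - int(tp[j]),
            )
            rows.append(
                {
                    "p": float(p),
                    "V": float(V),
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "tn": cm.tn,
                    "fn": cm.fn,
                    "sensitivity": cm.tp / n_pos,
                    "specificity": cm.tn / n_neg,
                    "accuracy": (cm.tp + cm.tn) / cm.n,
                    "mcc": _mcc(cm),
                }
            )
    return pd.DataFrame(rows)


def _pick(table: pd.DataFrame, objective: str) -> tuple[float, float]:
    """Argmax of ``objective`` with deterministic tie-breaks:
    higher sensitivity, then lower V, then lower p."""
    if len(table) == 0:
        raise ValueError("empty metric table")
    ordered = table.sort_values(
        by=[objective, "sensitivity", "V", "p"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    best = ordered.iloc[0]
    return float(best["p"]), float(best["V"])


def select_strategy1(table: pd.DataFrame) -> tuple[float, float]:
    """Operating point with maximal MCC (best sens/spec trade-off)."""
    return _pick(table, "mcc")


def select_strategy2(
    table: pd.DataFrame, min_sensitivity: float = 0.0
) -> tuple[float, float]:
    """Operating point with maximal specificity.

    ``min_sensitivity`` excludes degenerate all-negative rules when a
    floor is wanted; the default 0 keeps the unconstrained reading.
    """
    eligible = table[table["sensitivity"] >= min_sensitivity]
    if len(eligible) == 0:
        raise ValueError(
            f"no grid point reaches sensitivity >= {min_sensitivity}"
        )
    return _pick(eligible, "specificity")


@dataclass
class CalibrationResult:
    """Fitted operating points plus the full grid-search trace."""

    table: pd.DataFrame
    strategy1: StrategyConfig
    strategy2: StrategyConfig
    grid: GridSpec
    n_cases: int
    n_positive: int
    min_sensitivity: float = 0.0

    def _row(self, p: float, V: float) -> pd.Series:
        m = self.table[(self.table["p"] == p) & (self.table["V"] == V)]
        return m.iloc[0]

    @property
    def strategy1_point(self) -> tuple[float, float]:
        r = self.strategy1.rules[0]
        return r.p, r.V

    @property
    def strategy2_point(self) -> tuple[float, float]:
        r = self.strategy2.rules[0]
        return r.p, r.V

    def summary(self) -> str:
        lines = [
            "Threshold calibration (grid search)",
            "=" * 51,
            f"cases: {self.n_cases} ({self.n_positive} PE positive, "
            f"{self.n_cases - self.n_positive} negative)",
            f"grid: {len(self.grid.p_values)} softmax thresholds x "
            f"{len(self.grid.v_values)} volume thresholds "
            f"= {self.grid.size} points",
            "",
            f"{'strategy':<12}{'p':>6}{'V mm^3':>9}{'MCC':>8}"
            f"{'sens':>8}{'spec':>8}",
            "-" * 51,
        ]
        for name, (p, V) in (
            ("strategy1", self.strategy1_point),
            ("strategy2", self.strategy2_point),
        ):
            row = self._row(p, V)
            lines.append(
                f"{name:<12}{p:>6.2f}{V:>9.0f}{row['mcc']:>8.3f}"
                f"{row['sensitivity']:>8.3f}{row['specificity']:>8.3f}"
            )
        lines.append("-" * 51)
        lines.append(
            "strategy1: MCC argmax; strategy2: specificity argmax"
            + (
                f" (sensitivity >= {self.min_sensitivity:g})"
                if self.min_sensitivity > 0
                else ""
            )
        )
        return "\n".join(lines)


class ThresholdCalibrator:
    """Grid-search calibrator for patient-level PE decision thresholds.

    Parameters
    ----------
    profiles : sequence of mappings
        Per-case volume profiles ``{p: total volume mm^3}`` covering at
        least the grid's probability thresholds.
    labels : sequence of int
        Ground-truth PE labels (1 positive, 0 negative), parallel to
        ``profiles``. Both classes must be present.
    case_ids : sequence of str, optional
    """

    def __init__(
        self,
        profiles: Sequence[Mapping[float, float]],
        labels: Sequence[int],
        case_ids: Sequence[str] | None = None,
    ) -> None:
        if len(profiles) != len(labels):
            raise ValueError("profiles and labels lengths differ")
        self.profiles = list(profiles)
        self.labels = [int(l) for l in labels]
        self.case_ids = (
            list(case_ids) if case_ids is not None else [str(i) for i in range(len(labels))]
        )

    @classmethod
    def from_volumes(
        cls,
        volumes: Sequence[ProbabilityVolume],
        labels: Sequence[int],
        grid: GridSpec | None = None,
    ) -> "ThresholdCalibrator":
        """Build the calibrator from probability volumes, computing each
        case's volume profile once over the grid's p values."""
        grid = grid or GridSpec()
        profiles = [volumetry.volume_profile(v, grid.p_values) for v in volumes]
        return cls(profiles, labels, case_ids=[v.case_id for v in volumes])

    def fit(
        self,
        grid: GridSpec | None = None,
        min_sensitivity: float = 0.0,
    ) -> CalibrationResult:
        grid = grid or GridSpec()
        table = _metric_table(self.profiles, self.labels, grid)
        p1, V1 = select_strategy1(table)
        p2, V2 = select_strategy2(table, min_sensitivity)
        n_pos = sum(self.labels)
        return CalibrationResult(
            table=table,
            strategy1=StrategyConfig("strategy1", (AtomicRule(p=p1, V=V1),)),
            strategy2=StrategyConfig("strategy2", (AtomicRule(p=p2, V=V2),)),
            grid=grid,
            n_cases=len(self.labels),
            n_positive=n_pos,
            min_sensitivity=min_sensitivity,
        )


def grid_search(
    profiles: Sequence[Mapping[float, float]],
    labels: Sequence[int],
    grid: GridSpec | None = None,
    min_sensitivity: float = 0.0,
) -> CalibrationResult:
    """Functional wrapper around :class:`ThresholdCalibrator`."""
    return ThresholdCalibrator(profiles, labels).fit(
        grid=grid, min_sensitivity=min_sensitivity
    )
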