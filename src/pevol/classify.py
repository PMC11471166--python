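"""Patient-level PE / non-PE decisions from probability volumes.

A strategy is a set of atomic rules combined with ANY or ALL. An atomic
rule binarizes the probability volume at a softmax threshold ``p`` and
fires when the predicted embolus volume strictly exceeds ``V`` mm^3 —
either the total volume or (with per-component scope) the volume of
some single connected component. The strict ``>`` makes ``V = 0`` mean
"any predicted voxel at all".

Two named operating points ship as defaults: strategy 1 targets the
best sensitivity/specificity trade-off (volume threshold 20 mm^3) and
strategy 2 the highest specificity (50 mm^3). Their probability
thresholds sit mid-grid and are meant to be replaced by the output of
:mod:`pevol.calibrate` on a cohort of interest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import volumetry
from .volume_io import ProbabilityVolume, read_volume

__all__ = [
    "AtomicRule",
    "StrategyConfig",
    "CaseRecord",
    "classify_case",
    "classify_cohort",
    "baseline_no_postprocessing",
    "STRATEGY1",
    "STRATEGY2",
    "BASELINE_P",
]

logger = logging.getLogger(__name__)

#: probability threshold of the raw argmax mask of a two-class softmax
BASELINE_P = 0.5


@dataclass(frozen=True)
class AtomicRule:
    """Fires when volume above probability threshold ``p`` exceeds ``V`` mm^3."""

    p: float
    V: float
    scope: str = "total"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"rule probability must be in [0, 1], got {self.p}")
        if self.V < 0:
            raise ValueError(f"rule volume threshold must be >= 0, got {self.V}")
        if self.scope not in ("total", "per_component"):
            raise ValueError(f"scope must be 'total' or 'per_component', got {self.scope!r}")

    def evaluate(self, vol: ProbabilityVolume) -> bool:
        mask = volumetry.binarize(vol, self.p)
        if self.scope == "total":
            return volumetry.total_volume(mask) > self.V
        comps = volumetry.label_components_3d(mask)
        return any(c.volume_mm3 > self.V for c in comps)


@dataclass(frozen=True)
class StrategyConfig:
    """A named patient-level classification rule set."""

    name: str
    rules: tuple[AtomicRule, ...]
    combiner: str = "ANY"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        if not self.rules:
            raise ValueError("strategy needs at least one rule")
        if self.combiner not in ("ANY", "ALL"):
            raise ValueError(f"combiner must be ANY or ALL, got {self.combiner!r}")

    @property
    def reference_p(self) -> float:
        """Probability threshold whose total volume serves as the ROC score."""
        return self.rules[0].p

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "combiner": self.combiner,
                "rules": [
                    {"p": r.p, "V": r.V, "scope": r.scope} for r in self.rules
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StrategyConfig":
        try:
            obj = json.loads(text)
            rules = tuple(
                AtomicRule(p=float(r["p"]), V=float(r["V"]), scope=r.get("scope", "total"))
                for r in obj["rules"]
            )
            return cls(
                name=str(obj.get("name", "custom")),
                rules=rules,
                combiner=str(obj.get("combiner", "ANY")),
            )
        except (KeyError, TypeError, json.JSONDecodeError) as e:
            raise ValueError(f"invalid strategy JSON: {e}") from e


STRATEGY1 = StrategyConfig("strategy1", (AtomicRule(p=0.85, V=20.0),))
STRATEGY2 = StrategyConfig("strategy2", (AtomicRule(p=0.90, V=50.0),))


@dataclass
class CaseRecord:
    """One examination's decision and volume evidence."""

    case_id: str
    label: int | None
    predicted: int
    score: float
    volumes: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "case_id": self.case_id,
            "label": self.label,
            "predicted": self.predicted,
            "score_mm3": self.score,
        }
        for p, v in sorted(self.volumes.items()):
            d[f"volume_mm3_p{p:g}"] = v
        return d


def classify_case(
    vol: ProbabilityVolume,
    strategy: StrategyConfig,
    label: int | None = None,
) -> CaseRecord:
    """Apply a strategy to one probability volume.

    The decision is the strategy's combiner over its atomic rules; the
    ROC score is the total volume at the strategy's first rule's
    probability threshold.
    """
    verdicts = [rule.evaluate(vol) for rule in strategy.rules]
    predicted = any(verdicts) if strategy.combiner == "ANY" else all(verdicts)
    p_values = sorted({rule.p for rule in strategy.rules})
    volumes = volumetry.volume_profile(vol, p_values)
    return CaseRecord(
        case_id=vol.case_id,
        label=label,
        predicted=int(predicted),
        score=volumes[strategy.reference_p],
        volumes=volumes,
    )


def baseline_no_postprocessing(
    vol: ProbabilityVolume, V: float, label: int | None = None
) -> CaseRecord:
    """Classification without post-processing: the raw argmax mask
    (probability 0.5 for a two-class softmax) thresholded on total
    volume only."""
    if V < 0:
        raise ValueError(f"volume threshold must be >= 0, got {V}")
    strategy = StrategyConfig("baseline", (AtomicRule(p=BASELINE_P, V=V),))
    return classify_case(vol, strategy, label=label)


def classify_cohort(
    manifest: pd.DataFrame,
    strategy: StrategyConfig,
    volumes: Mapping[str, ProbabilityVolume] | None = None,
) -> tuple[list[CaseRecord], list[dict]]:
    """Classify every case in a cohort manifest.

    Parameters
    ----------
    manifest : DataFrame
        Columns ``case_id``, ``label``, and ``path`` (NIfTI probability
        volume). ``path`` is ignored for cases supplied via ``volumes``.
    strategy : StrategyConfig
    volumes : mapping, optional
        In-memory ``case_id -> ProbabilityVolume`` overrides, for
        cohorts that were never written to disk.

    Returns
    -------
    (records, skipped)
        One record per successfully classified case; per-case failures
        are logged and collected in ``skipped`` (case_id + error) so one
        unreadable file does not abort a cohort run.
    """
    if len(manifest) == 0:
        raise ValueError("empty cohort manifest")
    records: list[CaseRecord] = []
    skipped: list[dict] = []
    for row in manifest.itertuples(index=False):
        case_id = str(row.case_id)
        try:
            if volumes is not None and case_id in volumes:
                vol = volumes[case_id]
            else:
                vol = read_volume(row.path, kind="probability")
                vol.case_id = case_id
            rec = classify_case(vol, strategy, label=int(row.label))
            rec.case_id = case_id
            records.append(rec)
        except Exception as e:  # noqa: BLE001 - per-case isolation is the contract
            logger.warning("skipping case %s: %s", case_id, e)
            skipped.append({"case_id": case_id, "error": str(e)})
    return records, skipped
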