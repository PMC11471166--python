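"""Published reference confusion matrices for the pipeline's operating
points.

These are the patient-level TP/FP/TN/FN counts reported for a trained
nnU-Net-based PE classifier on its internal CTPA cohort (128 positive /
551 negative after small-PE exclusion) and the FUMPE (32/2) and RSPECT
(385/385) external cohorts, with and without threshold post-processing.
They serve as worked examples for the statistics in :mod:`pevol.metrics`:
every published percentage (sensitivity, specificity, accuracy, MCC,
Wilson intervals) is recomputable from these counts.

``baseline`` is volume thresholding of the raw argmax mask at 20 mm^3
with no probability post-processing; ``strategy1`` is the best
sensitivity/specificity trade-off (volume threshold 20 mm^3);
``strategy2`` is the highest-specificity operating point (50 mm^3).
Strategy-2 per-cohort counts are reconstructed exactly from the
published sensitivity/specificity percentages and the (fixed) class
sizes; each reconstruction is the unique integer count consistent with
the printed one-decimal percentage.

The ``*_combined`` entries pool the cohorts the way the published
combined evaluation does: all negatives (938) but only the external
positives (417) enter the pool.
"""

from __future__ import annotations

from .metrics import ConfusionMatrix

__all__ = ["REPORTED", "COHORT_SIZES"]

COHORT_SIZES = {
    "internal": {"positive": 128, "negative": 551},
    "fumpe": {"positive": 32, "negative": 2},
    "rspect": {"positive": 385, "negative": 385},
}

REPORTED: dict[str, ConfusionMatrix] = {
    # no post-processing, volume threshold 20 mm^3
    "internal_baseline": ConfusionMatrix(tp=128, fp=118, tn=433, fn=0),
    "fumpe_baseline": ConfusionMatrix(tp=32, fp=0, tn=2, fn=0),
    "rspect_baseline": ConfusionMatrix(tp=385, fp=116, tn=269, fn=0),
    # strategy 1: best sensitivity/specificity trade-off, 20 mm^3
    "internal_strategy1": ConfusionMatrix(tp=123, fp=30, tn=521, fn=5),
    "fumpe_strategy1": ConfusionMatrix(tp=31, fp=0, tn=2, fn=1),
    "rspect_strategy1": ConfusionMatrix(tp=379, fp=39, tn=346, fn=6),
    # strategy 2: highest specificity, 50 mm^3 (counts reconstructed from
    # published percentages: internal sens 87.5/spec 96.7, FUMPE 90.6/100,
    # RSPECT 96.6/96.9)
    "internal_strategy2": ConfusionMatrix(tp=112, fp=18, tn=533, fn=16),
    "fumpe_strategy2": ConfusionMatrix(tp=29, fp=0, tn=2, fn=3),
    "rspect_strategy2": ConfusionMatrix(tp=372, fp=12, tn=373, fn=13),
}

# combined pools: external positives (FUMPE + RSPECT), all negatives
REPORTED["combined_strategy1"] = (
    REPORTED["fumpe_strategy1"]
    + REPORTED["rspect_strategy1"]
    + ConfusionMatrix(tp=0, fp=30, tn=521, fn=0)  # internal negative arm
)
REPORTED["combined_strategy2"] = (
    REPORTED["fumpe_strategy2"]
    + REPORTED["rspect_strategy2"]
    + ConfusionMatrix(tp=0, fp=18, tn=533, fn=0)  # internal negative arm
)
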