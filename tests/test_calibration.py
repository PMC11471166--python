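"""Grid-search calibration: selection rules, tie-breaks, and
compositional equivalence with per-point cohort classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pevol import (
    AtomicRule,
    GridSpec,
    StrategyConfig,
    ThresholdCalibrator,
    classify_case,
    confusion_matrix,
    grid_search,
    mcc,
    select_strategy1,
    select_strategy2,
)
from pevol.synthetic import CohortSpec, make_cohort
from pevol.volumetry import volume_profile


@pytest.fixture(scope="module")
def separable_cohort():
    manifest, volumes, _ = make_cohort(
        CohortSpec(n_positive=10, n_negative=10, seed=5)
    )
    vols = [volumes[c] for c in manifest["case_id"]]
    return vols, manifest["label"].tolist()


class TestGridSpec:
    def test_default_grid_has_105_points(self):
        grid = GridSpec()
        assert len(grid.p_values) == 5
        assert len(grid.v_values) == 21
        assert grid.size == 105

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(p_values=(1.2,))
        with pytest.raises(ValueError):
            GridSpec(v_values=())


class TestGridSearch:
    def test_separable_cohort_reaches_perfect_mcc(self, separable_cohort):
        vols, labels = separable_cohort
        result = ThresholdCalibrator.from_volumes(vols, labels).fit()
        assert result.table["mcc"].max() == pytest.approx(1.0)
        p1, V1 = result.strategy1_point
        assert p1 in GridSpec().p_values and V1 in GridSpec().v_values

    def test_two_case_separable_cohort(self):
        profiles = [{0.75: 100.0, 0.8: 90.0, 0.85: 80.0, 0.9: 60.0, 0.95: 0.0},
                    {0.75: 5.0, 0.8: 0.0, 0.85: 0.0, 0.9: 0.0, 0.95: 0.0}]
        result = grid_search(profiles, [1, 0])
        row = result.table[
            (result.table["p"] == result.strategy1_point[0])
            & (result.table["V"] == result.strategy1_point[1])
        ].iloc[0]
        assert row["mcc"] == pytest.approx(1.0)

    def test_single_class_cohort_rejected(self, separable_cohort):
        vols, _ = separable_cohort
        with pytest.raises(ValueError, match="no negative"):
            ThresholdCalibrator.from_volumes(vols, [1] * len(vols)).fit()
        with pytest.raises(ValueError, match="no positive"):
            ThresholdCalibrator.from_volumes(vols, [0] * len(vols)).fit()

    def test_table_matches_compositional_oracle(self, separable_cohort):
        """Every grid row must equal classify-then-tally at that point."""
        vols, labels = separable_cohort
        grid = GridSpec(p_values=(0.75, 0.9), v_values=(0.0, 30.0, 100.0))
        result = ThresholdCalibrator.from_volumes(vols, labels, grid).fit(grid=grid)
        for _, row in result.table.iterrows():
            strat = StrategyConfig("pt", (AtomicRule(p=row["p"], V=row["V"]),))
            records = [
                classify_case(v, strat, label=l) for v, l in zip(vols, labels)
            ]
            cm = confusion_matrix(records)
            assert (cm.tp, cm.fp, cm.tn, cm.fn) == (
                row["tp"], row["fp"], row["tn"], row["fn"]
            )
            assert row["mcc"] == pytest.approx(mcc(cm))

    def test_profiles_computed_once_per_case_and_p(self, separable_cohort, monkeypatch):
        vols, labels = separable_cohort
        calls = []
        import pevol.calibrate as cal_mod

        original = cal_mod.volumetry.volume_profile

        def counting(vol, p_grid):
            calls.append(vol.case_id)
            return original(vol, p_grid)

        monkeypatch.setattr(cal_mod.volumetry, "volume_profile", counting)
        ThresholdCalibrator.from_volumes(vols, labels).fit()
        assert len(calls) == len(vols)  # one profile per case, reused over all V


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=["p", "V", "tp", "fp", "tn", "fn", "sensitivity",
                 "specificity", "accuracy", "mcc"],
    )


class TestSelection:
    def test_unique_mcc_argmax(self):
        t = _table([
            (0.75, 0, 1, 1, 1, 1, 0.5, 0.5, 0.5, 0.0),
            (0.80, 10, 2, 0, 2, 0, 1.0, 1.0, 1.0, 1.0),
        ])
        assert select_strategy1(t) == (0.80, 10.0)

    def test_mcc_tie_broken_by_sensitivity(self):
        t = _table([
            (0.75, 0, 1, 0, 2, 1, 0.5, 1.0, 0.75, 0.577),
            (0.80, 10, 2, 1, 1, 0, 1.0, 0.5, 0.75, 0.577),
        ])
        assert select_strategy1(t) == (0.80, 10.0)

    def test_full_tie_prefers_lowest_V_then_p(self):
        rows = [
            (p, V, 2, 0, 2, 0, 1.0, 1.0, 1.0, 1.0)
            for p in (0.75, 0.80)
            for V in (0.0, 10.0)
        ]
        assert select_strategy1(_table(rows)) == (0.75, 0.0)
        assert select_strategy2(_table(rows)) == (0.75, 0.0)

    def test_strategy2_specificity_argmax_with_floor(self):
        t = _table([
            (0.75, 0, 4, 2, 2, 0, 1.0, 0.5, 0.75, 0.577),
            (0.75, 50, 3, 0, 4, 1, 0.75, 1.0, 0.875, 0.756),
            (0.75, 100, 1, 0, 4, 3, 0.25, 1.0, 0.625, 0.378),
        ])
        assert select_strategy2(t) == (0.75, 50.0)
        assert select_strategy2(t, min_sensitivity=0.9) == (0.75, 0.0)
        with pytest.raises(ValueError, match="sensitivity"):
            select_strategy2(t, min_sensitivity=1.5)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_strategy1(_table([]))

    def test_selection_matches_exhaustive_scan(self, separable_cohort, rng):
        """Selections must agree with a brute-force scan of the table
        under the documented tie-break order."""
        vols, labels = separable_cohort
        # perturb labels to create a non-separable, tie-rich table
        noisy = list(labels)
        flip = rng.choice(len(noisy), size=4, replace=False)
        for i in flip:
            noisy[i] = 1 - noisy[i]
        result = ThresholdCalibrator.from_volumes(vols, noisy).fit()
        t = result.table

        def scan(objective):
            best = None
            for _, row in t.iterrows():
                key = (-row[objective], -row["sensitivity"], row["V"], row["p"])
                if best is None or key < best[0]:
                    best = (key, (row["p"], row["V"]))
            return best[1]

        assert result.strategy1_point == scan("mcc")
        assert result.strategy2_point == scan("specificity")

    def test_strategy2_specificity_at_least_strategy1(self, separable_cohort):
        vols, labels = separable_cohort
        result = ThresholdCalibrator.from_volumes(vols, labels).fit()
        t = result.table

        def spec_at(point):
            p, V = point
            return t[(t["p"] == p) & (t["V"] == V)].iloc[0]["specificity"]

        assert spec_at(result.strategy2_point) >= spec_at(result.strategy1_point)


class TestSummary:
    def test_summary_reports_selected_points(self, separable_cohort):
        vols, labels = separable_cohort
        result = ThresholdCalibrator.from_volumes(vols, labels).fit()
        text = result.summary()
        assert "strategy1" in text and "strategy2" in text
        assert f"{result.n_cases}" in text
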