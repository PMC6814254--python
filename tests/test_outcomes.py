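"""Outcome derivation: counts, MME day grid, ICD-10 flags, panel assembly."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_rx
from coprescribenet.outcomes import (
    CodeDictionary,
    assemble_panel,
    count_prescribers,
    count_rx,
    flag_codes,
    max_daily_mme,
    restrict_high_risk,
)


def make_dx(rows):
    return pd.DataFrame(rows, columns=["patient_id", "quarter", "icd10_code"])


def day_grid_oracle(fills, quarter_days=90):
    """Brute-force per-day accumulation: loop every day, sum active fills."""
    best = 0.0
    for day in range(quarter_days):
        tot = sum(
            dose * fac
            for (d0, supply, dose, fac) in fills
            if d0 <= day < d0 + supply
        )
        best = max(best, tot)
    return best


class TestCounts:
    def test_no_records_zero(self):
        rx = make_rx([("P1", "D1", 0)])
        assert count_rx(rx, "P2", 0) == 0
        assert count_prescribers(rx, "P1", 1) == 0

    def test_fills_not_prescribers(self):
        rx = make_rx([("P1", "D1", 2), ("P1", "D1", 2), ("P1", "D2", 2)])
        assert count_rx(rx, "P1", 2) == 3
        assert count_prescribers(rx, "P1", 2) == 2

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(3)
        rx = make_rx(
            [(f"P{rng.integers(10)}", f"D{rng.integers(5)}", int(rng.integers(3)))
             for _ in range(200)]
        )
        for p in rx["patient_id"].unique()[:5]:
            for q in range(3):
                sub = rx[(rx["patient_id"] == p) & (rx["quarter"] == q)]
                assert count_rx(rx, p, q) == len(sub)
                assert count_prescribers(rx, p, q) == sub["prescriber_id"].nunique()


class TestMaxDailyMME:
    def test_single_fill_arithmetic(self):
        rx = make_rx([("P1", "D1", 0, 30.0, 1.5)])
        val, flag = max_daily_mme(rx, "P1", 0)
        assert val == 45.0 and flag == 0

    def test_threshold_is_strict_at_90(self):
        rx = make_rx([("P1", "D1", 0, 60.0, 1.0), ("P1", "D2", 0, 20.0, 1.5)])
        val, flag = max_daily_mme(rx, "P1", 0)
        assert val == 90.0 and flag == 0
        rx2 = make_rx([("P1", "D1", 0, 90.01, 1.0)])
        val2, flag2 = max_daily_mme(rx2, "P1", 0)
        assert val2 == 90.01 and flag2 == 1

    def test_non_overlapping_fills_do_not_sum(self):
        rx = make_rx(
            [("P1", "D1", 0, 60.0, 1.0, 0, 10), ("P1", "D2", 0, 60.0, 1.0, 50, 10)]
        )
        val, flag = max_daily_mme(rx, "P1", 0)
        assert val == 60.0 and flag == 0

    def test_random_overlaps_match_day_grid_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = rng.integers(1, 8)
            fills = [
                (int(rng.integers(0, 90)), int(rng.integers(5, 45)),
                 float(rng.uniform(5, 60)), float(rng.choice([0.15, 1.0, 1.5, 2.4])))
                for _ in range(n)
            ]
            rx = make_rx(
                [("P1", f"D{i}", 0, dose, fac, d0, sup)
                 for i, (d0, sup, dose, fac) in enumerate(fills)]
            )
            val, flag = max_daily_mme(rx, "P1", 0)
            oracle = day_grid_oracle(fills)
            assert abs(val - oracle) < 1e-9
            assert flag == int(oracle > 90.0)

    def test_mat_fills_excluded_and_bad_dose_raises(self):
        rx = make_rx([("P1", "D1", 0, 500.0, 1.0, 0, 30, 1)])
        assert max_daily_mme(rx, "P1", 0) == (0.0, 0)
        bad = make_rx([("P1", "D1", 0, -5.0, 1.0)])
        with pytest.raises(ValueError, match="nonpositive"):
            max_daily_mme(bad, "P1", 0)

    def test_monotone_in_every_dose(self):
        rng = np.random.default_rng(15)
        rx = make_rx(
            [("P1", f"D{i}", 0, float(rng.uniform(10, 40)), 1.0,
              int(rng.integers(0, 60)), 30) for i in range(4)]
        )
        base, _ = max_daily_mme(rx, "P1", 0)
        for i in range(4):
            bumped = rx.copy()
            bumped.loc[i, "daily_dose_mg"] += 10.0
            val, _ = max_daily_mme(bumped, "P1", 0)
            assert val >= base


class TestFlagCodes:
    def test_opioid_poisoning_code_hits_both_measures(self):
        dx = make_dx([("P1", 0, "T40.2X1A")])
        assert flag_codes(dx, "P1", 0, which="overdose_opioid_only") == 1
        assert flag_codes(dx, "P1", 0, which="overdose_inclusive") == 1

    def test_unspecified_poisoning_only_in_inclusive_measure(self):
        dx = make_dx([("P1", 0, "T50.901A")])
        assert flag_codes(dx, "P1", 0, which="overdose_opioid_only") == 0
        assert flag_codes(dx, "P1", 0, which="overdose_inclusive") == 1

    def test_intentional_poisoning_does_not_flag(self):
        dx = make_dx([("P1", 0, "T40.2X2A")])  # intent '2' = self-harm
        assert flag_codes(dx, "P1", 0, which="overdose_inclusive") == 0

    def test_oud_codes(self):
        dx = make_dx([("P1", 0, "F11.20"), ("P2", 0, "F19.20")])
        assert flag_codes(dx, "P1", 0, which="oud") == 1
        assert flag_codes(dx, "P2", 0, which="oud") == 0

    def test_unknown_which_raises(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            flag_codes(make_dx([]), "P1", 0, which="sepsis")

    def test_random_codes_match_prefix_oracle(self):
        rng = np.random.default_rng(21)
        pool = ["T40.2X1A", "T40.4X1A", "T50.901A", "F11.10", "F11.21",
                "C50.911", "J06.9", "T40.2X2A", "M54.5"]
        codes = CodeDictionary()
        dx = make_dx(
            [("P1", 0, pool[rng.integers(len(pool))]) for _ in range(100)]
        )
        oracle_inc = any(
            codes.is_overdose_opioid(c) or codes.is_overdose_unspecified(c)
            for c in dx["icd10_code"]
        )
        assert flag_codes(dx, "P1", 0, which="overdose_inclusive") == int(oracle_inc)


class TestPanelAssembly:
    @staticmethod
    def _centrality_for(rx, quarters):
        from coprescribenet.centrality import centrality_table
        from coprescribenet.network import filter_opioid_claims

        return centrality_table(filter_opioid_claims(rx), quarters,
                                max_quarter=max(quarters))

    def _patients_for(self, rx):
        ids = sorted(rx["patient_id"].unique())
        return pd.DataFrame(
            {"patient_id": ids, "female": 1, "age_years": 50.0,
             "insurance": "Other", "state": "WV"}
        )

    def test_included_patient_contributes_all_quarters(self):
        rx = make_rx([("P1", "D1", 2)])
        cent = self._centrality_for(rx, [0, 1, 2, 3])
        panel = assemble_panel(self._patients_for(rx), rx, make_dx([]), cent, [0, 1, 2, 3])
        assert len(panel) == 4
        assert panel.sort_values("quarter")["n_rx"].tolist() == [0, 0, 1, 0]

    def test_mat_only_patient_excluded(self):
        rx = make_rx([("P1", "D1", 0), ("P2", "D1", 0, 10, 1, 0, 30, 1)])
        cent = self._centrality_for(rx, [0])
        panel = assemble_panel(self._patients_for(rx), rx, make_dx([]), cent, [0])
        assert set(panel["patient_id"]) == {"P1"}

    def test_row_count_is_patients_times_quarters(self, small_study, small_panel):
        from coprescribenet.network import filter_opioid_claims

        cfg = small_study["config"]
        n_inc = filter_opioid_claims(small_study["rx"])["patient_id"].nunique()
        assert len(small_panel) == n_inc * cfg.n_panel_quarters

    def test_overdose_opioid_implies_inclusive(self, small_panel):
        assert (
            small_panel["overdose_opioid_only"] <= small_panel["overdose_any"]
        ).all()

    def test_missing_centrality_quarter_raises(self):
        rx = make_rx([("P1", "D1", 0)])
        cent = self._centrality_for(rx, [0])
        with pytest.raises(ValueError, match="lacks panel quarters"):
            assemble_panel(self._patients_for(rx), rx, make_dx([]), cent, [0, 1])

    def test_mat_records_change_no_outcome_column(self, small_study, small_panel):
        cfg = small_study["config"]
        rng = np.random.default_rng(99)
        mat = small_study["rx"].sample(50, random_state=1).copy()
        mat["is_mat"] = 1
        mat["daily_dose_mg"] = 400.0
        rx2 = pd.concat([small_study["rx"], mat], ignore_index=True)
        cent = self._centrality_for(rx2, cfg.panel_quarters)
        panel2 = assemble_panel(
            small_study["patients"], rx2, small_study["dx"], cent, cfg.panel_quarters
        )
        cols = ["n_rx", "n_prescribers", "max_daily_mme", "mme_gt90",
                "overdose_any", "oud"]
        a = small_panel.set_index(["patient_id", "quarter"])[cols].sort_index()
        b = panel2.set_index(["patient_id", "quarter"])[cols].sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestHighRiskRestriction:
    def test_single_prescriber_patient_dropped(self):
        panel = pd.DataFrame(
            {"patient_id": ["A"] * 4, "quarter": range(4), "n_prescribers": [1, 1, 0, 1]}
        )
        assert len(restrict_high_risk(panel)) == 0

    def test_one_qualifying_quarter_keeps_all_quarters(self):
        panel = pd.DataFrame(
            {"patient_id": ["A"] * 4, "quarter": range(4), "n_prescribers": [1, 2, 0, 1]}
        )
        assert len(restrict_high_risk(panel)) == 4

    def test_matches_patient_level_max_oracle(self, small_panel):
        got = restrict_high_risk(small_panel)
        keep = {
            p for p, g in small_panel.groupby("patient_id")
            if g["n_prescribers"].max() >= 2
        }
        assert set(got["patient_id"]) == keep
        assert (got.groupby("patient_id").size()
                == small_panel.groupby("patient_id").size()[sorted(keep)]).all()
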