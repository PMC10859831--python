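"""Cost accounting, discounting closed forms, INMB arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uroflow import (
    ConfigurationError,
    CostTable,
    DecrementTable,
    EconParams,
    discount_factor,
    incremental_summary,
    life_years_lost,
    total_cost,
)
from uroflow.cohort import Patient


def _patient(steps, cancer=False, subtype="prostate", band="60-79", delay=0):
    p = Patient(id=0, arrival_day=0, has_cancer=cancer, subtype=subtype,
                age_band=band, referral_delay_months=delay)
    for s in steps:
        p.add_event(s, 0)
    return p


class TestCostTable:
    def test_empty_timeline_is_zero(self):
        assert total_cost(_patient([]), CostTable()) == 0

    def test_additivity(self):
        table = CostTable({"gp-consult": 39.0, "psa-test": 35.0})
        assert total_cost(_patient(["gp-consult", "psa-test"]), table) == 7400

    def test_non_cost_events_ignored(self):
        table = CostTable({"gp-consult": 39.0})
        p = _patient(["gp-consult"])
        p.add_event("referral", 1)
        p.add_event("seen", 5)
        assert total_cost(p, table) == 3900

    def test_missing_step_raises_with_name(self):
        with pytest.raises(ConfigurationError, match="mpmri"):
            total_cost(_patient(["mpmri"]), CostTable({"gp-consult": 39.0}))

    def test_inflation_applied(self):
        table = CostTable({"gp-consult": 100.0}, inflation_factor=1.059)
        assert table.pence("gp-consult") == 10590

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "costs.csv"
        path.write_text("step,unit_cost,ref_year\ngp-consult,39.00,2020\nmpmri,250.50,2020\n")
        table = CostTable.from_csv(path, inflation_factor=1.0)
        assert table.pence("mpmri") == 25050

    def test_negative_cost_rejected(self):
        with pytest.raises(ConfigurationError):
            CostTable({"gp-consult": -1.0})


class TestDiscounting:
    def test_lump_sum_closed_form(self):
        econ = EconParams(accrual="lump", lump_year=10)
        assert np.isclose(0.10 * discount_factor(econ), 0.10 * 1.035 ** -10)
        assert np.isclose(0.10 * discount_factor(econ), 0.0709, atol=5e-5)

    def test_zero_rate_recovers_raw_decrement(self):
        econ = EconParams(discount_rate=0.0)
        table = DecrementTable()
        p = _patient([], cancer=True, subtype="bladder", delay=6)
        assert life_years_lost(p, table, econ) == table.lookup("bladder", "60-79", 6)

    def test_uniform_accrual_is_mean_of_annual_factors(self):
        econ = EconParams()
        expected = np.mean([1.035 ** -t for t in range(1, 11)])
        assert np.isclose(discount_factor(econ), expected)

    def test_non_cancer_and_timely_patients_lose_nothing(self):
        econ = EconParams()
        table = DecrementTable()
        assert life_years_lost(_patient([], cancer=False, delay=6), table, econ) == 0.0
        assert life_years_lost(_patient([], cancer=True, delay=0), table, econ) == 0.0

    def test_missing_cell_raises(self):
        table = DecrementTable({("prostate", "60-79", 2): 0.01,
                                ("prostate", "60-79", 4): 0.02,
                                ("prostate", "60-79", 6): 0.03})
        p = _patient([], cancer=True, subtype="bladder", delay=6)
        with pytest.raises(ConfigurationError):
            life_years_lost(p, table, EconParams())


class TestDecrementTable:
    def test_monotone_in_delay_enforced(self):
        with pytest.raises(ConfigurationError):
            DecrementTable({("prostate", "60-79", 2): 0.05, ("prostate", "60-79", 6): 0.01})

    def test_defaults_cover_all_cells_and_are_monotone(self):
        table = DecrementTable()
        for s in ("prostate", "bladder", "kidney"):
            for b in ("<60", "60-79", "80+"):
                vals = [table.lookup(s, b, d) for d in (2, 4, 6)]
                assert vals == sorted(vals)

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "dec.csv"
        rows = ["subtype,age_band,delay_months,ly_lost"]
        for d, v in ((2, 0.01), (4, 0.02), (6, 0.05)):
            rows.append(f"bladder,60-79,{d},{v}")
        path.write_text("\n".join(rows) + "\n")
        table = DecrementTable.from_csv(path)
        assert table.lookup("bladder", "60-79", 6) == 0.05


class TestIncrementalSummary:
    def test_identical_arms_are_all_zero(self):
        r = {"cost_gbp": [100.0, 120.0], "ly_lost": [0.5, 0.6]}
        out = incremental_summary(r, r, EconParams())
        assert out["delta_cost"] == 0 and out["delta_ly"] == 0 and out["inmb"] == 0

    def test_pure_saving(self):
        sc = {"cost_gbp": [200.0], "ly_lost": [0.0]}
        test = {"cost_gbp": [100.0], "ly_lost": [0.0]}
        out = incremental_summary(sc, test, EconParams())
        assert out["delta_cost"] == -100.0 and out["inmb"] == 100.0

    def test_direct_arithmetic(self):
        sc = {"cost_gbp": [0.0], "ly_lost": [0.001]}
        test = {"cost_gbp": [35.20], "ly_lost": [0.0]}
        out = incremental_summary(sc, test, EconParams(wtp=20_000))
        assert np.isclose(out["inmb"], 20_000 * 0.001 - 35.20)
        assert np.isclose(out["inmb"], -15.20)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ConfigurationError):
            incremental_summary(
                {"cost_gbp": [1.0], "ly_lost": [0.0]},
                {"cost_gbp": [1.0, 2.0], "ly_lost": [0.0, 0.0]},
                EconParams(),
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.floats(-500, 500),
        st.floats(1e-4, 0.1),
        st.floats(1000, 50_000),
        st.floats(1000, 50_000),
    )
    def test_inmb_affine_increasing_in_wtp(self, dcost, dly, wtp1, wtp2):
        """INMB is affine in WTP with slope delta-QALY; the zero crossing is
        delta-cost / delta-QALY."""
        sc = {"cost_gbp": [0.0], "ly_lost": [dly]}
        test = {"cost_gbp": [dcost], "ly_lost": [0.0]}
        i1 = incremental_summary(sc, test, EconParams(wtp=wtp1))["inmb"]
        i2 = incremental_summary(sc, test, EconParams(wtp=wtp2))["inmb"]
        assert np.isclose(i2 - i1, (wtp2 - wtp1) * dly, rtol=1e-9, atol=1e-9)
        crossing = dcost / dly
        if crossing > 0:
            at_cross = incremental_summary(sc, test, EconParams(wtp=crossing))["inmb"]
            assert abs(at_cross) < 1e-6 * max(1.0, abs(dcost))
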