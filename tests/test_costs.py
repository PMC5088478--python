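"""Cost engine: CPT build-up, compounding, perspective ledgers."""

import pytest

from amdvalue.costs import (
    PerspectiveCostLedger,
    compound_to_treatment_age,
    cpt_total,
    ledger_adjust,
    ledger_from_params,
    ledger_table,
    net_cost_per_early_case,
    per_capita_screening_cost,
)
from amdvalue.params import CptLine


class TestCptBuildUp:
    def test_panel_total_is_1461(self, params):
        assert cpt_total(params.cpt_items) == pytest.approx(1461, abs=1)

    def test_single_line_rounding(self):
        assert cpt_total([CptLine("83891", "", 1, 5.7)]) == 6

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValueError):
            cpt_total([])
        with pytest.raises(ValueError):
            cpt_total([CptLine("x", "", 1, -5.0)])


class TestCompounding:
    def test_nine_periods_reproduces_1906(self):
        assert compound_to_treatment_age(1461, 0.03, 9) == 1906

    def test_ten_period_alternative(self):
        assert compound_to_treatment_age(1461, 0.03, 10) == 1963

    def test_zero_periods_identity(self):
        assert compound_to_treatment_age(1461, 0.07, 0) == 1461

    def test_per_capita_sum(self):
        assert per_capita_screening_cost(1906, 299) == 2205
        assert per_capita_screening_cost(1906, 0) == 1906
        # reduced-price scenario per-capita entry
        assert per_capita_screening_cost(500, 299) == 799


class TestLedger:
    def test_adjustment_reproduces_printed_columns(self, params):
        factor = params.adjustment_factor
        adjusted = ledger_adjust(
            {
                "direct_non_ophthalmic": -93_699,
                "caregiver": -394_929,
                "employment": -32_288,
            },
            factor,
        )
        assert adjusted["direct_non_ophthalmic"] == pytest.approx(-40_914, abs=5)
        assert adjusted["caregiver"] == pytest.approx(-172_443, abs=10)
        assert adjusted["employment"] == pytest.approx(-14_098, abs=5)

    def test_identity_factor_recovers_column_a(self):
        col_a = {"caregiver": -394_929.0}
        assert ledger_adjust(col_a, 1.0) == col_a
        with pytest.raises(ValueError):
            ledger_adjust(col_a, 0.0)

    def test_societal_totals(self, params):
        ledger = ledger_from_params(params, "societal")
        assert ledger.total_negative == -227_455
        assert net_cost_per_early_case(ledger) == -160_582

    def test_third_party_totals(self, params):
        ledger = ledger_from_params(params, "third_party")
        assert ledger.total_negative == -40_914
        assert net_cost_per_early_case(ledger) == pytest.approx(25_960, abs=1)

    def test_zero_negatives_leaves_screening_cost(self, params):
        ledger = PerspectiveCostLedger("societal", 66_873, 0.0, 0.0, 0.0)
        assert net_cost_per_early_case(ledger) == 66_873

    def test_sign_discipline(self, params):
        with pytest.raises(ValueError):
            PerspectiveCostLedger("societal", 66_873, 40_914, 0.0, 0.0)
        with pytest.raises(ValueError):
            PerspectiveCostLedger("payer", 66_873, -1.0, 0.0, 0.0)
        soc = net_cost_per_early_case(ledger_from_params(params, "societal"))
        third = net_cost_per_early_case(ledger_from_params(params, "third_party"))
        assert soc < third

    def test_ledger_table_structure(self, params):
        df = ledger_table(params).set_index("component")
        assert df.loc["total_negative", "societal_adjusted"] == -227_455
        assert df.loc["net_total", "societal_adjusted"] == -160_582
        assert df.loc["net_total", "third_party"] == pytest.approx(25_960, abs=1)
        # scaling the unadjusted column by the factor recovers the adjusted
        # column within per-row rounding
        for row in ("direct_non_ophthalmic", "caregiver", "employment"):
            assert df.loc[row, "unadjusted"] * params.adjustment_factor == pytest.approx(
                df.loc[row, "societal_adjusted"], abs=20
            )
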