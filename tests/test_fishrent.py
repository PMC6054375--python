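"""Bio-economic fleet model: production, quotas, accounting, NPV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baltisim.fishrent_econ import (
    CatchParams,
    EconPolicy,
    FleetSegment,
    StockInput,
    apply_tac,
    catch_production,
    default_fleets,
    default_stocks,
    fleet_economics,
    project_npv,
    scale_stocks,
)
from baltisim.model_domain import ValidationError


def _fleet(**kw):
    defaults = dict(
        fleet_id="test",
        effort=1000.0,
        max_effort=2000.0,
        fuel_per_day=100.0,
        variable_per_day=50.0,
        crew_share=0.3,
        fixed_per_year=10_000.0,
        capital_per_year=5_000.0,
        cobb_douglas={
            "A": CatchParams(A=100.0, quota_share=1.0),
            "B": CatchParams(A=50.0, quota_share=1.0),
        },
        area_keys={"kattegat": 0.6, "western_baltic": 0.4},
    )
    defaults.update(kw)
    return FleetSegment(**defaults)


def _stocks():
    return {
        "A": StockInput("A", TSB=1000.0, F=0.3, M=0.2, TAC=500.0, price=10.0),
        "B": StockInput("B", TSB=500.0, F=0.3, M=0.2, TAC=100.0, price=20.0),
    }


class TestScaleStocks:
    def test_zero_index_unchanged(self):
        out = scale_stocks(_stocks(), {"A": 0.0, "B": 0.0})
        assert out["A"].TSB == 1000.0

    def test_published_style_negative_index(self):
        stocks = {"NEP": StockInput("NEP", TSB=1000.0, F=0.2, M=0.3, TAC=300.0, price=9000.0)}
        out = scale_stocks(stocks, {"NEP": -20.97})
        assert out["NEP"].TSB == pytest.approx(790.3)

    def test_plus_hundred_doubles(self):
        out = scale_stocks(_stocks(), {"A": 100.0, "B": 0.0})
        assert out["A"].TSB == 2000.0

    def test_missing_index_lists_the_stock(self):
        with pytest.raises(ValidationError, match="B"):
            scale_stocks(_stocks(), {"A": 0.0})


class TestCatchProduction:
    def test_zero_effort_zero_catch(self):
        f, s = _fleet(), _stocks()
        assert catch_production(f, s["A"], 0.0, 1000.0, 1000.0) == 0.0

    def test_reference_normalisation(self):
        f, s = _fleet(), _stocks()
        assert catch_production(f, s["A"], 1000.0, 1000.0, 1000.0) == pytest.approx(100.0)

    def test_effort_homogeneity_at_unit_exponent(self):
        f, s = _fleet(), _stocks()
        single = catch_production(f, s["A"], 1000.0, 1000.0, 1000.0)
        double = catch_production(f, s["A"], 2000.0, 1000.0, 1000.0)
        assert double == pytest.approx(2.0 * single)

    def test_negative_effort_rejected(self):
        with pytest.raises(ValidationError):
            catch_production(_fleet(), _stocks()["A"], -1.0, 1000.0, 1000.0)


class TestApplyTac:
    def test_ample_quotas_change_nothing(self):
        f, s = _fleet(), _stocks()
        landings = {"test": {"A": 100.0, "B": 50.0}}
        out, chokes, scales = apply_tac(landings, s, [f])
        assert out["test"] == landings["test"]
        assert chokes["test"] is None
        assert scales["test"] == 1.0

    def test_hand_solved_two_stock_choke(self):
        """Quota for B at half the unconstrained landings (alpha=1):
        effort and hence both landings halve; B lands exactly on quota."""
        f = _fleet(cobb_douglas={
            "A": CatchParams(A=100.0, quota_share=1.0),
            "B": CatchParams(A=50.0, quota_share=0.25),  # cap = 0.25*100 = 25 = half of 50
        })
        s = _stocks()
        landings = {"test": {"A": 100.0, "B": 50.0}}
        out, chokes, scales = apply_tac(landings, s, [f])
        assert chokes["test"] == "B"
        assert scales["test"] == pytest.approx(0.5)
        assert out["test"]["B"] == pytest.approx(25.0)  # exactly at quota
        assert out["test"]["A"] == pytest.approx(50.0)  # dragged down with effort

    def test_zero_quota_stops_the_fleet(self):
        f = _fleet(cobb_douglas={
            "A": CatchParams(A=100.0, quota_share=1.0),
            "B": CatchParams(A=50.0, quota_share=0.0),
        })
        out, chokes, scales = apply_tac({"test": {"A": 100.0, "B": 50.0}}, _stocks(), [f])
        assert scales["test"] == 0.0
        assert out["test"]["A"] == 0.0
        assert out["test"]["B"] == 0.0


class TestFleetEconomics:
    def test_idle_fleet_pays_fixed_and_capital(self):
        f, s = _fleet(), _stocks()
        rec = fleet_economics(f, {"A": 0.0, "B": 0.0}, s, effort=0.0)
        assert rec["revenue"] == 0.0
        assert rec["profit"] == -(10_000.0 + 5_000.0)

    def test_crew_share_of_revenue(self):
        f, s = _fleet(crew_share=0.3), _stocks()
        rec = fleet_economics(f, {"A": 10.0, "B": 0.0}, s, effort=0.0)
        assert rec["revenue"] == pytest.approx(100.0)
        assert rec["crew"] == pytest.approx(30.0)

    def test_area_keys_split_revenue_exactly(self):
        f, s = _fleet(), _stocks()
        rec = fleet_economics(f, {"A": 10.0, "B": 5.0}, s, effort=100.0)
        assert rec["revenue_kattegat"] == pytest.approx(0.6 * rec["revenue"])
        assert rec["revenue_kattegat"] + rec["revenue_western_baltic"] == pytest.approx(
            rec["revenue"]
        )

    @settings(max_examples=25, deadline=None)
    @given(
        la=st.floats(0.0, 1e4),
        lb=st.floats(0.0, 1e4),
        effort=st.floats(0.0, 5e3),
    )
    def test_accounting_closure_exact(self, la, lb, effort):
        f, s = _fleet(), _stocks()
        rec = fleet_economics(f, {"A": la, "B": lb}, s, effort)
        costs = rec["fuel"] + rec["variable"] + rec["crew"] + rec["fixed"] + rec["capital"]
        assert rec["profit"] + costs - rec["revenue"] == pytest.approx(0.0, abs=1e-6)


class TestProjectNpv:
    def test_annuity_closed_form(self):
        """Constant profit P over n years at rate r matches the annuity sum."""
        f = _fleet(fuel_per_day=0.0, variable_per_day=0.0, crew_share=0.0,
                   fixed_per_year=0.0, capital_per_year=0.0)
        s = _stocks()
        policy = EconPolicy(start_year=2012, end_year=2021, discount_rate=0.05,
                            behavior_lambda=0.0)
        res = project_npv([f], s, policy)
        P = 100.0 * 10.0 + 50.0 * 20.0  # annual revenue = profit (no costs)
        n, r = 10, 0.05
        expected = P * (1.0 - (1.0 + r) ** -n) / r * (1.0 + r)
        assert res.npv_total * 1e6 == pytest.approx(expected, abs=1e-9 * expected)

    def test_zero_discount_is_plain_sum(self):
        f = _fleet()
        s = _stocks()
        policy = EconPolicy(start_year=2012, end_year=2016, discount_rate=0.0,
                            behavior_lambda=0.0)
        res = project_npv([f], s, policy)
        assert res.npv_total * 1e6 == pytest.approx(res.annual["profit"].sum())

    def test_no_behavior_constant_records(self):
        f, s = _fleet(), _stocks()
        policy = EconPolicy(behavior_lambda=0.0)
        res = project_npv([f], s, policy)
        assert res.annual["effort"].nunique() == 1
        assert res.annual["profit"].round(6).nunique() == 1

    def test_choke_dominance_stricter_tac_never_raises_effort(self):
        fleets = default_fleets()
        stocks = default_stocks()
        res_loose = project_npv(fleets, stocks, EconPolicy())
        strict = {k: v for k, v in stocks.items()}
        strict["NEP_KAWB"] = StockInput("NEP_KAWB", TSB=4000.0, F=0.25, M=0.3,
                                        TAC=200.0, price=9000.0)
        res_strict = project_npv(default_fleets(), strict, EconPolicy())
        for fleet_id in res_loose.annual["fleet"].unique():
            e_loose = res_loose.annual[res_loose.annual.fleet == fleet_id]["effort"].to_numpy()
            e_strict = res_strict.annual[res_strict.annual.fleet == fleet_id]["effort"].to_numpy()
            assert np.all(e_strict <= e_loose + 1e-9)

    def test_lower_stock_index_never_raises_its_landings(self):
        fleets = default_fleets()
        base = project_npv(fleets, default_stocks(), EconPolicy(behavior_lambda=0.0))
        reduced = scale_stocks(default_stocks(), {
            "COD_KA": 0.0, "COD_WB": 0.0, "SPR_KAWB": 0.0, "HER_KAWB": 0.0,
            "NEP_KAWB": -40.0,
        })
        res = project_npv(default_fleets(), reduced, EconPolicy(behavior_lambda=0.0))
        col = "landings_NEP_KAWB"
        assert res.annual[col].sum() <= base.annual[col].sum() + 1e-9

    def test_default_configuration_is_profitable(self):
        res = project_npv(default_fleets(), default_stocks(), EconPolicy())
        assert res.npv_total > 0.0
        assert set(res.npv_by_area) == {"kattegat", "western_baltic"}
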