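"""Multi-fleet, multi-stock bio-economic evaluation of ecosystem output.

The model follows the five-module structure of European bio-economic
fleet models: a biological module (constant stock biomasses, optionally
rescaled by ecosystem-scenario indices), a production module
(Cobb-Douglas catch per fleet and stock, normalised so the intercept A
is in tons at reference effort and biomass), a policy module (TAC
quota shares with a choke rule: when any quota binds, the fleet's
effort -- and hence its landings of every stock -- is scaled down by
the single factor that puts the binding stock exactly on its quota), an
economic module (revenue, fuel/variable/crew/fixed/capital costs,
profit, with an area decomposition), and a behaviour module (bounded
proportional effort adjustment toward profit).  Net present value is
the discounted profit sum over a fixed horizon (2012-2037 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model_domain import ValidationError

AREAS = ("kattegat", "western_baltic")


@dataclass
class StockInput:
    stock_id: str
    TSB: float  # tons, held constant over the projection
    F: float  # yr-1
    M: float  # yr-1
    TAC: float  # tons yr-1
    price: float  # EUR per ton
    atlantis_index: float = 0.0  # relative-change multiplier, percent

    def validate(self) -> None:
        if min(self.TSB, self.TAC, self.price) < 0:
            raise ValidationError(f"{self.stock_id}: TSB, TAC and price must be >= 0")


@dataclass
class CatchParams:
    A: float  # tons at reference effort and biomass
    alpha_E: float = 1.0
    beta_B: float = 1.0
    quota_share: float = 0.0


@dataclass
class FleetSegment:
    fleet_id: str
    effort: float  # days yr-1
    max_effort: float
    fuel_per_day: float
    variable_per_day: float
    crew_share: float
    fixed_per_year: float
    capital_per_year: float
    cobb_douglas: dict[str, CatchParams] = field(default_factory=dict)
    area_keys: dict[str, float] = field(default_factory=lambda: {"kattegat": 0.5, "western_baltic": 0.5})

    def validate(self) -> None:
        if not 0 <= self.crew_share <= 1:
            raise ValidationError(f"{self.fleet_id}: crew_share outside [0, 1]")
        if abs(sum(self.area_keys.values()) - 1.0) > 1e-9:
            raise ValidationError(f"{self.fleet_id}: area keys must sum to 1")
        if self.effort < 0 or self.max_effort < self.effort * 0:
            raise ValidationError(f"{self.fleet_id}: negative effort")


def validate_fleets(fleets: Sequence[FleetSegment], stocks: Mapping[str, StockInput]) -> None:
    for f in fleets:
        f.validate()
    for sid in stocks:
        total = sum(f.cobb_douglas.get(sid, CatchParams(0.0)).quota_share for f in fleets)
        if total > 1.0 + 1e-9:
            raise ValidationError(f"quota shares for {sid} sum to {total} > 1")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def scale_stocks(
    stocks: Mapping[str, StockInput], indices: Mapping[str, float]
) -> dict[str, StockInput]:
    """Apply ecosystem-scenario relative-change indices (percent) to TSB."""
    missing = [s for s in stocks if s not in indices]
    if missing:
        raise ValidationError(f"no scenario index for stocks: {missing}")
    out = {}
    for sid, st in stocks.items():
        out[sid] = replace(st, TSB=st.TSB * (1.0 + indices[sid] / 100.0), atlantis_index=indices[sid])
    return out


def catch_production(
    fleet: FleetSegment,
    stock: StockInput,
    effort: float,
    effort_ref: float,
    tsb_ref: float,
) -> float:
    """Cobb-Douglas catch (tons per year), normalised to reference levels."""
    if effort < 0:
        raise ValidationError("effort must be >= 0")
    cp = fleet.cobb_douglas.get(stock.stock_id)
    if cp is None or cp.A <= 0 or effort == 0:
        return 0.0
    return cp.A * (effort / effort_ref) ** cp.alpha_E * (stock.TSB / tsb_ref) ** cp.beta_B


def apply_tac(
    landings: Mapping[str, dict[str, float]],
    stocks: Mapping[str, StockInput],
    fleets: Sequence[FleetSegment],
) -> tuple[dict[str, dict[str, float]], dict[str, Optional[str]], dict[str, float]]:
    """Constrain landings by quota shares with the choke rule.

    Returns (constrained landings, choke stock per fleet or None, the
    effort scale factor per fleet).  When a fleet's quota for any stock
    binds, its effort is scaled by the single factor that brings the
    binding (choke) stock exactly to its quota, reducing its landings
    of all stocks.
    """
    out: dict[str, dict[str, float]] = {}
    chokes: dict[str, Optional[str]] = {}
    scales: dict[str, float] = {}
    for fleet in fleets:
        lf = dict(landings[fleet.fleet_id])
        best_f = 1.0
        choke = None
        for sid, catch in lf.items():
            cp = fleet.cobb_douglas.get(sid)
            if cp is None or catch <= 0:
                continue
            cap = cp.quota_share * stocks[sid].TAC
            if catch > cap:
                # effort factor bringing this stock exactly to quota
                f = (cap / catch) ** (1.0 / cp.alpha_E) if cap > 0 else 0.0
                if f < best_f:
                    best_f = f
                    choke = sid
        if choke is not None:
            lf = {
                sid: catch * best_f ** fleet.cobb_douglas[sid].alpha_E if sid in fleet.cobb_douglas else catch
                for sid, catch in lf.items()
            }
        out[fleet.fleet_id] = lf
        chokes[fleet.fleet_id] = choke
        scales[fleet.fleet_id] = best_f
    return out, chokes, scales


def fleet_economics(
    fleet: FleetSegment,
    landings: Mapping[str, float],
    stocks: Mapping[str, StockInput],
    effort: float,
) -> dict:
    """One fleet-year accounting record (EUR).

    profit = revenue - (fuel + variable + crew + fixed + capital),
    exactly; every line item also carries an area decomposition by the
    fleet's fixed area keys.
    """
    revenue = sum(stocks[sid].price * tons for sid, tons in landings.items())
    fuel = fleet.fuel_per_day * effort
    variable = fleet.variable_per_day * effort
    crew = fleet.crew_share * revenue
    fixed = fleet.fixed_per_year
    capital = fleet.capital_per_year
    profit = revenue - (fuel + variable + crew + fixed + capital)
    rec = {
        "fleet": fleet.fleet_id,
        "effort": effort,
        "revenue": revenue,
        "fuel": fuel,
        "variable": variable,
        "crew": crew,
        "fixed": fixed,
        "capital": capital,
        "profit": profit,
    }
    for area, key in fleet.area_keys.items():
        rec[f"revenue_{area}"] = revenue * key
        rec[f"profit_{area}"] = profit * key
    return rec


@dataclass
class EconResult:
    annual: pd.DataFrame  # fleet-year records incl. landings columns
    npv_total: float  # million EUR
    npv_by_area: dict[str, float]
    npv_by_fleet: dict[str, float]
    choke_flags: pd.DataFrame  # fleet, year, choke stock


@dataclass
class EconPolicy:
    start_year: int = 2012
    end_year: int = 2037
    discount_rate: float = 0.04
    behavior_lambda: float = 0.1
    behavior_cap: float = 0.5


def project_npv(
    fleets: Sequence[FleetSegment],
    stocks: Mapping[str, StockInput],
    policy: EconPolicy | None = None,
) -> EconResult:
    """Annual projection with effort behaviour, production, TAC, and
    accounting; NPV discounts profits to the start year.

    Stock biomasses and TACs stay constant (the ecosystem scenario
    enters only through pre-scaled TSB values); fleets adjust effort
    toward profit by a bounded proportional rule.
    """
    policy = policy or EconPolicy()
    if policy.end_year < policy.start_year:
        raise ValidationError("economic horizon must be at least one year")
    if policy.discount_rate < 0:
        raise ValidationError("discount rate must be >= 0")
    validate_fleets(fleets, stocks)
    effort_ref = {f.fleet_id: f.effort for f in fleets}
    # the Cobb-Douglas reference is the base-year biomass, i.e. the TSB
    # before any ecosystem-scenario index was applied
    tsb_ref = {
        sid: st.TSB / (1.0 + st.atlantis_index / 100.0) for sid, st in stocks.items()
    }
    effort = dict(effort_ref)

    rows = []
    chokes_rows = []
    npv = 0.0
    npv_area = {a: 0.0 for a in AREAS}
    npv_fleet = {f.fleet_id: 0.0 for f in fleets}
    for year in range(policy.start_year, policy.end_year + 1):
        landings = {
            f.fleet_id: {
                sid: catch_production(f, st, effort[f.fleet_id], effort_ref[f.fleet_id], tsb_ref[sid])
                for sid, st in stocks.items()
            }
            for f in fleets
        }
        landings, chokes, scales = apply_tac(landings, stocks, fleets)
        disc = (1.0 + policy.discount_rate) ** (year - policy.start_year)
        for f in fleets:
            eff = effort[f.fleet_id] * scales[f.fleet_id]
            rec = fleet_economics(f, landings[f.fleet_id], stocks, eff)
            rec["year"] = year
            for sid, tons in landings[f.fleet_id].items():
                rec[f"landings_{sid}"] = tons
            rows.append(rec)
            if chokes[f.fleet_id] is not None:
                chokes_rows.append({"fleet": f.fleet_id, "year": year, "choke": chokes[f.fleet_id]})
            npv += rec["profit"] / disc
            npv_fleet[f.fleet_id] += rec["profit"] / disc
            for a in AREAS:
                npv_area[a] += rec.get(f"profit_{a}", 0.0) / disc
            # behaviour: bounded proportional profit following
            if rec["revenue"] > 0 and policy.behavior_lambda > 0:
                step = policy.behavior_lambda * np.sign(rec["profit"]) * min(
                    abs(rec["profit"]) / rec["revenue"], policy.behavior_cap
                )
                effort[f.fleet_id] = float(
                    np.clip(effort[f.fleet_id] * (1.0 + step), 0.0, f.max_effort)
                )
    return EconResult(
        annual=pd.DataFrame(rows),
        npv_total=npv / 1e6,
        npv_by_area={a: v / 1e6 for a, v in npv_area.items()},
        npv_by_fleet={k: v / 1e6 for k, v in npv_fleet.items()},
        choke_flags=pd.DataFrame(chokes_rows, columns=["fleet", "year", "choke"]),
    )


# ---------------------------------------------------------------------------
# shipped fleet/stock configuration (synthetic, survey-magnitude values)
# ---------------------------------------------------------------------------


def default_stocks() -> dict[str, StockInput]:
    """Five stocks of the western evaluation area (synthetic magnitudes)."""
    stocks = {
        "COD_KA": StockInput("COD_KA", TSB=9_000.0, F=0.4, M=0.2, TAC=3_500.0, price=1_800.0),
        "COD_WB": StockInput("COD_WB", TSB=22_000.0, F=0.5, M=0.2, TAC=12_000.0, price=1_800.0),
        "SPR_KAWB": StockInput("SPR_KAWB", TSB=80_000.0, F=0.3, M=0.4, TAC=40_000.0, price=250.0),
        "HER_KAWB": StockInput("HER_KAWB", TSB=120_000.0, F=0.3, M=0.25, TAC=60_000.0, price=300.0),
        "NEP_KAWB": StockInput("NEP_KAWB", TSB=4_000.0, F=0.25, M=0.3, TAC=2_000.0, price=9_000.0),
    }
    for s in stocks.values():
        s.validate()
    return stocks


def default_fleets() -> list[FleetSegment]:
    """Four fleet segments: three trawler length classes plus netters."""
    def cd(**kw):
        return {sid: CatchParams(A=a, quota_share=q) for sid, (a, q) in kw.items()}

    fleets = [
        FleetSegment(
            "trawl_12_15m", effort=4_000.0, max_effort=6_000.0,
            fuel_per_day=250.0, variable_per_day=250.0, crew_share=0.30,
            fixed_per_year=300_000.0, capital_per_year=150_000.0,
            cobb_douglas=cd(
                COD_KA=(380.0, 0.22), COD_WB=(700.0, 0.12),
                NEP_KAWB=(260.0, 0.35), SPR_KAWB=(1_200.0, 0.08),
            ),
            area_keys={"kattegat": 0.6, "western_baltic": 0.4},
        ),
        FleetSegment(
            "trawl_15_18m", effort=5_000.0, max_effort=7_500.0,
            fuel_per_day=400.0, variable_per_day=250.0, crew_share=0.30,
            fixed_per_year=500_000.0, capital_per_year=300_000.0,
            cobb_douglas=cd(
                COD_KA=(520.0, 0.30), COD_WB=(1_300.0, 0.20),
                NEP_KAWB=(300.0, 0.40), SPR_KAWB=(4_000.0, 0.22),
                HER_KAWB=(3_500.0, 0.14),
            ),
            area_keys={"kattegat": 0.55, "western_baltic": 0.45},
        ),
        FleetSegment(
            "trawl_18_24m", effort=5_500.0, max_effort=8_000.0,
            fuel_per_day=700.0, variable_per_day=350.0, crew_share=0.28,
            fixed_per_year=750_000.0, capital_per_year=500_000.0,
            cobb_douglas=cd(
                COD_KA=(420.0, 0.25), COD_WB=(2_100.0, 0.32),
                SPR_KAWB=(9_500.0, 0.50), HER_KAWB=(12_000.0, 0.45),
                NEP_KAWB=(120.0, 0.15),
            ),
            area_keys={"kattegat": 0.35, "western_baltic": 0.65},
        ),
        FleetSegment(
            "netters_liners", effort=6_000.0, max_effort=9_000.0,
            fuel_per_day=120.0, variable_per_day=150.0, crew_share=0.35,
            fixed_per_year=400_000.0, capital_per_year=200_000.0,
            cobb_douglas=cd(
                COD_KA=(350.0, 0.23), COD_WB=(1_600.0, 0.30),
                HER_KAWB=(2_500.0, 0.10),
            ),
            area_keys={"kattegat": 0.45, "western_baltic": 0.55},
        ),
    ]
    validate_fleets(fleets, default_stocks())
    return fleets


def stocks_to_frame(stocks: Mapping[str, StockInput]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stocks.values()])


def econ_to_csv(result: EconResult, path: str | Path) -> None:
    df = result.annual.copy()
    summary = pd.DataFrame(
        [{"fleet": "TOTAL_NPV_MEUR", "revenue": result.npv_total},
         *({"fleet": f"NPV_{a}_MEUR", "revenue": v} for a, v in result.npv_by_area.items())]
    )
    pd.concat([df, summary], ignore_index=True).to_csv(path, index=False)
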