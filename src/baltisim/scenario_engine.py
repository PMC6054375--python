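"""Scenario definition, projection runs, and comparison metrics.

The experiment design: every projection runs for ``horizon_years``
(default 60) with a spin-up of ``change_year`` years (default 35) under
baseline forcing; at the change year the scenario's river-load
multipliers and/or fishing-mortality overrides apply as an
instantaneous step.  Results are compared on terminal averages (default
the last five years) as percent change against the status-quo run with
the same forcing seed, so differences are attributable to the
intervention alone.

The shipped catalog holds ten scenarios: status quo, four
nutrient-load-reduction designs (selected Danish rivers; the Danish/
Swedish/German coast; a burden-sharing set over many basins; a
pan-Baltic 33% cut) and five fishing-pressure changes on cod and sprat
(halved, doubled, and the 2005-2012 maximum observed F).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ecosystem import EcosystemParams, RunResult, Simulation
from .groups import AvailabilityMatrix, FunctionalGroup, default_availability, default_groups
from .model_domain import ModelGeometry, ValidationError, load_builtin_geometry
from .synthetic_forcing import (
    DepositionParams,
    InitialConditionParams,
    LoadParams,
    PhysicsParams,
    deposition_flux,
    generate_initial_conditions,
    generate_loads,
    generate_physics,
)

#: baseline adult fishing mortalities (yr-1) the scenario rules derive from
BASELINE_F_COD = 0.32
BASELINE_F_SPRAT = 0.07


@dataclass
class ScenarioSpec:
    """One experiment: per-box load multipliers and/or F overrides."""

    name: str
    load_multiplier: dict[int, float] = field(default_factory=dict)  # box -> (1 - reduction)
    F_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    change_year: int = 35
    horizon_years: int = 60
    terminal_window: int = 5

    def validate(self, geometry: ModelGeometry | None = None) -> None:
        for box, m in self.load_multiplier.items():
            if not 0.0 <= m <= 1.0:
                raise ValidationError(f"{self.name}: load multiplier for box {box} outside [0, 1]")
            if geometry is not None:
                if box >= geometry.n_boxes or box < 0:
                    raise ValidationError(f"{self.name}: box {box} absent from geometry")
        if self.change_year >= self.horizon_years:
            raise ValidationError(f"{self.name}: change_year must be < horizon_years")
        if self.terminal_window <= 0 or self.terminal_window > self.horizon_years - self.change_year:
            raise ValidationError(f"{self.name}: terminal_window out of range")
        for grp, fo in self.F_overrides.items():
            if "adult" not in fo:
                raise ValidationError(f"{self.name}: F override for {grp} missing adult rate")
            if fo["adult"] < 0 or fo.get("juvenile", 0.0) < 0:
                raise ValidationError(f"{self.name}: negative F override")

    def resolved_F(self) -> dict[str, tuple[float, float]]:
        """(adult, juvenile) override pairs; juvenile defaults to half adult."""
        out = {}
        for grp, fo in self.F_overrides.items():
            fa = float(fo["adult"])
            fj = float(fo.get("juvenile", fa / 2.0))
            out[grp] = (fa, fj)
        return out

    def multiplier_array(self, geometry: ModelGeometry) -> np.ndarray:
        mult = np.ones(geometry.n_boxes)
        for box, m in self.load_multiplier.items():
            mult[box] = m
        return mult


def scenario_catalog() -> list[dict]:
    """The ten shipped scenario definitions.

    Load reductions are percent; fishing scenarios #6/#7 are expressed
    through the 50%-reduction rule on the baseline adult rates, while
    #8-#10 carry the catalog's printed rates verbatim.
    """
    return [
        {"name": "status_quo"},
        {"name": "s2_denmark", "reductions": {1: 12.0, 2: 33.0, 4: 24.0}},
        {"name": "s3_dk_se_de", "reductions": {1: 33.0, 2: 33.0, 3: 33.0, 4: 33.0}},
        {
            "name": "s4_bsap",
            "reductions": {
                1: 9.0, 2: 20.0, 3: 15.0, 4: 32.0,
                5: 21.4, 9: 23.0, 12: 19.0, 13: 19.0, 14: 35.0, 17: 33.0,
            },
        },
        {"name": "s5_pan_baltic", "reductions": "pan_baltic_33"},
        {"name": "s6_cod_half_f", "F_rule": {"FCD": ("halve", BASELINE_F_COD)}},
        {"name": "s7_sprat_half_f", "F_rule": {"FSR": ("halve", BASELINE_F_SPRAT)}},
        {"name": "s8_cod_double_f", "F": {"FCD": 0.64}},
        {"name": "s9_sprat_double_f", "F": {"FSR": 0.14}},
        {"name": "s10_max_f", "F": {"FCD": 1.2, "FSR": 0.6}},
    ]


def build_scenarios(
    geometry: ModelGeometry,
    catalog: Sequence[dict] | None = None,
    *,
    change_year: int = 35,
    horizon_years: int = 60,
) -> list[ScenarioSpec]:
    """Resolve the catalog into validated ScenarioSpec objects.

    Scenario #6/#7 adult F values are computed by the halving rule from
    the baseline rates (0.32 cod, 0.07 sprat); juvenile overrides
    default to half the new adult rate.  A load reduction referencing a
    box the geometry does not have raises a validation error.
    """
    specs = []
    for entry in catalog if catalog is not None else scenario_catalog():
        spec = ScenarioSpec(
            name=entry["name"], change_year=change_year, horizon_years=horizon_years
        )
        red = entry.get("reductions")
        if red == "pan_baltic_33":
            spec.load_multiplier = {
                int(b): 1.0 - 0.33 for b in geometry.dynamic_ids
            }
        elif isinstance(red, dict):
            spec.load_multiplier = {int(b): 1.0 - pct / 100.0 for b, pct in red.items()}
        for grp, (rule, base) in entry.get("F_rule", {}).items():
            if rule != "halve":
                raise ValidationError(f"unknown F rule {rule!r}")
            spec.F_overrides[grp] = {"adult": base / 2.0}
        for grp, fa in entry.get("F", {}).items():
            spec.F_overrides[grp] = {"adult": float(fa)}
        spec.validate(geometry)
        specs.append(spec)
    return specs


def applicable_scenarios(geometry: ModelGeometry, names: Sequence[str] | None = None,
                         **kw) -> dict[str, ScenarioSpec]:
    """Catalog entries that validate on this geometry, keyed by name."""
    out = {}
    for entry in scenario_catalog():
        if names is not None and entry["name"] not in names:
            continue
        try:
            (spec,) = build_scenarios(geometry, [entry], **kw)
        except ValidationError:
            continue
        out[spec.name] = spec
    return out


def write_scenario_catalog(path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"scenarios": scenario_catalog()}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# experiment configuration and projection runs
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a projection from a seed."""

    geometry: ModelGeometry
    groups: Mapping[str, FunctionalGroup]
    avail: AvailabilityMatrix
    physics: PhysicsParams = field(default_factory=PhysicsParams)
    loads: LoadParams = field(default_factory=LoadParams)
    deposition: DepositionParams = field(default_factory=DepositionParams)
    initial: InitialConditionParams = field(default_factory=InitialConditionParams)
    eco: EcosystemParams = field(default_factory=EcosystemParams)
    seed: int = 1

    @classmethod
    def mini8_default(cls, seed: int = 1) -> "ExperimentConfig":
        return cls(
            geometry=load_builtin_geometry("mini8"),
            groups=default_groups(),
            avail=default_availability(),
            seed=seed,
        )


def setup_simulation(cfg: ExperimentConfig):
    """Generate forcing + initial conditions and build the Simulation."""
    forcing = generate_physics(cfg.geometry, cfg.physics, cfg.seed)
    load_table = generate_loads(cfg.geometry, cfg.loads, cfg.seed)
    dep = deposition_flux(cfg.geometry, cfg.deposition)
    ic = generate_initial_conditions(cfg.geometry, cfg.groups, cfg.initial, cfg.seed, physics=forcing)
    sim = Simulation(cfg.geometry, cfg.groups, cfg.avail, forcing, load_table, dep, cfg.eco)
    return sim, ic


def run_projection(
    cfg: ExperimentConfig,
    spec: ScenarioSpec,
    sim_ic=None,
    track_daily: bool = False,
) -> RunResult:
    """Run one scenario projection (deterministic for the config seed).

    Years [0, change_year) use baseline loads and fishing mortalities;
    from the change year onward the spec's multipliers and F overrides
    apply as a step change.
    """
    spec.validate(cfg.geometry)
    sim, ic = setup_simulation(cfg) if sim_ic is None else sim_ic
    return sim.run(
        ic,
        spec.horizon_years,
        scenario_name=spec.name,
        change_year=spec.change_year,
        load_multipliers=spec.multiplier_array(cfg.geometry) if spec.load_multiplier else None,
        F_overrides=spec.resolved_F() or None,
        track_daily=track_daily,
    )


# ---------------------------------------------------------------------------
# terminal averaging and comparison
# ---------------------------------------------------------------------------


def terminal_average(result: RunResult, window: int | None = None) -> np.ndarray:
    """(n_groups, n_boxes) mean of annual means over the last ``window`` years."""
    if window is None:
        window = 5
    if window <= 0:
        raise ValidationError("terminal window must be > 0")
    if window > result.years:
        raise ValidationError("terminal window exceeds run length")
    return result.annual_box_biomass[-window:].mean(axis=0)


@dataclass
class ComparisonResult:
    """Scenario-vs-baseline percent changes on terminal averages."""

    scenario: str
    baseline: str
    group_pct: dict[str, float]
    group_undefined: dict[str, bool]
    bottom_o2_delta: np.ndarray  # (n_boxes,) mg m-3 change of terminal-mean bottom O2
    stock_table: Optional[pd.DataFrame] = None  # stock, index_plain, index_migration


def _area_boxes(geometry: ModelGeometry, regions: Sequence[str]) -> np.ndarray:
    return np.array([b.box_id for b in geometry.boxes if b.region in regions], dtype=int)


def stock_index(
    result: RunResult,
    baseline: RunResult,
    group: str,
    boxes: np.ndarray,
    window: int = 5,
    migration: bool = False,
) -> float:
    """Percent change of the stock's area biomass, two averaging variants.

    Variant (i) sums terminal-average annual-mean box biomasses over the
    area; variant (ii) averages the four quarterly mean fields first,
    respecting the seasonal distribution maps.  The two coincide when
    distributions are quarter-invariant.
    """
    gi = result.group_index(group)
    if migration:
        s = result.quarter_box_biomass[-window:, :, gi][:, :, boxes].mean(axis=(0, 1)).sum()
        b = baseline.quarter_box_biomass[-window:, :, gi][:, :, boxes].mean(axis=(0, 1)).sum()
    else:
        s = result.annual_box_biomass[-window:, gi][:, boxes].mean(axis=0).sum()
        b = baseline.annual_box_biomass[-window:, gi][:, boxes].mean(axis=0).sum()
    if b == 0:
        return float("nan")
    return 100.0 * (s - b) / b


def compare(
    result: RunResult,
    baseline: RunResult,
    geometry: ModelGeometry,
    window: int | None = None,
    stocks: Mapping[str, tuple[str, Sequence[str]]] | None = None,
) -> ComparisonResult:
    """Percent change of terminal-average domain biomass per group,
    bottom-O2 change per box, and optional per-stock area indices.

    A group whose baseline terminal average is zero is reported with an
    undefined flag rather than an infinite percentage.
    """
    if result.group_codes != baseline.group_codes:
        raise ValidationError("runs do not share a group list")
    w = min(window if window is not None else 5, result.years)
    ta_s = terminal_average(result, w).sum(axis=1)
    ta_b = terminal_average(baseline, w).sum(axis=1)
    pct = {}
    undef = {}
    for i, code in enumerate(result.group_codes):
        if ta_b[i] == 0:
            pct[code] = float("nan")
            undef[code] = True
        else:
            pct[code] = float(100.0 * (ta_s[i] - ta_b[i]) / ta_b[i])
            undef[code] = False
    o2_delta = (
        result.bottom_o2_annual[-w:].mean(axis=0) - baseline.bottom_o2_annual[-w:].mean(axis=0)
    )
    table = None
    if stocks:
        rows = []
        for stock_id, (group, regions) in stocks.items():
            boxes = _area_boxes(geometry, regions)
            rows.append(
                {
                    "stock": stock_id,
                    "group": group,
                    "index_plain": stock_index(result, baseline, group, boxes, w, migration=False),
                    "index_migration": stock_index(result, baseline, group, boxes, w, migration=True),
                }
            )
        table = pd.DataFrame(rows)
    return ComparisonResult(
        scenario=result.scenario,
        baseline=baseline.scenario,
        group_pct=pct,
        group_undefined=undef,
        bottom_o2_delta=o2_delta,
        stock_table=table,
    )


def comparison_to_frame(cmp_: ComparisonResult) -> pd.DataFrame:
    rows = [
        {"group": g, "pct_change": cmp_.group_pct[g], "undefined": cmp_.group_undefined[g]}
        for g in cmp_.group_pct
    ]
    return pd.DataFrame(rows)


#: default stock -> (group, regions) mapping for the bio-economic layer
DEFAULT_STOCKS: dict[str, tuple[str, tuple[str, ...]]] = {
    "COD_KA": ("FCD", ("kattegat",)),
    "COD_WB": ("FCD", ("western_baltic",)),
    "SPR_KAWB": ("FSR", ("kattegat", "western_baltic")),
    "HER_KAWB": ("FHR", ("kattegat", "western_baltic")),
    "NEP_KAWB": ("NE", ("kattegat", "western_baltic")),
}
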