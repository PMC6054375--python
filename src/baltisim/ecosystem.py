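"""The coupled run loop: physics forcing + transport + biogeochemistry
+ trophic dynamics on a daily ecological step with 12 h physics
sub-steps (advect -> vertical mix -> settle, then sediment exchange).

Nitrogen bookkeeping is exact by construction: every biological flux is
a transfer between tracer pools and biomass at the fixed N:wet-weight
conversion, so with the external terms (rivers, deposition, boundary
exchange, denitrification, burial, catch, anoxia removals) logged in
the budget ledger, total nitrogen closes to floating-point precision.
Recruitment is mass-conserving as well: the biomass of new recruits is
drawn from the prey fields of the juvenile stage (first-feeding larvae
graze the plankton/benthos), capped at a configurable fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .biogeochem import (
    LightParams,
    SinkParams,
    denitrify,
    light_profile,
    oxygen_step,
    producer_step,
    remineralize,
    surface_irradiance,
)
from .constants import MG_N_PER_TON_WW, O2_PER_N as O2_PER_N_CONST, SI_PER_N_DIATOM as SI_PER_N_CONST
from .groups import (
    ADULT,
    AvailabilityMatrix,
    DETRITAL_PREY,
    FunctionalGroup,
    JUVENILE,
    MG_N_PER_G_WW,
    validate_availability,
)
from .model_domain import ModelGeometry, TracerState, ValidationError
from .synthetic_forcing import (
    ForcingSeries,
    InitialConditions,
    STEPS_PER_DAY,
    effective_daily_loads,
)
from .transport import (
    TransportParams,
    advect,
    sediment_exchange,
    settle,
    vertical_mix,
)
from .trophic import (
    GroupState,
    MortalityResult,
    VertState,
    apply_anoxia_rule,
    condition_factor,
    age_cohorts,
    feeding_volume,
    gape_ok,
    holling_intake,
    pelagic_layer_mask,
    pool_mortality,
    recruit,
    refuge_fraction,
    stage_biomass_tons,
    stage_mean_weight_g,
    stage_slices,
    vertebrate_mortality,
)

#: nitrogen-bearing water tracers entering the budget identity.
N_WATER_TRACERS = ("NO3", "NH4", "DON", "DL", "DR")
N_SED_TRACERS = ("NO3", "NH4", "DL", "DR")


@dataclass
class EcosystemParams:
    """All process parameters of one simulation."""

    transport: TransportParams = field(default_factory=TransportParams)
    light: LightParams = field(default_factory=LightParams)
    sinks: SinkParams = field(default_factory=SinkParams)
    latitude: float = 56.0
    egestion_frac: float = 0.5
    egestion_refractory_frac: float = 0.3  # share of egestion going to refractory detritus
    recruit_prey_cap: float = 0.3  # recruit biomass cap as fraction of juvenile prey
    rivers_enabled: bool = True
    deposition_enabled: bool = True
    boundary_open: bool = True
    fishing_enabled: bool = True


@dataclass
class RunResult:
    """Trajectories and ledgers of one projection run."""

    scenario: str
    group_codes: list[str]
    years: int
    change_year: int
    annual_box_biomass: np.ndarray  # (Y, G, B) annual-mean tons
    quarter_box_biomass: np.ndarray  # (Y, 4, G, B)
    bottom_o2_annual: np.ndarray  # (Y, B) annual-mean mg m-3
    bottom_o2_min: np.ndarray  # (Y, B) annual minimum
    diet: pd.DataFrame  # year, predator, stage, prey, tons
    catch: pd.DataFrame  # year, group, stage, tons
    budget: pd.DataFrame  # per-year nitrogen budget ledger (mg N)
    demography: dict[str, np.ndarray]  # code -> (Y, A) annual-mean numbers
    recruitment: dict[str, np.ndarray]  # code -> (Y,) recruits
    final_tracers: TracerState
    final_groups: GroupState
    daily_n_total: Optional[np.ndarray] = None
    daily_budget: Optional[pd.DataFrame] = None

    @property
    def annual_biomass(self) -> np.ndarray:
        """(Y, G) domain-total annual-mean biomass."""
        return self.annual_box_biomass.sum(axis=2)

    def group_index(self, code: str) -> int:
        return self.group_codes.index(code)


def total_nitrogen_mg(state: TracerState, gs: GroupState, geometry: ModelGeometry) -> float:
    """Total nitrogen (mg) over the dynamic domain: water + sediment + biota.

    Boundary boxes are externally prescribed reservoirs and are excluded.
    """
    dyn = geometry.dynamic_mask
    vol = geometry.volume_matrix[dyn]
    sed_vol = (geometry.areas * geometry.layers.sediment_thickness)[dyn]
    tot = 0.0
    for tr in N_WATER_TRACERS:
        tot += float((state.water[tr][dyn] * vol).sum())
    for tr in N_SED_TRACERS:
        tot += float((state.sediment[tr][dyn] * sed_vol).sum())
    return tot + gs.biota_nitrogen_mg()


class Simulation:
    """Precomputed context for running one configuration."""

    def __init__(
        self,
        geometry: ModelGeometry,
        groups: Mapping[str, FunctionalGroup],
        avail: AvailabilityMatrix,
        forcing: ForcingSeries,
        load_table: pd.DataFrame,
        deposition_mg_day: np.ndarray,
        params: EcosystemParams | None = None,
    ):
        validate_availability(dict(avail), groups)
        self.geom = geometry
        self.groups = dict(groups)
        self.avail = dict(avail)
        self.forcing = forcing
        self.load_table = load_table
        self.dep_flux = np.asarray(deposition_mg_day)
        self.p = params or EcosystemParams()
        self.p.transport.validate()
        self.p.light.validate()
        self.p.sinks.validate()

        g = geometry
        self.vol = g.volume_matrix
        self.areas = g.areas
        self.sed_vol = g.areas * g.layers.sediment_thickness
        self.bottom = g.bottom_layer
        self.box_idx = np.arange(g.n_boxes)
        self.dyn = g.dynamic_mask
        self.thick = g.thickness_matrix
        self.pel_mask = pelagic_layer_mask(g)
        pel_vol = self.vol * self.pel_mask
        s = pel_vol.sum(axis=1, keepdims=True)
        self.pel_frac = np.divide(pel_vol, np.where(s > 0, s, 1.0))
        self.bottom_onehot = np.zeros_like(self.vol)
        self.bottom_onehot[self.box_idx, self.bottom] = 1.0
        self.surf_vol = self.vol[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            self._inv_vol = np.where(self.vol > 0, 1.0 / np.where(self.vol > 0, self.vol, 1.0), 0.0)
        # vertical-mixing exchange volumes (m3 day-1 across each interface)
        dt_dummy = 1.0
        thick = self.thick
        if thick.shape[1] > 1:
            dist = 0.5 * (thick[:, :-1] + thick[:, 1:])
            open_if = (thick[:, :-1] > 0) & (thick[:, 1:] > 0)
            rate = np.full(g.n_boxes, self.p.transport.vertical_mixing_rate)
            for b, r in self.p.transport.mixing_overrides.items():
                rate[b] = r
            if_depth = np.asarray(g.layers.interface_depths)[: thick.shape[1] - 1]
            damp = np.where(if_depth >= self.p.transport.halocline_depth,
                            self.p.transport.deep_mixing_factor, 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                self._mix_ex = np.where(
                    open_if,
                    rate[:, None] * damp[None, :] * g.areas[:, None] / np.where(dist > 0, dist, 1.0),
                    0.0,
                )
        else:
            self._mix_ex = np.zeros((g.n_boxes, 0))
        # settling fraction of each layer per 12 h sub-step, capped at 1
        self._settle_frac = {}
        for tr, ws in self.p.transport.settling_velocity.items():
            if ws > 0:
                with np.errstate(divide="ignore", invalid="ignore"):
                    self._settle_frac[tr] = np.where(
                        thick > 0,
                        np.minimum(ws / STEPS_PER_DAY / np.where(thick > 0, thick, 1.0), 1.0),
                        0.0,
                    )

        self.consumers = [
            (code, stage)
            for (code, stage) in self.avail
            if self.avail[(code, stage)]
        ]
        self.refuge = {
            code: refuge_fraction(grp, g) for code, grp in self.groups.items()
        }
        # vertical feeding masks: which water layers a predator searches
        self.feed_mask = {}
        surface_onehot = np.zeros_like(self.vol, dtype=bool)
        surface_onehot[:, 0] = True
        for code, grp in self.groups.items():
            if grp.habitat == "pelagic":
                self.feed_mask[code] = self.pel_mask
            elif grp.habitat == "benthic" and "bedrock" in grp.habitat_affinity:
                self.feed_mask[code] = surface_onehot
            else:
                self.feed_mask[code] = self.bottom_onehot > 0
        self.vfeed = {code: feeding_volume(grp, g) for code, grp in self.groups.items()}
        # dispersal target profiles per pool group
        self.mix_profile = {}
        for code, grp in self.groups.items():
            if grp.is_vertebrate:
                continue
            if grp.habitat == "pelagic":
                prof = self.pel_frac * (self.vol * self.pel_mask).sum(axis=1, keepdims=True)
            elif grp.habitat == "demersal":
                prof = self.bottom_onehot * self.vol[self.box_idx, self.bottom][:, None]
            else:
                cover = np.zeros(g.n_boxes)
                for hab, aff in grp.habitat_affinity.items():
                    cover += aff * np.array([b.habitat_cover.get(hab, 0.0) for b in g.boxes])
                w = cover * g.areas
                if "bedrock" in grp.habitat_affinity:
                    prof = np.zeros_like(self.vol)
                    prof[:, 0] = w
                else:
                    prof = self.bottom_onehot * w[:, None]
            prof = prof * self.dyn[:, None]
            tot = prof.sum()
            self.mix_profile[code] = prof / tot if tot > 0 else prof

        # suitable-habitat area for space-limited benthic producers
        self.space_cap = {}
        for code, grp in self.groups.items():
            if grp.kind == "producer" and grp.params.space_capacity_per_m2 is not None:
                cover = np.zeros(g.n_boxes)
                for hab, aff in grp.habitat_affinity.items():
                    cover += aff * np.array([b.habitat_cover.get(hab, 0.0) for b in g.boxes])
                cap_box = grp.params.space_capacity_per_m2 * cover * g.areas * self.dyn
                prof = np.zeros_like(self.vol)
                if grp.habitat == "benthic" and "bedrock" in grp.habitat_affinity:
                    prof[:, 0] = 1.0
                else:
                    prof = self.bottom_onehot
                self.space_cap[code] = cap_box[:, None] * prof

    # ------------------------------------------------------------------
    def run(
        self,
        ic: InitialConditions,
        years: int,
        *,
        scenario_name: str = "status_quo",
        change_year: int | None = None,
        load_multipliers: np.ndarray | None = None,
        F_overrides: Mapping[str, tuple[float, float]] | None = None,
        track_daily: bool = False,
        progress: bool = False,
    ) -> RunResult:
        geom = self.geom
        G = len(self.groups)
        B = geom.n_boxes
        codes = list(self.groups)
        state = ic.tracers.copy()
        gs = ic.groups.copy()

        base_loads = effective_daily_loads(geom, self.load_table)
        scen_loads = base_loads
        if load_multipliers is not None:
            scen_loads = effective_daily_loads(geom, self.load_table, load_multipliers)
        cur_F: dict[str, tuple[float, float]] = {}
        for code, grp in self.groups.items():
            if grp.is_vertebrate:
                cur_F[code] = (grp.params.F_adult, grp.params.F_juvenile)
        if not self.p.fishing_enabled:
            cur_F = {c: (0.0, 0.0) for c in cur_F}

        Y = years
        annual_box = np.zeros((Y, G, B))
        quarter_box = np.zeros((Y, 4, G, B))
        quarter_days = np.zeros((Y, 4))
        o2_sum = np.zeros((Y, B))
        o2_min = np.full((Y, B), np.inf)
        demo = {
            c: np.zeros((Y, self.groups[c].params.n_cohorts))
            for c in codes
            if self.groups[c].is_vertebrate
        }
        recr = {c: np.zeros(Y) for c in demo}
        diet_acc: dict[tuple[int, str, str, str], float] = {}
        catch_acc: dict[tuple[int, str, str], float] = {}
        budget_rows = []
        daily_n = [] if track_daily else None
        daily_rows = [] if track_daily else None

        ledger = {
            "rivers": 0.0, "deposition": 0.0, "boundary": 0.0,
            "denitrification": 0.0, "burial": 0.0, "catch": 0.0, "anoxia_loss": 0.0,
        }

        for year in range(Y):
            if change_year is not None and year == change_year:
                loads_now = scen_loads
                if F_overrides and self.p.fishing_enabled:
                    for code, (fa, fj) in F_overrides.items():
                        cur_F[code] = (fa, fj)
            elif year == 0:
                loads_now = base_loads
            y_ledger0 = dict(ledger)
            n_start = total_nitrogen_mg(state, gs, geom)

            for doy in range(365):
                quarter = min(3, doy // 92)
                state = self._physics_day(state, doy, ledger)
                if self.p.rivers_enabled:
                    self._apply_loads(state, loads_now, ledger)
                if self.p.deposition_enabled:
                    self._apply_deposition(state, ledger)
                state = self._biogeochem_day(state, gs, doy, ledger)
                o2_bot = state.water["O2"][self.box_idx, self.bottom]
                pelv = self.vol * self.pel_mask
                o2_pel = (state.water["O2"] * pelv).sum(axis=1) / np.maximum(pelv.sum(axis=1), 1.0)
                eff_dists, anoxia_lost = self._anoxia(gs, quarter, o2_bot, o2_pel, ledger)
                self._trophic_day(state, gs, quarter, o2_bot, eff_dists, year, diet_acc)
                self._mortality_day(state, gs, o2_bot, cur_F, eff_dists, year, catch_acc, ledger)
                self._recruitment(gs, state, doy, quarter, recr, year)
                if doy == 364:
                    for code in demo:
                        gs.verts[code] = age_cohorts(gs.verts[code], self.groups[code].params)

                self._mix_mobile_pools(gs)

                # accumulators
                box_b = self._box_biomass(gs, eff_dists, quarter)
                annual_box[year] += box_b / 365.0
                quarter_box[year, quarter] += box_b
                quarter_days[year, quarter] += 1.0
                o2_sum[year] += o2_bot / 365.0
                o2_min[year] = np.minimum(o2_min[year], o2_bot)
                if doy == 363:  # pre-ageing snapshot: every cohort fully recruited
                    for code in demo:
                        demo[code][year] = gs.verts[code].numbers.copy()
                if track_daily:
                    daily_n.append(total_nitrogen_mg(state, gs, geom))
                    daily_rows.append(dict(ledger))
                if not np.isfinite(state.water["NO3"]).all():
                    raise ValidationError(
                        f"non-finite state in year {year}, day {doy}: run aborted"
                    )

            n_end = total_nitrogen_mg(state, gs, geom)
            row = {"year": year, "n_start": n_start, "n_end": n_end}
            for k in ledger:
                row[k] = ledger[k] - y_ledger0[k]
            budget_rows.append(row)

        for y in range(Y):
            for q in range(4):
                if quarter_days[y, q] > 0:
                    quarter_box[y, q] /= quarter_days[y, q]

        diet = pd.DataFrame(
            [
                {"year": y, "predator": p, "stage": s, "prey": pr, "tons": v}
                for (y, p, s, pr), v in sorted(diet_acc.items())
            ],
            columns=["year", "predator", "stage", "prey", "tons"],
        )
        catch = pd.DataFrame(
            [
                {"year": y, "group": c, "stage": s, "tons": v}
                for (y, c, s), v in sorted(catch_acc.items())
            ],
            columns=["year", "group", "stage", "tons"],
        )
        budget = pd.DataFrame(budget_rows)
        daily_budget = pd.DataFrame(daily_rows) if track_daily else None
        return RunResult(
            scenario=scenario_name,
            group_codes=codes,
            years=Y,
            change_year=change_year if change_year is not None else Y,
            annual_box_biomass=annual_box,
            quarter_box_biomass=quarter_box,
            bottom_o2_annual=o2_sum,
            bottom_o2_min=o2_min,
            diet=diet,
            catch=catch,
            budget=budget,
            demography=demo,
            recruitment=recr,
            final_tracers=state,
            final_groups=gs,
            daily_n_total=np.array(daily_n) if track_daily else None,
            daily_budget=daily_budget,
        )

    # ------------------------------------------------------------------
    # daily sub-processes
    # ------------------------------------------------------------------

    def _physics_day(self, state: TracerState, doy: int, ledger: dict) -> TracerState:
        """Stacked-tracer fast path: advect -> mix -> settle per 12 h
        sub-step, then sediment exchange.  Numerically identical to the
        pure operators in :mod:`baltisim.transport` (asserted by test)."""
        tp = self.p.transport
        geom = self.geom
        dt = 1.0 / STEPS_PER_DAY
        names = list(state.water)
        K = len(names)
        n_idx = [i for i, n in enumerate(names) if n in N_WATER_TRACERS]
        c = np.stack([state.water[n] for n in names])  # (K, B, L)
        vol = self.vol
        left, right = geom.face_left, geom.face_right
        dyn = self.dyn
        bnd_face = ~dyn[left] | ~dyn[right]
        flm = geom.face_layer_mask
        inv_vol = self._inv_vol
        boundary_gain = 0.0

        for sub in range(STEPS_PER_DAY):
            idx = self.forcing.step_index(doy, sub)
            if self.p.boundary_open:
                for i, tr in enumerate(names):
                    clim = self.forcing.boundary_tracers.get(tr)
                    if clim is not None:
                        c[i][~dyn] = clim[idx][~dyn]
                q = np.where(flm, self.forcing.exchange[idx], 0.0)
            else:
                q = np.where(flm & ~bnd_face[:, None], self.forcing.exchange[idx], 0.0)
            pos = np.clip(q, 0.0, None)
            neg = np.clip(-q, 0.0, None)
            m_lr = pos[None] * c[:, left, :]
            m_rl = neg[None] * c[:, right, :]
            net = m_lr - m_rl  # (K, F, L) mass left -> right
            dm = np.zeros_like(c)
            np.add.at(dm, (slice(None), right), net)
            np.add.at(dm, (slice(None), left), -net)
            if self.p.boundary_open:
                gain = np.where(dyn[right][:, None], net, 0.0) - np.where(dyn[left][:, None], net, 0.0)
                boundary_gain += float(gain[n_idx][:, bnd_face].sum())
            c = np.where(dyn[None, :, None], c + dm * inv_vol[None], c)
            # vertical mixing (single sub-step; coefficients precomputed)
            if c.shape[2] > 1:
                grad = c[:, :, :-1] - c[:, :, 1:]
                m = self._mix_ex[None] * dt * grad
                c[:, :, :-1] -= m * inv_vol[None, :, :-1]
                c[:, :, 1:] += m * inv_vol[None, :, 1:]
            # settling
            for tr, frac in self._settle_frac.items():
                i = names.index(tr)
                m_down = frac * c[i] * vol
                dmass = -m_down.copy()
                dmass[:, 1:] += m_down[:, :-1]
                to_sed = m_down[self.box_idx, self.bottom]
                below = self.bottom + 1
                ok = below < c.shape[2]
                dmass[self.box_idx[ok], below[ok]] -= m_down[self.box_idx[ok], self.bottom[ok]]
                c[i] = c[i] + dmass * inv_vol
                if tr in state.sediment:
                    state.sediment[tr] = state.sediment[tr] + to_sed / self.sed_vol
        for i, n in enumerate(names):
            state.water[n] = c[i]
        # sediment porewater <-> bottom water solute exchange
        k = min(tp.bioturbation_exchange, 0.5)
        if k > 0:
            vb = vol[self.box_idx, self.bottom]
            for tr in ("NO3", "NH4"):
                c_sed = state.sediment[tr]
                c_bot = state.water[tr][self.box_idx, self.bottom]
                m = k * (c_sed - c_bot) * self.sed_vol
                state.sediment[tr] = c_sed - m / self.sed_vol
                state.water[tr][self.box_idx, self.bottom] = c_bot + m / vb
        ledger["boundary"] += boundary_gain
        return state

    def _apply_loads(self, state: TracerState, loads: dict, ledger: dict) -> None:
        for tracer, key in (("NO3", "din"), ("DON", "don"), ("DR", "refractory")):
            tons = loads[key]
            mg = tons * 1e9  # tons N -> mg N
            state.water[tracer][:, 0] += mg / self.surf_vol
            ledger["rivers"] += float(mg[self.dyn].sum())

    def _apply_deposition(self, state: TracerState, ledger: dict) -> None:
        mg = np.where(self.dyn, self.dep_flux, 0.0)
        state.water["NH4"][:, 0] += mg / self.surf_vol
        ledger["deposition"] += float(mg.sum())

    def _biogeochem_day(self, state: TracerState, gs: GroupState, doy: int, ledger: dict) -> TracerState:
        p = self.p
        I0 = surface_irradiance(p.latitude, doy, p.light.transmissivity)
        # light attenuation from pelagic producer biomass
        conc = np.zeros_like(self.vol)
        for code, grp in self.groups.items():
            if grp.kind == "producer" and grp.habitat == "pelagic":
                with np.errstate(divide="ignore", invalid="ignore"):
                    conc += np.where(
                        self.vol > 0, gs.pools[code] * MG_N_PER_TON_WW / np.where(self.vol > 0, self.vol, 1.0), 0.0
                    )
        k = p.light.k_w + p.light.k_bio * conc
        tau_layer = k * self.thick
        tau_top = np.concatenate(
            [np.zeros((self.geom.n_boxes, 1)), np.cumsum(tau_layer, axis=1)[:, :-1]], axis=1
        )
        light = I0 * np.exp(-(tau_top + 0.5 * tau_layer))

        # all producers draw on the same start-of-day nutrient fields;
        # when their combined demand exceeds the available N in a cell,
        # every group's uptake is scaled down proportionally
        producer_growth: dict[str, np.ndarray] = {}
        need_tot = np.zeros_like(self.vol)
        for code, grp in self.groups.items():
            if grp.kind != "producer":
                continue
            cap = self.space_cap.get(code)
            grp_light = light
            if grp.habitat == "benthic":
                # shoreline fringe producers sit just below the surface
                grp_light = light.copy()
                grp_light[:, 0] = I0 * np.exp(-k[:, 0] * 1.5)
            res = producer_step(
                gs.pools[code],
                state.water["NO3"],
                state.water["NH4"],
                grp_light,
                self.vol,
                grp.params,
                1.0,
                space_capacity=cap,
                cap_at_available=False,
            )
            growth = np.where(self.dyn[:, None], res["growth"], 0.0)
            producer_growth[code] = growth
            need_tot += growth * MG_N_PER_TON_WW
        nh4_mass = np.clip(state.water["NH4"], 0, None) * self.vol
        no3_mass = np.clip(state.water["NO3"], 0, None) * self.vol
        avail_mg = nh4_mass + no3_mass
        factor = np.ones_like(need_tot)
        over = need_tot > avail_mg
        if np.any(over):
            factor[over] = avail_mg[over] / need_tot[over]
        take_tot = need_tot * factor
        from_nh4 = np.minimum(take_tot, nh4_mass)
        from_no3 = take_tot - from_nh4
        inv_v = self._inv_vol
        state.water["NH4"] = state.water["NH4"] - from_nh4 * inv_v
        state.water["NO3"] = state.water["NO3"] - from_no3 * inv_v
        state.water["O2"] = state.water["O2"] + take_tot * O2_PER_N_CONST * inv_v
        for code, growth in producer_growth.items():
            grp = self.groups[code]
            growth = growth * factor
            gs.pools[code] = gs.pools[code] + growth
            if code == "PL" and "SiO4" in state.water:
                state.water["SiO4"] = np.clip(
                    state.water["SiO4"] - growth * MG_N_PER_TON_WW * SI_PER_N_CONST * inv_v, 0.0, None
                )
            # linear producer mortality -> labile detritus
            frac = 1.0 - np.exp(-grp.params.mortality_lin)
            loss = gs.pools[code] * frac
            gs.pools[code] = gs.pools[code] - loss
            loss_mg = loss * MG_N_PER_TON_WW
            if grp.habitat == "pelagic":
                state.water["DL"] += loss_mg * inv_v
            else:
                state.sediment["DL"] += loss_mg.sum(axis=1) / self.sed_vol

        bledger: dict[str, float] = {}
        dledger: dict[str, float] = {}
        state = remineralize(state, self.geom, p.sinks, 1.0, burial_ledger=bledger, ledger_mask=self.dyn, inplace=True)
        state = denitrify(state, self.geom, p.sinks, 1.0, denit_ledger=dledger, ledger_mask=self.dyn, inplace=True)
        idx = self.forcing.step_index(doy, 0)
        state = oxygen_step(
            state, self.geom, p.sinks, self.forcing.temperature[idx], self.forcing.salinity[idx], 1.0,
            inplace=True,
        )
        ledger["burial"] += sum(bledger.values())
        ledger["denitrification"] += sum(dledger.values())
        return state

    # ------------------------------------------------------------------

    def _anoxia(self, gs: GroupState, quarter: int, o2_bot: np.ndarray,
                o2_pel: np.ndarray, ledger: dict):
        eff_dists: dict[tuple[str, str], np.ndarray] = {}
        for code, grp in self.groups.items():
            if not grp.is_vertebrate:
                continue
            vs = gs.verts[code]
            o2_field = o2_pel if grp.habitat == "pelagic" else o2_bot
            dists, lost = apply_anoxia_rule(vs, grp.params, quarter, o2_field)
            for stage, d in dists.items():
                eff_dists[(code, stage)] = d
            ledger["anoxia_loss"] += lost * MG_N_PER_TON_WW
        return eff_dists, None

    def _vert_info(self, gs: GroupState):
        """Per-day cache of stage aggregates for every vertebrate."""
        info = {}
        for code, grp in self.groups.items():
            if not grp.is_vertebrate:
                continue
            vs = gs.verts[code]
            p = grp.params
            b_coh = vs.numbers * vs.weight / MG_N_PER_TON_WW
            w_ref = np.asarray(p.init_weight_g) * MG_N_PER_G_WW
            for stage, sl in stage_slices(p).items():
                b = b_coh[sl]
                bt = float(b.sum())
                n = vs.numbers[sl]
                nt = float(n.sum())
                if bt > 0:
                    C = float((b * np.asarray(p.clearance)[sl]).sum() / bt)
                    g = float((b * np.asarray(p.max_intake)[sl]).sum() / bt)
                    mean_w = float((n * vs.weight[sl]).sum() / nt) / MG_N_PER_G_WW if nt > 0 else 0.0
                    ratio = float((n * vs.weight[sl]).sum() / (n * w_ref[sl]).sum()) if nt > 0 else 1.0
                    satiety = float(np.clip((1.4 - ratio) / 0.4, 0.0, 1.0))
                    res = float((n * vs.w_res[sl]).sum())
                    struct = float((n * vs.w_struct[sl]).sum())
                    ref = p.reserve_frac / (1.0 - p.reserve_frac)
                    cond = float(np.clip((res / struct) / ref, 0.5, 1.5)) if struct > 0 else 1.0
                else:
                    C = float(np.mean(np.asarray(p.clearance)[sl]))
                    g = float(np.mean(np.asarray(p.max_intake)[sl]))
                    mean_w = float(np.mean(vs.weight[sl])) / MG_N_PER_G_WW
                    satiety = 1.0
                    cond = 1.0
                info[(code, stage)] = {
                    "total": bt, "C": C, "g": g, "mean_w_g": mean_w,
                    "cond": cond * satiety,
                }
        return info

    def _prey_entities(self, state: TracerState, gs: GroupState, eff_dists, vert_info):
        """Box biomass (tons) of every consumable entity."""
        ent: dict[tuple[str, str], np.ndarray] = {}
        for code, grp in self.groups.items():
            if grp.is_vertebrate:
                for stage in (JUVENILE, ADULT):
                    ent[(code, stage)] = vert_info[(code, stage)]["total"] * eff_dists[(code, stage)]
            else:
                ent[(code, ADULT)] = gs.pools[code].sum(axis=1)
        ent[("DL", ADULT)] = (state.water["DL"] * self.vol).sum(axis=1) / MG_N_PER_TON_WW
        ent[("DLsed", ADULT)] = state.sediment["DL"] * self.sed_vol / MG_N_PER_TON_WW
        ent[("DRsed", ADULT)] = state.sediment["DR"] * self.sed_vol / MG_N_PER_TON_WW
        return ent

    def _trophic_day(self, state, gs, quarter, o2_bot, eff_dists, year, diet_acc):
        vert_info = self._vert_info(gs)
        ent = self._prey_entities(state, gs, eff_dists, vert_info)

        demands = []  # (pred, stage, prey_keys, demand (J,B))
        total_demand: dict[tuple[str, str], np.ndarray] = {}
        for code, stage in self.consumers:
            grp = self.groups[code]
            prey_map = self.avail[(code, stage)]
            if grp.is_vertebrate:
                vi = vert_info[(code, stage)]
                P = vi["total"] * eff_dists[(code, stage)]
                cond = vi["cond"]
                pw = vi["mean_w_g"]
                C, g = vi["C"], vi["g"]
            else:
                P = gs.pools[code].sum(axis=1)
                cond = 1.0
                pw = None
                C, g = grp.params.clearance, grp.params.max_intake
            if P.sum() <= 0:
                continue
            keys = []
            beff = []
            fmask = self.feed_mask[code]
            for prey, a in prey_map.items():
                for pstage in ((JUVENILE, ADULT) if (prey in self.groups and self.groups[prey].is_vertebrate) else (ADULT,)):
                    b_box = ent[(prey, pstage)]
                    if pw is not None and prey not in DETRITAL_PREY:
                        if prey in self.groups and self.groups[prey].is_vertebrate:
                            prw = vert_info[(prey, pstage)]["mean_w_g"]
                        else:
                            prw = self.groups[prey].nominal_prey_weight_g
                        if not gape_ok(pw, prw, grp.params):
                            continue
                    refg = self.refuge.get(prey, 0.0) if prey in self.groups else 0.0
                    # vertical overlap: share of the prey field inside the
                    # predator's searched layers (mobile vertebrate prey and
                    # sediment pools are fully encounterable)
                    if prey == "DL":
                        fld = state.water["DL"] * self.vol
                        tot = fld.sum(axis=1)
                        ov = np.divide((fld * fmask).sum(axis=1), np.where(tot > 0, tot, 1.0))
                    elif prey in self.groups and not self.groups[prey].is_vertebrate:
                        fld = gs.pools[prey]
                        tot = fld.sum(axis=1)
                        ov = np.divide((fld * fmask).sum(axis=1), np.where(tot > 0, tot, 1.0))
                    else:
                        ov = 1.0
                    keys.append((prey, pstage))
                    beff.append(a * (1.0 - refg) * ov * b_box)
            if not keys:
                continue
            beff = np.array(beff)  # (J, B)
            D = beff / self.vfeed[code][None, :]
            aB = D
            denom = 1.0 + (C / g) * aB.sum(axis=0)
            r = C * aB / denom
            demand = r * (P * cond)[None, :]  # tons/day
            demands.append((code, stage, keys, demand))
            for j, key in enumerate(keys):
                if key in total_demand:
                    total_demand[key] = total_demand[key] + demand[j]
                else:
                    total_demand[key] = demand[j]

        # proportional capping at the available prey biomass
        factors = {}
        for key, dem in total_demand.items():
            av = ent[key]
            f = np.ones_like(dem)
            over = dem > av
            if np.any(over):
                f[over] = np.where(dem[over] > 0, av[over] / dem[over], 0.0)
            factors[key] = f

        debits: dict[tuple[str, str], np.ndarray] = {}
        for code, stage, keys, demand in demands:
            grp = self.groups[code]
            realized = np.array([demand[j] * factors[keys[j]] for j in range(len(keys))])
            intake_box = realized.sum(axis=0)  # (B,) tons eaten by this stage per box
            for j, key in enumerate(keys):
                if key in debits:
                    debits[key] = debits[key] + realized[j]
                else:
                    debits[key] = realized[j]
                tons = float(realized[j].sum())
                if tons > 0:
                    k = (year, code, stage, key[0])
                    diet_acc[k] = diet_acc.get(k, 0.0) + tons
            growth = grp.params.assimilation * intake_box
            waste = intake_box - growth
            eg = waste * self.p.egestion_frac
            ex = waste - eg
            self._deposit_waste(state, grp, eg, ex)
            self._apply_growth(gs, code, stage, growth)

        self._apply_debits(state, gs, ent, debits, eff_dists, quarter)

    def _deposit_waste(self, state, grp, egestion_tons, excretion_tons):
        fr = self.p.egestion_refractory_frac
        eg_dl = egestion_tons * (1.0 - fr) * MG_N_PER_TON_WW
        eg_dr = egestion_tons * fr * MG_N_PER_TON_WW
        ex_mg = excretion_tons * MG_N_PER_TON_WW
        if grp.habitat == "benthic":
            state.sediment["DL"] += eg_dl / self.sed_vol
            state.sediment["DR"] += eg_dr / self.sed_vol
            nh = state.water["NH4"]
            nh[self.box_idx, self.bottom] += ex_mg / self.vol[self.box_idx, self.bottom]
        elif grp.habitat == "demersal":
            vb = self.vol[self.box_idx, self.bottom]
            state.water["DL"][self.box_idx, self.bottom] += eg_dl / vb
            state.water["DR"][self.box_idx, self.bottom] += eg_dr / vb
            state.water["NH4"][self.box_idx, self.bottom] += ex_mg / vb
        else:
            inv = self._inv_vol
            state.water["DL"] += eg_dl[:, None] * self.pel_frac * inv
            state.water["DR"] += eg_dr[:, None] * self.pel_frac * inv
            state.water["NH4"] += ex_mg[:, None] * self.pel_frac * inv

    def _apply_growth(self, gs, code, stage, growth_box):
        grp = self.groups[code]
        total = float(growth_box.sum())
        if total <= 0:
            return
        if not grp.is_vertebrate:
            pool = gs.pools[code]
            box_tot = pool.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.divide(pool, np.where(box_tot[:, None] > 0, box_tot[:, None], 1.0))
            has = box_tot > 0
            gs.pools[code] = pool + np.where(has[:, None], growth_box[:, None] * frac, 0.0)
            # growth in boxes without standing biomass: put in bottom/pelagic profile
            rest = growth_box * (~has)
            if rest.sum() > 0:
                prof = self.pel_frac if grp.habitat == "pelagic" else self.bottom_onehot
                gs.pools[code] = gs.pools[code] + rest[:, None] * prof
        else:
            vs = gs.verts[code]
            p = grp.params
            sl = stage_slices(p)[stage]
            n = vs.numbers[sl]
            w = vs.weight[sl]
            cap = n * w * np.asarray(p.max_intake)[sl]
            if cap.sum() <= 0:
                return
            share = cap / cap.sum()
            add_mg = total * MG_N_PER_TON_WW * share
            with np.errstate(divide="ignore", invalid="ignore"):
                dw = np.where(n > 0, add_mg / np.where(n > 0, n, 1.0), 0.0)
            vs.w_res[sl] = vs.w_res[sl] + dw * p.growth_split_reserve
            vs.w_struct[sl] = vs.w_struct[sl] + dw * (1.0 - p.growth_split_reserve)

    def _apply_debits(self, state, gs, ent, debits, eff_dists, quarter):
        for (prey, pstage), tons_box in debits.items():
            tons_box = np.minimum(tons_box, ent[(prey, pstage)])
            total = float(tons_box.sum())
            if total <= 0:
                continue
            if prey == "DL":
                mass = state.water["DL"] * self.vol
                box_mass = mass.sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    f = np.where(box_mass > 0, tons_box * MG_N_PER_TON_WW / np.where(box_mass > 0, box_mass, 1.0), 0.0)
                state.water["DL"] = state.water["DL"] * (1.0 - np.clip(f, 0.0, 1.0))[:, None]
            elif prey in ("DLsed", "DRsed"):
                tr = "DL" if prey == "DLsed" else "DR"
                mass = state.sediment[tr] * self.sed_vol
                with np.errstate(divide="ignore", invalid="ignore"):
                    f = np.where(mass > 0, tons_box * MG_N_PER_TON_WW / np.where(mass > 0, mass, 1.0), 0.0)
                state.sediment[tr] = state.sediment[tr] * (1.0 - np.clip(f, 0.0, 1.0))
            elif not self.groups[prey].is_vertebrate:
                pool = gs.pools[prey]
                box_tot = pool.sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    f = np.where(box_tot > 0, tons_box / np.where(box_tot > 0, box_tot, 1.0), 0.0)
                gs.pools[prey] = pool * (1.0 - np.clip(f, 0.0, 1.0))[:, None]
            else:
                vs = gs.verts[prey]
                p = self.groups[prey].params
                sl = stage_slices(p)[pstage]
                stage_mg = float((vs.numbers[sl] * vs.weight[sl]).sum())
                if stage_mg <= 0:
                    continue
                f = min(total * MG_N_PER_TON_WW / stage_mg, 1.0)
                vs.numbers[sl] = vs.numbers[sl] * (1.0 - f)

    # ------------------------------------------------------------------

    def _mortality_day(self, state, gs, o2_bot, cur_F, eff_dists, year, catch_acc, ledger):
        for code, grp in self.groups.items():
            if grp.kind == "producer":
                continue  # producer mortality applied in the biogeochem step
            if not grp.is_vertebrate:
                new_pool, loss_box = pool_mortality(gs.pools[code], grp, o2_bot, 1.0)
                gs.pools[code] = new_pool
                loss_mg = loss_box * MG_N_PER_TON_WW
                if grp.habitat == "benthic":
                    state.sediment["DL"] += loss_mg / self.sed_vol
                elif grp.habitat == "demersal":
                    dl = state.water["DL"]
                    dl[self.box_idx, self.bottom] += loss_mg / self.vol[self.box_idx, self.bottom]
                else:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        inv = np.where(self.vol > 0, 1.0 / np.where(self.vol > 0, self.vol, 1.0), 0.0)
                    state.water["DL"] += loss_mg[:, None] * self.pel_frac * inv
            else:
                fa, fj = cur_F[code]
                vs, res = vertebrate_mortality(gs.verts[code], grp.params, 1.0, fa, fj)
                gs.verts[code] = vs
                for stage, tons in res.catch_tons.items():
                    if tons > 0:
                        k = (year, code, stage)
                        catch_acc[k] = catch_acc.get(k, 0.0) + tons
                        ledger["catch"] += tons * MG_N_PER_TON_WW
                # carrion to labile detritus, distributed by the stage maps
                det_mg = res.detritus_tons * MG_N_PER_TON_WW
                d = eff_dists[(code, ADULT)]
                if d.sum() <= 0:
                    d = np.where(self.dyn, self.areas, 0.0) / self.areas[self.dyn].sum()
                with np.errstate(divide="ignore", invalid="ignore"):
                    inv = np.where(self.vol > 0, 1.0 / np.where(self.vol > 0, self.vol, 1.0), 0.0)
                state.water["DL"] += det_mg * d[:, None] * self.pel_frac * inv

    def _recruitment(self, gs, state, doy, quarter, recr, year):
        for code, grp in self.groups.items():
            if not grp.is_vertebrate:
                continue
            p = grp.params
            if doy != p.spawn_day:
                continue
            vs = gs.verts[code]
            d_spawn = vs.dist[ADULT][p.spawn_quarter]
            if grp.habitat == "pelagic":
                pelv = self.vol * self.pel_mask
                o2_bot = (state.water["O2"] * pelv).sum(axis=1) / np.maximum(pelv.sum(axis=1), 1.0)
            else:
                o2_bot = state.water["O2"][self.box_idx, self.bottom]
            if grp.habitat == "demersal":
                T = self.forcing.temperature[self.forcing.step_index(doy, 0)][self.box_idx, self.bottom]
                S = self.forcing.salinity[self.forcing.step_index(doy, 0)][self.box_idx, self.bottom]
            else:
                T = self.forcing.temperature[self.forcing.step_index(doy, 0)][:, 0]
                S = self.forcing.salinity[self.forcing.step_index(doy, 0)][:, 0]
            envT = float((d_spawn * T).sum())
            envS = float((d_spawn * S).sum())
            envO2 = float((d_spawn * o2_bot).sum())
            new_vs, R = recruit(vs, p, env_T=envT, env_S=envS, env_O2=envO2)
            # mass conservation: recruit biomass is grazed off the
            # juvenile stage's prey fields
            need_mg = R * p.recruit_weight_g * MG_N_PER_G_WW
            if need_mg > 0:
                got = self._debit_recruit_mass(gs, state, code, quarter, need_mg)
                if got < need_mg:
                    R_new = R * (got / need_mg)
                    new_vs = vs.copy()
                    wr = p.recruit_weight_g * MG_N_PER_G_WW
                    ntot = vs.numbers[0] + R_new
                    if ntot > 0:
                        mean_w = (vs.numbers[0] * vs.weight[0] + R_new * wr) / ntot
                        new_vs.w_struct[0] = mean_w * (1.0 - p.reserve_frac)
                        new_vs.w_res[0] = mean_w * p.reserve_frac
                    new_vs.numbers[0] = ntot
                    R = R_new
            gs.verts[code] = new_vs
            recr[code][year] += R

    def _debit_recruit_mass(self, gs, state, code, quarter, need_mg) -> float:
        """Remove recruit biomass from the juvenile diet's prey pools."""
        prey_map = self.avail.get((code, JUVENILE), {})
        dyn = self.dyn
        pools = []
        for prey in prey_map:
            if prey == "DL":
                pools.append(("DL", float((state.water["DL"][dyn] * self.vol[dyn]).sum())))
            elif prey == "DLsed":
                pools.append(("DLsed", float((state.sediment["DL"][dyn] * self.sed_vol[dyn]).sum())))
            elif prey == "DRsed":
                pools.append(("DRsed", float((state.sediment["DR"][dyn] * self.sed_vol[dyn]).sum())))
            elif prey in gs.pools:
                pools.append((prey, float(gs.pools[prey].sum()) * MG_N_PER_TON_WW))
            elif prey in gs.verts:
                vs = gs.verts[prey]
                pools.append((prey, float((vs.numbers * vs.weight).sum())))
        avail_mg = sum(m for _, m in pools)
        take = min(need_mg, self.p.recruit_prey_cap * avail_mg)
        if avail_mg <= 0 or take <= 0:
            return 0.0
        for prey, m in pools:
            if m <= 0:
                continue
            share = take * m / avail_mg
            f = 1.0 - share / m
            if prey == "DL":
                state.water["DL"][dyn] *= f
            elif prey == "DLsed":
                state.sediment["DL"][dyn] *= f
            elif prey == "DRsed":
                state.sediment["DR"][dyn] *= f
            elif prey in gs.pools:
                gs.pools[prey] *= f
            else:
                gs.verts[prey].numbers *= f
        return take

    # ------------------------------------------------------------------

    #: day-1 relaxation of pool fields toward their habitat profile:
    #: swimming pools follow the circulation quickly, drifting
    #: phytoplankton slowly, and sessile benthos only through larval
    #: dispersal.
    POOL_MIX_RATES = {"pool_mobile": 0.05, "producer": 0.005, "benthic": 0.0005}

    def _mix_mobile_pools(self, gs: GroupState) -> None:
        """Slow exchange of pool biomass between boxes (dispersal).

        Each pool relaxes toward its habitat profile at a
        kind-dependent rate, which reseeds locally depleted boxes and
        represents passive drift/larval dispersal; totals are conserved
        exactly."""
        for code, grp in self.groups.items():
            if code not in gs.pools:
                continue
            if grp.habitat == "benthic":
                k_use = self.POOL_MIX_RATES["benthic"]
            elif grp.kind == "producer":
                k_use = self.POOL_MIX_RATES["producer"]
            else:
                k_use = self.POOL_MIX_RATES["pool_mobile"]
            pool = gs.pools[code]
            total = pool.sum()
            if total <= 0:
                continue
            gs.pools[code] = (1.0 - k_use) * pool + k_use * total * self.mix_profile[code]

    def _box_biomass(self, gs: GroupState, eff_dists, quarter) -> np.ndarray:
        out = np.zeros((len(self.groups), self.geom.n_boxes))
        for i, (code, grp) in enumerate(self.groups.items()):
            if grp.is_vertebrate:
                vs = gs.verts[code]
                for stage in (JUVENILE, ADULT):
                    out[i] += stage_biomass_tons(vs, grp.params, stage) * eff_dists[(code, stage)]
            else:
                out[i] = gs.pools[code].sum(axis=1)
        return out
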