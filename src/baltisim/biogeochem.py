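"""Nitrogen-currency biogeochemistry.

Primary production is Liebig-minimum limited (nutrient x light, times a
space term for benthic producers), with Michaelis-Menten forms for both
nutrient and light limitation and strict NH4-before-NO3 drawdown.
Detritus remineralizes to NH4 at labile/refractory first-order rates,
consuming oxygen stoichiometrically; sediment detritus is additionally
buried (a permanent sink, logged).  Denitrification removes sediment
NO3 under low bottom-water oxygen.  Oxygen gains from photosynthesis
and air-sea relaxation toward saturation at the surface, loses to
remineralization and sediment oxygen demand, and is floored at zero.

Integration is explicit Euler on the daily ecological step; uptake is
capped at the available nutrient mass so concentrations never go
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MG_N_PER_TON_WW, O2_PER_N, SI_PER_N_DIATOM
from .model_domain import ModelGeometry, TracerState, ValidationError


@dataclass
class LightParams:
    k_w: float = 0.15  # m-1 background attenuation
    k_bio: float = 2.0e-3  # m2 (mg N)-1 biological attenuation
    transmissivity: float = 0.7  # clear-sky atmosphere factor

    def validate(self) -> None:
        if self.k_w <= 0 or self.k_bio < 0:
            raise ValidationError("k_w must be > 0 and k_bio >= 0")


@dataclass
class SinkParams:
    lambda_L: float = 0.04  # day-1 labile detritus decay
    lambda_R: float = 0.003  # day-1 refractory decay
    don_remin: float = 0.01  # day-1 DON -> NH4
    burial_fraction: float = 0.0015  # day-1 on sediment detritus (both pools)
    denit_rate: float = 0.05  # day-1 on sediment NO3
    denit_O2_threshold: float = 3000.0  # mg O2 m-3 bottom-water gate
    sediment_o2_demand: float = 0.003  # day-1 of sediment detritus N, as O2 drawdown
    o2_relax_days: float = 3.0  # air-sea relaxation timescale, surface layer

    def validate(self) -> None:
        vals = [self.lambda_L, self.lambda_R, self.don_remin, self.burial_fraction,
                self.denit_rate, self.denit_O2_threshold, self.sediment_o2_demand]
        if any(v < 0 for v in vals):
            raise ValidationError("sink rates must be >= 0")
        if self.lambda_R >= self.lambda_L:
            raise ValidationError("lambda_R must be < lambda_L")


def surface_irradiance(lat_deg: float, doy: int, transmissivity: float = 0.7) -> float:
    """Daily-mean clear-sky shortwave irradiance (W m-2) at the surface.

    Standard top-of-atmosphere daily-mean insolation for the given
    latitude and day of year, scaled by a bulk atmospheric
    transmissivity.
    """
    S0 = 1361.0
    phi = np.deg2rad(lat_deg)
    decl = np.deg2rad(23.44) * np.sin(2 * np.pi * (doy - 81) / 365.0)
    cos_h0 = -np.tan(phi) * np.tan(decl)
    cos_h0 = np.clip(cos_h0, -1.0, 1.0)
    h0 = np.arccos(cos_h0)
    q = (S0 / np.pi) * (h0 * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(h0))
    return float(max(q, 0.0) * transmissivity)


def light_profile(
    I0: float,
    biomass_conc: np.ndarray,
    params: LightParams,
    thicknesses: np.ndarray,
) -> np.ndarray:
    """Irradiance at each layer mid-depth under exponential attenuation.

    ``biomass_conc`` (mg N m-3 of light-attenuating biomass per layer)
    and ``thicknesses`` (m) run surface -> deep.  I(z) = I0 *
    exp(-integral of (k_w + k_bio * B)).  Strictly decreasing with
    depth whenever k_w > 0.
    """
    if I0 < 0:
        raise ValidationError("surface irradiance must be >= 0")
    if np.any(biomass_conc < 0):
        raise ValidationError("negative biomass in light profile")
    k = params.k_w + params.k_bio * np.asarray(biomass_conc, dtype=float)
    tau_layer = k * np.asarray(thicknesses, dtype=float)
    tau_top = np.concatenate([[0.0], np.cumsum(tau_layer)[:-1]])
    tau_mid = tau_top + 0.5 * tau_layer
    return I0 * np.exp(-tau_mid)


def producer_step(
    biomass: np.ndarray,
    no3: np.ndarray,
    nh4: np.ndarray,
    light: np.ndarray,
    volumes: np.ndarray,
    params,
    dt: float,
    space_capacity: np.ndarray | None = None,
    cap_at_available: bool = True,
) -> dict[str, np.ndarray]:
    """One growth step for a producer group on matching-shaped arrays.

    ``biomass`` is tons ww per cell; nutrients are mg N m-3; light is
    W m-2; ``volumes`` m3.  Returns increments: ``growth`` (tons per
    cell), ``dNH4``/``dNO3`` (mg N m-3, negative = uptake), ``dO2``
    (mg O2 m-3).  Uptake debits NH4 first, then NO3, by exactly the
    nitrogen fixed into biomass, capped at what is available.
    """
    if np.any(biomass < 0):
        raise ValidationError("negative producer biomass")
    N = np.clip(no3, 0, None) + np.clip(nh4, 0, None)
    n_lim = N / (params.K_N + N)
    i_lim = light / (params.K_I + light)
    lim = np.minimum(n_lim, i_lim)
    if space_capacity is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            space = np.where(space_capacity > 0,
                             np.clip(1.0 - biomass / np.where(space_capacity > 0, space_capacity, 1.0), 0.0, None),
                             0.0)
        lim = lim * space
    growth = params.mu_max * lim * biomass * dt  # tons
    need_mg = growth * MG_N_PER_TON_WW  # mg N per cell
    avail_mg = (np.clip(nh4, 0, None) + np.clip(no3, 0, None)) * volumes
    if cap_at_available:
        scale = np.ones_like(need_mg)
        over = need_mg > avail_mg
        if np.any(over):
            scale[over] = avail_mg[over] / need_mg[over]
        growth = growth * scale
    need_mg = growth * MG_N_PER_TON_WW
    # NH4 preferred first, remainder from NO3
    nh4_mass = np.clip(nh4, 0, None) * volumes
    from_nh4 = np.minimum(need_mg, nh4_mass)
    from_no3 = need_mg - from_nh4
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_v = np.where(volumes > 0, 1.0 / np.where(volumes > 0, volumes, 1.0), 0.0)
    return {
        "growth": growth,
        "dNH4": -from_nh4 * inv_v,
        "dNO3": -from_no3 * inv_v,
        "dO2": need_mg * O2_PER_N * inv_v,
        "dSiO4": -need_mg * SI_PER_N_DIATOM * inv_v,  # applied for diatoms only
    }


def remineralize(
    state: TracerState,
    geometry: ModelGeometry,
    params: SinkParams,
    dt: float,
    burial_ledger: dict[str, float] | None = None,
    ledger_mask: "np.ndarray | None" = None,
    inplace: bool = False,
) -> TracerState:
    """First-order decay of detrital pools to NH4, consuming O2.

    Water column: DL and DR remineralize at lambda_L / lambda_R, DON at
    don_remin.  Sediment: detritus remineralizes into porewater NH4 and
    additionally loses burial_fraction per day out of the system
    (logged in mg N to ``burial_ledger``).
    """
    out = state if inplace else state.copy()
    vol = geometry.volume_matrix
    f_L = min(params.lambda_L * dt, 1.0)
    f_R = min(params.lambda_R * dt, 1.0)
    f_DON = min(params.don_remin * dt, 1.0)

    d_dl = out.water["DL"] * f_L
    d_dr = out.water["DR"] * f_R
    d_don = out.water["DON"] * f_DON if "DON" in out.water else 0.0
    remin = d_dl + d_dr + d_don  # mg N m-3
    out.water["DL"] = out.water["DL"] - d_dl
    out.water["DR"] = out.water["DR"] - d_dr
    if "DON" in out.water:
        out.water["DON"] = out.water["DON"] - d_don
    out.water["NH4"] = out.water["NH4"] + remin
    out.water["O2"] = np.clip(out.water["O2"] - remin * O2_PER_N, 0.0, None)

    sed_vol = geometry.areas * geometry.layers.sediment_thickness
    for tr, lam in (("DL", params.lambda_L), ("DR", params.lambda_R)):
        if tr not in out.sediment:
            continue
        pool = out.sediment[tr]
        f_dec = min(lam * dt, 1.0)
        f_bur = min(params.burial_fraction * dt, 1.0 - f_dec)
        dec = pool * f_dec
        bur = pool * f_bur
        out.sediment[tr] = pool - dec - bur
        out.sediment["NH4"] = out.sediment["NH4"] + dec
        if burial_ledger is not None:
            m = np.ones_like(bur, dtype=bool) if ledger_mask is None else ledger_mask
            burial_ledger[tr] = burial_ledger.get(tr, 0.0) + float(np.sum((bur * sed_vol)[m]))
    return out


def denitrify(
    state: TracerState,
    geometry: ModelGeometry,
    params: SinkParams,
    dt: float,
    denit_ledger: dict[str, float] | None = None,
    ledger_mask: "np.ndarray | None" = None,
    inplace: bool = False,
) -> TracerState:
    """Sediment NO3 loss to N2 where bottom-water O2 is below threshold."""
    out = state if inplace else state.copy()
    bottom = geometry.bottom_layer
    box_idx = np.arange(geometry.n_boxes)
    o2_bot = out.water["O2"][box_idx, bottom]
    active = o2_bot < params.denit_O2_threshold
    f = min(params.denit_rate * dt, 1.0)
    loss = np.where(active, out.sediment["NO3"] * f, 0.0)
    out.sediment["NO3"] = out.sediment["NO3"] - loss
    if denit_ledger is not None:
        sed_vol = geometry.areas * geometry.layers.sediment_thickness
        m = np.ones_like(loss, dtype=bool) if ledger_mask is None else ledger_mask
        denit_ledger["NO3"] = denit_ledger.get("NO3", 0.0) + float(np.sum((loss * sed_vol)[m]))
    return out


def o2_saturation(temperature: np.ndarray, salinity: np.ndarray) -> np.ndarray:
    """Dissolved O2 saturation (mg m-3), linearised in T and S."""
    sat = 14.6 - 0.35 * np.asarray(temperature) - 0.06 * np.asarray(salinity)
    return np.clip(sat, 5.0, None) * 1000.0


def oxygen_step(
    state: TracerState,
    geometry: ModelGeometry,
    params: SinkParams,
    temperature: np.ndarray,
    salinity: np.ndarray,
    dt: float,
    inplace: bool = False,
) -> TracerState:
    """Air-sea relaxation (surface layer) plus sediment oxygen demand.

    Surface O2 relaxes linearly toward saturation on ``o2_relax_days``;
    sediment detritus exerts an oxygen demand on the bottom water layer
    proportional to its nitrogen content.  O2 never goes negative:
    sinks are capped at the available oxygen.
    """
    out = state if inplace else state.copy()
    o2 = out.water["O2"].copy()
    sat = o2_saturation(temperature[:, 0], salinity[:, 0])
    f = min(dt / params.o2_relax_days, 1.0)
    o2[:, 0] = o2[:, 0] + f * (sat - o2[:, 0])

    bottom = geometry.bottom_layer
    box_idx = np.arange(geometry.n_boxes)
    sed_vol = geometry.areas * geometry.layers.sediment_thickness
    sed_N = (out.sediment["DL"] + out.sediment["DR"]) * sed_vol  # mg N
    demand = params.sediment_o2_demand * dt * sed_N * O2_PER_N  # mg O2
    vol_bot = geometry.volume_matrix[box_idx, bottom]
    o2_bot_mass = o2[box_idx, bottom] * vol_bot
    drawdown = np.minimum(demand, o2_bot_mass)
    o2[box_idx, bottom] = (o2_bot_mass - drawdown) / vol_bot
    out.water["O2"] = np.clip(o2, 0.0, None)
    return out
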