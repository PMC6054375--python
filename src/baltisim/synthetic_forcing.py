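"""Synthetic generators for the external inputs the simulator is forced
with: seasonal physics (temperature, salinity, face exchange volumes at
12 h cadence), boundary-box tracer climatology, riverine nitrogen loads
with coastal retention and bioavailability, uniform atmospheric NH4
deposition, and winter-style initial conditions (nutrients, low initial
detritus, group biomass fields, cohort demography, quarterly
distribution maps).

All generators are pure functions of (geometry, params, seed).  One
calendar year of forcing is produced and repeated for every projection
year, so annual periodicity holds exactly.  Exchange fields are built
from a seasonal random template and then projected onto the
divergence-free subspace so every dynamic box has zero net volume flux
each step (rigid-lid box volumes), which makes tracer conservation
exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import MG_N_PER_MMOL_N, MG_N_PER_TON_WW
from .groups import ADULT, FunctionalGroup, JUVENILE, MG_N_PER_G_WW
from .model_domain import (
    ModelGeometry,
    TracerState,
    ValidationError,
    WATER_TRACERS,
)
from .trophic import (
    GroupState,
    VertState,
    pelagic_layer_mask,
    photic_layer_mask,
    stage_slices,
    validate_dist_maps,
)

STEPS_PER_DAY = 2  # 12 h physics cadence
STEPS_PER_YEAR = 365 * STEPS_PER_DAY


# ---------------------------------------------------------------------------
# physics forcing
# ---------------------------------------------------------------------------


@dataclass
class PhysicsParams:
    """Seasonal physics statistics per region class."""

    coastal_surface_mean: float = 8.5  # deg C
    coastal_winter_min: float = -0.1  # deg C (brackish coastal water hits zero)
    offshore_surface_mean: float = 8.0
    offshore_surface_amp: float = 5.0
    temp_peak_doy: float = 210.0
    mean_decay_depth: float = 40.0  # m, e-folding of the seasonal mean excess over deep T
    amp_decay_depth: float = 25.0  # m, e-folding of the seasonal amplitude
    deep_temperature: float = 4.0
    salinity_south: float = 22.0  # psu at the Kattegat end (axis=0)
    salinity_north: float = 4.0  # psu at the Bothnian end (axis=1)
    halocline_depth: float = 25.0  # m; layers below get the deep increment
    halocline_increment: float = 4.5  # psu
    exchange_frac: float = 0.008  # face volume flux per 12 h as fraction of smaller cell
    deep_exchange_factor: float = 0.25  # damping of exchange below the halocline
    exchange_seasonal_amp: float = 0.4
    exchange_noise: float = 0.25
    temperature_bounds: tuple[float, float] = (-2.0, 30.0)


@dataclass
class ForcingSeries:
    """One repeated calendar year of 12 h forcing.

    temperature/salinity: (steps, n_boxes, n_layers); exchange:
    (steps, n_faces, n_layers) signed m3 per 12 h, left->right positive;
    boundary_tracers: tracer -> (steps, n_boxes, n_layers), meaningful
    on boundary boxes only.
    """

    time_days: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    exchange: np.ndarray
    boundary_tracers: dict[str, np.ndarray]

    @property
    def n_steps(self) -> int:
        return self.temperature.shape[0]

    def step_index(self, day: int, substep: int) -> int:
        return (day * STEPS_PER_DAY + substep) % self.n_steps


def _divergence_projector(geometry: ModelGeometry, layer: int) -> tuple[np.ndarray, np.ndarray]:
    """Projection removing net flux into every dynamic box at one layer."""
    open_faces = np.flatnonzero(geometry.face_layer_mask[:, layer])
    dyn = geometry.dynamic_ids
    A = np.zeros((len(dyn), len(open_faces)))
    for j, f in enumerate(open_faces):
        l, r = geometry.face_left[f], geometry.face_right[f]
        for i, b in enumerate(dyn):
            if r == b:
                A[i, j] += 1.0
            if l == b:
                A[i, j] -= 1.0
    if A.size == 0:
        return open_faces, np.zeros((0, 0))
    P = np.eye(len(open_faces)) - A.T @ np.linalg.pinv(A @ A.T) @ A
    return open_faces, P


def generate_physics(
    geometry: ModelGeometry, params: PhysicsParams, seed: int
) -> ForcingSeries:
    """Deterministic seasonal physics for one calendar year.

    Surface temperature is an annual sinusoid whose coastal amplitude
    exceeds the offshore one (coastal boxes reach the configured winter
    minimum); salinity decreases monotonically along the
    Kattegat->Bothnian axis with a halocline increment at depth; signed
    face exchanges are divergence-projected so every dynamic box has
    exactly zero net volume flux at every step.
    """
    rng = np.random.default_rng(seed)
    B, L, F = geometry.n_boxes, geometry.n_layers, geometry.n_faces
    t = (np.arange(STEPS_PER_YEAR) + 0.5) / STEPS_PER_DAY  # days
    doy = t % 365.0

    thick = geometry.thickness_matrix
    tops = np.concatenate([[0.0], np.asarray(geometry.layers.interface_depths)[:-1]])
    mids = np.where(thick > 0, tops[None, :] + 0.5 * thick, 0.0)  # (B, L)

    coastal = np.array([b.coastal for b in geometry.boxes])
    surf_mean = np.where(coastal, params.coastal_surface_mean, params.offshore_surface_mean)
    surf_amp = np.where(
        coastal,
        params.coastal_surface_mean - params.coastal_winter_min,
        params.offshore_surface_amp,
    )
    rel_depth = mids - mids[:, :1]  # depth below the surface layer's midpoint
    mean_z = params.deep_temperature + (surf_mean[:, None] - params.deep_temperature) * np.exp(
        -rel_depth / params.mean_decay_depth
    )
    amp_z = surf_amp[:, None] * np.exp(-rel_depth / params.amp_decay_depth)
    season = np.cos(2 * np.pi * (doy - params.temp_peak_doy) / 365.0)  # (T,)
    temperature = mean_z[None, :, :] + amp_z[None, :, :] * season[:, None, None]
    lo, hi = params.temperature_bounds
    if temperature.min() < lo or temperature.max() > hi:
        raise ValidationError("temperature parameters exceed configured bounds")

    axis = np.array([b.axis for b in geometry.boxes])
    s_surf = params.salinity_south + (params.salinity_north - params.salinity_south) * axis
    deep = (mids > params.halocline_depth).astype(float)
    salinity = np.broadcast_to(
        s_surf[:, None] + params.halocline_increment * deep, (STEPS_PER_YEAR, B, L)
    ).copy()
    salinity += 0.3 * season[:, None, None] * (1.0 - deep)[None, :, :]
    if salinity.min() < 0:
        raise ValidationError("salinity parameters produce negative salinity")

    # --- exchange volumes ------------------------------------------------
    vol = geometry.volume_matrix
    exchange = np.zeros((STEPS_PER_YEAR, F, L))
    for layer in range(L):
        open_faces, P = _divergence_projector(geometry, layer)
        if len(open_faces) == 0:
            continue
        vmin = np.minimum(
            vol[geometry.face_left[open_faces], layer],
            vol[geometry.face_right[open_faces], layer],
        )
        layer_top = 0.0 if layer == 0 else geometry.layers.interface_depths[layer - 1]
        frac = params.exchange_frac
        if layer_top >= params.halocline_depth:
            frac *= params.deep_exchange_factor
        base = frac * vmin * rng.choice([-1.0, 1.0], size=len(open_faces))
        phase = rng.uniform(0, 2 * np.pi, size=len(open_faces))
        seasonal = 1.0 + params.exchange_seasonal_amp * np.sin(
            2 * np.pi * doy[:, None] / 365.0 + phase[None, :]
        )
        noise = 1.0 + params.exchange_noise * rng.standard_normal((STEPS_PER_YEAR, len(open_faces)))
        q = base[None, :] * seasonal * noise  # (T, Fopen)
        q = q @ P.T  # remove divergence on dynamic boxes
        exchange[:, open_faces, layer] = q

    # scale down if any step violates a conservative CFL margin
    lf, rf = geometry.face_left, geometry.face_right
    outflow = np.zeros((STEPS_PER_YEAR, B, L))
    for f in range(F):
        qf = exchange[:, f, :]
        outflow[:, lf[f], :] += np.clip(qf, 0, None)
        outflow[:, rf[f], :] += np.clip(-qf, 0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        cour = np.where(vol[None] > 0, outflow / np.where(vol[None] > 0, vol[None], 1.0), 0.0)
    cmax = cour.max() if cour.size else 0.0
    if cmax > 0.45:
        exchange *= 0.45 / cmax

    boundary_tracers = _boundary_climatology(geometry, doy, temperature, salinity)
    return ForcingSeries(
        time_days=t,
        temperature=temperature,
        salinity=salinity,
        exchange=exchange,
        boundary_tracers=boundary_tracers,
    )


def _boundary_climatology(
    geometry: ModelGeometry, doy: np.ndarray, temperature: np.ndarray, salinity: np.ndarray
) -> dict[str, np.ndarray]:
    """Fixed seasonal tracer climatology prescribed on boundary boxes.

    Stands in for the exchange with the open North Sea: winter-high
    nutrients, oxygenated inflow water, modest detritus.
    """
    from .biogeochem import o2_saturation

    B, L = geometry.n_boxes, geometry.n_layers
    T = len(doy)
    winter = 0.5 * (1.0 - np.cos(2 * np.pi * (doy - 30.0) / 365.0))  # 1 mid-winter.. 0 summer
    winter = winter[:, None, None]
    thick = geometry.thickness_matrix
    tops = np.concatenate([[0.0], np.asarray(geometry.layers.interface_depths)[:-1]])
    mids = np.where(thick > 0, tops[None, :] + 0.5 * thick, 0.0)
    zfac = np.clip(mids / 100.0, 0.0, 1.0)[None, :, :]
    out = {
        "NO3": 20.0 + 60.0 * winter + 40.0 * zfac * np.ones((T, B, L)),
        "NH4": 5.0 + 4.0 * winter * np.ones((T, B, L)),
        "SiO4": 60.0 + 80.0 * winter * np.ones((T, B, L)),
        "O2": np.clip(o2_saturation(temperature, salinity) - 9000.0 * np.clip(mids / 60.0, 0.0, 1.0)[None, :, :], 800.0, None),
        "DON": 40.0 * np.ones((T, B, L)),
        "DL": 5.0 * np.ones((T, B, L)),
        "DR": 3.0 * np.ones((T, B, L)),
    }
    return out


# ---------------------------------------------------------------------------
# riverine loads
# ---------------------------------------------------------------------------


@dataclass
class LoadParams:
    """Riverine nitrogen load statistics (HELCOM-compilation style).

    Per-box annual totals default to the domain total shared among
    coastal dynamic boxes in proportion to area; ``box_totals`` may
    override individual boxes.  Retention and the DIN/DON split are
    stand-ins for basin-specific retention/bioavailability factors.
    """

    total_annual_tN: float = 100_000.0  # tons N yr-1 over the domain
    din_fraction: float = 0.7
    retention: Mapping[str, float] = field(
        default_factory=lambda: {
            "kattegat": 0.30,
            "western_baltic": 0.35,
            "baltic_proper": 0.40,
            "gulfs": 0.45,
        }
    )
    default_retention: float = 0.35
    bioavailable_don_fraction: float = 0.5
    offshore_spill_fraction: float = 0.3
    box_totals: Mapping[int, float] = field(default_factory=dict)
    noise_cv: float = 0.2


LOAD_COLUMNS = [
    "box_id",
    "annual_total_tN",
    "din_fraction",
    "retention",
    "bioavailable_don_fraction",
    "offshore_spill_fraction",
    "spill_target",
]


def generate_loads(geometry: ModelGeometry, params: LoadParams, seed: int) -> pd.DataFrame:
    """Per-box annual riverine nitrogen loads (LoadTable as a DataFrame).

    Loads attach to coastal dynamic boxes; a spill fraction of each
    coastal load is redirected to the adjacent offshore box (largest
    non-coastal dynamic neighbour).  Loads on boundary boxes are
    rejected.
    """
    rng = np.random.default_rng(seed)
    coastal = [
        b for b in geometry.boxes if b.kind == "dynamic" and b.coastal
    ]
    if not coastal and not params.box_totals:
        raise ValidationError("no coastal dynamic boxes to receive river loads")
    for b_id in params.box_totals:
        if geometry.boxes[b_id].kind != "dynamic":
            raise ValidationError(f"river load assigned to boundary box {b_id}")

    rows = []
    if params.box_totals:
        totals = dict(params.box_totals)
    else:
        area = np.array([b.area for b in coastal])
        w = area * np.clip(1.0 + params.noise_cv * rng.standard_normal(len(coastal)), 0.2, None)
        w = w / w.sum()
        totals = {b.box_id: params.total_annual_tN * wi for b, wi in zip(coastal, w)}

    for box_id, tot in sorted(totals.items()):
        box = geometry.boxes[box_id]
        rho = params.retention.get(box.region, params.default_retention)
        target = -1
        best_area = -1.0
        for nb in geometry.neighbors(box_id):
            nbox = geometry.boxes[nb]
            if nbox.kind == "dynamic" and not nbox.coastal and nbox.area > best_area:
                best_area = nbox.area
                target = nb
        spill = params.offshore_spill_fraction if target >= 0 else 0.0
        rows.append(
            {
                "box_id": box_id,
                "annual_total_tN": tot,
                "din_fraction": params.din_fraction,
                "retention": rho,
                "bioavailable_don_fraction": params.bioavailable_don_fraction,
                "offshore_spill_fraction": spill,
                "spill_target": target,
            }
        )
    table = pd.DataFrame(rows, columns=LOAD_COLUMNS)
    _validate_load_table(table, geometry)
    return table


def _validate_load_table(table: pd.DataFrame, geometry: ModelGeometry) -> None:
    for col in ("din_fraction", "retention", "bioavailable_don_fraction", "offshore_spill_fraction"):
        if ((table[col] < 0) | (table[col] > 1)).any():
            raise ValidationError(f"load table column {col} outside [0, 1]")
    for b in table["box_id"]:
        if geometry.boxes[int(b)].kind != "dynamic":
            raise ValidationError(f"river load assigned to boundary box {int(b)}")


def effective_daily_loads(
    geometry: ModelGeometry,
    table: pd.DataFrame,
    multipliers: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Daily applied loads per box (tons N day-1), after retention,
    DIN/DON split, bioavailability, and offshore spill redirection.

    Returns arrays ``din`` (-> NO3), ``don`` (bioavailable -> DON) and
    ``refractory`` (non-bioavailable DON share -> refractory detritus),
    each (n_boxes,).  Their summed annual total equals
    sum(annual_total * (1 - retention) * multiplier) exactly.
    """
    _validate_load_table(table, geometry)
    B = geometry.n_boxes
    din = np.zeros(B)
    don = np.zeros(B)
    refr = np.zeros(B)
    mult = np.ones(B) if multipliers is None else np.asarray(multipliers, dtype=float)
    for row in table.itertuples(index=False):
        b = int(row.box_id)
        daily = row.annual_total_tN * (1.0 - row.retention) * mult[b] / 365.0
        d_din = daily * row.din_fraction
        d_dob = daily * (1.0 - row.din_fraction) * row.bioavailable_don_fraction
        d_ref = daily * (1.0 - row.din_fraction) * (1.0 - row.bioavailable_don_fraction)
        spill = row.offshore_spill_fraction
        tgt = int(row.spill_target)
        for arr, val in ((din, d_din), (don, d_dob), (refr, d_ref)):
            if spill > 0 and tgt >= 0:
                arr[b] += val * (1.0 - spill)
                arr[tgt] += val * spill
            else:
                arr[b] += val
    return {"din": din, "don": don, "refractory": refr}


def write_load_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_load_table(path: str | Path, geometry: ModelGeometry) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(LOAD_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"load table missing columns {sorted(missing)}")
    _validate_load_table(table, geometry)
    return table


# ---------------------------------------------------------------------------
# atmospheric deposition
# ---------------------------------------------------------------------------


@dataclass
class DepositionParams:
    """Spatially uniform, time-invariant NH4 deposition."""

    areal_rate: float = 0.15  # mmol NH4 m-2 day-1

    def validate(self) -> None:
        if self.areal_rate < 0:
            raise ValidationError("deposition rate must be >= 0")


def deposition_flux(geometry: ModelGeometry, dep: DepositionParams) -> np.ndarray:
    """Per-box NH4-N source (mg N day-1) applied to the surface layer."""
    dep.validate()
    return dep.areal_rate * MG_N_PER_MMOL_N * geometry.areas


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------


@dataclass
class InitialConditionParams:
    """Winter-style initial tracer values and biomass placement knobs."""

    no3_surface: float = 70.0  # mg N m-3
    no3_deep_increment: float = 30.0
    nh4: float = 7.0
    sio4: float = 120.0
    don: float = 40.0
    dl: float = 1.0  # purposefully very low initial detritus
    dr: float = 0.5
    sed_dl: float = 800.0  # mg N m-3 of sediment volume
    sed_dr: float = 1200.0
    sed_no3: float = 50.0
    sed_nh4: float = 200.0
    o2_deficit_deep: float = 4000.0  # mg m-3 below saturation at depth
    detritus_max_fraction: float = 0.5  # of plankton standing stock
    placement_noise: float = 0.3
    juvenile_coastal_bias: float = 2.0
    adult_offshore_bias: float = 2.0


@dataclass
class InitialConditions:
    tracers: TracerState
    groups: GroupState


def _pool_spatial_weights(
    grp: FunctionalGroup, geometry: ModelGeometry, rng: np.random.Generator, noise: float
) -> np.ndarray:
    dyn = geometry.dynamic_mask.astype(float)
    if grp.habitat in ("pelagic", "demersal"):
        base = geometry.volume_matrix.sum(axis=1) * dyn
    else:
        cover = np.zeros(geometry.n_boxes)
        for hab, aff in grp.habitat_affinity.items():
            cover += aff * np.array([b.habitat_cover.get(hab, 0.0) for b in geometry.boxes])
        base = cover * geometry.areas * dyn
    if getattr(grp, "coastal_bias", 1.0) != 1.0:
        coastal = np.array([b.coastal for b in geometry.boxes], dtype=float)
        base = base * (1.0 + (grp.coastal_bias - 1.0) * coastal)
    if base.sum() <= 0:
        raise ValidationError(f"{grp.code}: no admissible habitat anywhere in the domain")
    w = base * np.clip(1.0 + noise * rng.standard_normal(geometry.n_boxes), 0.1, None)
    w = w * (base > 0)
    return w / w.sum()


def _vertical_profile(grp: FunctionalGroup, geometry: ModelGeometry) -> np.ndarray:
    """(B, L) fractions splitting a box biomass across layers."""
    B, L = geometry.n_boxes, geometry.n_layers
    out = np.zeros((B, L))
    if grp.habitat == "pelagic":
        mask = photic_layer_mask(geometry) if grp.kind == "producer" else pelagic_layer_mask(geometry)
        vol = geometry.volume_matrix * mask
        s = vol.sum(axis=1, keepdims=True)
        out = np.divide(vol, np.where(s > 0, s, 1.0), out=out, where=s > 0)
    elif grp.habitat == "benthic" and "bedrock" in grp.habitat_affinity:
        # hard-substrate communities occupy the shallow shoreline fringe
        out[:, 0] = 1.0
    else:
        idx = np.arange(B)
        out[idx, geometry.bottom_layer] = 1.0
    return out


def _vert_dist_maps(
    grp: FunctionalGroup,
    geometry: ModelGeometry,
    rng: np.random.Generator,
    params: InitialConditionParams,
) -> dict[str, np.ndarray]:
    dyn = geometry.dynamic_mask.astype(float)
    coastal = np.array([b.coastal for b in geometry.boxes], dtype=float)
    depth = geometry.max_depths
    vol = geometry.volume_matrix.sum(axis=1)
    maps = {}
    p = grp.params
    for stage in (JUVENILE, ADULT):
        bias = params.juvenile_coastal_bias if stage == JUVENILE else 1.0 / params.adult_offshore_bias
        base = vol * (1.0 + (bias - 1.0) * coastal) * dyn
        rows = []
        for q in range(4):
            w = base * np.clip(1.0 + 0.25 * rng.standard_normal(geometry.n_boxes), 0.1, None)
            if stage == ADULT and q == p.spawn_quarter and grp.habitat == "demersal":
                # spawning aggregation in deep (high-salinity) basins
                w = w * np.clip(depth / depth.max(), 0.05, None) ** 2
            w = w * dyn
            rows.append(w / w.sum())
        maps[stage] = np.array(rows)
    return maps


def generate_initial_conditions(
    geometry: ModelGeometry,
    groups: Mapping[str, FunctionalGroup],
    params: InitialConditionParams,
    seed: int,
    physics: ForcingSeries | None = None,
) -> InitialConditions:
    """Winter-state tracers plus group biomass/demography placement.

    Deterministic for a given seed.  Each group's domain-total biomass
    matches its configured target exactly (up to float rounding);
    benthic groups are placed only on admissible habitat; quarterly
    vertebrate maps sum to one.  Initial detritus is validated to be
    small relative to the plankton standing stock.
    """
    from .biogeochem import o2_saturation

    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    B, L = geometry.n_boxes, geometry.n_layers
    thick = geometry.thickness_matrix
    tops = np.concatenate([[0.0], np.asarray(geometry.layers.interface_depths)[:-1]])
    mids = np.where(thick > 0, tops[None, :] + 0.5 * thick, 0.0)
    mask = geometry.layer_mask

    if physics is not None:
        T0, S0 = physics.temperature[0], physics.salinity[0]
    else:
        T0 = np.full((B, L), 4.0)
        S0 = np.full((B, L), 8.0)

    state = TracerState.zeros(geometry)
    zfac = np.clip(mids / 80.0, 0.0, 1.0)
    state.water["NO3"] = (params.no3_surface + params.no3_deep_increment * zfac) * mask
    state.water["NH4"] = params.nh4 * mask
    state.water["SiO4"] = params.sio4 * mask
    state.water["DON"] = params.don * mask
    state.water["DL"] = params.dl * mask
    state.water["DR"] = params.dr * mask
    state.water["O2"] = np.clip(o2_saturation(T0, S0) - params.o2_deficit_deep * zfac, 500.0, None) * mask
    state.sediment["DL"] = np.full(B, params.sed_dl)
    state.sediment["DR"] = np.full(B, params.sed_dr)
    state.sediment["NO3"] = np.full(B, params.sed_no3)
    state.sediment["NH4"] = np.full(B, params.sed_nh4)

    pools: dict[str, np.ndarray] = {}
    verts: dict[str, VertState] = {}
    for code, grp in groups.items():
        if grp.is_vertebrate:
            p = grp.params
            Z = np.asarray(p.mort_lin) + np.array(
                [p.F_juvenile if a < p.maturation_cohort else p.F_adult for a in range(p.n_cohorts)]
            )
            surv = np.exp(-np.concatenate([[0.0], np.cumsum(Z[:-1])]))
            w_mg = np.asarray(p.init_weight_g) * MG_N_PER_G_WW
            k = grp.init_biomass * MG_N_PER_TON_WW / (surv * w_mg).sum()
            numbers = k * surv
            verts[code] = VertState(
                numbers=numbers,
                w_struct=w_mg * (1.0 - p.reserve_frac),
                w_res=w_mg * p.reserve_frac,
                dist=_vert_dist_maps(grp, geometry, rng, params),
            )
            validate_dist_maps(verts[code].dist, code)
        else:
            w_box = _pool_spatial_weights(grp, geometry, rng, params.placement_noise)
            prof = _vertical_profile(grp, geometry)
            pools[code] = grp.init_biomass * w_box[:, None] * prof

    gs = GroupState(pools=pools, verts=verts)

    # low-initial-detritus rule: water detritus must stay a small
    # fraction of the plankton standing stock
    plankton = sum(
        gs.pools[c].sum() for c, g in groups.items() if not g.is_vertebrate and g.habitat == "pelagic"
    )
    det_tons = (
        (state.water["DL"] + state.water["DR"]) * geometry.volume_matrix
    ).sum() / MG_N_PER_TON_WW
    if plankton > 0 and det_tons > params.detritus_max_fraction * plankton:
        raise ValidationError(
            "initial detritus exceeds the configured fraction of plankton standing stock"
        )
    return InitialConditions(tracers=state, groups=gs)


# ---------------------------------------------------------------------------
# NetCDF output of generated datasets
# ---------------------------------------------------------------------------


def write_forcing(forcing: ForcingSeries, path) -> None:
    """Write a ForcingSeries as NetCDF (dims time/box/layer/face)."""
    import xarray as xr

    ds = xr.Dataset(
        {
            "temperature": (("time", "box", "layer"), forcing.temperature),
            "salinity": (("time", "box", "layer"), forcing.salinity),
            "exchange": (("time", "face", "layer"), forcing.exchange),
            **{
                f"boundary_{tr}": (("time", "box", "layer"), arr)
                for tr, arr in forcing.boundary_tracers.items()
            },
        },
        coords={"time": forcing.time_days},
        attrs={
            "exchange_units": "m3 per 12 h, signed left->right",
            "temperature_units": "degC",
            "salinity_units": "psu",
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_forcing(path) -> ForcingSeries:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    boundary = {
        name[len("boundary_"):]: np.asarray(ds[name].values)
        for name in ds.data_vars
        if str(name).startswith("boundary_")
    }
    return ForcingSeries(
        time_days=np.asarray(ds["time"].values),
        temperature=np.asarray(ds["temperature"].values),
        salinity=np.asarray(ds["salinity"].values),
        exchange=np.asarray(ds["exchange"].values),
        boundary_tracers=boundary,
    )


def write_initial_conditions(ic: InitialConditions, geometry: ModelGeometry, path) -> None:
    """Write initial tracers plus per-group biomass fields as NetCDF."""
    import xarray as xr

    codes = sorted(ic.groups.pools)
    pools = np.stack([ic.groups.pools[c] for c in codes]) if codes else np.zeros((0, geometry.n_boxes, geometry.n_layers))
    wnames = sorted(ic.tracers.water)
    snames = sorted(ic.tracers.sediment)
    data = {
        "water": (("tracer", "box", "layer"), np.stack([ic.tracers.water[t] for t in wnames])),
        "sediment": (("sediment_tracer", "box"), np.stack([ic.tracers.sediment[t] for t in snames])),
        "pool_biomass": (("pool", "box", "layer"), pools),
    }
    for code, vs in ic.groups.verts.items():
        data[f"numbers_{code}"] = (("cohort_" + code,), vs.numbers)
        data[f"weight_struct_{code}"] = (("cohort_" + code,), vs.w_struct)
        data[f"weight_res_{code}"] = (("cohort_" + code,), vs.w_res)
        for stage, d in vs.dist.items():
            data[f"dist_{code}_{stage}"] = (("quarter", "box"), d)
    ds = xr.Dataset(
        data,
        coords={
            "tracer": wnames,
            "sediment_tracer": snames,
            "pool": codes,
            "box": np.arange(geometry.n_boxes),
            "layer": np.arange(geometry.n_layers),
            "quarter": np.arange(4),
        },
    )
    ds.to_netcdf(path, engine="scipy")
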