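"""Tracer transport: box-face advection, vertical mixing, particle
settling, and sediment-water solute exchange.

The advection scheme is first-order upwind donor-cell with automatic
sub-stepping to respect the CFL bound; it is positivity-preserving and
exactly mass-conserving, which are the contracts the rest of the model
relies on (accuracy needs at box scale are modest).  Within each
physics step the operators apply in the fixed order
advect -> vertical_mix -> settle (then sediment exchange).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_domain import (
    ModelGeometry,
    SETTLING_TRACERS,
    TracerState,
    ValidationError,
)


@dataclass
class TransportParams:
    """Transport coefficients (all >= 0).

    vertical_mixing_rate is a single domain-wide diffusivity (m2 day-1)
    with optional per-box overrides; settling velocities are m day-1
    per particulate tracer; bioturbation_exchange is a first-order
    day-1 coefficient for sediment porewater <-> bottom water solute
    exchange (resuspension/erosion folded in).
    """

    vertical_mixing_rate: float = 5.0  # m2 day-1
    mixing_overrides: dict[int, float] = field(default_factory=dict)
    halocline_depth: float = 25.0  # m; interfaces at/below are damped
    deep_mixing_factor: float = 0.12  # multiplier on mixing below the halocline
    settling_velocity: dict[str, float] = field(
        default_factory=lambda: {"DL": 3.0, "DR": 1.0}
    )
    bioturbation_exchange: float = 0.05  # day-1
    cfl_max: float = 0.5

    def validate(self) -> None:
        vals = [self.vertical_mixing_rate, self.bioturbation_exchange,
                *self.mixing_overrides.values(), *self.settling_velocity.values()]
        if any(v < 0 for v in vals):
            raise ValidationError("transport rates must be >= 0")
        for tr in self.settling_velocity:
            if tr not in SETTLING_TRACERS:
                raise ValidationError(
                    f"settling applied to non-particulate tracer {tr!r}"
                )


def advect(
    state: TracerState,
    geometry: ModelGeometry,
    exchange: np.ndarray,
    *,
    allow_substeps: bool = True,
    cfl_max: float = 0.5,
    boundary_ledger: dict[str, float] | None = None,
) -> TracerState:
    """Upwind donor-cell advection by one forcing interval.

    ``exchange`` has shape (n_faces, n_layers): signed water volume (m3)
    moved during this interval, positive left->right.  Dynamic-box
    concentrations are updated; boundary boxes act as fixed reservoirs.
    Net tracer mass gained by the dynamic domain across boundary faces
    is accumulated into ``boundary_ledger`` (mg, per tracer) if given.
    """
    if np.any(~np.isfinite(exchange)):
        raise ValidationError("NaN/inf in exchange forcing")
    q = np.where(geometry.face_layer_mask, exchange, 0.0)
    left, right = geometry.face_left, geometry.face_right
    vol = geometry.volume_matrix
    dyn = geometry.dynamic_mask

    # CFL: total outflow from any cell per sub-step must stay below
    # cfl_max * cell volume.
    outflow = np.zeros_like(vol)
    np.add.at(outflow, left, np.clip(q, 0.0, None))
    np.add.at(outflow, right, np.clip(-q, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        courant = np.where(vol > 0, outflow / np.where(vol > 0, vol, 1.0), 0.0)
    cmax = float(courant.max()) if courant.size else 0.0
    n_sub = max(1, int(np.ceil(cmax / cfl_max)))
    if n_sub > 1 and not allow_substeps:
        raise ValidationError(
            f"CFL violation (max Courant {cmax:.3f} > {cfl_max}); "
            f"sub-step the advection ({n_sub} sub-steps needed)"
        )

    qs = q / n_sub
    pos = np.clip(qs, 0.0, None)
    neg = np.clip(-qs, 0.0, None)
    bnd_face = ~dyn[left] | ~dyn[right]

    out = state.copy()
    for tracer, conc in out.water.items():
        c = conc
        for _ in range(n_sub):
            # mass moved per face-layer: donor concentration times volume
            m_lr = pos * c[left]  # left -> right
            m_rl = neg * c[right]  # right -> left
            dm = np.zeros_like(c)
            np.add.at(dm, right, m_lr - m_rl)
            np.add.at(dm, left, m_rl - m_lr)
            if boundary_ledger is not None:
                flux_to_dyn = np.where(
                    bnd_face[:, None],
                    np.where(dyn[right][:, None], m_lr - m_rl, 0.0)
                    + np.where(dyn[left][:, None], m_rl - m_lr, 0.0),
                    0.0,
                )
                boundary_ledger[tracer] = boundary_ledger.get(tracer, 0.0) + float(
                    flux_to_dyn.sum()
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                dc = np.where(vol > 0, dm / np.where(vol > 0, vol, 1.0), 0.0)
            c = np.where(dyn[:, None], c + dc, c)
        out.water[tracer] = c
    return out


def vertical_mix(
    state: TracerState,
    geometry: ModelGeometry,
    params: TransportParams,
    dt: float,
) -> TracerState:
    """Diffusive exchange between vertically adjacent layers.

    Exchange volume across the interface below layer k is
    rate * area / dist(k, k+1) * dt, with dist the mid-depth distance.
    Column mass is conserved exactly; across-layer variance cannot
    increase.  Automatically sub-steps for stability.
    """
    if params.vertical_mixing_rate < 0:
        raise ValidationError("vertical mixing rate must be >= 0")
    thick = geometry.thickness_matrix
    vol = geometry.volume_matrix
    B, L = thick.shape
    if L < 2:
        return state.copy()
    rate = np.full(B, params.vertical_mixing_rate)
    for b, r in params.mixing_overrides.items():
        rate[b] = r
    dist = 0.5 * (thick[:, :-1] + thick[:, 1:])  # (B, L-1)
    open_if = (thick[:, :-1] > 0) & (thick[:, 1:] > 0)
    if_depth = np.asarray(geometry.layers.interface_depths)[: thick.shape[1] - 1]
    damp = np.where(if_depth >= params.halocline_depth, params.deep_mixing_factor, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(open_if, rate[:, None] * damp[None, :] * geometry.areas[:, None] / np.where(dist > 0, dist, 1.0) * dt, 0.0)
    # stability: exchange volume per sub-step < half the smaller layer volume
    vmin = np.minimum(vol[:, :-1], vol[:, 1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vmin > 0, ex / np.where(vmin > 0, vmin, 1.0), 0.0)
    n_sub = max(1, int(np.ceil(ratio.max() / 0.5))) if ratio.size else 1
    exs = ex / n_sub

    out = state.copy()
    for tracer, conc in out.water.items():
        c = conc.copy()
        for _ in range(n_sub):
            grad = c[:, :-1] - c[:, 1:]
            m = exs * grad  # mg moved downward across each open interface
            dmass = np.zeros_like(c)
            dmass[:, :-1] -= m
            dmass[:, 1:] += m
            with np.errstate(divide="ignore", invalid="ignore"):
                c = c + np.where(vol > 0, dmass / np.where(vol > 0, vol, 1.0), 0.0)
        out.water[tracer] = c
    return out


def settle(
    state: TracerState,
    geometry: ModelGeometry,
    params: TransportParams,
    dt: float,
    tracers: tuple[str, ...] | None = None,
) -> TracerState:
    """Downward particle flux; the deepest water layer feeds the sediment.

    Water + sediment mass of each settling tracer is conserved exactly.
    """
    if tracers is None:
        tracers = tuple(params.settling_velocity)
    for tr in tracers:
        if tr not in SETTLING_TRACERS:
            raise ValidationError(f"settling applied to non-particulate tracer {tr!r}")
    thick = geometry.thickness_matrix
    vol = geometry.volume_matrix
    areas = geometry.areas
    bottom = geometry.bottom_layer
    sed_vol = areas * geometry.layers.sediment_thickness
    box_idx = np.arange(geometry.n_boxes)

    out = state.copy()
    for tr in tracers:
        ws = params.settling_velocity.get(tr, 0.0)
        if ws <= 0:
            continue
        c = out.water[tr].copy()
        # settled fraction of each layer, capped at the full layer content
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(thick > 0, np.minimum(ws * dt / np.where(thick > 0, thick, 1.0), 1.0), 0.0)
        m_down = frac * c * vol  # mg leaving each layer downward
        dmass = -m_down.copy()
        dmass[:, 1:] += m_down[:, :-1]
        # flux out of a box's bottom layer goes to its sediment, not the
        # (non-realized) layer below
        to_sed = m_down[box_idx, bottom]
        below = bottom + 1
        ok = below < c.shape[1]
        dmass[box_idx[ok], below[ok]] -= m_down[box_idx[ok], bottom[ok]]
        with np.errstate(divide="ignore", invalid="ignore"):
            out.water[tr] = c + np.where(vol > 0, dmass / np.where(vol > 0, vol, 1.0), 0.0)
        if tr in out.sediment:
            out.sediment[tr] = out.sediment[tr] + to_sed / sed_vol
    return out


def sediment_exchange(
    state: TracerState,
    geometry: ModelGeometry,
    params: TransportParams,
    dt: float,
    solutes: tuple[str, ...] = ("NO3", "NH4"),
) -> TracerState:
    """Bioirrigation/bioturbation: linear porewater <-> bottom-water exchange."""
    k = min(params.bioturbation_exchange * dt, 0.5)
    if k <= 0:
        return state.copy()
    bottom = geometry.bottom_layer
    box_idx = np.arange(geometry.n_boxes)
    vol_bot = geometry.volume_matrix[box_idx, bottom]
    sed_vol = geometry.areas * geometry.layers.sediment_thickness
    out = state.copy()
    for tr in solutes:
        if tr not in out.sediment or tr not in out.water:
            continue
        c_sed = out.sediment[tr]
        c_bot = out.water[tr][box_idx, bottom]
        m = k * (c_sed - c_bot) * sed_vol  # mg moved sediment -> bottom water
        out.sediment[tr] = c_sed - m / sed_vol
        w = out.water[tr].copy()
        w[box_idx, bottom] = c_bot + m / vol_bot
        out.water[tr] = w
    return out
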