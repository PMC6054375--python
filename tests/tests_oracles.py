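"""Independent closed-form oracles shared by the acceptance tests.

Each function runs the package's operator against an analytic solution
computed here (exponential relaxation, dense ODE integration, renewal
survivorship, the annuity formula) and returns the discrepancy.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from baltisim.biogeochem import producer_step
from baltisim.groups import MG_N_PER_G_WW, ProducerParams, VertebrateParams
from baltisim.model_domain import (
    BoxGeometry,
    FaceGeometry,
    LayerScheme,
    ModelGeometry,
    TracerState,
)
from baltisim.transport import TransportParams, advect, vertical_mix
from baltisim.trophic import VertState, age_cohorts, vertebrate_mortality


def _square():
    return ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0))


def two_box_advection_error() -> float:
    """Closed two-box exchange vs the exponential relaxation solution."""
    geom = ModelGeometry(
        boxes=(
            BoxGeometry(0, _square(), 1.0, 10.0, "dynamic", {"mud": 1.0}),
            BoxGeometry(1, _square(), 1.0, 10.0, "dynamic", {"mud": 1.0}),
        ),
        faces=(FaceGeometry(0, 0, 1, 1.0), FaceGeometry(1, 1, 0, 1.0)),
        layers=LayerScheme((10.0,)),
    )
    state = TracerState.zeros(geom)
    state.water["NO3"][0, 0] = 2.0
    Q, V, n = 0.025, 10.0, 400
    q = np.zeros((2, 1))
    q[0, 0] = q[1, 0] = Q
    for _ in range(n):
        state = advect(state, geom, q)
    diff = state.water["NO3"][0, 0] - state.water["NO3"][1, 0]
    expected = 2.0 * np.exp(-2.0 * Q * n / V)
    return abs(diff - expected) / expected


def mixing_ode_error() -> float:
    """Three-layer mixing vs a brute-force dense tridiagonal integration.

    The oracle integrates the equivalent 3x3 ODE system with an
    independent dense implementation at the same explicit step, so the
    comparison isolates the operator's bookkeeping (masking, volumes,
    interface coefficients) from time-discretisation error.
    """
    geom = ModelGeometry(
        boxes=(
            BoxGeometry(0, _square(), 2.0, 30.0, "dynamic", {"mud": 1.0}),
        ),
        faces=(),
        layers=LayerScheme((10.0, 20.0, 30.0)),
    )
    rate, area, dist, vol = 4.0, 2.0, 10.0, 20.0
    params = TransportParams(vertical_mixing_rate=rate, halocline_depth=1e9)
    k = rate * area / dist / vol
    A = np.array([[-k, k, 0.0], [k, -2 * k, k], [0.0, k, -k]])
    c_ref = np.array([3.0, 1.0, 0.5])
    state = TracerState.zeros(geom)
    state.water["NO3"][0] = c_ref.copy()
    dt, n = 1e-3, 5000
    for _ in range(n):
        c_ref = c_ref + dt * (A @ c_ref)
        state = vertical_mix(state, geom, params, dt)
    return float(np.abs(state.water["NO3"][0] - c_ref).max())


def producer_growth_error() -> float:
    """Unlimited producer growth vs B0 exp(mu t) over 10 days at dt=0.1."""
    p = ProducerParams(mu_max=0.08, K_N=1e-6, K_I=1e-6, mortality_lin=0.0)
    B = np.array([[1.0]])
    for _ in range(100):
        res = producer_step(
            B, np.array([[1e9]]), np.array([[1e9]]), np.array([[1e9]]),
            np.array([[1e15]]), p, 0.1,
        )
        B = B + res["growth"]
    return float(abs(B[0, 0] - np.exp(0.8)) / np.exp(0.8))


def survivorship_error() -> float:
    """Constant-R, constant-Z cohort equilibrium vs R exp(-sum Z)."""
    Z = np.array([0.5, 0.4, 0.3, 0.3, 0.3])
    p = VertebrateParams(
        n_cohorts=5, maturation_cohort=2, spawn_ogive=(0.0, 0.5, 1.0, 1.0, 1.0),
        clearance=(1e5,) * 5, max_intake=(0.05,) * 5, assimilation=0.3,
        mort_lin=tuple(Z), F_adult=0.0, F_juvenile=0.0,
        BH_alpha=1e6, BH_beta=100.0,
        init_weight_g=(5.0, 10.0, 20.0, 30.0, 40.0), recruit_weight_g=5.0,
    )
    w = np.asarray(p.init_weight_g) * MG_N_PER_G_WW
    vs = VertState(
        numbers=np.zeros(5), w_struct=w * 0.75, w_res=w * 0.25,
        dist={"juvenile": np.full((4, 2), 0.5), "adult": np.full((4, 2), 0.5)},
    )
    R = 1e6
    for _ in range(30):
        for _ in range(365):
            vs, _ = vertebrate_mortality(vs, p, 1.0)
        vs = age_cohorts(vs, p)
        vs.numbers[0] = R
    expected = R * np.exp(-np.concatenate([[0.0], np.cumsum(Z[:-1])]))
    expected[-1] = expected[-1] / (1.0 - np.exp(-Z[-1]))
    return float(np.max(np.abs(vs.numbers - expected) / expected))


def annuity_error() -> float:
    """Constant-profit NPV vs the closed-form annuity sum (EUR)."""
    from baltisim.fishrent_econ import (
        CatchParams,
        EconPolicy,
        FleetSegment,
        StockInput,
        project_npv,
    )

    fleet = FleetSegment(
        "f", effort=1000.0, max_effort=2000.0, fuel_per_day=0.0,
        variable_per_day=0.0, crew_share=0.0, fixed_per_year=0.0,
        capital_per_year=0.0,
        cobb_douglas={"A": CatchParams(A=100.0, quota_share=1.0)},
        area_keys={"kattegat": 0.5, "western_baltic": 0.5},
    )
    stocks = {"A": StockInput("A", 1000.0, 0.3, 0.2, TAC=1e9, price=10.0)}
    policy = EconPolicy(start_year=2012, end_year=2021, discount_rate=0.05,
                       behavior_lambda=0.0)
    res = project_npv([fleet], stocks, policy)
    P, n, r = 1000.0, 10, 0.05
    expected = P * (1.0 - (1.0 + r) ** -n) / r * (1.0 + r)
    return abs(res.npv_total * 1e6 - expected)
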