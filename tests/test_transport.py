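"""Advection, vertical mixing, settling: conservation and ODE oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from baltisim.model_domain import (
    BoxGeometry,
    FaceGeometry,
    LayerScheme,
    ModelGeometry,
    TracerState,
    ValidationError,
)
from baltisim.transport import TransportParams, advect, sediment_exchange, settle, vertical_mix


def _two_box(kind0="dynamic", depth=10.0, area=1.0):
    def box(i, kind):
        return BoxGeometry(
            i, ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)),
            area, depth, kind, {"mud": 1.0}, axis=0.2 * i,
        )

    return ModelGeometry(
        boxes=(box(0, kind0), box(1, "dynamic")),
        faces=(FaceGeometry(0, 0, 1, 1.0), FaceGeometry(1, 1, 0, 1.0)),
        layers=LayerScheme((depth,)),
    )


def _column(n_layers=3, area=1.0, thickness=10.0):
    depths = tuple(thickness * (i + 1) for i in range(n_layers))
    return ModelGeometry(
        boxes=(
            BoxGeometry(
                0, ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)),
                area, depths[-1], "dynamic", {"mud": 1.0},
            ),
        ),
        faces=(),
        layers=LayerScheme(depths),
    )


class TestAdvection:
    def test_uniform_field_is_invariant(self, mini8, forcing):
        state = TracerState.zeros(mini8)
        c0 = 3.7
        state.water["NO3"] = np.where(mini8.layer_mask, c0, 0.0)
        out = advect(state, mini8, forcing.exchange[0])
        np.testing.assert_allclose(
            out.water["NO3"][mini8.layer_mask], c0, rtol=1e-12
        )

    def test_two_box_relaxation_matches_closed_form(self):
        """Closed symmetric exchange: concentrations relax as exp(-2Qt/V)."""
        geom = _two_box()
        V = 10.0  # area 1 x depth 10
        Q = 0.025  # per step, both directions -> symmetric mixing
        state = TracerState.zeros(geom)
        state.water["NO3"][0, 0] = 2.0
        state.water["NO3"][1, 0] = 0.0
        # face 0: 0->1 carries +Q; face 1: 1->0 carries +Q (both positive)
        q = np.zeros((2, 1))
        q[0, 0] = Q
        q[1, 0] = Q
        n_steps = 400
        for _ in range(n_steps):
            state = advect(state, geom, q)
        t = n_steps  # steps, dt=1 per application with volume V
        diff = state.water["NO3"][0, 0] - state.water["NO3"][1, 0]
        # discrete upwind solution: diff_n = diff_0 * (1 - 2Q/V)^n ~ exp(-2Qt/V)
        expected = 2.0 * np.exp(-2 * Q * t / V)
        assert diff == pytest.approx(expected, rel=0.01)
        total = (state.water["NO3"] * geom.volume_matrix).sum()
        assert total == pytest.approx(2.0 * V, rel=1e-12)

    def test_boundary_reservoir_fixed_point(self):
        """A dynamic box exchanging with a fixed boundary approaches c_ext."""
        geom = _two_box(kind0="boundary")
        c_ext = 5.0
        state = TracerState.zeros(geom)
        state.water["NO3"][0, 0] = c_ext  # boundary held at c_ext
        state.water["NO3"][1, 0] = 0.0
        q = np.zeros((2, 1))
        q[0, 0] = 0.2
        q[1, 0] = 0.2
        for _ in range(2000):
            state = advect(state, geom, q)
            state.water["NO3"][0, 0] = c_ext
        assert state.water["NO3"][1, 0] == pytest.approx(c_ext, abs=1e-6)

    def test_cfl_violation_reports_substepping(self):
        geom = _two_box()
        state = TracerState.zeros(geom)
        q = np.full((2, 1), 8.0)  # moves most of the cell volume in one step
        with pytest.raises(ValidationError, match="[Ss]ub-step"):
            advect(state, geom, q, allow_substeps=False)

    def test_nan_forcing_rejected(self, mini8):
        state = TracerState.zeros(mini8)
        q = np.full((mini8.n_faces, mini8.n_layers), np.nan)
        with pytest.raises(ValidationError, match="NaN"):
            advect(state, mini8, q)


class TestVerticalMix:
    def test_two_layer_symmetry_and_conservation(self):
        geom = _column(2)
        params = TransportParams(vertical_mixing_rate=5.0, halocline_depth=1e9)
        state = TracerState.zeros(geom)
        state.water["NO3"][0] = [2.0, 0.0]
        mass0 = (state.water["NO3"] * geom.volume_matrix).sum()
        for _ in range(3000):
            state = vertical_mix(state, geom, params, 1.0)
        np.testing.assert_allclose(state.water["NO3"][0], 1.0, rtol=1e-6)
        assert (state.water["NO3"] * geom.volume_matrix).sum() == pytest.approx(
            mass0, rel=1e-12
        )

    def test_zero_rate_is_identity(self, mini8):
        state = TracerState.zeros(mini8)
        rng = np.random.default_rng(3)
        state.water["NO3"] = rng.random((8, 3)) * mini8.layer_mask
        out = vertical_mix(state, mini8, TransportParams(vertical_mixing_rate=0.0), 1.0)
        np.testing.assert_array_equal(out.water["NO3"], state.water["NO3"])

    def test_three_layer_column_matches_dense_ode(self):
        """The operator equals an independent dense tridiagonal
        integration at the same step, and converges on scipy's dense
        solution as the step shrinks."""
        geom = _column(3, area=2.0, thickness=10.0)
        rate = 4.0
        params = TransportParams(vertical_mixing_rate=rate, halocline_depth=1e9)
        area, dist, vol = 2.0, 10.0, 20.0
        k = rate * area / dist / vol
        A = np.array([[-k, k, 0.0], [k, -2 * k, k], [0.0, k, -k]])
        c0 = np.array([3.0, 1.0, 0.5])

        # independent dense implementation, same explicit step
        c_ref = c0.copy()
        state = TracerState.zeros(geom)
        state.water["NO3"][0] = c0
        dt, n = 1e-3, 5000
        for _ in range(n):
            c_ref = c_ref + dt * (A @ c_ref)
            state = vertical_mix(state, geom, params, dt)
        np.testing.assert_allclose(state.water["NO3"][0], c_ref, atol=1e-12)

        # and the small-dt trajectory tracks the continuous solution
        sol = solve_ivp(lambda t, c: A @ c, (0, n * dt), c0, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(state.water["NO3"][0], sol.y[:, -1], atol=1e-3)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            TransportParams(vertical_mixing_rate=-1.0).validate()


class TestSettle:
    def test_all_detritus_reaches_the_sediment(self):
        geom = _column(3)
        params = TransportParams(settling_velocity={"DL": 3.0})
        state = TracerState.zeros(geom)
        state.water["DL"][0, 0] = 10.0
        mass0 = (state.water["DL"] * geom.volume_matrix).sum()
        for _ in range(2000):
            state = settle(state, geom, params, 1.0)
        sed_mass = state.sediment["DL"][0] * geom.areas[0] * 0.5
        assert (state.water["DL"] * geom.volume_matrix).sum() == pytest.approx(0.0, abs=1e-9 * mass0)
        assert sed_mass == pytest.approx(mass0, rel=1e-9)

    def test_zero_velocity_identity(self):
        geom = _column(3)
        state = TracerState.zeros(geom)
        state.water["DL"][0] = [1.0, 2.0, 3.0]
        out = settle(state, geom, TransportParams(settling_velocity={"DL": 0.0}), 1.0)
        np.testing.assert_array_equal(out.water["DL"], state.water["DL"])

    def test_water_plus_sediment_mass_constant(self):
        geom = _column(3)
        params = TransportParams(settling_velocity={"DL": 1.5, "DR": 0.5})
        state = TracerState.zeros(geom)
        state.water["DL"][0] = [5.0, 1.0, 0.2]
        state.water["DR"][0] = [2.0, 0.5, 0.1]
        sed_vol = geom.areas[0] * 0.5

        def total(tr):
            return (state.water[tr] * geom.volume_matrix).sum() + state.sediment[tr][0] * sed_vol

        m0 = {tr: total(tr) for tr in ("DL", "DR")}
        for _ in range(1000):
            state = settle(state, geom, params, 1.0)
        for tr in ("DL", "DR"):
            assert total(tr) == pytest.approx(m0[tr], rel=1e-12)

    def test_settling_a_solute_is_rejected(self):
        geom = _column(2)
        state = TracerState.zeros(geom)
        with pytest.raises(ValidationError, match="non-particulate"):
            settle(state, geom, TransportParams(), 1.0, tracers=("NO3",))
        with pytest.raises(ValidationError, match="non-particulate"):
            TransportParams(settling_velocity={"NO3": 1.0}).validate()


class TestSedimentExchange:
    def test_solutes_relax_between_porewater_and_bottom(self):
        geom = _column(2)
        params = TransportParams(bioturbation_exchange=0.2)
        state = TracerState.zeros(geom)
        state.sediment["NH4"][0] = 100.0
        sed_vol = geom.areas[0] * 0.5
        m0 = state.sediment["NH4"][0] * sed_vol
        out = sediment_exchange(state, geom, params, 1.0)
        assert out.sediment["NH4"][0] < 100.0
        assert out.water["NH4"][0, 1] > 0.0
        m1 = out.sediment["NH4"][0] * sed_vol + (out.water["NH4"] * geom.volume_matrix).sum()
        assert m1 == pytest.approx(m0, rel=1e-12)


class TestEngineFastPath:
    def test_stacked_physics_matches_pure_operators(self, mini8, groups, avail, forcing, load_table, dep_flux, initial_conditions):
        """One day of the engine's fused transport equals the sequential
        pure operators applied at the same forcing steps."""
        from baltisim.ecosystem import Simulation

        sim = Simulation(mini8, groups, avail, forcing, load_table, dep_flux)
        state = initial_conditions.tracers.copy()
        ledger = {"boundary": 0.0}
        fast = sim._physics_day(state.copy(), 0, ledger)

        ref = state.copy()
        tp = sim.p.transport
        for sub in range(2):
            idx = forcing.step_index(0, sub)
            for tr, clim in forcing.boundary_tracers.items():
                if tr in ref.water:
                    ref.water[tr][~mini8.dynamic_mask] = clim[idx][~mini8.dynamic_mask]
            ref = advect(ref, mini8, forcing.exchange[idx], cfl_max=tp.cfl_max)
            ref = vertical_mix(ref, mini8, tp, 0.5)
            ref = settle(ref, mini8, tp, 0.5)
        ref = sediment_exchange(ref, mini8, tp, 1.0)
        for tr in ref.water:
            np.testing.assert_allclose(fast.water[tr], ref.water[tr], rtol=1e-10, atol=1e-12)
        for tr in ref.sediment:
            np.testing.assert_allclose(fast.sediment[tr], ref.sediment[tr], rtol=1e-10, atol=1e-12)
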