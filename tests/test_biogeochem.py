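"""Light, primary production, remineralization, denitrification, oxygen."""

import numpy as np
import pytest

from baltisim.biogeochem import (
    LightParams,
    SinkParams,
    denitrify,
    light_profile,
    o2_saturation,
    oxygen_step,
    producer_step,
    remineralize,
    surface_irradiance,
)
from baltisim.groups import ProducerParams
from baltisim.model_domain import (
    BoxGeometry,
    FaceGeometry,
    LayerScheme,
    ModelGeometry,
    TracerState,
    ValidationError,
)


def _column(n_layers=3, thickness=10.0, area=1.0):
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


class TestLight:
    def test_closed_form_attenuation(self):
        # I(10 m) with k_w = 0.1 and no biomass: 100 * e^-1
        prof = light_profile(
            100.0, np.zeros(1), LightParams(k_w=0.1, k_bio=0.0), np.array([20.0])
        )
        assert prof[0] == pytest.approx(100.0 * np.exp(-1.0), rel=1e-12)

    def test_profile_independent_of_biomass_when_kbio_zero(self):
        params = LightParams(k_w=0.2, k_bio=0.0)
        thick = np.array([5.0, 10.0, 20.0])
        a = light_profile(50.0, np.zeros(3), params, thick)
        b = light_profile(50.0, np.full(3, 100.0), params, thick)
        np.testing.assert_array_equal(a, b)

    def test_more_biomass_darkens_deeper_layers(self):
        params = LightParams(k_w=0.1, k_bio=1e-3)
        thick = np.array([5.0, 10.0, 20.0])
        base = light_profile(50.0, np.full(3, 10.0), params, thick)
        shaded = light_profile(50.0, np.full(3, 20.0), params, thick)
        assert np.all(shaded[1:] < base[1:])
        assert np.all(np.diff(base) < 0)

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValidationError):
            light_profile(10.0, np.array([-1.0]), LightParams(), np.array([5.0]))

    def test_irradiance_seasonal_ordering(self):
        assert surface_irradiance(56.0, 172) > surface_irradiance(56.0, 355)


class TestProducerStep:
    def _params(self, **kw):
        defaults = dict(mu_max=0.08, K_N=10.0, K_I=25.0, mortality_lin=0.0)
        defaults.update(kw)
        return ProducerParams(**defaults)

    def test_half_saturation_identity(self):
        """At N = K_N under saturating light the realized rate is mu/2."""
        p = self._params(mu_max=0.4, K_N=10.0)
        res = producer_step(
            biomass=np.array([[1.0]]),
            no3=np.array([[10.0]]),
            nh4=np.array([[0.0]]),
            light=np.array([[1e9]]),
            volumes=np.array([[1e12]]),
            params=p,
            dt=1.0,
        )
        assert res["growth"][0, 0] == pytest.approx(0.2, rel=1e-9)

    def test_zero_nutrients_zero_growth_and_uptake(self):
        p = self._params()
        res = producer_step(
            np.array([[5.0]]), np.array([[0.0]]), np.array([[0.0]]),
            np.array([[100.0]]), np.array([[1e9]]), p, 1.0,
        )
        assert res["growth"][0, 0] == 0.0
        assert res["dNO3"][0, 0] == 0.0
        assert res["dNH4"][0, 0] == 0.0

    def test_nh4_drawn_before_no3(self):
        p = self._params(mu_max=0.5)
        vol = np.array([[1e6]])
        res = producer_step(
            np.array([[1000.0]]), np.array([[50.0]]), np.array([[0.05]]),
            np.array([[1e9]]), vol, p, 1.0,
        )
        nh4_removed = -res["dNH4"][0, 0] * vol[0, 0]
        assert nh4_removed == pytest.approx(0.05 * 1e6, rel=1e-9)  # all NH4 first
        assert res["dNO3"][0, 0] < 0.0

    def test_exponential_growth_oracle(self):
        """Ample nutrients, constant light: B(t) = B0 e^(mu t) within 0.5%."""
        p = self._params(mu_max=0.08, K_N=1e-6, K_I=1e-6)
        B = np.array([[1.0]])
        dt = 0.1
        for _ in range(100):  # 10 days
            res = producer_step(
                B, np.array([[1e9]]), np.array([[1e9]]),
                np.array([[1e9]]), np.array([[1e15]]), p, dt,
            )
            B = B + res["growth"]
        assert B[0, 0] == pytest.approx(np.exp(0.08 * 10.0), rel=5e-3)

    def test_space_limitation_stops_growth_at_capacity(self):
        p = self._params(mu_max=0.5)
        res = producer_step(
            np.array([[4.0]]), np.array([[100.0]]), np.array([[0.0]]),
            np.array([[1e9]]), np.array([[1e9]]), p, 1.0,
            space_capacity=np.array([[4.0]]),
        )
        assert res["growth"][0, 0] == 0.0


class TestRemineralize:
    def test_labile_efolding_oracle(self):
        """DL=100, lambda=0.1/day, one day in Euler steps of 0.1."""
        geom = _column(1)
        state = TracerState.zeros(geom)
        state.water["DL"][0, 0] = 100.0
        state.water["O2"][0, 0] = 1e9
        params = SinkParams(lambda_L=0.1, lambda_R=0.001, don_remin=0.0, burial_fraction=0.0)
        for _ in range(10):
            state = remineralize(state, geom, params, 0.1)
        assert state.water["DL"][0, 0] == pytest.approx(100.0 * (1 - 0.01) ** 10, rel=1e-9)
        assert state.water["DL"][0, 0] == pytest.approx(90.44, abs=0.01)
        assert state.water["NH4"][0, 0] == pytest.approx(100.0 - state.water["DL"][0, 0], rel=1e-9)

    def test_zero_rates_no_change(self):
        geom = _column(1)
        state = TracerState.zeros(geom)
        state.water["DL"][0, 0] = 7.0
        params = SinkParams(lambda_L=1e-12, lambda_R=0.0, don_remin=0.0, burial_fraction=0.0)
        out = remineralize(state, geom, params, 1.0)
        assert out.water["DL"][0, 0] == pytest.approx(7.0, rel=1e-9)

    def test_burial_ledger_closes_sediment_budget(self):
        geom = _column(1)
        state = TracerState.zeros(geom)
        state.sediment["DL"][0] = 500.0
        state.sediment["DR"][0] = 300.0
        sed_vol = geom.areas[0] * 0.5
        m0 = 800.0 * sed_vol
        params = SinkParams(lambda_L=0.0, lambda_R=0.0, don_remin=0.0, burial_fraction=0.01)
        ledger = {}
        # lambda_R >= lambda_L would fail validation; rates of zero are used
        for _ in range(50):
            state = remineralize(state, geom, params, 1.0, burial_ledger=ledger)
        remaining = (state.sediment["DL"][0] + state.sediment["DR"][0]) * sed_vol
        assert sum(ledger.values()) + remaining == pytest.approx(m0, rel=1e-9)


class TestDenitrify:
    def test_gated_by_bottom_oxygen(self):
        geom = _column(1)
        state = TracerState.zeros(geom)
        state.sediment["NO3"][0] = 50.0
        state.water["O2"][0, 0] = 9000.0
        params = SinkParams(denit_rate=0.02, denit_O2_threshold=3000.0)
        out = denitrify(state, geom, params, 1.0)
        assert out.sediment["NO3"][0] == 50.0

    def test_efolding_loss_under_hypoxia(self):
        geom = _column(1)
        state = TracerState.zeros(geom)
        state.sediment["NO3"][0] = 50.0
        state.water["O2"][0, 0] = 100.0
        params = SinkParams(denit_rate=0.02, denit_O2_threshold=3000.0)
        ledger = {}
        for _ in range(10):
            state = denitrify(state, geom, params, 0.1, denit_ledger=ledger)
        loss = 50.0 - state.sediment["NO3"][0]
        assert loss == pytest.approx(50.0 * (1 - (1 - 0.002) ** 10), rel=1e-9)
        assert loss == pytest.approx(0.99, abs=0.01)

    def test_ledger_monotone(self):
        geom = _column(1)
        state = TracerState.zeros(geom)
        state.sediment["NO3"][0] = 10.0
        params = SinkParams(denit_rate=0.05, denit_O2_threshold=3000.0)
        ledger = {}
        last = 0.0
        for _ in range(20):
            state = denitrify(state, geom, params, 1.0, denit_ledger=ledger)
            assert ledger["NO3"] >= last
            last = ledger["NO3"]


class TestOxygen:
    def test_surface_relaxes_toward_saturation(self):
        geom = _column(2)
        state = TracerState.zeros(geom)
        T = np.full((1, 2), 10.0)
        S = np.full((1, 2), 8.0)
        sat = o2_saturation(np.array(10.0), np.array(8.0))
        state.water["O2"][0] = [1000.0, 1000.0]
        params = SinkParams()
        prev = 1000.0
        for _ in range(30):
            state = oxygen_step(state, geom, params, T, S, 1.0)
            assert state.water["O2"][0, 0] >= prev  # monotone toward saturation
            prev = state.water["O2"][0, 0]
        assert prev == pytest.approx(float(sat), rel=1e-3)

    def test_oxygen_floored_at_zero_under_heavy_demand(self):
        geom = _column(2)
        state = TracerState.zeros(geom)
        state.water["O2"][0] = [100.0, 50.0]
        state.sediment["DL"][0] = 1e9  # extreme sediment oxygen demand
        T = np.full((1, 2), 5.0)
        S = np.full((1, 2), 8.0)
        params = SinkParams()
        for _ in range(10):
            state = oxygen_step(state, geom, params, T, S, 1.0)
            assert state.water["O2"].min() >= 0.0
        assert state.water["O2"][0, 1] == 0.0
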