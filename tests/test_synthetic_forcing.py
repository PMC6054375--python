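"""Synthetic physics forcing, riverine loads, deposition, and initial
conditions: determinism, balance, and bookkeeping contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baltisim.constants import MG_N_PER_MMOL_N
from baltisim.groups import default_groups
from baltisim.model_domain import BoxGeometry, FaceGeometry, LayerScheme, ModelGeometry, ValidationError
from baltisim.synthetic_forcing import (
    DepositionParams,
    InitialConditionParams,
    LoadParams,
    PhysicsParams,
    deposition_flux,
    effective_daily_loads,
    generate_initial_conditions,
    generate_loads,
    generate_physics,
    read_forcing,
    write_forcing,
)


class TestPhysics:
    def test_deterministic_for_fixed_seed(self, mini8):
        a = generate_physics(mini8, PhysicsParams(), 1)
        b = generate_physics(mini8, PhysicsParams(), 1)
        np.testing.assert_array_equal(a.exchange, b.exchange)
        np.testing.assert_array_equal(a.temperature, b.temperature)

    def test_different_seed_changes_exchange(self, mini8):
        a = generate_physics(mini8, PhysicsParams(), 1)
        b = generate_physics(mini8, PhysicsParams(), 2)
        assert not np.array_equal(a.exchange, b.exchange)

    def test_dynamic_boxes_have_zero_net_volume_flux(self, mini8, forcing):
        net = np.zeros((forcing.n_steps, mini8.n_boxes, mini8.n_layers))
        for f in range(mini8.n_faces):
            q = forcing.exchange[:, f, :]
            net[:, mini8.face_right[f], :] += q
            net[:, mini8.face_left[f], :] -= q
        scale = np.abs(forcing.exchange).max()
        assert np.abs(net[:, mini8.dynamic_mask, :]).max() <= 1e-6 * scale

    def test_coastal_winter_minimum_at_or_below_target(self, mini8, forcing):
        params = PhysicsParams()
        coastal = [b.box_id for b in mini8.boxes if b.coastal]
        tmin = forcing.temperature[:, coastal, 0].min()
        assert tmin <= max(params.coastal_winter_min, 0.0)

    def test_coastal_amplitude_exceeds_offshore(self, mini8, forcing):
        coastal = [b.box_id for b in mini8.boxes if b.coastal]
        offshore = [b.box_id for b in mini8.boxes if not b.coastal and b.kind == "dynamic"]
        amp_c = np.ptp(forcing.temperature[:, coastal, 0], axis=0).min()
        amp_o = np.ptp(forcing.temperature[:, offshore, 0], axis=0).max()
        assert amp_c > amp_o

    def test_salinity_decreases_along_axis(self, mini8, forcing):
        order = np.argsort([b.axis for b in mini8.boxes])
        surf = forcing.salinity[0, order, 0]
        assert np.all(np.diff(surf) <= 1e-9)

    def test_negative_salinity_rejected(self, mini8):
        params = PhysicsParams(salinity_north=-5.0)
        with pytest.raises(ValidationError, match="salinity"):
            generate_physics(mini8, params, 1)

    def test_forcing_netcdf_roundtrip(self, mini8, forcing, tmp_path):
        path = tmp_path / "forcing.nc"
        write_forcing(forcing, path)
        back = read_forcing(path)
        np.testing.assert_array_equal(back.exchange, forcing.exchange)
        np.testing.assert_array_equal(
            back.boundary_tracers["NO3"], forcing.boundary_tracers["NO3"]
        )


class TestLoads:
    def test_plain_arithmetic(self, mini8):
        table = generate_loads(
            mini8,
            LoadParams(
                box_totals={1: 36_500.0},
                retention={},
                default_retention=0.0,
                din_fraction=1.0,
                offshore_spill_fraction=0.0,
            ),
            seed=1,
        )
        daily = effective_daily_loads(mini8, table)
        assert daily["din"][1] == pytest.approx(100.0)
        assert daily["don"].sum() == 0.0

    def test_full_retention_means_zero_load(self, mini8):
        table = generate_loads(
            mini8, LoadParams(box_totals={1: 1000.0}, retention={}, default_retention=1.0), 1
        )
        daily = effective_daily_loads(mini8, table)
        assert daily["din"].sum() + daily["don"].sum() + daily["refractory"].sum() == 0.0

    def test_offshore_spill_split(self, mini8):
        table = generate_loads(
            mini8,
            LoadParams(
                box_totals={1: 365.0},
                retention={},
                default_retention=0.0,
                din_fraction=1.0,
                offshore_spill_fraction=0.3,
            ),
            1,
        )
        daily = effective_daily_loads(mini8, table)
        target = int(table.loc[0, "spill_target"])
        assert target != 1
        assert daily["din"][1] == pytest.approx(0.7, rel=1e-9)
        assert daily["din"][target] == pytest.approx(0.3, rel=1e-9)

    def test_boundary_box_load_rejected(self, mini8):
        with pytest.raises(ValidationError, match="boundary box"):
            generate_loads(mini8, LoadParams(box_totals={0: 100.0}), 1)

    @settings(max_examples=20, deadline=None)
    @given(
        rho=st.floats(0.0, 1.0),
        din=st.floats(0.0, 1.0),
        spill=st.floats(0.0, 1.0),
        bio=st.floats(0.0, 1.0),
    )
    def test_load_bookkeeping_closes(self, rho, din, spill, bio):
        geom = _spill_geometry()
        table = generate_loads(
            geom,
            LoadParams(
                box_totals={1: 1000.0},
                retention={},
                default_retention=rho,
                din_fraction=din,
                offshore_spill_fraction=spill,
                bioavailable_don_fraction=bio,
            ),
            1,
        )
        daily = effective_daily_loads(geom, table)
        total = (daily["din"] + daily["don"] + daily["refractory"]).sum() * 365.0
        assert total == pytest.approx(1000.0 * (1.0 - rho), rel=1e-9, abs=1e-12)


def _spill_geometry():
    """Two dynamic boxes (coastal + offshore neighbour) and a boundary box."""
    def box(i, kind, coastal, hab):
        return BoxGeometry(
            i, ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)),
            1e9, 30.0, kind, hab, coastal=coastal, axis=0.1 * i,
        )

    return ModelGeometry(
        boxes=(
            box(0, "boundary", False, {"mud": 1.0}),
            box(1, "dynamic", True, {"sand": 0.6, "mud": 0.4}),
            box(2, "dynamic", False, {"mud": 1.0}),
        ),
        faces=(FaceGeometry(0, 0, 1, 1e4), FaceGeometry(1, 1, 2, 1e4)),
        layers=LayerScheme((10.0, 30.0)),
    )


class TestDeposition:
    def test_stated_rate_on_a_square_kilometre_scale_box(self):
        geom = _spill_geometry()
        flux = deposition_flux(geom, DepositionParams(areal_rate=0.15))
        # 0.15 mmol m-2 day-1 on 1e9 m2 -> 1.5e8 mmol -> 2.1e9 mg N per day
        assert flux[1] == pytest.approx(0.15 * MG_N_PER_MMOL_N * 1e9)
        assert flux[1] == pytest.approx(2.1e9)

    def test_zero_rate_zero_flux(self, mini8):
        assert deposition_flux(mini8, DepositionParams(areal_rate=0.0)).sum() == 0.0

    def test_linearity_in_area(self):
        geom = _spill_geometry()
        flux = deposition_flux(geom, DepositionParams())
        assert flux[2] == pytest.approx(flux[1])  # equal areas -> equal source


class TestInitialConditions:
    def test_group_totals_match_targets(self, mini8, groups, initial_conditions):
        gs = initial_conditions.groups
        for code, grp in groups.items():
            assert gs.total_biomass(code) == pytest.approx(grp.init_biomass, rel=1e-6)

    def test_two_seeds_same_totals_different_fields(self, mini8, groups, forcing):
        a = generate_initial_conditions(mini8, groups, InitialConditionParams(), 1, physics=forcing)
        b = generate_initial_conditions(mini8, groups, InitialConditionParams(), 2, physics=forcing)
        assert a.groups.total_biomass("FSR") == pytest.approx(
            b.groups.total_biomass("FSR"), rel=1e-9
        )
        assert not np.array_equal(a.groups.pools["PS"], b.groups.pools["PS"])

    def test_distribution_maps_sum_to_one(self, initial_conditions):
        for code, vs in initial_conditions.groups.verts.items():
            for stage, d in vs.dist.items():
                np.testing.assert_allclose(d.sum(axis=1), 1.0, atol=1e-9)

    def test_hard_substrate_group_placed_only_on_bedrock(self, groups):
        geom = _bedrock_only_box3_geometry()
        ic = generate_initial_conditions(geom, {"HF": groups["HF"]}, InitialConditionParams(), 1)
        per_box = ic.groups.pools["HF"].sum(axis=1)
        assert per_box[3] == pytest.approx(groups["HF"].init_biomass, rel=1e-6)
        assert per_box[[1, 2]].sum() == 0.0

    def test_no_admissible_habitat_raises(self, groups):
        geom = _spill_geometry()  # no bedrock anywhere
        with pytest.raises(ValidationError, match="admissible habitat"):
            generate_initial_conditions(geom, {"HF": groups["HF"]}, InitialConditionParams(), 1)

    def test_low_initial_detritus_rule_enforced(self, mini8, groups):
        params = InitialConditionParams(dl=5000.0, dr=5000.0)
        with pytest.raises(ValidationError, match="detritus"):
            generate_initial_conditions(mini8, groups, params, 1)


def _bedrock_only_box3_geometry():
    def box(i, kind, hab):
        return BoxGeometry(
            i, ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)),
            1e9, 30.0, kind, hab, axis=0.1 * i,
        )

    return ModelGeometry(
        boxes=(
            box(0, "boundary", {"mud": 1.0}),
            box(1, "dynamic", {"mud": 1.0}),
            box(2, "dynamic", {"sand": 1.0}),
            box(3, "dynamic", {"bedrock": 1.0}),
        ),
        faces=(
            FaceGeometry(0, 0, 1, 1e4),
            FaceGeometry(1, 1, 2, 1e4),
            FaceGeometry(2, 2, 3, 1e4),
        ),
        layers=LayerScheme((10.0, 30.0)),
    )
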