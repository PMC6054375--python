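"""Feeding, growth, mortality, recruitment, and cohort bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baltisim.constants import MG_N_PER_TON_WW
from baltisim.groups import ADULT, EnvRamp, JUVENILE, MG_N_PER_G_WW, VertebrateParams
from baltisim.model_domain import ValidationError
from baltisim.trophic import (
    VertState,
    age_cohorts,
    apply_anoxia_rule,
    available_prey,
    beverton_holt,
    condition_factor,
    effective_dist,
    gape_ok,
    grow,
    holling_intake,
    recruit,
    stage_slices,
    vertebrate_mortality,
)


def _vert_params(**kw):
    defaults = dict(
        n_cohorts=5,
        maturation_cohort=2,
        spawn_ogive=(0.0, 0.5, 1.0, 1.0, 1.0),
        clearance=(1e5,) * 5,
        max_intake=(0.05,) * 5,
        assimilation=0.3,
        mort_lin=(0.4, 0.3, 0.2, 0.2, 0.2),
        F_adult=0.0,
        F_juvenile=0.0,
        BH_alpha=1e6,
        BH_beta=100.0,
        init_weight_g=(5.0, 10.0, 20.0, 30.0, 40.0),
        recruit_weight_g=5.0,
    )
    defaults.update(kw)
    return VertebrateParams(**defaults)


def _vert_state(params, numbers=None, n_boxes=4):
    w = np.asarray(params.init_weight_g) * MG_N_PER_G_WW
    dist = np.full((4, n_boxes), 1.0 / n_boxes)
    return VertState(
        numbers=np.asarray(numbers if numbers is not None else [1e6] * params.n_cohorts, dtype=float),
        w_struct=w * 0.75,
        w_res=w * 0.25,
        dist={JUVENILE: dist.copy(), ADULT: dist.copy()},
    )


class TestHollingIntake:
    def test_committed_functional_form_single_prey(self):
        """C=0.1, g=0.5, a=1, B=10 -> rate = C a B / (1 + (C/g) a B) = 1/3."""
        rate = holling_intake(0.1, 0.5, np.array([1.0]), np.array([10.0]))
        assert rate[0] == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_against_independent_scalar_implementation(self):
        rng = np.random.default_rng(11)
        C, g = 0.37, 0.21
        a = rng.random(4)
        B = rng.random(4) * 5.0
        rates = holling_intake(C, g, a, B)
        denom = 1.0 + (C / g) * float(np.dot(a, B))
        for j in range(4):
            assert rates[j] == pytest.approx(C * a[j] * B[j] / denom, rel=1e-12)

    def test_saturation_at_max_intake(self):
        rate = holling_intake(0.1, 0.5, np.array([1.0]), np.array([1e12]))
        assert rate.sum() == pytest.approx(0.5, rel=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(b=st.floats(min_value=1e-6, max_value=0.05))
    def test_linear_clearance_regime(self, b):
        """For C a B / g < 0.01 the rate is the clearance limit within 1%."""
        C, g = 0.1, 0.5
        B = b  # C*a*B/g = 0.02*b <= 0.01 in the sampled range
        rate = holling_intake(C, g, np.array([1.0]), np.array([B]))
        assert rate[0] == pytest.approx(C * B, rel=0.01)

    def test_negative_prey_rejected(self):
        with pytest.raises(ValidationError):
            holling_intake(0.1, 0.5, np.array([1.0]), np.array([-1.0]))


class TestGrow:
    def test_full_assimilation_no_waste(self):
        growth, det, nh4 = grow(10.0, 1.0)
        assert (growth, det, nh4) == (10.0, 0.0, 0.0)

    def test_split_arithmetic(self):
        growth, det, nh4 = grow(10.0, 0.1, egestion_frac=0.5)
        assert growth == pytest.approx(1.0)
        assert det == pytest.approx(4.5)
        assert nh4 == pytest.approx(4.5)

    @settings(max_examples=30, deadline=None)
    @given(
        intake=st.floats(0.0, 1e6),
        e=st.floats(0.01, 1.0),
        eg=st.floats(0.0, 1.0),
    )
    def test_mass_balance_exact(self, intake, e, eg):
        growth, det, nh4 = grow(intake, e, eg)
        assert growth + det + nh4 == pytest.approx(intake, rel=1e-12, abs=1e-12)


class TestMortality:
    def test_no_mortality_no_change(self):
        p = _vert_params(mort_lin=(0.0,) * 5)
        vs = _vert_state(p)
        out, res = vertebrate_mortality(vs, p, 1.0)
        np.testing.assert_array_equal(out.numbers, vs.numbers)
        assert res.detritus_tons == 0.0

    def test_adult_fishing_decay_over_one_year(self):
        """F = 0.32/yr alone: numbers ratio e^-0.32 after 365 daily steps."""
        p = _vert_params(mort_lin=(0.0,) * 5, F_adult=0.32, F_juvenile=0.0)
        vs = _vert_state(p)
        n0 = vs.numbers.copy()
        for _ in range(365):
            vs, _ = vertebrate_mortality(vs, p, 1.0)
        adults = stage_slices(p)[ADULT]
        ratio = vs.numbers[adults] / n0[adults]
        np.testing.assert_allclose(ratio, np.exp(-0.32), rtol=5e-3)
        juv = stage_slices(p)[JUVENILE]
        np.testing.assert_allclose(vs.numbers[juv], n0[juv])

    def test_catch_and_carrion_split_balances_losses(self):
        p = _vert_params(mort_lin=(0.2,) * 5, F_adult=0.3, F_juvenile=0.1)
        vs = _vert_state(p)
        b0 = vs.biomass_tons().sum()
        out, res = vertebrate_mortality(vs, p, 1.0)
        b1 = out.biomass_tons().sum()
        removed = b0 - b1
        assert res.detritus_tons + sum(res.catch_tons.values()) == pytest.approx(removed, rel=1e-9)

    def test_total_anoxia_removes_the_stage(self):
        p = _vert_params(O2_refuge_threshold=2000.0)
        vs = _vert_state(p)
        o2 = np.zeros(4)  # every box anoxic
        dists, lost = apply_anoxia_rule(vs, p, 0, o2)
        assert lost > 0.0
        assert vs.numbers.sum() == 0.0
        assert dists[ADULT].sum() == 0.0

    def test_partial_anoxia_relocates_proportionally(self):
        p = _vert_params(O2_refuge_threshold=2000.0)
        vs = _vert_state(p)
        o2 = np.array([5000.0, 0.0, 5000.0, 0.0])
        dists, lost = apply_anoxia_rule(vs, p, 0, o2)
        assert lost == 0.0
        np.testing.assert_allclose(dists[ADULT], [0.5, 0.0, 0.5, 0.0])
        assert vs.numbers.sum() > 0.0


class TestRecruitment:
    def test_asymptote(self):
        assert beverton_holt(1e6, 100.0, 1e12) == pytest.approx(1e6, rel=1e-6)

    def test_half_saturation(self):
        assert beverton_holt(1e6, 100.0, 100.0) == pytest.approx(5e5, rel=1e-12)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValidationError):
            beverton_holt(1.0, 0.0, 1.0)

    def test_cod_style_oxygen_ramp_zero_below_reproductive_volume_anchor(self):
        """O2 below 2 mL/L (2858 mg m-3) shuts recruitment off entirely."""
        ramp = EnvRamp(2858.0, 5716.0)
        p = _vert_params(env_O2=ramp)
        vs = _vert_state(p)
        _, R = recruit(vs, p, env_O2=2000.0)
        assert R == 0.0
        _, R_ok = recruit(vs, p, env_O2=5716.0)
        assert R_ok > 0.0

    def test_mammal_style_recruitment_ignores_temperature_and_salinity(self):
        p = _vert_params(env_T=None, env_S=None, env_O2=None)
        vs = _vert_state(p)
        _, R_cold = recruit(vs, p, env_T=-100.0, env_S=0.0)
        _, R_warm = recruit(vs, p, env_T=100.0, env_S=40.0)
        assert R_cold == pytest.approx(R_warm, rel=1e-12)

    def test_recruits_enter_youngest_cohort(self):
        p = _vert_params()
        vs = _vert_state(p, numbers=[0.0, 1e6, 1e6, 1e6, 1e6])
        out, R = recruit(vs, p)
        assert out.numbers[0] == pytest.approx(R)
        assert out.weight[0] == pytest.approx(p.recruit_weight_g * MG_N_PER_G_WW)


class TestAgeing:
    def test_numbers_shift_and_plus_group_accumulates(self):
        p = _vert_params()
        vs = _vert_state(p, numbers=[100.0, 80.0, 60.0, 40.0, 20.0])
        out = age_cohorts(vs, p)
        np.testing.assert_allclose(out.numbers, [0.0, 100.0, 80.0, 60.0, 60.0])

    def test_total_numbers_conserved_by_redistribution(self):
        p = _vert_params()
        vs = _vert_state(p)
        total = vs.numbers.sum()
        for q in range(4):
            d = effective_dist(vs, ADULT, q)
            assert d.sum() == pytest.approx(1.0, abs=1e-12)
        assert vs.numbers.sum() == total

    def test_survivorship_equilibrium_oracle(self):
        """Constant recruitment and mortality: N_a -> R exp(-sum Z_j) within 1%."""
        Z = np.array([0.5, 0.4, 0.3, 0.3, 0.3])
        p = _vert_params(mort_lin=tuple(Z), F_adult=0.0, F_juvenile=0.0)
        vs = _vert_state(p, numbers=[0.0] * 5)
        R = 1e6
        for _ in range(30):  # burn-in well past 5 cohorts
            for _ in range(365):
                vs, _ = vertebrate_mortality(vs, p, 1.0)
            vs = age_cohorts(vs, p)
            vs.numbers[0] = R
        expected = R * np.exp(-np.concatenate([[0.0], np.cumsum(Z[:-1])]))
        expected[-1] = expected[-1] / (1.0 - np.exp(-Z[-1]))  # plus-group sum
        np.testing.assert_allclose(vs.numbers, expected, rtol=0.01)


class TestAvailablePrey:
    def test_zero_availability_means_zero(self, mini8, groups, avail, initial_conditions):
        gs = initial_conditions.groups
        tr = initial_conditions.tracers
        # seals are not in the mesozooplankton diet
        b = available_prey("ZM", ADULT, "SEA", 1, gs, tr, mini8, groups, avail)
        assert b == 0.0

    def test_gape_window_excludes_oversized_prey(self, mini8, groups, avail, initial_conditions):
        gs = initial_conditions.groups
        tr = initial_conditions.tracers
        # sprat cannot swallow adult herring: ratio far above gape_max
        custom = {("FSR", ADULT): {"FHR": 1.0}}
        b = available_prey("FSR", ADULT, "FHR", 2, gs, tr, mini8, groups, custom)
        assert b == 0.0

    def test_full_availability_no_refuge_returns_prey_biomass(self, mini8, groups, avail, initial_conditions):
        gs = initial_conditions.groups
        tr = initial_conditions.tracers
        custom = {("ZM", ADULT): {"PS": 1.0}}
        b = available_prey("ZM", ADULT, "PS", 2, gs, tr, mini8, groups, custom)
        assert b == pytest.approx(gs.pools["PS"][2].sum(), rel=1e-12)

    def test_result_never_exceeds_prey_biomass(self, mini8, groups, avail, initial_conditions):
        gs = initial_conditions.groups
        tr = initial_conditions.tracers
        for (pred, stage), prey_map in avail.items():
            for prey in prey_map:
                b = available_prey(pred, stage, prey, 4, gs, tr, mini8, groups, avail)
                if prey in gs.pools:
                    assert b <= gs.pools[prey][4].sum() + 1e-9


class TestCondition:
    def test_reference_condition_is_unity(self):
        p = _vert_params()
        vs = _vert_state(p)
        assert condition_factor(vs, p, ADULT) == pytest.approx(1.0)

    def test_clamped_between_half_and_one_and_a_half(self):
        p = _vert_params()
        vs = _vert_state(p)
        vs.w_res[:] = vs.w_struct * 10.0
        assert condition_factor(vs, p, ADULT) == 1.5
        vs.w_res[:] = 0.0
        assert condition_factor(vs, p, ADULT) == 0.5


class TestGape:
    def test_window_boundaries(self):
        p = _vert_params(gape_min=0.01, gape_max=0.1)
        assert gape_ok(100.0, 1.0, p)
        assert gape_ok(100.0, 10.0, p)
        assert not gape_ok(100.0, 0.5, p)
        assert not gape_ok(100.0, 20.0, p)
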