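"""Unit and property tests for the model right-hand sides."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptivecrm import (
    CommunityParams,
    CommunityState,
    DiauxicParams,
    ResourceParams,
    SpeciesParams,
    community_rhs,
    constraint_phi,
    diauxic_rhs,
    growth_rate,
    monod,
    strategy_rhs,
)
from adaptivecrm.core import THETA_WIDTH

from conftest import random_community


class TestMonod:
    @pytest.mark.parametrize(
        "c, K, expected",
        [
            (2.0, 2.0, 0.5),       # half-saturation definition
            (0.0, 1.0, 0.0),       # no resource, no uptake
            (3.0, 1.0, 0.75),      # c = 3K
        ],
    )
    def test_values(self, c, K, expected):
        assert monod(c, K) == pytest.approx(expected, abs=1e-15)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            monod(-1.0, 1.0)
        with pytest.raises(ValueError):
            monod(1.0, 0.0)

    @given(
        x=st.floats(0.0, 100.0),     # concentration in units of K
        dx=st.floats(0.01, 100.0),   # resolvable increment in units of K
        K=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_and_bounded(self, x, dx, K):
        r1, r2 = monod(x * K, K), monod((x + dx) * K, K)
        assert 0.0 <= r1 < 1.0
        assert r2 > r1


class TestGrowthRate:
    def test_all_zero_strategies_is_pure_death(self, two_by_two):
        params, state = two_by_two
        state.A = np.zeros_like(state.A)
        assert growth_rate(0, state, params) == pytest.approx(-0.1)

    def test_balance_point(self):
        # p=1: v*alpha*r == delta  ->  growth rate 0
        sp = SpeciesParams(death_rate=0.1, ctr=2.0)
        rs = ResourceParams(value=2.0, half_saturation=1.0, supply=1.0)
        params = CommunityParams([sp], [rs])
        # r(c=1) = 0.5, so alpha = delta / (v r) = 0.1
        state = CommunityState([10.0], [1.0], [[0.1]])
        assert growth_rate(0, state, params) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_two_resources(self):
        # v=(1,2), alpha=(1,1), r=(0.5,0.5), delta=1 -> 0.5 + 1.0 - 1 = 0.5
        sp = SpeciesParams(death_rate=1.0, ctr=10.0)
        resources = [
            ResourceParams(value=1.0, half_saturation=1.0),
            ResourceParams(value=2.0, half_saturation=1.0),
        ]
        params = CommunityParams([sp], resources)
        state = CommunityState([1.0], [1.0, 1.0], [[1.0, 1.0]])
        assert growth_rate(0, state, params) == pytest.approx(0.5)

    def test_index_error(self, two_by_two):
        params, state = two_by_two
        with pytest.raises(IndexError):
            growth_rate(5, state, params)


class TestConstraintPhi:
    @pytest.mark.parametrize(
        "row, e_star, expected",
        [
            ([4.0, 6.0], 10.0, 0.0),      # boundary
            ([0.0, 0.0], 10.0, -1.0),     # empty budget
            ([2.0, 3.0], 10.0, -0.5),     # half budget
        ],
    )
    def test_values(self, row, e_star, expected):
        assert constraint_phi(row, e_star) == pytest.approx(expected, abs=1e-15)

    def test_requires_positive_budget(self):
        with pytest.raises(ValueError):
            constraint_phi([1.0], 0.0)


class TestStrategyRhs:
    def test_zero_entries_stay_zero(self, two_by_two):
        params, state = two_by_two
        state.A[0, 1] = 0.0
        dA = strategy_rhs(state, params)
        assert dA[0, 1] == 0.0

    def test_all_zero_row_has_zero_derivative(self, two_by_two):
        params, state = two_by_two
        state.A[1] = 0.0
        dA = strategy_rhs(state, params)
        assert np.all(dA[1] == 0.0)

    def test_interior_rows_grow_while_resources_present(self, two_by_two):
        # phi well below the surface: pure gradient ascent, all derivatives >= 0
        params, state = two_by_two
        state.A *= 0.3  # rowsum far below E*
        assert all(
            constraint_phi(state.A[i], params.e_star[i]) < -THETA_WIDTH
            for i in range(params.m)
        )
        dA = strategy_rhs(state, params)
        assert np.all(dA >= 0.0)
        # and equal to A * lambda * v_i r_i exactly on that branch
        r = state.c / (params.K + state.c)
        expected = state.A * params.lam[:, None] * (params.v * r)[None, :]
        np.testing.assert_allclose(dA, expected, rtol=1e-14)

    def test_row_sum_conserved_on_constraint_surface(self, rng):
        # on the surface the projection cancels the gradient row sum exactly
        for _ in range(20):
            params, state = random_community(rng, m=4, p=3)
            state.A *= (params.e_star / state.A.sum(axis=1))[:, None]  # phi = 0
            dA = strategy_rhs(state, params)
            scale = np.abs(state.A * params.lam[:, None]).sum(axis=1) + 1e-300
            np.testing.assert_allclose(dA.sum(axis=1) / scale, 0.0, atol=1e-13)


class TestCommunityRhs:
    def test_consumer_free_resource_dynamics(self, two_by_two):
        params, state = two_by_two
        state.n = np.zeros_like(state.n)
        dn, dc, dA = community_rhs(0.0, state, params)
        np.testing.assert_allclose(dc, params.s - params.mu * state.c)
        assert np.all(dn == 0.0)

    def test_single_species_fixed_point(self):
        # m=1, p=1, mu=0: at r(c*) = delta/(v alpha), n* = v s / delta
        v, s, delta, alpha, K = 1.5, 60.0, 0.1, 0.2, 1.0
        sp = SpeciesParams(death_rate=delta, ctr=5.0, learning_rate=0.0)
        rs = ResourceParams(value=v, half_saturation=K, supply=s)
        params = CommunityParams([sp], [rs], adaptive=False)
        r_star = delta / (v * alpha)
        c_star = K * r_star / (1.0 - r_star)
        n_star = v * s / delta
        state = CommunityState([n_star], [c_star], [[alpha]])
        dn, dc, dA = community_rhs(0.0, state, params)
        assert dn[0] == pytest.approx(0.0, abs=1e-9)
        assert dc[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_strategies_give_exponential_decay(self, two_by_two):
        params, state = two_by_two
        state.A = np.zeros_like(state.A)
        dn, _, _ = community_rhs(0.0, state, params)
        np.testing.assert_allclose(dn, -params.delta * state.n)

    def test_supply_callable_is_used(self, two_by_two):
        params, state = two_by_two
        state.n = np.zeros_like(state.n)
        _, dc, _ = community_rhs(0.0, state, params, supply=lambda t: np.array([7.0, 9.0]))
        np.testing.assert_allclose(dc, np.array([7.0, 9.0]) - params.mu * state.c)

    def test_non_adaptive_strategies_frozen(self, two_by_two):
        params, state = two_by_two
        params.adaptive = False
        _, _, dA = community_rhs(0.0, state, params)
        assert np.all(dA == 0.0)


class TestValidation:
    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            ResourceParams(value=-1.0, half_saturation=1.0)
        with pytest.raises(ValueError):
            SpeciesParams(death_rate=0.0, ctr=1.0)
        with pytest.raises(ValueError):
            SpeciesParams(death_rate=0.1, ctr=1.0, learning_rate=-1.0)

    def test_state_shape_mismatch(self):
        with pytest.raises(ValueError):
            CommunityState([1.0, 2.0], [1.0], [[1.0]])

    def test_uptake_constraint_validation(self, two_by_two):
        params, state = two_by_two
        state.A[0] = params.e_star[0]  # row sum = p * E*
        with pytest.raises(ValueError):
            state.validate(params)

    def test_e_star_derived(self):
        sp = SpeciesParams(death_rate=0.2, ctr=3.0)
        assert sp.max_uptake == pytest.approx(0.6)

    def test_diauxic_budget_invariant(self):
        with pytest.raises(ValueError):
            DiauxicParams(
                v_gal=1e10, v_eth=1e10, K_gal=1e-3, K_eth=1e-3,
                delta=0.1, Q=1e-10, d=1e-9, Y=0.5,
                n0=1e5, c_gal0=5e-3, c_eth0=0.0,
                alpha_gal0=1e-11, alpha_eth0=1e-11,  # sum > Q*delta = 1e-11
            )


class TestDiauxicRhs:
    @pytest.fixture
    def params(self):
        return DiauxicParams(
            v_gal=2e10, v_eth=1.7e10, K_gal=5e-4, K_eth=1e-3,
            delta=0.01, Q=4.5e-9, d=1e-8, Y=0.5,
            n0=1.6e5, c_gal0=5e-3, c_eth0=0.0,
            alpha_gal0=2e-11, alpha_eth0=1e-12,
        )

    def test_galactose_never_replenished(self, params):
        y = np.array([1e6, 2e-3, 1e-3, 2e-11, 1e-11])
        dy = diauxic_rhs(0.0, y, params)
        assert dy[1] <= 0.0

    def test_ethanol_production_proportional_to_consumption(self, params):
        # with ethanol uptake off, dc_eth = -Y * dc_gal exactly
        y = np.array([1e6, 2e-3, 1e-3, 2e-11, 0.0])
        dy = diauxic_rhs(0.0, y, params)
        assert dy[2] == pytest.approx(-params.Y * dy[1], rel=1e-14)

    def test_zero_yield_decouples_ethanol(self, params):
        import dataclasses

        p0 = dataclasses.replace(params, Y=1e-300, alpha_eth0=1e-300, c_eth0=0.0)
        y = p0.y0()
        dy = diauxic_rhs(0.0, y, p0)
        assert dy[2] == pytest.approx(0.0, abs=1e-250)
        # density equation reduces to one-species batch growth on galactose
        r_gal = p0.c_gal0 / (p0.K_gal + p0.c_gal0)
        assert dy[0] == pytest.approx(
            p0.n0 * (p0.v_gal * p0.alpha_gal0 * r_gal - p0.delta), rel=1e-12
        )

    def test_fixed_variant_freezes_strategies(self, params):
        y = params.y0()
        dy = diauxic_rhs(0.0, y, params, adaptive=False)
        assert dy[3] == 0.0 and dy[4] == 0.0

    def test_budget_conservation_on_surface(self, params):
        # strategies summing to Q*delta: total uptake derivative cancels
        e = params.e_star
        y = np.array([1e6, 2e-3, 1e-3, 0.6 * e, 0.4 * e])
        dy = diauxic_rhs(0.0, y, params)
        assert dy[3] + dy[4] == pytest.approx(0.0, abs=1e-13 * e)


class TestNonNegativityInvariance:
    def test_derivatives_vanish_or_point_inward_at_zero(self, rng):
        """Each derivative is proportional to its own variable or non-negative
        when that variable is zero, so exact solutions stay non-negative."""
        for _ in range(30):
            params, state = random_community(rng, m=3, p=2)
            which = rng.integers(3)
            if which == 0:
                state.n[rng.integers(params.m)] = 0.0
            elif which == 1:
                state.c[rng.integers(params.p)] = 0.0
            else:
                state.A[rng.integers(params.m), rng.integers(params.p)] = 0.0
            dn, dc, dA = community_rhs(0.0, state, params)
            assert np.all(dn[state.n == 0] == 0.0)
            assert np.all(dc[state.c == 0] >= 0.0)
            assert np.all(dA[state.A == 0] == 0.0)
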