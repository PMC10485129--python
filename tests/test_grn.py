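"""Binding probabilities, steady states, stability analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatepattern.grn import (
    binding_prob_general,
    binding_probs,
    critical_signal,
    exclusion_condition,
    jacobian,
    l_max,
    rhs,
    stability_interval,
    steady_states,
)
from fatepattern.params import ModelParams, default_params

conc = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
pos_coeff = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def general_params(**kw):
    base = dict(
        r_u=1.0,
        r_v=1.0,
        gamma_u=1.0,
        gamma_v=1.0,
        eta_u=2.0,
        eta_v=3.0,
        eta_s=0.5,
        eta_vs=2.0,
        eta_uv=0.7,
        eta_us=1.3,
        eta_uvs=0.2,
    )
    base.update(kw)
    return ModelParams(**base)


def boltzmann_enumeration(u, v, s, p):
    """Independent oracle: enumerate the seven bound microstates one by one."""
    states = [
        ("u", p.eta_u * u),
        ("v", p.eta_v * v),
        ("s", p.eta_s * s),
        ("uv", p.eta_u * u * p.eta_v * v * p.eta_uv),
        ("us", p.eta_u * u * p.eta_s * s * p.eta_us),
        ("vs", p.eta_v * v * p.eta_s * s * p.eta_vs),
        ("uvs", p.eta_u * u * p.eta_v * v * p.eta_s * s * p.eta_uvs),
    ]
    z = 1.0 + sum(w for _, w in states)
    p_u = sum(w for name, w in states if "u" in name) / z
    p_v = sum(w for name, w in states if "v" in name) / z
    return p_u, p_v


class TestBindingProbabilities:
    @given(u=conc, v=conc, s=conc)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_term_enumeration_oracle(self, u, v, s):
        p = general_params()
        got = binding_prob_general(u, v, s, p)
        want = boltzmann_enumeration(u, v, s, p)
        assert got == pytest.approx(want, rel=1e-12)

    @given(u=conc, v=conc, s=conc)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_probabilities_bounded_under_blocking_inhibition(self, u, v, s):
        p = general_params(eta_uv=0.0, eta_us=0.0, eta_uvs=0.0)
        p_u, p_v = binding_prob_general(u, v, s, p)
        assert 0.0 <= p_u <= 1.0
        assert 0.0 <= p_v <= 1.0
        assert p_u + p_v <= 1.0 + 1e-12

    def test_no_interaction_factorizes_to_single_species(self):
        # with eta_uv = 1 and no signal the two-species form collapses
        p = general_params(eta_uv=1.0)
        u, v = 0.31, 0.57
        p_u, _ = binding_prob_general(u, v, 0.0, p)
        assert p_u == pytest.approx(p.eta_u * u / (1 + p.eta_u * u), rel=1e-12)

    def test_zero_concentration_gives_zero_probability(self):
        p_u, p_v = binding_prob_general(0.0, 0.4, 0.2, general_params())
        assert p_u == 0.0
        assert p_v > 0.0

    def test_specialized_form_equals_general_with_blocking(self, rng):
        p = default_params()
        u, v, s = rng.uniform(0, 0.2, (3, 50))
        got_u, got_v = binding_probs(u, v, s, p)
        want_u, want_v = binding_prob_general(u, v, s, p)
        np.testing.assert_allclose(got_u, want_u, rtol=1e-13)
        np.testing.assert_allclose(got_v, want_v, rtol=1e-13)

    def test_signal_inhibits_u_and_activates_v(self, params):
        u, v = 0.05, 0.05
        s_grid = np.linspace(0.0, 0.1, 30)
        p_u, p_v = binding_probs(u, v, s_grid, params)
        assert np.all(np.diff(p_u) < 0)
        assert np.all(np.diff(p_v) > 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            binding_prob_general(-0.1, 0.1, 0.0, general_params())


class TestRhs:
    def test_zero_state_is_fixed_point(self, params):
        du, dv = rhs(np.zeros(5), np.zeros(5), np.full(5, 0.03), params)
        assert np.all(du == 0) and np.all(dv == 0)

    def test_closed_form_u_state_has_zero_derivative(self, params):
        s = np.array([0.0, 0.01, 0.02])
        u = params.r_u / params.gamma_u - (1 + params.eta_s * s) / params.eta_u
        du, dv = rhs(u, np.zeros(3), s, params)
        np.testing.assert_allclose(du, 0.0, atol=1e-12)
        np.testing.assert_allclose(dv, 0.0, atol=1e-12)

    def test_matches_direct_formula_evaluation(self, params, rng):
        u, v, s = rng.uniform(0, 0.1, (3, 40))
        du, dv = rhs(u, v, s, params)
        p_u, p_v = binding_prob_general(u, v, s, params)
        np.testing.assert_allclose(du, params.r_u * p_u - params.gamma_u * u, rtol=1e-12)
        np.testing.assert_allclose(dv, params.r_v * p_v - params.gamma_v * v, rtol=1e-12)

    def test_shape_mismatch_rejected(self, params):
        with pytest.raises(ValueError, match="shape"):
            rhs(np.zeros(3), np.zeros(4), np.zeros(3), params)


def euler_single_cell(params, s, u0=1e-4, v0=1e-4, t_end=30.0, dt=1e-3):
    """Independent scalar integrator for one cell at constant signal."""
    u, v = u0, v0
    for _ in range(int(t_end / dt)):
        den = (
            1.0
            + params.eta_v * v * (1 + params.eta_s * params.eta_vs * s)
            + params.eta_u * u
            + params.eta_s * s
        )
        du = params.r_u * params.eta_u * u / den - params.gamma_u * u
        dv = (
            params.r_v * params.eta_v * v * (1 + params.eta_s * params.eta_vs * s) / den
            - params.gamma_v * v
        )
        u, v = u + dt * du, v + dt * dv
    return u, v


class TestCriticalSignal:
    def test_zero_numerator_gives_zero(self):
        p = general_params(eta_u=3.0, eta_v=3.0)
        assert critical_signal(p) == 0.0

    def test_direct_substitution(self):
        p = general_params(eta_u=10.0, eta_v=5.0, eta_s=1.0, eta_vs=1.0)
        assert critical_signal(p) == pytest.approx(1.0)

    @pytest.mark.parametrize("side", [-1, +1])
    def test_single_cell_fate_switches_across_critical_signal(self, params, side):
        s_star = critical_signal(params)
        u, v = euler_single_cell(params, s_star * (1 + 0.1 * side))
        if side < 0:
            assert u > 100 * v  # u+v-
        else:
            assert v > 100 * u  # u-v+


class TestSteadyStates:
    def test_u_state_at_zero_signal(self, params):
        states = steady_states(params, 0.0)
        u_plus, v_val = states.u_on
        assert u_plus == pytest.approx(params.r_u / params.gamma_u - 1 / params.eta_u)
        assert v_val == 0.0
        assert not states.degenerate

    def test_degeneracy_flag_at_critical_signal(self, params):
        assert steady_states(params, critical_signal(params)).degenerate

    def test_nonzero_states_near_production_decay_ratio(self, params):
        # well-separated regime: both one-hot levels sit within the
        # (1 + eta_s s)/eta stated corrections of r/gamma
        s = 0.05
        states = steady_states(params, s)
        corr_u = (1 + params.eta_s * s) / params.eta_u
        assert states.u_on[0] == pytest.approx(params.r_u / params.gamma_u - corr_u)
        assert params.r_u / params.gamma_u - states.u_on[0] <= corr_u + 1e-12
        assert (
            params.r_v / params.gamma_v - states.v_on[1]
            <= (1 + params.eta_s * s) / params.eta_v + 1e-12
        )

    def test_negative_closed_form_reported_absent(self):
        p = general_params(eta_u=0.5, r_u=1.0, gamma_u=1.0)  # r_u/gamma_u < 1/eta_u
        assert steady_states(p, 0.0).u_on is None


class TestStabilityInterval:
    def test_lower_endpoint_equals_minus_delta_eps_v_at_zero_signal(self):
        p = general_params(r_u=2.0, r_v=2.0, gamma_u=3.0, gamma_v=3.0)
        interval = stability_interval(p, 0.0, 0.08)
        assert interval.delta_eps_min == pytest.approx(-p.delta_eps_v)

    @given(
        eta_v=pos_coeff,
        eta_s=pos_coeff,
        eta_vs=st.floats(min_value=1.0, max_value=50.0),
        s_max=st.floats(min_value=1e-4, max_value=10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_width_identity(self, eta_v, eta_s, eta_vs, s_max):
        p = general_params(eta_v=eta_v, eta_s=eta_s, eta_vs=eta_vs)
        interval = stability_interval(p, 0.0, s_max)
        assert interval.width == pytest.approx(
            math.log(1 + eta_s * eta_vs * s_max), rel=1e-12
        )

    def test_invalid_order_rejected(self, params):
        with pytest.raises(ValueError):
            stability_interval(params, 0.2, 0.1)

    def test_default_mode_uses_signal_ceiling(self, params):
        auto = stability_interval(params)
        explicit = stability_interval(params, 0.0, params.r_u / params.gamma_u)
        assert auto == explicit


class TestExclusionCondition:
    def test_strictness(self):
        assert exclusion_condition(general_params(eta_v=2.0, gamma_v=1.0, r_v=1.0))
        assert not exclusion_condition(general_params(eta_v=1.0, gamma_v=1.0, r_v=1.0))

    def test_default_parameters_exclude_double_negative_state(self, params):
        assert exclusion_condition(params)

    def test_double_negative_attracts_when_condition_fails(self):
        p = general_params(eta_v=0.5, eta_u=0.5, gamma_v=1.0, r_v=1.0)
        u, v = euler_single_cell(p, 0.0, u0=1e-6, v0=1e-6, t_end=50.0)
        assert u < 1e-9 and v < 1e-9


class TestLMax:
    @pytest.mark.parametrize(
        "eta_u_factor, expected",
        [(1.0, 0), (1.0 + 1e-6, 0)],
    )
    def test_tiny_weight_advantage_gives_zero(self, eta_u_factor, expected):
        p = general_params(eta_v=5.0, eta_u=5.0 * eta_u_factor)
        assert l_max(p, 6) == expected

    def test_floor_of_fractional_count(self):
        # degree * (gamma_v/r_v) * (eta_u-eta_v)/(eta_v*eta_s*eta_vs) = 2.4
        p = general_params(
            gamma_v=1.0, r_v=1.0, eta_v=1.0, eta_u=1.4, eta_s=1.0, eta_vs=1.0
        )
        assert l_max(p, 6) == 2

    def test_clamped_at_zero_when_u_disadvantaged(self):
        p = general_params(eta_u=1.0, eta_v=5.0)
        assert l_max(p, 6) == 0


class TestJacobian:
    def fd_jacobian(self, u, v, weights, params, h=1e-7):
        """Central finite differences of the coupled right-hand side."""
        n = len(u)
        J = np.empty((2 * n, 2 * n))
        x0 = np.concatenate([u, v])

        def f(x):
            uu, vv = x[:n], x[n:]
            s = weights @ uu
            du, dv = rhs(uu, vv, s, params)
            return np.concatenate([du, dv])

        for j in range(2 * n):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (f(xp) - f(xm)) / (2 * h)
        return J

    def test_matches_finite_differences(self, params, small_tissue, small_kernel, rng):
        n = small_tissue[1].n
        u = rng.uniform(0.01, 0.1, n)
        v = rng.uniform(0.01, 0.1, n)
        L, _ = jacobian(u, v, small_kernel, params)
        J = self.fd_jacobian(u, v, small_kernel.weights, params)
        scale = np.abs(J).max()
        np.testing.assert_allclose(L, J, atol=1e-5 * scale)

    def test_homogeneous_v_state_unstable_above_threshold(self, params, small_kernel):
        # all cells u-v+: s = 0, instability needs eta_u above the
        # zero-signal threshold eta_v * (r_v gamma_u)/(r_u gamma_v)
        n = small_kernel.n
        threshold = (
            params.r_v
            * params.gamma_u
            / (params.r_u * params.gamma_v)
            * params.eta_v
        )
        p = ModelParams(**{**params.to_dict(), "eta_u": 2.0 * threshold})
        v_plus = p.r_v / p.gamma_v - 1.0 / p.eta_v
        _, lead = jacobian(np.zeros(n), np.full(n, v_plus), small_kernel, p)
        assert lead.real > 0

    def test_homogeneous_u_state_unstable_below_threshold(self, params, small_kernel):
        # all cells u+v-: every received signal equals the common u level;
        # instability needs eta_u below the max-signal threshold
        n = small_kernel.n
        p = params  # default eta_u sits mid-interval, below the ceiling
        u_star = (p.r_u / p.gamma_u - 1.0 / p.eta_u) / (1.0 + p.eta_s / p.eta_u)
        _, lead = jacobian(np.full(n, u_star), np.zeros(n), small_kernel, p)
        ceiling = (
            p.r_v * p.gamma_u / (p.r_u * p.gamma_v)
            * p.eta_v
            * (1.0 + p.eta_s * p.eta_vs * u_star)
        )
        assert p.eta_u < ceiling
        assert lead.real > 0

    def test_interval_endpoints_match_eigenvalue_sign_changes(self, params, small_kernel):
        # the analytic heterogeneity interval should bracket the numerical
        # stability transitions of both homogeneous states
        n = small_kernel.n
        interval = stability_interval(params)
        delta = interval.width / 100.0

        def lead_v_state(x):
            p = params.with_delta_eps_u(x)
            v_plus = p.r_v / p.gamma_v - 1.0 / p.eta_v
            return jacobian(np.zeros(n), np.full(n, v_plus), small_kernel, p)[1].real

        assert lead_v_state(interval.delta_eps_min - delta) < 0
        assert lead_v_state(interval.delta_eps_min + delta) > 0

        def lead_u_state(x):
            p = params.with_delta_eps_u(x)
            u_star = (p.r_u / p.gamma_u - 1.0 / p.eta_u) / (1.0 + p.eta_s / p.eta_u)
            return jacobian(np.full(n, u_star), np.zeros(n), small_kernel, p)[1].real

        # the upper endpoint uses the s_max ~ r_u/gamma_u approximation, so
        # allow a few interval-percent of slack there
        assert lead_u_state(interval.delta_eps_max - 3 * delta) > 0
        assert lead_u_state(interval.delta_eps_max + 3 * delta) < 0

    def test_dimension_mismatch_rejected(self, params, small_kernel):
        with pytest.raises(ValueError, match="mismatch"):
            jacobian(np.zeros(3), np.zeros(3), small_kernel, params)
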