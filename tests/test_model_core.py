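"""Unit tests for the reaction kinetics, steady state and LOF mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pax6rd.model import (
    FieldState,
    ShhField,
    homogeneous_steady_state,
    pax6_activity,
    reaction_rates,
)
from pax6rd.params import ModelParameters, ParameterError, apply_lof


def uniform_state(values, n=1):
    return FieldState.uniform(values, (n,))


class TestPax6Activity:
    @pytest.mark.parametrize(
        "P, B, beta, expected",
        [
            (1.0, 0.0, 5.0, 1.0),   # no signalling, no inhibition
            (2.0, 1.0, 1.0, 1.0),   # P/(1+beta*B) = 2/2
            (3.0, 0.5, 4.0, 1.0),   # 3/(1+2)
        ],
    )
    def test_pointwise_values(self, P, B, beta, expected):
        out = pax6_activity(np.array([P]), np.array([B]), beta)
        assert out[0] == pytest.approx(expected)

    def test_full_inhibition_limit(self):
        out = pax6_activity(np.array([1.0]), np.array([1e12]), 5.0)
        assert out[0] == pytest.approx(0.0, abs=1e-11)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            pax6_activity(np.zeros(3), np.zeros(4), 1.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ParameterError):
            pax6_activity(np.zeros(3), np.zeros(3), -0.1)

    @given(
        P=st.floats(0.0, 10.0),
        B1=st.floats(0.0, 10.0),
        dB=st.floats(0.0, 10.0),
        beta=st.floats(0.0, 10.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_B_and_P(self, P, B1, dB, beta):
        """P* is non-increasing in B and non-decreasing in P, bounded by P."""
        a1 = pax6_activity(np.array([P]), np.array([B1]), beta)[0]
        a2 = pax6_activity(np.array([P]), np.array([B1 + dB]), beta)[0]
        assert a2 <= a1 + 1e-12
        assert a1 <= P + 1e-12
        a3 = pax6_activity(np.array([P + 1.0]), np.array([B1]), beta)[0]
        assert a3 >= a1 - 1e-12


class TestReactionRates:
    def test_extinction_fixed_point(self, simple_params):
        p = simple_params.replace(sigma_P=0.0)
        state = uniform_state([0, 0, 0, 0, 0])
        rates = reaction_rates(state, p, variant="B")
        assert np.allclose(rates.stack(), 0.0)

    def test_mass_action_complex_formation(self, simple_params):
        # single point, F=T=1, C=0, k_on=2, k_off=0, everything else off
        p = simple_params.replace(
            rho_P=0, sigma_P=0, rho_F=0, rho_T=0,
            delta_P=0, delta_F=0, delta_T=0, delta_C=0,
            k_on=2.0, k_off=0.0, k_b=0.0, k_u=0.0,
        )
        state = uniform_state([0, 1.0, 1.0, 0, 0])
        rates = reaction_rates(state, p, variant="B")
        assert rates.C[0] == pytest.approx(2.0)
        assert rates.F[0] == pytest.approx(-2.0)
        assert rates.T[0] == pytest.approx(-2.0)

    def test_steady_state_has_zero_rates(self, simple_params):
        ss = homogeneous_steady_state(simple_params, variant="B")
        rates = reaction_rates(ss, simple_params, variant="B")
        assert np.abs(rates.stack()).max() < 1e-10

    def test_variant_a_freezes_pax6(self, simple_params):
        state = uniform_state([2.0, 0.3, 0.4, 0.1, 0.2])
        rates = reaction_rates(state, simple_params, variant="A")
        assert np.all(rates.P == 0.0)
        rates_b = reaction_rates(state, simple_params, variant="B")
        assert np.allclose(rates.stack()[1:], rates_b.stack()[1:])

    def test_variant_d_with_zero_shh_equals_variant_b(self, simple_params):
        state = uniform_state([1.0, 0.5, 0.5, 0.2, 0.3], n=4)
        shh = ShhField.zero((4,))
        rd = reaction_rates(state, simple_params, shh=shh, variant="D")
        rb = reaction_rates(state, simple_params, variant="B")
        assert np.array_equal(rd.stack(), rb.stack())

    def test_variant_d_requires_shh(self, simple_params):
        with pytest.raises(ValueError, match="Shh"):
            reaction_rates(uniform_state([1, 0, 0, 0, 0]), simple_params, variant="D")

    def test_unknown_variant_rejected(self, simple_params):
        with pytest.raises(ValueError, match="variant"):
            reaction_rates(uniform_state([1, 0, 0, 0, 0]), simple_params, variant="X")

    def test_shh_suppresses_pax6_production(self, simple_params):
        state = uniform_state([1.0, 0.5, 0.5, 0.2, 0.3])
        high = ShhField(S=np.array([5.0]))
        r_hi = reaction_rates(state, simple_params, shh=high, variant="D")
        r_lo = reaction_rates(state, simple_params, shh=ShhField.zero((1,)), variant="D")
        assert r_hi.P[0] < r_lo.P[0]


class TestHomogeneousSteadyState:
    def test_zero_production_gives_zero_state(self, simple_params):
        p = simple_params.replace(rho_P=0, sigma_P=0, rho_F=0, rho_T=0)
        ss = homogeneous_steady_state(p, variant="B")
        assert np.allclose(ss.stack(), 0.0)

    def test_receptor_binding_isotherm(self, simple_params):
        ss = homogeneous_steady_state(simple_params, variant="B")
        p = simple_params
        T = ss.T[0]
        expected_B = p.R_tot * p.k_b * T / (p.k_b * T + p.k_u)
        assert ss.B[0] == pytest.approx(expected_B, rel=1e-10)

    def test_pax6_positive_branch(self, simple_params):
        ss = homogeneous_steady_state(simple_params, variant="B")
        assert ss.P[0] > 0

    def test_agrees_with_damped_fixed_point_iteration(self, simple_params):
        """Independent oracle: damped pseudo-time iteration to the fixed point."""
        ss = homogeneous_steady_state(simple_params, variant="B")
        y = np.array([1.0, 0.5, 0.5, 0.1, 0.1])[:, None]
        state = FieldState.from_stack(y)
        for _ in range(200_000):
            rates = reaction_rates(state, simple_params, variant="B").stack()
            y = y + 0.02 * rates
            state = FieldState.from_stack(y)
            if np.abs(rates).max() < 1e-13:
                break
        assert np.allclose(state.stack(), ss.stack(), atol=1e-8)

    def test_fields_all_nonnegative(self, reference_params):
        ss = homogeneous_steady_state(reference_params, variant="B")
        assert np.all(ss.stack() >= 0)
        assert ss.B[0] <= reference_params.R_tot


class TestApplyLof:
    def test_tgfb_lof_zeros_beta_only(self, simple_params):
        p = apply_lof(simple_params, "tgfb_lof")
        assert p.beta == 0.0
        assert p.gamma == simple_params.gamma
        assert p.replace(beta=simple_params.beta) == simple_params

    def test_shh_lof_zeros_gamma_only(self, simple_params):
        p = apply_lof(simple_params, "shh_lof")
        assert p.gamma == 0.0
        assert p.beta == simple_params.beta

    def test_double_lof_zeros_both(self, simple_params):
        p = apply_lof(simple_params, "double_lof")
        assert p.beta == 0.0 and p.gamma == 0.0

    def test_sequential_lofs_commute_to_double(self, simple_params):
        seq = apply_lof(apply_lof(simple_params, "shh_lof"), "tgfb_lof")
        assert seq == apply_lof(simple_params, "double_lof")

    def test_unknown_tag_rejected(self, simple_params):
        with pytest.raises(ParameterError):
            apply_lof(simple_params, "wnt_lof")


class TestParameterValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            ModelParameters(
                rho_P=-1, sigma_P=0, n_hill=2, K_hill=1, rho_F=1, rho_T=1,
                delta_P=1, delta_F=1, delta_T=1, delta_C=1, k_on=1, k_off=1,
                k_b=1, k_u=1, R_tot=1, beta=1, gamma=1, D_F=0.01, D_T=0.01, D_C=1,
            )

    def test_hill_coefficient_below_one_rejected(self, simple_params):
        with pytest.raises(ParameterError):
            simple_params.replace(n_hill=0.5)

    def test_yaml_round_trip(self, tmp_path, simple_params):
        from pax6rd.params import load_parameters, save_parameters

        path = tmp_path / "p.yaml"
        save_parameters(simple_params, path)
        assert load_parameters(path) == simple_params

    def test_reference_set_has_fast_complex_diffusion(self, reference_params):
        """The key counter-intuitive assumption: complexes outrun Fst monomers."""
        assert reference_params.D_C > reference_params.D_F
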