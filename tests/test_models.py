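"""Closed-form model family: defining values, limits, and oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopk.models import (
    ArterialInput,
    DegenerateParameterizationError,
    DomainError,
    KineticParams,
    ModelVariant,
    arterial_forcing,
    auc_closed_form,
    auc_quadrature,
    eval_double_exp,
    eval_excretion,
    eval_mono_decay,
    eval_uptake_only,
    half_life,
    integrate_compartment_ode,
    ip_initial_concentration,
    macro_constant,
    time_of_peak,
)

GRID = np.linspace(0.0, 24.0, 97)


class TestCurveValues:
    def test_mono_decay_halving(self):
        assert eval_mono_decay(10, math.log(2), 0) == pytest.approx(10)
        assert eval_mono_decay(10, math.log(2), 1) == pytest.approx(5)

    def test_double_exp_starts_at_zero_and_stays_nonnegative(self):
        vals = eval_double_exp(5, 2, 0.1, GRID)
        assert vals[0] == 0.0
        assert np.all(vals >= 0)

    def test_double_exp_unimodal(self):
        vals = eval_double_exp(5, 2, 0.1, GRID[1:])
        d = np.diff(vals)
        # rises then falls: the sign pattern of differences changes once
        sign_changes = np.sum(np.diff(np.sign(d)) != 0)
        assert sign_changes == 1

    def test_uptake_asymptote(self):
        assert eval_uptake_only(10, 1, 0) == pytest.approx(0)
        assert eval_uptake_only(10, 1, 1e6) == pytest.approx(10)
        vals = eval_uptake_only(10, 1, GRID)
        assert np.all(np.diff(vals) >= 0)

    def test_excretion_matches_uptake_form(self):
        t = np.array([0.0, 6.0, 24.0])
        np.testing.assert_allclose(eval_excretion(40, 0.2, t),
                                   eval_uptake_only(40, 0.2, t))
        assert eval_excretion(40, 0.2, 1e6) == pytest.approx(40)

    def test_arterial_forcing_is_mono_decay(self):
        inp = ArterialInput(C_0=7.0, k_in=2.0)
        assert arterial_forcing(inp, 0) == pytest.approx(7.0)
        assert arterial_forcing(inp, math.log(2) / 2) == pytest.approx(3.5)
        np.testing.assert_allclose(arterial_forcing(inp, GRID),
                                   eval_mono_decay(7.0, 2.0, GRID))

    def test_ip_average_is_half_peak(self):
        assert ip_initial_concentration(10.0) == 5.0
        assert ip_initial_concentration(0.0) == 0.0
        # time-average of a linear absorption ramp r*t on [0, T] is r*T/2
        r, T = 0.7, 6.0
        tt = np.linspace(0, T, 100001)
        avg = np.trapezoid(r * tt, tt) / T
        assert avg == pytest.approx(ip_initial_concentration(r * T), rel=1e-6)


class TestDomainErrors:
    @pytest.mark.parametrize("fn,args", [
        (eval_mono_decay, (-1, 0.5, 1.0)),
        (eval_mono_decay, (1, -0.5, 1.0)),
        (eval_uptake_only, (0, 1, 1.0)),
        (eval_excretion, (120, 0.2, 1.0)),   # cannot excrete > injected dose
        (eval_excretion, (40, -0.2, 1.0)),
        (eval_double_exp, (-5, 2, 0.1, 1.0)),
    ])
    def test_invalid_parameters_rejected(self, fn, args):
        with pytest.raises(DomainError):
            fn(*args)

    def test_equal_rates_degenerate(self):
        with pytest.raises(DegenerateParameterizationError):
            eval_double_exp(5, 0.1, 0.1, 1.0)
        with pytest.raises(DegenerateParameterizationError):
            eval_double_exp(5, 0.1, 0.2, 1.0)  # wrong label order

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            eval_mono_decay(1, 1, -0.5)

    def test_negative_ip_peak_rejected(self):
        with pytest.raises(DomainError):
            ip_initial_concentration(-1.0)


class TestDerivedQuantities:
    def test_half_life_inverts_rate(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)
        assert half_life(0.08852) == pytest.approx(7.83, abs=0.005)

    def test_half_life_defining_property(self, rng):
        for _ in range(20):
            A = rng.uniform(0.1, 50)
            k = rng.uniform(0.01, 5)
            t_half = half_life(k)
            assert eval_mono_decay(A, k, t_half) == pytest.approx(A / 2,
                                                                  rel=1e-12)

    def test_time_of_peak_closed_form(self):
        assert time_of_peak(2, 1) == pytest.approx(math.log(2))

    def test_time_of_peak_zero_derivative(self, rng):
        for _ in range(20):
            k_out = rng.uniform(0.01, 1)
            k_in = k_out * rng.uniform(1.5, 50)
            t_star = time_of_peak(k_in, k_out)
            h = 1e-6
            deriv = (eval_double_exp(1.0, k_in, k_out, t_star + h)
                     - eval_double_exp(1.0, k_in, k_out, t_star - h)) / (2 * h)
            assert abs(deriv) < 1e-9

    def test_time_of_peak_shrinks_with_fast_uptake(self):
        ks = [1, 10, 100, 1000]
        peaks = [time_of_peak(k, 0.1) for k in ks]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))
        assert peaks[-1] < 0.01

    def test_macro_constant_round_trip(self):
        A = macro_constant(C_0=7.0, k_in=2.0, k_out=0.1)
        assert A == pytest.approx(2.0 * 7.0 / 1.9)
        from nanopk.models import initial_concentration_from_macro
        assert initial_concentration_from_macro(A, 2.0, 0.1) == pytest.approx(7.0)


class TestODEOracle:
    """The double exponential is the exact solution of the compartment ODE."""

    def test_closed_form_matches_integrator(self, rng):
        worst = 0.0
        for _ in range(100):
            k_out = rng.uniform(0.01, 0.3)   # half-lives ~2-70 h, the plausible range
            k_in = k_out * rng.uniform(1.5, 100.0)
            C_0 = rng.uniform(0.1, 20.0)
            A = macro_constant(C_0, k_in, k_out)
            inp = ArterialInput(C_0=C_0, k_in=k_in)
            num = integrate_compartment_ode(inp, k_out, GRID)
            closed = eval_double_exp(A, k_in, k_out, GRID)
            mask = closed > 0
            worst = max(worst, np.max(np.abs(num[mask] - closed[mask])
                                      / closed[mask]))
        assert worst < 1e-6

    def test_zero_elimination_limit_is_uptake_curve(self):
        inp = ArterialInput(C_0=1.0, k_in=1.0)
        num = integrate_compartment_ode(inp, 0.0, GRID[1:])
        closed = eval_uptake_only(1.0, 1.0, GRID[1:])
        np.testing.assert_allclose(num, closed, rtol=1e-6)

    def test_uptake_is_small_kout_limit_of_double_exp(self):
        t = np.linspace(0.1, 24, 40)
        lim = eval_double_exp(10.0, 0.5, 1e-9, t)
        np.testing.assert_allclose(lim, eval_uptake_only(10.0, 0.5, t),
                                   rtol=1e-6)


class TestAUC:
    def test_unit_rate_mono_decay(self):
        p = KineticParams(A=1.0, k_out=1.0)
        assert auc_closed_form(ModelVariant.MONO_DECAY, p, 24) == \
            pytest.approx(1 - math.exp(-24), rel=1e-12)

    @pytest.mark.parametrize("variant,params", [
        (ModelVariant.MONO_DECAY, KineticParams(A=8.6, k_out=0.0885)),
        (ModelVariant.DOUBLE_EXP, KineticParams(A=5, k_in=2, k_out=0.1)),
        (ModelVariant.UPTAKE_ONLY, KineticParams(A=3, k_in=0.4)),
        (ModelVariant.EXCRETION, KineticParams(U_t=40, k_u=0.2)),
    ])
    def test_closed_form_matches_quadrature(self, variant, params):
        analytic = auc_closed_form(variant, params, 24)
        numeric = auc_quadrature(variant, params, 24)
        assert analytic == pytest.approx(numeric, rel=1e-8)

    def test_instant_saturation_limit(self):
        p = KineticParams(A=3.0, k_in=1e6)
        assert auc_closed_form(ModelVariant.UPTAKE_ONLY, p, 24) == \
            pytest.approx(72.0, rel=1e-4)

    def test_double_exp_limit_chain_to_uptake(self):
        eps = 1e-8
        de = auc_closed_form(ModelVariant.DOUBLE_EXP,
                             KineticParams(A=5, k_in=0.5, k_out=eps), 24)
        up = auc_closed_form(ModelVariant.UPTAKE_ONLY,
                             KineticParams(A=5, k_in=0.5), 24)
        assert de == pytest.approx(up, rel=1e-5)

    @pytest.mark.parametrize("variant,params", [
        (ModelVariant.MONO_DECAY, KineticParams(A=8.6, k_out=0.0885)),
        (ModelVariant.DOUBLE_EXP, KineticParams(A=5, k_in=2, k_out=0.1)),
        (ModelVariant.UPTAKE_ONLY, KineticParams(A=3, k_in=0.4)),
        (ModelVariant.EXCRETION, KineticParams(U_t=40, k_u=0.2)),
    ])
    def test_auc_additivity_over_subintervals(self, variant, params):
        full = auc_closed_form(variant, params, T=24.0)
        parts = (auc_closed_form(variant, params, T=12.0)
                 + auc_closed_form(variant, params, T=24.0, t0=12.0))
        assert full == pytest.approx(parts, rel=1e-10)

    def test_wrong_variant_params_pairing(self):
        from nanopk.models import ContractError
        with pytest.raises(ContractError):
            auc_closed_form(ModelVariant.MONO_DECAY, KineticParams(U_t=40), 24)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    A=st.floats(0.1, 50),
    k_out=st.floats(0.01, 1.0),
    ratio=st.floats(1.5, 50),
    c=st.floats(0.1, 10),
)
def test_unit_coherence_under_time_rescaling(A, k_out, ratio, c):
    """Rescaling time by c and rates by 1/c preserves curve values and
    multiplies AUC by c."""
    k_in = k_out * ratio
    t = np.linspace(0.1, 24, 7)
    base = eval_double_exp(A, k_in, k_out, t)
    rescaled = eval_double_exp(A, k_in / c, k_out / c, t * c)
    np.testing.assert_allclose(base, rescaled, rtol=1e-12)
    auc1 = auc_closed_form(ModelVariant.DOUBLE_EXP,
                           KineticParams(A=A, k_in=k_in, k_out=k_out), T=24.0)
    auc2 = auc_closed_form(ModelVariant.DOUBLE_EXP,
                           KineticParams(A=A, k_in=k_in / c, k_out=k_out / c),
                           T=24.0 * c)
    assert auc2 == pytest.approx(auc1 * c, rel=1e-10)
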