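"""Unit and property tests for the Hill terms, estrogen laws, and RHS."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import osteomeno as om
from osteomeno.model import (
    STATE_VARS,
    EstrogenModel,
    estrogen_kinetics_from_physiology,
    estrogen_level,
    eta_t,
    hill_activation,
    hill_inhibition,
    omega_t,
    rhs,
)

positive = st.floats(1e-6, 1e8, allow_nan=False, allow_infinity=False)
nonneg = st.floats(0.0, 1e8, allow_nan=False, allow_infinity=False)


class TestHill:
    @pytest.mark.parametrize(
        "fn,X,k,expected",
        [
            (hill_activation, 3.7, 3.7, 0.5),
            (hill_activation, 0.0, 5.0, 0.0),
            (hill_activation, 1.12e4, 8.6e6, 1.12e4 / (1.12e4 + 8.6e6)),
            (hill_inhibition, 0.0, 0.42, 1.0),
            (hill_inhibition, 1.0, 0.2556, 0.2556 / 1.2556),
        ],
    )
    def test_values(self, fn, X, k, expected):
        assert fn(X, k) == pytest.approx(expected, rel=1e-12)

    def test_half_saturation_magnitudes(self):
        # the scaled sclerostin level is far below its osteoclast threshold
        assert hill_activation(1.12e4, 8.6e6) == pytest.approx(1.301e-3, rel=1e-3)
        assert hill_inhibition(1.0, 0.2556) == pytest.approx(0.20357, rel=1e-4)

    @pytest.mark.parametrize("fn", [hill_activation, hill_inhibition])
    def test_domain_errors(self, fn):
        with pytest.raises(om.DomainError):
            fn(1.0, 0.0)
        with pytest.raises(om.DomainError):
            fn(-0.5, 1.0)

    @given(X=nonneg, k=positive)
    def test_activation_inhibition_sum_to_one(self, X, k):
        assert hill_activation(X, k) + hill_inhibition(X, k) == pytest.approx(1.0)

    @given(X=nonneg, k=positive)
    def test_ranges(self, X, k):
        assert 0.0 <= hill_activation(X, k) < 1.0
        assert 0.0 < hill_inhibition(X, k) <= 1.0


class TestEstrogen:
    def test_natural_boundary_and_half_decline(self, p):
        e = EstrogenModel.natural(p.t_m, p.tau_E)
        assert estrogen_level(e, p.t_m - 1000.0) == 1.0
        assert estrogen_level(e, p.t_m) == 1.0
        assert estrogen_level(e, p.t_m + p.tau_E) == pytest.approx(0.5)

    def test_natural_strictly_decreasing_post_onset(self, p):
        e = EstrogenModel.natural(p.t_m, p.tau_E)
        ts = p.t_m + np.linspace(1.0, 30 * 365.0, 200)
        vals = [estrogen_level(e, t) for t in ts]
        assert np.all(np.diff(vals) < 0)
        assert all(0 < v <= 1 for v in vals)

    def test_surgical_boundary_plateau_and_monotone(self, p, s_short):
        e = EstrogenModel.surgical(p.t_m, s_short.kappa_E, s_short.k_syn)
        assert estrogen_level(e, p.t_m) == 1.0
        plateau = s_short.k_syn / s_short.kappa_E
        # kappa_E * 30 days >> 1: level at 30 days is numerically the plateau
        assert estrogen_level(e, p.t_m + 30.0) == pytest.approx(plateau, abs=1e-6)
        ts = p.t_m + np.linspace(0.01, 100.0, 300)
        vals = np.array([estrogen_level(e, t) for t in ts])
        assert np.all(np.diff(vals) <= 0)
        assert np.all(vals >= plateau - 1e-12)

    def test_constant_variant(self):
        e = EstrogenModel.constant(0.3)
        assert estrogen_level(e, -1e5) == 0.3
        assert estrogen_level(e, 1e5) == 0.3

    def test_kinetics_from_physiology(self):
        kappa, k_syn, plateau = estrogen_kinetics_from_physiology(161.0, 156.0, 15.0)
        assert kappa == pytest.approx(math.log(2) * 24 * 60 / 161, rel=1e-12)
        assert plateau == pytest.approx(15.0 / 156.0, rel=1e-12)
        assert k_syn == pytest.approx(kappa * plateau, rel=1e-12)
        # halving the concentration gives a plateau of exactly one half
        assert estrogen_kinetics_from_physiology(100.0, 2.0, 1.0)[2] == 0.5

    def test_kinetics_rejects_non_decline(self):
        with pytest.raises(om.DomainError):
            estrogen_kinetics_from_physiology(161.0, 15.0, 156.0)


class TestTimeDependentRates:
    def test_baseline_values(self, p, s_short):
        assert omega_t(0.0, p, s_short) == pytest.approx(0.93)
        assert eta_t(0.0, p, s_short) == pytest.approx(1.1e-4)
        # at exactly t_m the pre-menopause branch applies
        assert omega_t(p.t_m, p, s_short) == pytest.approx(p.omega_PC)

    def test_no_effect_limits(self, p, s_short):
        zero = s_short.replace(eta_surg=0.0, omega_surg=0.0)
        for t in (0.0, p.t_m, p.t_m + 100.0, p.t_m + 1e4):
            assert omega_t(t, p, zero) == p.omega_PC
            assert omega_t(t, p, None) == p.omega_PC
            assert eta_t(t, p, zero) == p.eta_S

    def test_jump_and_relaxation(self, p, s_short):
        peak = omega_t(p.t_m, p, s_short, post_branch_at_onset=True)
        assert peak == pytest.approx(p.omega_PC * (1 + s_short.omega_surg))
        assert peak == pytest.approx(0.93 * 2.86, rel=1e-10)
        # a six-fold apoptosis peak for a fold-increase of 5
        s5 = s_short.replace(eta_surg=5.0)
        assert eta_t(p.t_m, p, s5, post_branch_at_onset=True) == pytest.approx(
            6 * p.eta_S
        )
        # relaxes monotonically back toward baseline, staying within bounds
        ts = p.t_m + np.linspace(0.1, 3000.0, 500)
        vals = np.array([omega_t(t, p, s_short) for t in ts])
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals <= p.omega_PC * (1 + s_short.omega_surg) + 1e-12)
        assert np.all(vals >= p.omega_PC - 1e-12)

    def test_permanent_effect_when_tau_zero(self, p, s_long):
        assert s_long.tau == 0.0
        v0 = eta_t(p.t_m + 1.0, p, s_long)
        v1 = eta_t(p.t_m + 1e5, p, s_long)
        assert v0 == v1 == pytest.approx(p.eta_S * (1 + s_long.eta_surg))


class TestRHS:
    def test_zero_cell_state_has_basal_production_only(self, p, e_nat):
        y = np.zeros(7)
        d = rhs(0.0, y, p, None, e_nat)
        assert d[STATE_VARS.index("PB")] == pytest.approx(1.0)
        assert d[STATE_VARS.index("PC")] == pytest.approx(1.0)

    def test_surgical_with_zero_folds_matches_natural_structure(self, p, s_short):
        e = EstrogenModel.constant(0.5)
        zero = s_short.replace(eta_surg=0.0, omega_surg=0.0)
        y = om.premenopausal_steady_state(p, E=0.7, cross_check=False).state.as_array()
        for t in (0.0, p.t_m + 5.0, p.t_m + 5000.0):
            np.testing.assert_allclose(
                rhs(t, y, p, None, e), rhs(t, y, p, zero, e), rtol=0, atol=0
            )

    def test_derivatives_vanish_at_equilibrium(self, p):
        st_eq = om.premenopausal_steady_state(p).state.as_array()
        d = rhs(0.0, st_eq, p, None, EstrogenModel.constant(1.0))
        # the six cell/signal equations balance; density has a constant drift
        scales = np.maximum(np.abs(st_eq), 1.0)
        assert np.max(np.abs(d[:6]) / scales[:6]) < 1e-12

    @given(idx=st.integers(0, 5))
    def test_nonnegativity_preserved_at_zero_components(self, idx):
        # with any single cell/signal component at zero, its derivative >= 0
        p = om.natural_defaults()
        e = EstrogenModel.constant(0.8)
        y = om.premenopausal_steady_state(p, E=0.8, cross_check=False).state.as_array()
        y[idx] = 0.0
        d = rhs(0.0, y, p, None, e)
        assert d[idx] >= 0.0
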