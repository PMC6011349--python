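"""Rate functions and right-hand sides of the delayed system."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemodelay import (
    ModelParameters,
    SystemState,
    cytokine_decay,
    cytokine_rate,
    deprivation_loss_rate,
    reentry_rate,
    rhs,
)

BASELINE_N_STAR = 3347.2584564029557
BASELINE_P_STAR = 775.0873941264084


class TestReentryRate:
    @pytest.mark.parametrize(
        "N, expected",
        [
            (0.0, 16.0),                       # beta(0) = beta0
            (650.0, 8.0),                      # half-maximum at N = theta
            (BASELINE_N_STAR, 0.1163117744997401),  # 16*650^3/(650^3+N*^3)
        ],
    )
    def test_values(self, table_params, N, expected):
        assert reentry_rate(N, table_params) == pytest.approx(expected, rel=1e-12)

    def test_negative_population_rejected(self, table_params):
        with pytest.raises(ValueError):
            reentry_rate(-1.0, table_params)

    @given(st.floats(min_value=0.0, max_value=1e8),
           st.floats(min_value=1.0, max_value=1e8))
    @settings(deadline=None)
    def test_strictly_decreasing_and_bounded(self, N, dN):
        p = ModelParameters()
        lo, hi = reentry_rate(N + dN, p), reentry_rate(N, p)
        assert lo < hi <= p.beta0
        assert lo > 0.0


class TestCytokineDecay:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (50.0, 1.0),                       # before decay onset
            (100.0, 1.0),                      # continuity at t = tau1
            (169.31471805599455, 0.5),         # one half-life past onset
        ],
    )
    def test_values(self, table_params, t, expected):
        assert cytokine_decay(t, table_params) == pytest.approx(expected, rel=1e-12)

    def test_continuous_at_onset(self, table_params):
        eps = 1e-10
        below = cytokine_decay(table_params.tau1 - eps, table_params)
        above = cytokine_decay(table_params.tau1 + eps, table_params)
        assert abs(below - above) < 1e-9

    @given(st.floats(min_value=0.0, max_value=1e4),
           st.floats(min_value=0.0, max_value=1e4))
    @settings(deadline=None)
    def test_non_increasing(self, t, dt):
        p = ModelParameters()
        assert cytokine_decay(t + dt, p) <= cytokine_decay(t, p) + 1e-15


class TestCytokineRate:
    def test_zero_when_switched_off(self, table_params):
        assert table_params.beta0c == 0.0
        for P, t in [(0.0, 0.0), (450.0, 50.0), (1e6, 500.0)]:
            assert cytokine_rate(P, t, table_params) == 0.0

    def test_half_maximum(self):
        p = ModelParameters(beta0c=0.022)
        assert cytokine_rate(450.0, 50.0, p) == pytest.approx(0.011, rel=1e-12)

    def test_vanishes_at_large_population(self):
        p = ModelParameters(beta0c=0.022)
        assert cytokine_rate(1e9, 50.0, p) < 1e-12

    def test_negative_population_rejected(self):
        p = ModelParameters(beta0c=0.022)
        with pytest.raises(ValueError):
            cytokine_rate(-5.0, 0.0, p)

    def test_decreasing_in_P(self):
        p = ModelParameters(beta0c=0.022)
        vals = [cytokine_rate(P, 10.0, p) for P in (0.0, 100.0, 450.0, 2000.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestDeprivationLoss:
    def test_zero_at_baseline(self, table_params):
        assert deprivation_loss_rate(1234.5, table_params) == 0.0

    def test_frozen_rate(self):
        p = ModelParameters(rbar=0.07, deterministic_r=True, r_frozen=1.0)
        assert deprivation_loss_rate(1000.0, p) == pytest.approx(70.0)

    def test_stochastic_bounded_by_width(self):
        p = ModelParameters(rbar=0.07, deterministic_r=False,
                            r_noise_width=0.0005)
        bound = p.rbar * p.r_noise_width * 1000.0
        for k in range(101):
            draw = p.r_noise_width * k / 100
            assert 0.0 <= deprivation_loss_rate(1000.0, p, draw) <= bound + 1e-18

    def test_draw_outside_interval_rejected(self):
        p = ModelParameters(rbar=0.07, deterministic_r=False,
                            r_noise_width=0.0005)
        with pytest.raises(ValueError):
            deprivation_loss_rate(1000.0, p, 0.001)
        with pytest.raises(ValueError):
            deprivation_loss_rate(1000.0, p, -0.1)


class TestRhs:
    def _states(self, P, N, t, tau, A=0.0):
        return (SystemState(t=t, P=P, N=N, A=A),
                SystemState(t=t - tau, P=P, N=N, A=A))

    def test_fixed_point_annihilates_P_and_N(self, table_params):
        s, sd = self._states(BASELINE_P_STAR, BASELINE_N_STAR, 10.0,
                             table_params.tau)
        dP, dN, dA = rhs(s, sd, 10.0, table_params)
        assert abs(dP) < 1e-8 * BASELINE_P_STAR
        assert abs(dN) < 1e-8 * BASELINE_N_STAR
        assert dA == pytest.approx(table_params.gamma * BASELINE_P_STAR,
                                   rel=1e-10)

    def test_trivial_fixed_point(self, table_params):
        s, sd = self._states(0.0, 0.0, 5.0, table_params.tau)
        assert rhs(s, sd, 5.0, table_params) == (0.0, 0.0, 0.0)

    def test_apoptosis_rate_without_deprivation(self, table_params):
        s, sd = self._states(1000.0, 5000.0, 5.0, table_params.tau)
        _, _, dA = rhs(s, sd, 5.0, table_params)
        assert dA == pytest.approx(100.0)  # gamma * P with gamma = 0.1

    def test_mismatched_delay_time_rejected(self, table_params):
        s = SystemState(t=5.0, P=10.0, N=10.0, A=0.0)
        bad = SystemState(t=4.0, P=10.0, N=10.0, A=0.0)  # != t - tau
        with pytest.raises(ValueError):
            rhs(s, bad, 5.0, table_params)

    def test_cytokine_term_is_pure_transfer_at_constant_state(self):
        """On a time-constant trajectory the cytokine loss in dN/dt equals
        the gain in dP/dt, so switching the cytokine on moves flux between
        compartments without creating or destroying cells."""
        base = ModelParameters()
        cyt = ModelParameters(beta0c=0.022)
        s = SystemState(t=10.0, P=800.0, N=4000.0, A=0.0)
        sd = SystemState(t=10.0 - base.tau, P=800.0, N=4000.0, A=0.0)
        d0 = rhs(s, sd, 10.0, base)
        d1 = rhs(s, sd, 10.0, cyt)
        gain_P = d1[0] - d0[0]
        loss_N = d0[1] - d1[1]
        assert gain_P > 0
        assert gain_P == pytest.approx(loss_N, rel=1e-12)

    @given(st.floats(min_value=0.0, max_value=1e6),
           st.floats(min_value=0.0, max_value=1e6))
    @settings(deadline=None)
    def test_apoptosis_derivative_non_negative(self, P, N):
        p = ModelParameters(rbar=0.07)
        s = SystemState(t=5.0, P=P, N=N, A=0.0)
        sd = SystemState(t=5.0 - p.tau, P=P, N=N, A=0.0)
        assert rhs(s, sd, 5.0, p)[2] >= 0.0


class TestParameterValidation:
    @pytest.mark.parametrize("bad", [
        {"gamma": 0.0}, {"gamma": -0.1}, {"tau": 0.0}, {"theta": -1.0},
        {"beta0": 0.0}, {"delta": -0.01}, {"n": 0}, {"m": -2}, {"n": 1.5},
        {"rbar": -0.07}, {"r_noise_width": -1.0},
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)

    def test_unknown_override_rejected(self, table_params):
        with pytest.raises(ValueError):
            table_params.with_overrides(gamme=0.2)

    def test_effective_deprivation_rate(self):
        frozen = ModelParameters(rbar=0.07, deterministic_r=True, r_frozen=1.0)
        noisy = ModelParameters(rbar=0.07, deterministic_r=False,
                                r_noise_width=1.0)
        assert frozen.effective_deprivation_rate == pytest.approx(0.07)
        assert noisy.effective_deprivation_rate == pytest.approx(0.035)
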