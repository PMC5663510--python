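"""Rate functions: closed-form examples, switch continuity, mass balance."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulsecr.model_core import (
    Parameters,
    SeasonState,
    clipped_production,
    field_jacobian,
    maturation_rate,
    maturation_rate_derivative,
    net_production,
    resource_turnover,
    stage_mortality,
    within_season_derivatives,
)


def P(theta=1.0, mu=8.0, **kw):
    return Parameters(theta=theta, mu=mu, **kw)


class TestParameters:
    def test_defaults_are_standard_parameterisation(self):
        p = P()
        assert (p.rho, p.Kr, p.Imax, p.Q, p.sigma, p.z) == (10.0, 2.0, 100.0, 10.0, 0.5, 0.1)

    @pytest.mark.parametrize(
        "bad",
        [dict(theta=0.0), dict(mu=-1.0), dict(sigma=0.0), dict(sigma=1.5),
         dict(z=0.0), dict(z=1.0), dict(rho=-10.0), dict(Kr=0.0)],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            P(**bad)

    def test_starvation_threshold(self):
        assert P().starvation_threshold == pytest.approx(0.2)


class TestSeasonState:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            SeasonState(1.0, -0.1, 0.0, 0.0)
        with pytest.raises(ValueError):
            SeasonState(float("nan"), 0.0, 0.0, 0.0)

    def test_from_array_clips_roundoff(self):
        s = SeasonState.from_array([1.0, -1e-13, 0.2, 0.0], clip_negative_tol=1e-10)
        assert s.J == 0.0
        with pytest.raises(ValueError):
            SeasonState.from_array([1.0, -1e-6, 0.2, 0.0], clip_negative_tol=1e-10)


class TestResourceTurnover:
    @pytest.mark.parametrize(
        "R, expected",
        [(2.0, 0.0),      # semi-chemostat equilibrium at Kr
         (0.0, 20.0),     # rho * Kr
         (1.0, 10.0)],    # rho * (Kr - R)
    )
    def test_values(self, R, expected):
        assert resource_turnover(R, P()) == pytest.approx(expected)

    def test_negative_resource_rejected(self):
        with pytest.raises(ValueError):
            resource_turnover(-0.1, P())


class TestNetProduction:
    @pytest.mark.parametrize(
        "R, theta, stage, expected",
        [(0.2, 1.0, "juvenile", 0.0),    # starvation threshold Q/(sigma Imax)
         (2.0, 1.0, "adult", 90.0),      # sigma*theta*Imax*R - Q
         (0.0, 1.0, "juvenile", -10.0),  # -Q
         (0.0, 1.0, "adult", -10.0),
         (2.0, 2.0, "adult", 190.0)],
    )
    def test_values(self, R, theta, stage, expected):
        assert net_production(R, P(theta=theta), stage) == pytest.approx(expected)

    def test_clipping(self):
        assert clipped_production(90.0) == 90.0
        assert clipped_production(-10.0) == 0.0
        assert clipped_production(0.0) == 0.0


class TestMaturationRate:
    def test_zero_when_starving(self):
        assert maturation_rate(-5.0, 3.0, 0.1) == 0.0
        assert maturation_rate(0.0, 3.0, 0.1) == 0.0

    def test_singular_limit_value(self):
        # at nu_j == mu the removable singularity evaluates to -nu_j/ln(z)
        assert maturation_rate(8.0, 8.0, 0.1) == pytest.approx(-8.0 / math.log(0.1))

    def test_generic_value_against_direct_formula(self):
        # plain textbook evaluation away from the singularity
        nu, mu, z = 90.0, 8.0, 0.1
        direct = (nu - mu) / (1.0 - z ** (1.0 - mu / nu))
        assert maturation_rate(nu, mu, z) == pytest.approx(direct, rel=1e-12)
        assert direct == pytest.approx(93.4699, abs=5e-4)

    def test_continuous_across_singularity(self):
        # fine grid bracketing nu_j = mu: steps never exceed the smooth
        # Lipschitz bound, so the branch switch introduces no jump
        mu, z = 8.0, 0.1
        nus = np.linspace(mu - 1e-4, mu + 1e-4, 2001)
        vals = np.array([maturation_rate(nu, mu, z) for nu in nus])
        step = nus[1] - nus[0]
        slope = max(abs(maturation_rate_derivative(nu, mu, z)) for nu in nus)
        assert np.max(np.abs(np.diff(vals))) < 2.0 * slope * step + 1e-8
        # branch values agree at the singular-guard boundary to ~1e-8 relative
        limit = -mu / math.log(z)
        for nu in (mu * (1 - 2e-8), mu * (1 + 2e-8)):
            assert maturation_rate(nu, mu, z) == pytest.approx(limit, rel=1e-7)

    def test_continuous_at_zero_onset(self):
        # gamma -> 0 as nu_j -> 0+ and is exactly 0 below
        mu, z = 8.0, 0.1
        nus = np.linspace(1e-12, 1e-4, 200)
        vals = np.array([maturation_rate(nu, mu, z) for nu in nus])
        assert vals[0] < 1e-12
        assert np.all(vals >= 0.0)
        assert np.max(np.abs(np.diff(vals))) < 1e-8

    @given(st.floats(0.01, 500.0), st.floats(0.0, 50.0))
    def test_nonnegative_and_finite(self, nu, mu):
        g = maturation_rate(nu, mu, 0.1)
        assert g >= 0.0 and math.isfinite(g)

    def test_monotone_increasing_in_nu(self):
        mu, z = 8.0, 0.1
        nus = np.linspace(0.01, 200.0, 4000)
        vals = np.array([maturation_rate(nu, mu, z) for nu in nus])
        assert np.all(np.diff(vals) > 0.0)

    def test_derivative_matches_finite_difference(self):
        mu, z = 8.0, 0.1
        for nu in (0.5, 3.0, 7.9, 8.0, 8.1, 50.0, 90.0):
            h = 1e-6 * max(nu, 1.0)
            fd = (maturation_rate(nu + h, mu, z) - maturation_rate(nu - h, mu, z)) / (2 * h)
            assert maturation_rate_derivative(nu, mu, z) == pytest.approx(fd, rel=1e-4)

    def test_invalid_z_rejected(self):
        with pytest.raises(ValueError):
            maturation_rate(5.0, 1.0, 1.5)


class TestStageMortality:
    def test_background_only_above_threshold(self):
        p = P(mu=3.0)
        assert stage_mortality(2.0, p, "juvenile") == pytest.approx(3.0)
        # exactly at the threshold nu = 0: no starvation surcharge
        assert stage_mortality(0.2, p, "juvenile") == pytest.approx(3.0)

    def test_starvation_surcharge(self):
        # at R = 0 the surcharge is the full maintenance rate Q
        p = P(mu=8.0)
        assert stage_mortality(0.0, p, "juvenile") == pytest.approx(18.0)

    @given(st.floats(0.0, 3.0), st.floats(0.0, 20.0))
    def test_never_below_background(self, R, mu):
        p = P(mu=mu)
        assert stage_mortality(R, p, "juvenile") >= mu
        assert stage_mortality(R, p, "adult") >= mu


class TestDerivativeField:
    def test_resource_only_equilibrium(self):
        d = within_season_derivatives(SeasonState(2.0, 0.0, 0.0, 0.0), P())
        assert np.allclose(d, 0.0)

    def test_no_feeding_collapses_to_exponential_decay(self):
        # Imax = 0: nu_j = -Q < 0, so gamma = 0 and dJ/dt = -(Q + mu) J
        p = Parameters(theta=1.0, mu=8.0, Imax=1e-300)  # Imax must be positive
        d = within_season_derivatives(SeasonState(1.0, 0.5, 0.0, 0.0), p)
        assert d[1] == pytest.approx(-(p.Q + p.mu) * 0.5, rel=1e-12)

    def test_composed_example(self):
        # dJ = (nu_j+ - gamma - mu) J at R=2, theta=1, mu=8
        p = P(theta=1.0, mu=8.0)
        d = within_season_derivatives(SeasonState(2.0, 1.0, 0.0, 0.0), p)
        gam = maturation_rate(90.0, 8.0, 0.1)
        assert d[1] == pytest.approx(90.0 - gam - 8.0, rel=1e-12)

    def test_averaging_accumulators_mirror_state(self):
        s = SeasonState(1.0, 0.3, 0.2, 0.1)
        d = within_season_derivatives(s, P())
        assert tuple(d[4:]) == (s.J, s.A, s.B)

    @given(st.floats(0.0, 0.19), st.floats(0.01, 1.0), st.floats(0.0, 30.0))
    def test_starvation_mass_balance(self, R, J, mu):
        # below the juvenile threshold: dJ/dt = (nu_j - mu) J exactly,
        # i.e. clipping + starvation surcharge restore the unclipped balance
        p = P(mu=mu)
        nu_j = net_production(R, p, "juvenile")
        assert nu_j <= 0.0
        d = within_season_derivatives(SeasonState(R, J, 0.0, 0.0), p)
        assert d[1] == pytest.approx((nu_j - mu) * J, rel=1e-12, abs=1e-12)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            SeasonState(1.0, float("inf"), 0.0, 0.0)

    def test_field_jacobian_matches_finite_difference(self):
        p = P(theta=2.0, mu=5.0)
        y = np.array([1.3, 0.4, 0.1, 0.05])
        jac = field_jacobian(y, p)
        from pulsecr.model_core import make_rhs

        rhs = make_rhs(p, averages=False)
        fd = np.zeros((4, 4))
        for j in range(4):
            h = 1e-7 * (1 + abs(y[j]))
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] -= h
            fd[:, j] = (np.array(rhs(0, yp)) - np.array(rhs(0, ym))) / (2 * h)
        assert np.allclose(jac, fd, rtol=1e-5, atol=1e-6)
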