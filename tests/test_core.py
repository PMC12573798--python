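"""Closed-form signal model against an independent ODE integration, plus the
algebraic conversions between amplitudes, relaxation times and transport
coefficients."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from tdfrs.core import (
    ContrastFactors,
    GratingGeometry,
    SignalParams,
    TimescaleSeparationWarning,
    TransportCoefficients,
    amplitude_to_soret,
    grating_modes_on,
    heterodyne_intensity,
    heterodyne_intensity_off,
    relaxation_to_diffusivity,
    soret_steady_state_gradient,
    soret_to_amplitude,
    thermal_diffusion_coefficient,
)


def _params(tau_th=1e-3, tau=0.1, a0=0.5):
    return SignalParams(tau_th=tau_th, tau=tau, a0=a0)


def _ode_zeta_on(t, tau_th, tau, a0):
    """Independent oracle: integrate the driven two-mode system."""
    sol = solve_ivp(
        lambda _, y: [(1 - y[0]) / tau_th, (y[0] - y[1]) / tau],
        [0.0, float(np.max(t)) or 1.0],
        [0.0, 0.0],
        t_eval=np.atleast_1d(t),
        rtol=1e-11,
        atol=1e-13,
    )
    return sol.y[0] - a0 * sol.y[1]


def _ode_zeta_off(t, tau_th, tau, a0, theta0=1.0, g0=1.0):
    sol = solve_ivp(
        lambda _, y: [-y[0] / tau_th, (y[0] - y[1]) / tau],
        [0.0, float(np.max(t)) or 1.0],
        [theta0, g0],
        t_eval=np.atleast_1d(t),
        rtol=1e-11,
        atol=1e-13,
    )
    return sol.y[0] - a0 * sol.y[1]


class TestHeterodyneIntensity:
    def test_zero_at_t0(self):
        assert heterodyne_intensity(0.0, _params()) == 0.0

    def test_steady_state_is_one_minus_a0(self):
        p = _params(tau_th=1e-3, tau=0.1, a0=0.5)
        assert heterodyne_intensity(100 * p.tau, p) == pytest.approx(0.5, abs=1e-6)

    def test_matches_ode_oracle_single_point(self):
        p = _params(tau_th=1e-3, tau=0.1, a0=0.8)
        expected = _ode_zeta_on(0.05, p.tau_th, p.tau, p.a0)[0]
        assert heterodyne_intensity(0.05, p) == pytest.approx(expected, abs=1e-6)

    def test_ode_oracle_equivalence_random_params(self):
        """Closed form vs high-accuracy integration over 20 random draws
        with tau/tau_th spanning [10, 1e4]."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            tau_th = 10 ** rng.uniform(-4, -2)
            ratio = 10 ** rng.uniform(1, 4)
            a0 = rng.uniform(-1, 1)
            p = SignalParams(tau_th=tau_th, tau=tau_th * ratio, a0=a0)
            t = np.linspace(0.0, 3 * p.tau, 1000)
            closed = heterodyne_intensity(t, p)
            oracle = _ode_zeta_on(t, p.tau_th, p.tau, p.a0)
            assert np.max(np.abs(closed - oracle)) < 1e-6

    def test_early_time_slope_is_inverse_tau_th(self):
        """For t << tau_th the signal grows as t/tau_th."""
        p = _params(tau=1.0, a0=0.1)
        t = p.tau_th / 100
        h = t / 100
        slope = (heterodyne_intensity(t + h, p) - heterodyne_intensity(t - h, p)) / (2 * h)
        assert slope == pytest.approx(1 / p.tau_th, rel=0.01)

    def test_equal_timescale_branch_continuous(self):
        """The analytic tau -> tau_th limit joins the generic branch."""
        tau_th = 1e-3
        t = np.linspace(0, 10 * tau_th, 200)
        with pytest.warns(TimescaleSeparationWarning):
            limit = heterodyne_intensity(t, SignalParams(tau_th, tau_th, 0.7))
            near = heterodyne_intensity(t, SignalParams(tau_th, tau_th * (1 + 1e-10), 0.7))
        assert np.max(np.abs(limit - near)) < 1e-8

    @pytest.mark.parametrize("a0", [-1.0, -0.3, 0.0, 0.5, 1.0])
    def test_bounded_between_initial_and_steady_levels(self, a0):
        p = _params(a0=a0)
        t = np.linspace(0, 10 * p.tau, 2000)
        z = heterodyne_intensity(t, p)
        lo = min(0.0, 1.0 - a0) - 1e-9
        hi = max(1.0, 1.0 - a0) + 1e-9
        assert np.all(z >= lo) and np.all(z <= hi)

    def test_rejects_negative_or_nonfinite_time(self):
        with pytest.raises(ValueError):
            heterodyne_intensity(-1.0, _params())
        with pytest.raises(ValueError):
            heterodyne_intensity(np.nan, _params())


class TestHeterodyneIntensityOff:
    def test_initial_value_is_theta0_minus_a0_g0(self):
        assert heterodyne_intensity_off(0.0, _params(a0=0.5), (1.0, 1.0)) == 0.5

    def test_decays_to_zero(self):
        p = _params()
        assert heterodyne_intensity_off(100 * p.tau, p) == pytest.approx(0.0, abs=1e-9)

    def test_matches_ode_oracle(self):
        p = _params(tau_th=1e-3, tau=0.1, a0=0.8)
        expected = _ode_zeta_off(0.05, p.tau_th, p.tau, p.a0)[0]
        assert heterodyne_intensity_off(0.05, p) == pytest.approx(expected, abs=1e-6)

    def test_matches_ode_oracle_partial_state(self):
        p = _params(tau_th=2e-3, tau=0.5, a0=-0.4)
        theta0, g0 = 0.8, 0.3
        t = np.linspace(0, 1.0, 500)
        closed = heterodyne_intensity_off(t, p, (theta0, g0))
        oracle = _ode_zeta_off(t, p.tau_th, p.tau, p.a0, theta0, g0)
        assert np.max(np.abs(closed - oracle)) < 1e-6

    def test_rejects_invalid_theta0(self):
        with pytest.raises(ValueError):
            heterodyne_intensity_off(0.1, _params(), (1.5, 1.0))


class TestAmplitudeSoretConversion:
    CONTRAST = ContrastFactors(dn_dT=-1.0e-4, dn_dc=0.15)

    def test_zero_amplitude_gives_zero_soret(self):
        assert amplitude_to_soret(0.0, self.CONTRAST, 0.007) == 0.0

    def test_sign_convention(self):
        """Negative A0 with negative dn/dT and positive dn/dc means the
        solute is thermophobic (positive S_T)."""
        s_t = amplitude_to_soret(-0.01, self.CONTRAST, 0.007)
        assert s_t > 0
        # direct hand evaluation of the inverted amplitude relation
        assert s_t == pytest.approx(-0.01 * -1.0e-4 / (0.15 * 0.007 * 0.993), rel=1e-12)

    @given(
        a0=st.floats(-1.5, 1.5),
        c=st.floats(1e-4, 0.5),
        dn_dt=st.floats(-5e-4, -1e-5),
        dn_dc=st.floats(0.05, 0.3),
    )
    def test_round_trip(self, a0, c, dn_dt, dn_dc):
        contrast = ContrastFactors(dn_dT=dn_dt, dn_dc=dn_dc)
        s_t = amplitude_to_soret(a0, contrast, c)
        assert soret_to_amplitude(s_t, contrast, c) == pytest.approx(a0, abs=1e-12, rel=1e-12)

    def test_division_domain_error(self):
        with pytest.raises(ZeroDivisionError):
            amplitude_to_soret(0.1, self.CONTRAST, 0.0)


class TestRelaxationDiffusivity:
    @pytest.mark.parametrize(
        "tau_x, q, expected", [(1.0, 1e6, 1e-12), (1e-3, 1e6, 1e-9)]
    )
    def test_examples(self, tau_x, q, expected):
        geom = GratingGeometry(q=q)
        assert relaxation_to_diffusivity(tau_x, geom) == pytest.approx(expected, rel=1e-12)

    def test_inverse_property(self):
        geom = GratingGeometry(q=3.7e5)
        for d in (1e-10, 1e-9, 1.45e-7):
            tau = 1.0 / (d * geom.q**2)
            assert relaxation_to_diffusivity(tau, geom) == pytest.approx(d, rel=1e-12)

    def test_fringe_spacing_equivalence(self):
        by_q = GratingGeometry(q=2 * np.pi / 20e-6)
        by_fs = GratingGeometry(fringe_spacing=20e-6)
        assert by_q.q == pytest.approx(by_fs.q, rel=1e-15)

    def test_exactly_one_geometry_input(self):
        with pytest.raises(ValueError):
            GratingGeometry()
        with pytest.raises(ValueError):
            GratingGeometry(q=1e6, fringe_spacing=1e-5)


class TestSteadyStateAndTransport:
    def test_gradient_zero_cases(self):
        assert soret_steady_state_gradient(0.0, 0.007, 1e4) == 0.0
        assert soret_steady_state_gradient(0.01, 0.007, 0.0) == 0.0

    def test_gradient_value_and_direction(self):
        """Positive S_T drives the solute toward the cold side."""
        grad_c = soret_steady_state_gradient(0.01, 0.007, 1e4)
        assert grad_c == pytest.approx(-0.01 * 0.007 * 0.993 * 1e4, rel=1e-12)
        assert grad_c < 0

    def test_thermal_diffusion_coefficient(self):
        assert thermal_diffusion_coefficient(0.0, 1e-10) == 0.0
        assert thermal_diffusion_coefficient(0.02, 1e-10) == pytest.approx(2e-12, rel=1e-12)
        d_t = thermal_diffusion_coefficient(0.037, 2.2e-10)
        assert d_t / 2.2e-10 == pytest.approx(0.037, rel=1e-12)

    def test_transport_consistency_enforced(self):
        TransportCoefficients.from_soret(d=1e-10, d_th=1.4e-7, s_t=0.02)
        with pytest.raises(ValueError):
            TransportCoefficients(d=1e-10, d_th=1.4e-7, d_t=3e-12, s_t=0.02)


class TestSignalParamsValidation:
    def test_positive_times_required(self):
        with pytest.raises(ValueError):
            SignalParams(tau_th=-1e-3, tau=0.1, a0=0.5)
        with pytest.raises(ValueError):
            SignalParams(tau_th=1e-3, tau=0.0, a0=0.5)

    def test_poor_separation_warns_but_constructs(self):
        with pytest.warns(TimescaleSeparationWarning):
            p = SignalParams(tau_th=1e-3, tau=5e-3, a0=0.5)
        assert p.tau == 5e-3

    def test_modes_start_at_rest(self):
        theta, g = grating_modes_on(0.0, 1e-3, 0.1)
        assert theta == 0.0 and g == 0.0
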