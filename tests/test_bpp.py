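"""Forward BPP model: correlation times, rates, T1, and the T1 minimum."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bppfit import (
    Motion,
    RelaxationModel,
    SpectrometerConfig,
    correlation_time,
    motion_rate,
    t1,
    t1_minimum,
    total_rate,
)
from bppfit.bpp import OMEGA_TAU_AT_MINIMUM


class TestCorrelationTime:
    def test_zero_activation_energy_gives_tau0(self, config):
        m = Motion(tau0=4.45e-12, ea=0.0, dm2=0.1)
        assert correlation_time(m, 100.0, config) == pytest.approx(4.45e-12)

    @pytest.mark.parametrize(
        "tau0, ea, temp, expected",
        [
            # high-precision direct evaluations of the Arrhenius law
            (4.45e-12, 12.77, 300.0, 7.443395704e-10),
            (2.12e-14, 19.55, 194.0, 3.891210210e-9),
        ],
    )
    def test_arrhenius_values(self, config, tau0, ea, temp, expected):
        m = Motion(tau0=tau0, ea=ea, dm2=0.1)
        assert correlation_time(m, temp, config) == pytest.approx(expected, rel=1e-8)

    def test_rejects_non_positive_temperature(self, config):
        m = Motion(tau0=1e-12, ea=10.0, dm2=0.1)
        with pytest.raises(ValueError, match="-5"):
            correlation_time(m, -5.0, config)
        with pytest.raises(ValueError, match="temperature"):
            correlation_time(m, 0.0, config)

    @given(
        ea=st.floats(1.0, 20.0),
        t_lo=st.floats(80.0, 280.0),
        dt=st.floats(1.0, 100.0),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_strictly_decreasing_in_temperature(self, ea, t_lo, dt):
        # parameter box chosen to stay below the slow-motion cap, where the
        # monotonicity is strict
        m = Motion(tau0=1e-13, ea=ea, dm2=0.1)
        cfg = SpectrometerConfig()
        assert correlation_time(m, t_lo, cfg) > correlation_time(m, t_lo + dt, cfg)

    def test_overflow_capped(self, config):
        m = Motion(tau0=1e-10, ea=60.0, dm2=0.1)
        # Ea/(R T) huge at 1 K: would overflow without the log-space cap
        assert correlation_time(m, 1.0, config) == pytest.approx(1.0e3, rel=1e-12)


class TestMotionRate:
    def test_zero_second_moment_gives_zero_rate(self, config):
        m = Motion(tau0=1e-12, ea=15.0, dm2=0.0)
        assert motion_rate(m, 200.0, config) == 0.0

    def test_rate_near_t1_minimum(self, config):
        # independent high-precision evaluation at omega0*tau ~ 0.612
        m = Motion(tau0=2.12e-14, ea=19.55, dm2=0.110)
        assert motion_rate(m, 194.0, config) == pytest.approx(0.476167524, rel=1e-6)

    def test_extreme_narrowing_limit(self, config):
        m = Motion(tau0=1e-13, ea=5.0, dm2=0.05)
        temp = 500.0
        tau = correlation_time(m, temp, config)
        assert config.omega0 * tau < 1e-3
        expected = (10.0 / 3.0) * config.gamma**2 * m.dm2 * tau
        assert motion_rate(m, temp, config) == pytest.approx(expected, rel=1e-5)

    @given(
        log_tau0=st.floats(-15.0, -10.0),
        ea=st.floats(0.0, 40.0),
        dm2=st.floats(0.0, 1.0),
        temp=st.floats(10.0, 1000.0),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_rate_is_non_negative(self, log_tau0, ea, dm2, temp):
        m = Motion(tau0=10.0**log_tau0, ea=ea, dm2=dm2)
        assert motion_rate(m, temp, SpectrometerConfig()) >= 0.0


class TestTotalRateAndT1:
    def test_two_identical_motions_double_the_rate(self, config):
        m = Motion(tau0=1e-13, ea=15.0, dm2=0.05)
        single = RelaxationModel((m,), config)
        double = RelaxationModel((m, m), config)
        assert total_rate(double, 150.0) == pytest.approx(
            2.0 * total_rate(single, 150.0), rel=1e-14
        )

    def test_additivity_of_contributions(self, mag0):
        # total rate equals the sum over motions at 1e-12 relative
        for temp in np.linspace(80.0, 300.0, 12):
            parts = sum(motion_rate(m, temp, mag0.config) for m in mag0.motions)
            assert total_rate(mag0, temp) == pytest.approx(parts, rel=1e-12)

    def test_three_motion_t1_matches_brute_force_sum(self, mag0):
        # independent re-summation of the rate expression, term by term
        temp = 194.0
        gamma2 = mag0.config.gamma**2
        w0 = mag0.config.omega0
        acc = 0.0
        for m in mag0.motions:
            tau = m.tau0 * math.exp(m.ea * 1e3 / (mag0.config.gas_constant * temp))
            acc += (2.0 / 3.0) * gamma2 * m.dm2 * (
                tau / (1 + (w0 * tau) ** 2) + 4 * tau / (1 + 4 * (w0 * tau) ** 2)
            )
        assert t1(mag0, temp) == pytest.approx(1.0 / acc, rel=1e-9)

    def test_empty_model_rejected(self, config):
        model = RelaxationModel((), config)
        with pytest.raises(ValueError, match="no motions"):
            total_rate(model, 100.0)

    def test_t1_positive(self, mag0):
        temps = np.geomspace(5.0, 2000.0, 40)
        assert np.all(np.asarray(t1(mag0, temps)) > 0)

    def test_asymptotic_log_slopes(self, config):
        # d ln(T1) / d(1/T) -> -Ea/R (extreme narrowing) and +Ea/R (slow
        # motion), checked by finite differences on the asymptotic branches
        m = Motion(tau0=1e-13, ea=20.0, dm2=0.1)
        model = RelaxationModel((m,), config)
        ea_over_r = m.ea * 1e3 / config.gas_constant

        def slope(t_a, t_b):
            la, lb = math.log(t1(model, t_a)), math.log(t1(model, t_b))
            return (lb - la) / (1.0 / t_b - 1.0 / t_a)

        assert slope(1400.0, 1500.0) == pytest.approx(-ea_over_r, rel=0.01)
        assert slope(80.0, 82.0) == pytest.approx(ea_over_r, rel=0.01)

    def test_frequency_dependence_of_limits(self):
        m = Motion(tau0=1e-13, ea=20.0, dm2=0.1)
        low = RelaxationModel((m,), SpectrometerConfig(frequency=25.0))
        high = RelaxationModel((m,), SpectrometerConfig(frequency=50.0))
        # slow motion: T1 scales as omega0^2
        assert t1(high, 80.0) / t1(low, 80.0) == pytest.approx(4.0, rel=1e-3)
        # extreme narrowing: frequency-independent
        assert t1(high, 1500.0) == pytest.approx(t1(low, 1500.0), rel=1e-3)


class TestT1Minimum:
    @pytest.mark.parametrize(
        "tau0, ea, dm2, t_expected",
        [
            (2.12e-14, 19.55, 0.110, 193.9),  # grid + bisection oracle
            (9.99e-11, 8.40, 0.024, 275.3),
        ],
    )
    def test_minimum_temperature(self, config, tau0, ea, dm2, t_expected):
        res = t1_minimum(Motion(tau0=tau0, ea=ea, dm2=dm2), config)
        assert res.in_range
        assert res.temperature == pytest.approx(t_expected, abs=0.5)

    def test_omega_tau_condition_vs_dense_scan(self, config):
        # oracle: dense numeric scan of T1 over temperature
        m = Motion(tau0=5e-13, ea=15.0, dm2=0.08)
        model = RelaxationModel((m,), config)
        temps = np.linspace(50.0, 500.0, 200_001)
        vals = np.asarray(t1(model, temps))
        t_scan = temps[np.argmin(vals)]
        res = t1_minimum(m, config)
        assert res.temperature == pytest.approx(t_scan, abs=0.01)
        tau_at_min = correlation_time(m, res.temperature, config)
        assert config.omega0 * tau_at_min == pytest.approx(
            OMEGA_TAU_AT_MINIMUM, abs=1e-3
        )

    def test_doubling_frequency_raises_t_min(self):
        m = Motion(tau0=2.12e-14, ea=19.55, dm2=0.110)
        t25 = t1_minimum(m, SpectrometerConfig(frequency=25.0)).temperature
        t50 = t1_minimum(m, SpectrometerConfig(frequency=50.0)).temperature
        assert t50 > t25

    def test_unreachable_minimum_flagged_not_raised(self, config):
        # tau0 already slower than the optimal correlation time
        res = t1_minimum(Motion(tau0=1e-6, ea=10.0, dm2=0.1), config)
        assert not res.in_range

    def test_requires_activated_weighted_motion(self, config):
        with pytest.raises(ValueError):
            t1_minimum(Motion(tau0=1e-12, ea=0.0, dm2=0.1), config)
        with pytest.raises(ValueError):
            t1_minimum(Motion(tau0=1e-12, ea=10.0, dm2=0.0), config)


class TestTypes:
    def test_motion_invariants(self):
        with pytest.raises(ValueError):
            Motion(tau0=0.0, ea=1.0, dm2=0.1)
        with pytest.raises(ValueError):
            Motion(tau0=1e-12, ea=-1.0, dm2=0.1)
        with pytest.raises(ValueError):
            Motion(tau0=1e-12, ea=1.0, dm2=-0.1)

    def test_omega0_derived_and_checked(self):
        cfg = SpectrometerConfig(frequency=25.0)
        assert cfg.omega0 == pytest.approx(2 * math.pi * 25e6, rel=1e-12)
        with pytest.raises(ValueError, match="inconsistent"):
            SpectrometerConfig(frequency=25.0, omega0=1.0)
        with pytest.raises(ValueError):
            SpectrometerConfig(frequency=-1.0)
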