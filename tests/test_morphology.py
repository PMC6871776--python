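import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadrugait.morphology import (
    GaitTask,
    Morphology,
    dimensionless_inertia,
    froude_speed,
    malinois_stride_length,
    mass_fractions_from_grf,
    pendular_duty_factor,
    scale_force_rate,
    time_constant,
)


class TestDimensionlessInertia:
    @pytest.mark.parametrize(
        "mF, expected",
        [(0.63, 0.9324), (0.5, 1.0), (0.61, 0.9516)],
    )
    def test_values(self, mF, expected):
        assert dimensionless_inertia(mF) == pytest.approx(expected, abs=1e-12)

    def test_malinois_rounds_to_reported_value(self):
        assert round(dimensionless_inertia(0.63), 2) == 0.93

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, mF):
        a = dimensionless_inertia(mF)
        assert a == pytest.approx(dimensionless_inertia(1.0 - mF))
        assert 0.0 < a <= 1.0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            dimensionless_inertia(bad)


class TestFroudeSpeed:
    def test_identity_at_characteristic_speed(self):
        lH, g = 0.7, 9.81
        assert froude_speed(math.sqrt(g * lH), lH, g) == pytest.approx(1.0)

    def test_dalmatian_table_values_invert(self):
        # U'_H = 0.39 with lHmax = 0.89 * 0.61 m corresponds to U ~ 0.900 m/s
        lH = 0.89 * 0.61
        U = 0.39 * math.sqrt(9.81 * lH)
        assert U == pytest.approx(0.900, abs=5e-4)
        assert froude_speed(0.900, lH) == pytest.approx(0.39, abs=1e-3)

    def test_zero_speed(self):
        assert froude_speed(0.0, 0.5) == 0.0

    def test_linear_in_speed(self):
        assert froude_speed(2.0, 0.5) == pytest.approx(2 * froude_speed(1.0, 0.5))

    def test_bad_leg_length(self):
        with pytest.raises(ValueError):
            froude_speed(1.0, 0.0)


class TestTimeConstant:
    def test_identity(self):
        lB, g = 0.6, 9.81
        assert time_constant(math.sqrt(lB / g), lB, g) == pytest.approx(1.0)

    def test_dalmatian_case(self):
        # T = D/U = (1.21*0.61)/0.900 s gives T_hat ~ 3.29
        T = (1.21 * 0.61) / 0.900
        assert time_constant(T, 0.61) == pytest.approx(3.29, abs=0.01)

    def test_linearity(self):
        assert time_constant(0.8, 0.6) == pytest.approx(2 * time_constant(0.4, 0.6))


class TestForceRateScaling:
    def test_identity_at_reference(self):
        assert scale_force_rate(3e-3, 3.3, 3.3) == pytest.approx(3e-3)

    def test_inverse_proportionality(self):
        assert scale_force_rate(3e-3, 3.3, 6.6) == pytest.approx(1.5e-3)

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            scale_force_rate(3e-3, -1.0, 3.3)


class TestMassFractionsFromGrf:
    def test_equal_loads_split_evenly(self):
        assert mass_fractions_from_grf(10.0, 10.0, m=20.0) == pytest.approx((0.5, 0.5))

    def test_constant_grf_recovers_fractions(self):
        # single-limb stride means 0.315 mg and 0.185 mg give (0.63, 0.37)
        m, g = 25.0, 9.81
        mF, mH = mass_fractions_from_grf(0.315 * m * g, 0.185 * m * g, m, g)
        assert (mF, mH) == pytest.approx((0.63, 0.37))

    @given(st.floats(0.05, 0.95))
    @settings(max_examples=30, deadline=None)
    def test_round_trip(self, frac):
        m, g = 30.0, 9.81
        mF, mH = mass_fractions_from_grf(frac * m * g / 2, (1 - frac) * m * g / 2, m, g)
        assert mF == pytest.approx(frac, abs=1e-12)
        assert mF + mH == pytest.approx(1.0)

    def test_zero_hind_force_is_degenerate(self):
        with pytest.raises(ValueError):
            mass_fractions_from_grf(100.0, 0.0, m=20.0)


class TestPendularDutyFactor:
    @pytest.mark.parametrize(
        "Tn, T, expected", [(0.82, 0.82, 0.5), (1.64, 0.82, 0.0), (0.6, 0.82, 0.634)]
    )
    def test_values(self, Tn, T, expected):
        assert pendular_duty_factor(Tn, T) == pytest.approx(expected, abs=1e-3)

    def test_excessive_pendulum_period(self):
        with pytest.raises(ValueError):
            pendular_duty_factor(2.0, 0.9)


class TestStrideLengthRegression:
    @pytest.mark.parametrize(
        "U, D", [(0.0, 1.04), (1.0, 2.40), (2.8, 4.848)]
    )
    def test_regression_line(self, U, D):
        assert malinois_stride_length(U) == pytest.approx(D)


class TestMorphology:
    def test_derived_quantities(self, dalmatian):
        assert dalmatian.mH_prime == pytest.approx(0.39)
        assert dalmatian.I_prime == pytest.approx(0.61 * 0.39)
        assert dalmatian.I_hat == pytest.approx(4 * 0.61 * 0.39)
        assert dalmatian.lHmax == pytest.approx(0.89 * 0.61)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mF_prime": 1.2}, {"mF_prime": 0.0}, {"lB": -1.0},
            {"lHmax_prime": 2.5}, {"g": 0.0},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        base = dict(mF_prime=0.6, lB=0.5, lHmax_prime=0.9, lFmax_prime=0.8)
        base.update(kwargs)
        with pytest.raises(ValueError):
            Morphology(**base)


class TestGaitTask:
    def test_from_speed_reproduces_dalmatian_numbers(self, dalmatian):
        task = GaitTask.from_speed(dalmatian, U_H_prime=0.39, D_prime=1.21)
        assert task.D_prime == pytest.approx(1.21)
        assert task.T == pytest.approx(task.D / task.U)
        assert task.T_hat == pytest.approx(3.29, abs=0.01)
        # reference case: the rate coefficient stays at its calibrated value
        assert task.c1_prime == pytest.approx(3e-3, rel=1e-6)
        assert task.U_H_prime(dalmatian) == pytest.approx(0.39)

    def test_stride_regression_used_when_D_omitted(self, malinois):
        task = GaitTask.from_speed(malinois, U_H_prime=0.5)
        assert task.D_prime == pytest.approx(1.04 + 1.36 * 0.5)

    def test_c1_scales_inversely_with_time_constant(self, malinois):
        slow = GaitTask.from_speed(malinois, U_H_prime=0.3)
        fast = GaitTask.from_speed(malinois, U_H_prime=1.0)
        assert slow.T_hat > fast.T_hat
        assert slow.c1_prime < fast.c1_prime
        assert slow.c1_prime * slow.T_hat == pytest.approx(
            fast.c1_prime * fast.T_hat)
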