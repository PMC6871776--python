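import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadrugait import gait
from quadrugait.fixtures import (
    make_gait_fixture,
    make_pronk_fixture,
    make_trot_fixture,
    make_walk_fixture,
)
from quadrugait.morphology import GaitTask, Morphology


class TestContactIntervals:
    def test_no_force_no_contact(self):
        t = np.linspace(0, 1, 101)
        assert gait.contact_intervals(t, np.zeros_like(t)) == []

    def test_square_pulse(self):
        t = np.linspace(0, 1, 1001)
        f = np.where((t >= 0.1) & (t <= 0.7), 1.0, 0.0)
        (on, off), = gait.contact_intervals(t, f)
        assert on == pytest.approx(0.1, abs=2e-3)
        assert off == pytest.approx(0.7, abs=2e-3)

    def test_wrapping_contact_merges_across_stride_end(self):
        # stance alive at both stride ends is one wrapped interval
        t = np.linspace(0, 1, 1001)
        f = np.where((t <= 0.2) | (t >= 0.9), 1.0, 0.0)
        (on, off), = gait.contact_intervals(t, f)
        assert on == pytest.approx(0.9, abs=2e-3)
        assert off == pytest.approx(0.2, abs=2e-3)
        assert gait.duty_factor([(on, off)]) == pytest.approx(0.3, abs=5e-3)

    def test_full_stride_contact(self):
        t = np.linspace(0, 1, 101)
        assert gait.contact_intervals(t, np.ones_like(t)) == [(0.0, 1.0)]
        assert gait.duty_factor([(0.0, 1.0)]) == 1.0

    def test_two_disjoint_intervals(self):
        assert gait.duty_factor([(0.1, 0.35), (0.5, 0.75)]) == pytest.approx(0.5)


class TestPhaseLags:
    def test_pronk(self):
        lags = gait.phase_lags({limb: 0.2 for limb in gait.LIMBS})
        assert lags == pytest.approx((0.0, 0.0, 0.0))

    def test_perfect_trot(self):
        td = {"LH": 0.0, "RF": 0.0, "RH": 0.5, "LF": 0.5}
        assert gait.phase_lags(td) == pytest.approx((0.5, 0.5, 0.5))

    def test_missing_limb_flagged(self):
        with pytest.raises(ValueError):
            gait.phase_lags({"LH": 0.0, "RH": 0.5, "LF": None, "RF": 0.2})

    @given(st.floats(0, 0.99), st.floats(0, 0.99))
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_time_origin(self, shift, pl):
        td = {"LH": 0.1, "RH": 0.6, "LF": (0.1 + pl) % 1, "RF": (0.6 + pl) % 1}
        shifted = {k: (v + shift) % 1 for k, v in td.items()}
        a = np.array(gait.phase_lags(td))
        b = np.array(gait.phase_lags(shifted))
        assert np.allclose(np.minimum(np.abs(a - b), 1 - np.abs(a - b)), 0,
                           atol=1e-9)


class TestCanonicalization:
    def test_diagonal_walk_becomes_lateral(self):
        # diagonal-sequence walk PL=0.75 maps to lateral-sequence PL=0.25
        (HL, PL, FL), swapped = gait.canonicalize_lags(0.5, 0.75, 0.5)
        assert swapped
        assert PL == pytest.approx(0.25)
        assert HL == pytest.approx(0.5) and FL == pytest.approx(0.5)

    def test_lateral_walk_unchanged(self):
        (_, PL, _), swapped = gait.canonicalize_lags(0.5, 0.25, 0.5)
        assert not swapped and PL == pytest.approx(0.25)

    def test_normal_form_is_stable(self):
        lags, _ = gait.canonicalize_lags(0.5, 0.8, 0.5)
        again, swapped = gait.canonicalize_lags(*lags)
        assert not swapped
        assert again == pytest.approx(lags)


class TestHildebrandClassification:
    @pytest.mark.parametrize(
        "PL, label",
        [
            (0.25, "walk, singlefoot"),
            (0.15, "walk, lateral couplets"),
            (0.35, "walk, diagonal couplets"),
            (0.5, "trot"),
            (0.03, "pace"),
        ],
    )
    def test_bins(self, PL, label):
        assert gait.classify_hildebrand(PL, 0.5, 0.5) == label

    def test_asymmetric_gait_detected(self):
        assert gait.classify_hildebrand(0.25, 0.3, 0.5) == "asymmetric"


class TestApparentStiffness:
    def test_recovers_linear_law(self, rng):
        # F = -k (l - l0) / lmax exactly, starting from stance onset at l0
        lmax, k, l0 = 0.9, 25.0, 0.88
        l = l0 - 0.04 * np.sin(np.linspace(0, np.pi, 200))
        F = -k * (l - l0) / lmax + 1e-2
        est = gait.apparent_stiffness(F, l, lmax)
        assert est == pytest.approx(k, rel=1e-6)

    def test_zero_force_undefined(self):
        l = np.linspace(0.8, 0.9, 50)
        assert gait.apparent_stiffness(np.zeros(50), l, 0.9) is None

    def test_hook_shaped_curve_recovers_linear_region(self):
        # linear region near resting plus a saturating tail farther away
        lmax, k = 0.9, 30.0
        l0 = 0.89
        dl = np.concatenate([np.linspace(0, -0.04, 120),
                             np.linspace(-0.04, -0.18, 120)])
        l = l0 + dl
        F = np.where(-dl <= 0.05 * lmax, -k * dl / lmax,
                     -k * 0.05 * lmax / lmax + 5.0 * (-dl - 0.05 * lmax))
        est = gait.apparent_stiffness(F, l, lmax)
        assert est == pytest.approx(k, rel=0.05)


class TestTransitionSpeed:
    def test_label_sweep(self):
        sweep = {0.5: "walk, singlefoot", 0.6: "walk, singlefoot",
                 0.7: "trot", 0.8: "trot"}
        assert gait.transition_speed(sweep) == pytest.approx(0.7)

    def test_all_walk_returns_none(self):
        assert gait.transition_speed({0.4: "walk, singlefoot",
                                      0.5: "walk, lateral couplets"}) is None

    def test_frequency_crossing(self):
        assert gait.transition_speed({0.7: 0.8, 0.8: 0.45}) == pytest.approx(0.8)


class TestFixtureRoundTrips:
    """Analyzer outputs on synthetic strides match their construction."""

    @pytest.mark.parametrize("DF", [0.3, 0.4, 0.6])
    def test_trot_duty_factor_and_lags(self, DF):
        traj = make_trot_fixture(DF=DF, n_samples=2001)
        s = gait.summarize(traj)
        for limb in gait.LIMBS:
            # the contact threshold trims a sliver off each stance end
            assert s.duty_factors[limb] == pytest.approx(DF, abs=0.015)
        assert s.HL == pytest.approx(0.5, abs=5e-3)
        assert s.FL == pytest.approx(0.5, abs=5e-3)
        assert s.hildebrand == "trot"

    @pytest.mark.parametrize("PL", [0.2, 0.25, 0.3])
    def test_walk_pair_lag(self, PL):
        traj = make_walk_fixture(PL=PL, n_samples=2001)
        s = gait.summarize(traj)
        assert s.PL == pytest.approx(PL, abs=5e-3)
        assert s.hildebrand == "walk, singlefoot"
        assert s.symmetric

    def test_pronk_lags(self):
        traj = make_pronk_fixture(n_samples=2001)
        td = {limb: gait._touchdown(
            gait.contact_intervals(traj.t, traj.limb_force(limb)))
            for limb in gait.LIMBS}
        lags = np.array(gait.phase_lags(td))
        circ = np.minimum(lags, 1.0 - lags)  # lags live on the circle
        assert circ == pytest.approx((0, 0, 0), abs=5e-3)

    def test_diagonal_walk_fixture_canonicalizes(self):
        morph = Morphology(0.6, 0.55, 0.9, 0.8)
        touchdowns = {"LH": 0.05, "RH": 0.55, "LF": 0.80, "RF": 0.30}
        traj = make_gait_fixture(touchdowns, 0.6, morph, 1.2, n_samples=2001)
        s = gait.summarize(traj)
        assert s.forelimbs_swapped
        assert s.PL == pytest.approx(0.25, abs=5e-3)

    def test_summary_includes_costs_when_task_given(self):
        morph = Morphology(0.61, 0.61, 0.89, 0.79)
        task = GaitTask.from_speed(morph, U_H_prime=0.39, D_prime=1.21)
        traj = make_walk_fixture(morph=morph, D_prime=1.21)
        s = gait.summarize(traj, task)
        assert s.CoT is not None and s.CoT > 0
        assert 0 <= s.rate_fraction <= 1
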