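"""Microtrichia load sharing and the elastica stiffness bound."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from blephagrip.microstiff import (
    LoadSharing,
    MicrotrichiumBeam,
    complete_elliptic_k,
    critical_modulus,
    critical_modulus_numeric,
    elastica_side_contact,
    elliptic_amplitude,
    incomplete_elliptic_f,
    microtrichia_count,
    per_tip_force,
    round_to_thousand,
    second_moment,
    stiffness_scan,
)


class TestLoadSharing:
    def test_count_from_area_and_density(self):
        assert microtrichia_count(49_000.0, 0.7) == pytest.approx(34_300.0)
        assert round_to_thousand(34_300.0) == 34_000

    def test_zero_density_degenerate(self):
        assert microtrichia_count(100.0, 0.0) == 0.0

    def test_small_example(self):
        assert microtrichia_count(100.0, 0.5) == pytest.approx(50.0)

    def test_per_tip_force_measured_inputs(self):
        f = per_tip_force(11.6e-3, 6, 34_300.0)
        assert f == pytest.approx(56.4e-9, rel=1e-3)

    def test_single_tip_carries_everything(self):
        assert per_tip_force(0.01, 1, 1.0) == pytest.approx(0.01)

    def test_hand_evaluated(self):
        assert per_tip_force(12e-3, 6, 2000.0) == pytest.approx(1e-6)

    def test_dataclass_chains_the_defaults(self):
        ls = LoadSharing()
        assert ls.microtrichia_count == pytest.approx(34_300.0)
        assert ls.per_tip_force == pytest.approx(56e-9, rel=0.01)


class TestSecondMoment:
    def test_measured_diameter(self):
        assert second_moment(0.56e-6) == pytest.approx(4.83e-27, rel=1e-3)

    def test_fourth_power_scaling(self):
        assert second_moment(2 * 0.56e-6) == pytest.approx(
            16 * second_moment(0.56e-6)
        )

    def test_two_metre_rod(self):
        assert second_moment(2.0) == pytest.approx(math.pi / 4)


class TestEllipticIntegrals:
    def test_zero_amplitude(self):
        assert incomplete_elliptic_f(0.0, 0.5) == 0.0

    def test_circular_limit(self):
        assert incomplete_elliptic_f(1.0, 0.0) == pytest.approx(1.0)

    def test_complete_value_against_quadrature(self):
        # independent adaptive-quadrature oracle for K(m=0.5)
        oracle, _ = quad(lambda t: 1 / math.sqrt(1 - 0.5 * math.sin(t) ** 2),
                         0, math.pi / 2, epsrel=1e-12)
        assert complete_elliptic_k(0.5) == pytest.approx(oracle, rel=1e-10)
        assert complete_elliptic_k(0.5) == pytest.approx(1.85407, abs=1e-5)

    @pytest.mark.parametrize("phi", [0.3, 0.7, 1.2])
    def test_incomplete_against_quadrature(self, phi):
        oracle, _ = quad(lambda t: 1 / math.sqrt(1 - 0.5 * math.sin(t) ** 2),
                         0, phi, epsrel=1e-12)
        assert incomplete_elliptic_f(phi, 0.5) == pytest.approx(oracle, rel=1e-10)

    def test_invalid_parameter_rejected(self):
        with pytest.raises(ValueError):
            incomplete_elliptic_f(0.5, 1.0)


class TestCriticalModulus:
    def test_default_beam_bound(self):
        # measured geometry and load at the resting angle
        e = critical_modulus(MicrotrichiumBeam())
        assert e / 1e9 == pytest.approx(0.325, abs=0.001)

    def test_linear_in_force(self):
        b = MicrotrichiumBeam()
        assert critical_modulus(replace(b, tip_force=2 * b.tip_force)) == (
            pytest.approx(2 * critical_modulus(b))
        )

    def test_quadratic_in_length_and_inverse_quartic_in_diameter(self):
        b = MicrotrichiumBeam()
        assert critical_modulus(replace(b, length=2 * b.length)) == pytest.approx(
            4 * critical_modulus(b)
        )
        assert critical_modulus(replace(b, diameter=2 * b.diameter)) == (
            pytest.approx(critical_modulus(b) / 16)
        )

    def test_monotone_decreasing_in_angle(self):
        values = [
            critical_modulus(MicrotrichiumBeam(angle_deg=a))
            for a in np.linspace(10, 85, 16)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_range_minimum_at_steepest_angle(self):
        grid = np.arange(40.0, 50.0 + 1e-9, 0.5)
        scan = stiffness_scan(MicrotrichiumBeam(), grid)
        assert scan["E_crit_gpa"].idxmin() == len(grid) - 1
        assert scan["E_crit_gpa"].min() == pytest.approx(
            critical_modulus(MicrotrichiumBeam(angle_deg=50.0)) / 1e9
        )

    def test_steep_angle_limit_finite(self):
        # a nearly perpendicular microtrichium needs the least stiffness:
        # the amplitude vanishes and E -> F L^2 / (I K(1/2)^2)
        b = MicrotrichiumBeam(angle_deg=89.999)
        expected = b.tip_force * b.length**2 / (
            b.second_moment * complete_elliptic_k(0.5) ** 2
        )
        assert critical_modulus(b) == pytest.approx(expected, rel=1e-4)

    def test_shallow_angle_divergence(self):
        # nearly flat microtrichia flatten at any stiffness: the bound blows
        # up (logarithmically) as the contact angle closes
        e_mid = critical_modulus(MicrotrichiumBeam(angle_deg=45.0))
        e_flat = critical_modulus(MicrotrichiumBeam(angle_deg=0.5))
        e_flatter = critical_modulus(MicrotrichiumBeam(angle_deg=0.05))
        assert e_flat > 50 * e_mid
        assert e_flatter > e_flat

    def test_invalid_angle_rejected(self):
        with pytest.raises(ValueError):
            MicrotrichiumBeam(angle_deg=95.0)
        with pytest.raises(ValueError):
            elliptic_amplitude(0.0)


class TestElasticaOracle:
    def test_rigid_limit_no_side_contact(self):
        c = elastica_side_contact(1e12, MicrotrichiumBeam())
        assert not c.side_contact
        assert c.tip_rotation < 1e-3

    def test_zero_force_no_rotation(self):
        c = elastica_side_contact(1e9, MicrotrichiumBeam(tip_force=0.0))
        assert not c.side_contact
        assert c.tip_rotation == 0.0

    def test_consistency_with_closed_form(self):
        b = MicrotrichiumBeam()
        e_crit = critical_modulus(b)
        assert elastica_side_contact(0.95 * e_crit, b).side_contact
        assert not elastica_side_contact(1.05 * e_crit, b).side_contact

    def test_bisection_on_side_contact_matches_margin_solver(self):
        b = MicrotrichiumBeam(angle_deg=45.0)
        via_bisect = critical_modulus_numeric(b, rel_tol=1e-5, via="bisect")
        via_margin = critical_modulus_numeric(b)
        assert via_bisect == pytest.approx(via_margin, rel=1e-4)

    def test_tip_rotation_grows_as_modulus_drops(self):
        b = MicrotrichiumBeam()
        e_crit = critical_modulus(b)
        rots = [
            elastica_side_contact(k * e_crit, b).tip_rotation
            for k in (4.0, 2.0, 1.2)
        ]
        assert rots[0] < rots[1] < rots[2] < math.radians(b.angle_deg)
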