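import math

import numpy as np
import pytest

from paleobite.biomechanics import (BeamSection, SkullLeverMeasurements,
                                    bite_force, bite_force_estimate,
                                    bite_force_quotient,
                                    canine_bending_strength,
                                    elliptical_section_modulus,
                                    mandible_force_profile, muscle_force)
from paleobite.simulate import simulate_skull_fixture


def make_meas(**kw):
    base = dict(specimen_id="x", temporalis_area_mm2=300.0,
                masseter_pterygoid_area_mm2=150.0, temporalis_arm_mm=15.0,
                masseter_arm_mm=10.0, outlever_canine_mm=50.0,
                outlever_m1_mm=35.0)
    base.update(kw)
    return SkullLeverMeasurements(**base)


class TestMuscleForce:
    @pytest.mark.parametrize("area,stress,expected", [
        (100, 300, 30.0), (0, 300, 0.0), (250, 150, 37.5)])
    def test_unit_conversion(self, area, stress, expected):
        assert muscle_force(area, stress) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            muscle_force(-1.0)


class TestBiteForce:
    def test_zero_muscles_zero_force(self):
        m = make_meas(temporalis_area_mm2=0.0, masseter_pterygoid_area_mm2=0.0)
        assert bite_force(m, "canine") == 0.0

    def test_hand_computed_lever_value(self):
        """T=100 N at t=10 mm plus M=50 N at m=20 mm over o=20 mm,
        doubled: 2*(100*10 + 50*20)/20 = 200 N."""
        m = make_meas(
            temporalis_area_mm2=100 / 0.3, masseter_pterygoid_area_mm2=50 / 0.3,
            temporalis_arm_mm=10.0, masseter_arm_mm=20.0,
            outlever_canine_mm=20.0, outlever_m1_mm=15.0)
        assert bite_force(m, "canine") == pytest.approx(200.0)
        assert bite_force(m, "canine", bilateral=False) == pytest.approx(100.0)

    def test_molar_force_exceeds_canine_force(self):
        m = make_meas()
        est = bite_force_estimate(m)
        assert est.molar_force_N >= est.canine_force_N

    def test_stress_area_rescaling_invariance(self):
        m1 = make_meas()
        m2 = make_meas(temporalis_area_mm2=600.0,
                       masseter_pterygoid_area_mm2=300.0)
        assert bite_force(m1, "canine", stress_kPa=300) == pytest.approx(
            bite_force(m2, "canine", stress_kPa=150))

    def test_isometric_scaling(self):
        """Linear dims x k, areas x k^2 => force x k^2."""
        k = 1.7
        m1 = make_meas()
        m2 = make_meas(
            temporalis_area_mm2=300.0 * k**2,
            masseter_pterygoid_area_mm2=150.0 * k**2,
            temporalis_arm_mm=15.0 * k, masseter_arm_mm=10.0 * k,
            outlever_canine_mm=50.0 * k, outlever_m1_mm=35.0 * k)
        assert bite_force(m2, "canine") == pytest.approx(
            k**2 * bite_force(m1, "canine"))

    def test_canine_outlever_must_exceed_molar(self):
        with pytest.raises(ValueError):
            make_meas(outlever_canine_mm=30.0, outlever_m1_mm=35.0)

    def test_fixture_records_its_own_force(self):
        fixture, truth = simulate_skull_fixture(seed=5)
        assert truth["canine_force_N"] == pytest.approx(
            bite_force(fixture, "canine"))
        assert truth["molar_force_N"] == pytest.approx(
            bite_force(fixture, "m1"))

    def test_fixture_scales_quadratically(self):
        _, t1 = simulate_skull_fixture(seed=5, scale=1.0)
        _, t2 = simulate_skull_fixture(seed=5, scale=2.0)
        assert t2["canine_force_N"] == pytest.approx(
            4.0 * t1["canine_force_N"])

    def test_targeted_fixture_hits_requested_force(self):
        fixture, truth = simulate_skull_fixture(
            seed=0, target_canine_force_N=218.0)
        assert truth["canine_force_N"] == pytest.approx(218.0)


class TestBfq:
    def comparative(self):
        rng = np.random.default_rng(1)
        mass = 10 ** rng.uniform(-1, 3, 20)
        force = 10 ** (1.2 + 0.6 * np.log10(mass)
                       + rng.normal(0, 0.15, 20))
        return np.column_stack([mass, force])

    def test_point_on_line_scores_100(self):
        comp = np.array([[1, 10], [10, 100], [100, 1000]], dtype=float)
        assert bite_force_quotient(5.0, 50.0, comp) == pytest.approx(100.0)

    def test_double_force_scores_200(self):
        comp = np.array([[1, 10], [10, 100], [100, 1000]], dtype=float)
        assert bite_force_quotient(5.0, 100.0, comp) == pytest.approx(200.0)

    def test_training_geometric_mean_is_100(self):
        comp = self.comparative()
        bfqs = [bite_force_quotient(m, f, comp) for m, f in comp]
        gm = math.exp(np.mean(np.log(bfqs)))
        assert gm == pytest.approx(100.0, rel=1e-6)

    def test_unit_invariance(self):
        comp = self.comparative()
        a = bite_force_quotient(5.0, 80.0, comp)
        scaled = comp * np.array([1000.0, 4.448])  # g and lbf, say
        b = bite_force_quotient(5000.0, 80.0 * 4.448, scaled)
        assert a == pytest.approx(b)

    def test_degenerate_masses_rejected(self):
        comp = np.array([[5, 10], [5, 20], [5, 30]], dtype=float)
        with pytest.raises(ValueError):
            bite_force_quotient(5.0, 10.0, comp)


class TestSectionModulus:
    def test_circle_closed_form(self):
        """pi d^3/32 for a circle; d=2 gives pi/4."""
        assert elliptical_section_modulus(2.0, 2.0) == pytest.approx(
            math.pi / 4.0)

    def test_symmetry_and_cubic_scaling(self):
        z1 = elliptical_section_modulus(3.0, 3.0)
        z2 = elliptical_section_modulus(6.0, 6.0)
        assert z2 == pytest.approx(8.0 * z1)

    def test_matches_numerical_integration(self):
        """Z = I/c with I integrated numerically over the ellipse."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            d_bend, d_perp = rng.uniform(1.0, 20.0, 2)
            a, b = d_bend / 2.0, d_perp / 2.0  # bending semi-axis a
            ys = np.linspace(-a, a, 20001)
            width = 2.0 * b * np.sqrt(np.clip(1 - (ys / a) ** 2, 0, None))
            I = np.trapezoid(width * ys**2, ys)
            assert elliptical_section_modulus(d_bend, d_perp) == \
                pytest.approx(I / a, rel=1e-3)


class TestBendingStrength:
    def test_circular_canine_isotropic(self):
        s = canine_bending_strength(
            BeamSection("canine", d_ap_mm=4.0, d_ml_mm=4.0, arm_mm=10.0))
        assert s.zx == pytest.approx(s.zy)
        assert s.zx_over_zy == pytest.approx(1.0)

    def test_halving_arm_doubles_strengths(self):
        s1 = canine_bending_strength(BeamSection("canine", 4.0, 3.0, 10.0))
        s2 = canine_bending_strength(BeamSection("canine", 4.0, 3.0, 5.0))
        assert s2.zx_over_arm == pytest.approx(2 * s1.zx_over_arm)
        assert s2.zy_over_arm == pytest.approx(2 * s1.zy_over_arm)

    def test_location_must_be_canine(self):
        with pytest.raises(ValueError):
            canine_bending_strength(BeamSection("p2-p3", 4.0, 3.0, 10.0))


class TestMandibleProfile:
    GAPS = ["canine", "p2-p3", "p3-m1", "m1-m2", "m2-3", "post m4"]

    def sections(self, depths, widths, arms):
        return [BeamSection(loc, d, w, a) for loc, d, w, a in
                zip(self.GAPS, depths, widths, arms)]

    def test_circular_sections_ratio_one(self):
        secs = self.sections([4] * 6, [4] * 6, [50, 45, 40, 35, 30, 25])
        prof = mandible_force_profile(secs)
        assert all(p.zx_over_zy == pytest.approx(1.0) for p in prof)

    def test_deep_section_resists_dorsoventral_bending(self):
        secs = self.sections([6] * 6, [3] * 6, [50] * 6)
        prof = mandible_force_profile(secs)
        assert all(p.zx_over_zy > 1.0 for p in prof)

    def test_posterior_deepening_raises_zx_over_arm(self):
        depths = [3.0, 3.6, 4.2, 5.0, 6.0, 7.2]
        secs = self.sections(depths, [3.0] * 6, [50, 44, 38, 32, 26, 20])
        prof = mandible_force_profile(secs)
        vals = [p.zx_over_arm for p in prof]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_rejects_disorder_and_duplicates(self):
        secs = self.sections([4] * 6, [4] * 6, [50] * 6)
        with pytest.raises(ValueError):
            mandible_force_profile([secs[1], secs[0]])
        with pytest.raises(ValueError):
            mandible_force_profile([secs[0], secs[0]])
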