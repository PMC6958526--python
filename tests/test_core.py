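"""Contact-mechanics primitives and domain-type invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import poroindent as pi
from poroindent.core import DegenerateParameterError, DomainError


class TestContactRadius:
    @pytest.mark.parametrize("R, delta, expected", [
        (7.5e-3, 3e-3, 4.743416e-3),   # sqrt(22.5) mm^2
        (25e-6, 1e-6, 5e-6),
        (1.0, 0.0, 0.0),
    ])
    def test_values(self, R, delta, expected):
        assert pi.contact_radius(R, delta) == pytest.approx(expected, rel=1e-6)

    def test_negative_depth_rejected(self):
        with pytest.raises(DomainError):
            pi.contact_radius(1.0, -0.1)


class TestKinematics:
    def test_rise_time_micro_protocol(self):
        # 200 um at 0.005 um/s takes 4e4 s
        assert pi.core.rise_time(200e-6, 0.005e-6) == pytest.approx(4e4)

    def test_rise_time_macro_protocol(self):
        assert pi.core.rise_time(3e-3, 0.001e-3) == pytest.approx(3000.0)

    def test_velocity_inverse(self):
        assert pi.core.approach_velocity(1.0, 1.0) == 1.0
        with pytest.raises(DomainError):
            pi.core.rise_time(1.0, 0.0)

    @pytest.mark.parametrize("R, dM, tR, expected", [
        (5e-3, 1e-3, 100.0, 0.02236e-3),
        (10e-3, 0.5e-3, 100.0, 0.02236e-3),  # same R*delta_M product
        (1.0, 1.0, 1.0, 1.0),
    ])
    def test_effective_velocity(self, R, dM, tR, expected):
        assert pi.effective_velocity(R, dM, tR) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("D, tR, R, dM, expected", [
        (1e-9, 1000.0, 0.01, 1e-4, 1.0),
        (5e-8, 100.0, 7.5e-3, 3e-3, 0.22222),
        (1e-9, 0.0, 0.01, 1e-4, 0.0),  # instantaneous-ramp limit
    ])
    def test_normalized_rise_time(self, D, tR, R, dM, expected):
        assert pi.normalized_rise_time(D, tR, R, dM) == pytest.approx(
            expected, rel=1e-4, abs=1e-15)

    def test_dimensionless_groups_unit_invariant(self):
        # micrometre inputs against the same quantities in metres
        um = 1e-6
        a = pi.normalized_rise_time(4.5e-10, 0.4, 25e-6, 2e-6)
        b = pi.normalized_rise_time(4.5e-10 / um ** 2, 0.4, 25.0, 2.0)
        assert a == pytest.approx(b, rel=1e-12)
        va = pi.effective_velocity(25e-6, 2e-6, 0.4)
        vb = pi.effective_velocity(25.0, 2.0, 0.4) * um
        assert va == pytest.approx(vb, rel=1e-12)


class TestHertz:
    def test_reference_value(self):
        # 10 mm sphere, 100 um depth, 10 kPa, incompressible
        F = pi.hertz_force(0.01, 1e-4, 10e3, 0.5)
        assert F == pytest.approx(1.7778e-3, rel=1e-4)

    def test_zero_depth(self):
        assert pi.hertz_force(0.01, 0.0, 10e3, 0.3) == 0.0

    def test_poisson_ratio_of_forces(self):
        F_inc = pi.hertz_force(1.0, 1e-3, 1e4, 0.5)
        F_0 = pi.hertz_force(1.0, 1e-3, 1e4, 0.0)
        assert F_inc / F_0 == pytest.approx(4.0 / 3.0, rel=1e-12)

    @given(k=st.floats(0.01, 100.0))
    @settings(deadline=None)
    def test_homogeneity(self, k):
        # F(kR, k delta) = k^2 F(R, delta)
        F1 = pi.hertz_force(0.01 * k, 1e-4 * k, 1e4, 0.3)
        F0 = pi.hertz_force(0.01, 1e-4, 1e4, 0.3)
        assert F1 == pytest.approx(k ** 2 * F0, rel=1e-9)

    def test_nu_out_of_range(self):
        with pytest.raises(DomainError):
            pi.hertz_force(0.01, 1e-4, 1e4, 1.0)


class TestLimitForces:
    def test_reference_values(self):
        f_inst, f_drained = pi.limit_forces(0.01, 1.5e-4, 10e3, 0.3)
        assert f_drained == pytest.approx(2.690e-3, rel=1e-3)
        assert f_inst == pytest.approx(3.266e-3, rel=1e-3)

    def test_ratio_at_nu_zero(self):
        f_inst, f_drained = pi.limit_forces(1.0, 1e-3, 1e4, 0.0)
        assert f_inst / f_drained == pytest.approx(4.0 / 3.0, rel=1e-12)

    @pytest.mark.parametrize("nu", np.linspace(0.0, 0.49, 11))
    def test_ordering(self, nu):
        f_inst, f_drained = pi.limit_forces(1.0, 1e-3, 1e4, nu)
        assert f_inst > f_drained

    def test_ratio_approaches_one_near_incompressible(self):
        f_inst, f_drained = pi.limit_forces(1.0, 1e-3, 1e4, 0.4999)
        assert f_inst / f_drained == pytest.approx(1.0, abs=1e-3)

    def test_nu_domain(self):
        with pytest.raises(DomainError):
            pi.limit_forces(1.0, 1e-3, 1e4, 0.5)


class TestPermeability:
    def test_reduces_to_D_over_E_at_nu_zero(self):
        assert pi.permeability_from_diffusivity(1e4, 0.0, 1e-9) == pytest.approx(
            1e-13, rel=1e-12)

    def test_macro_agarose_value(self):
        K = pi.permeability_from_diffusivity(21.25e3, 0.24, 5e-8)
        assert K == pytest.approx(2.0e-12, rel=0.01)

    def test_monotone_vanishing_toward_incompressible(self):
        nus = np.linspace(0.3, 0.499, 50)
        Ks = [pi.permeability_from_diffusivity(1e4, nu, 1e-9) for nu in nus]
        assert all(a > b for a, b in zip(Ks, Ks[1:]))
        assert Ks[-1] > 0

    def test_singular_at_incompressible(self):
        with pytest.raises(DegenerateParameterError):
            pi.permeability_from_diffusivity(1e4, 0.5, 1e-9)


class TestValidityFlags:
    def test_safe_geometry(self):
        flags = pi.validity_flags(pi.Geometry(10e-3, h=60e-3), 1e-3)
        assert flags == set()

    def test_hertz_regime_flag(self):
        flags = pi.validity_flags(pi.Geometry(1e-3), 0.7e-3)
        assert flags == {"hertz_regime_exceeded"}

    def test_thin_sample_flag(self):
        flags = pi.validity_flags(pi.Geometry(10e-3, h=10e-3), 4e-3)
        assert "thin_sample" in flags


class TestDomainTypes:
    def test_material_rejects_undrained_nu(self):
        with pytest.raises(DomainError):
            pi.MaterialParams(1e4, 0.5, 1e-9)

    def test_material_rejects_auxetic_by_default(self):
        with pytest.raises(DomainError):
            pi.MaterialParams(1e4, -0.1, 1e-9)
        m = pi.MaterialParams(1e4, -0.1, 1e-9, allow_auxetic=True)
        assert m.nu == -0.1

    def test_shear_modulus(self):
        m = pi.MaterialParams(2.6e3, 0.3, 1e-9)
        assert m.shear_modulus == pytest.approx(1e3)

    def test_observation_velocity_consistency(self):
        g = pi.Geometry(25e-6)
        a = pi.RampObservation(g, t_R=0.4, delta_M=2e-6, F_M=1e-6)
        b = pi.RampObservation.from_velocity(g, V=5e-6, delta_M=2e-6, F_M=1e-6)
        assert a.t_R == pytest.approx(b.t_R, rel=1e-12)
        assert a.V == pytest.approx(b.V, rel=1e-12)

    def test_observation_inconsistent_velocity_rejected(self):
        with pytest.raises(DomainError):
            pi.RampObservation(pi.Geometry(1.0), t_R=1.0, delta_M=1.0,
                               F_M=1.0, V=2.0)

    def test_curve_requires_increasing_time(self):
        with pytest.raises(DomainError):
            pi.RelaxationCurve(t=np.array([0.0, 1.0, 1.0]),
                               F=np.array([0.0, 1.0, 2.0]))
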