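"""Feeding-section barrel-load model: SFL, SFL*, slip, maximum throughput."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sios2 as s
from sios2.errors import DomainError, FittingError


class TestSfl:
    def test_definitional_unit_load(self):
        # mdot = rho_true * n * d**3 makes SFL exactly 1
        assert s.sfl(1190.0 * 0.5 * 0.0283 ** 3, 1190.0, 0.5, 0.0283) == \
            pytest.approx(1.0)

    def test_first_step_conditions_scalar_value(self):
        # 3 kg/h at 20 rpm for a 28.3 mm screw, true density 1190 kg/m^3
        mdot, n, d = 3.0 / 3600.0, 20.0 / 60.0, 0.0283
        expected = (mdot / 1190.0) / (n * d ** 3)
        assert s.sfl(mdot, 1190.0, n, d) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(0.0927, abs=0.0005)

    def test_linear_in_mass_flow(self):
        assert s.sfl(2e-3, 1190.0, 1.0, 0.0283) == \
            pytest.approx(2 * s.sfl(1e-3, 1190.0, 1.0, 0.0283))

    def test_zero_speed_rejected(self):
        with pytest.raises(DomainError):
            s.sfl(1e-3, 1190.0, 0.0, 0.0283)


class TestSflStar:
    def test_filled_section_condition(self, geometry):
        powder = s.PowderState(315.0, 1190.0, slip=0.865)
        n = 2.0
        mdot = (1 - 0.865) * geometry.l_pitch * geometry.A_free * 315.0 * n
        assert s.sfl_star(mdot, powder, geometry, n) == pytest.approx(1.0)

    def test_empty_section_is_zero(self, geometry):
        powder = s.PowderState(315.0, 1190.0, slip=0.5)
        assert s.sfl_star(0.0, powder, geometry, 1.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(n=st.floats(0.1, 20.0), slip=st.floats(0.0, 0.95))
    def test_max_mass_flow_round_trip(self, geometry, n, slip):
        powder = s.PowderState(400.0, 1200.0, slip=slip)
        mdot = s.max_mass_flow(powder, geometry, n)
        assert s.sfl_star(mdot, powder, geometry, n) == pytest.approx(1.0)


class TestSlipFromFilledPoint:
    def test_reproduces_published_pvpva_slip(self, geometry):
        # inverse consistency: the mass flow that fills the section at
        # slip 0.865 must give back 0.865
        n = 2.0
        mdot = (1 - 0.865) * geometry.l_pitch * geometry.A_free * 315.0 * n
        assert s.slip_from_filled_point(mdot, 315.0, geometry, n) == \
            pytest.approx(0.865, rel=1e-12)

    def test_no_slip_when_geometry_fully_used(self, geometry):
        n = 1.5
        mdot = geometry.l_pitch * geometry.A_free * 315.0 * n
        assert s.slip_from_filled_point(mdot, 315.0, geometry, n) == \
            pytest.approx(0.0, abs=1e-14)

    def test_halving_speed_lowers_slip(self, geometry):
        mdot = 1e-3
        s_hi = s.slip_from_filled_point(mdot, 315.0, geometry, 2.0)
        s_lo = s.slip_from_filled_point(mdot, 315.0, geometry, 1.0)
        assert s_lo < s_hi

    def test_negative_slip_warns(self, geometry):
        n = 1.0
        mdot = 2.0 * geometry.l_pitch * geometry.A_free * 315.0 * n
        with pytest.warns(UserWarning, match="slip"):
            assert s.slip_from_filled_point(mdot, 315.0, geometry, n) < 0


class TestFitSlip:
    def test_exact_recovery_from_noiseless_points(self, geometry):
        powder = s.PowderState(315.0, 1190.0, slip=0.86)
        speeds = np.linspace(0.5, 8.0, 10)
        flows = [s.max_mass_flow(powder, geometry, n) for n in speeds]
        assert s.fit_slip(speeds, flows, 315.0, geometry) == \
            pytest.approx(0.86, abs=1e-12)

    def test_noisy_recovery_within_calibrated_tolerance(self, geometry):
        # 1% relative Gaussian noise on 10 speeds: repeated-seed simulation
        # puts the slip error well below 0.005 absolute.
        powder = s.PowderState(315.0, 1190.0, slip=0.86)
        speeds = np.linspace(0.5, 8.0, 10)
        clean = np.array([s.max_mass_flow(powder, geometry, n) for n in speeds])
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noisy = clean * (1 + rng.normal(0, 0.01, clean.shape))
            assert s.fit_slip(speeds, noisy, 315.0, geometry) == \
                pytest.approx(0.86, abs=0.005)

    def test_single_point_matches_filled_point_formula(self, geometry):
        powder = s.PowderState(315.0, 1190.0, slip=0.7)
        n = 3.0
        mdot = s.max_mass_flow(powder, geometry, n)
        assert s.fit_slip([n], [mdot], 315.0, geometry) == pytest.approx(
            s.slip_from_filled_point(mdot, 315.0, geometry, n), rel=1e-12)

    def test_impossible_transport_rejected(self, geometry):
        # measured flows above the zero-slip geometric capacity
        n = np.array([1.0, 2.0])
        mdot = 3.0 * geometry.l_pitch * geometry.A_free * 315.0 * n
        with pytest.raises(FittingError):
            s.fit_slip(n, mdot, 315.0, geometry)


class TestSflMax:
    def test_zero_at_full_slip(self, geometry):
        # slip -> 1 kills transport; use the closed form directly at s ~ 1
        powder = s.PowderState(315.0, 1190.0, slip=0.999999)
        assert s.sfl_max(powder, geometry) == pytest.approx(0.0, abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(n=st.floats(0.2, 20.0), slip=st.floats(0.0, 0.95),
           rho_bulk=st.floats(200.0, 800.0))
    def test_consistent_with_sfl_at_maximum_flow(self, geometry, n, slip,
                                                 rho_bulk):
        """SFL evaluated at mdot_max is speed-independent and equals SFLmax."""
        powder = s.PowderState(rho_bulk, 1200.0, slip=slip)
        mdot = s.max_mass_flow(powder, geometry, n)
        assert s.sfl(mdot, powder.rho_true, n, geometry.d) == \
            pytest.approx(s.sfl_max(powder, geometry), rel=1e-12)

    def test_reference_polymer_ranking(self, geometry):
        """Printed densities and slips rank SFLmax as SOL > bBMA > PVPVA."""
        vals = {
            name: s.sfl_max(
                s.REFERENCE_MATERIALS[name].powder(s.REFERENCE_SLIPS[name]),
                geometry)
            for name in ("PVPVA", "SOL", "bBMA")
        }
        assert vals["SOL"] > vals["bBMA"] > vals["PVPVA"]


class TestMaxMassFlow:
    def test_linear_in_speed(self, geometry):
        powder = s.PowderState(315.0, 1190.0, slip=0.5)
        assert s.max_mass_flow(powder, geometry, 4.0) == \
            pytest.approx(2 * s.max_mass_flow(powder, geometry, 2.0))

    def test_scalar_oracle(self, geometry):
        powder = s.PowderState(315.0, 1190.0, slip=0.865)
        n = 3.3333
        expected = (1 - 0.865) * geometry.l_pitch * geometry.A_free * 315.0 * n
        assert s.max_mass_flow(powder, geometry, n) == pytest.approx(
            expected, rel=1e-14)


class TestValidation:
    def test_powder_state_invariants(self):
        with pytest.raises(DomainError):
            s.PowderState(1200.0, 1000.0)  # bulk > true
        with pytest.raises(DomainError):
            s.PowderState(300.0, 1000.0, slip=1.0)

    def test_geometry_positivity(self):
        with pytest.raises(DomainError):
            s.ExtruderGeometry(d=0.0, A_free=1e-4, l_pitch=0.05,
                               r_die=1e-3, l_die=1e-2, n_max=20.0)
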