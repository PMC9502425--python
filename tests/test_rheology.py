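"""Carreau-Arrhenius model: shift factor, viscosity, inversion, refitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sios2 as s
from sios2.errors import BracketingError, DomainError, FittingError
from sios2.rheology import R_GAS


def oracle_viscosity(p, gammadot, T):
    """Independent single-expression evaluation of the viscosity law."""
    aT = math.exp(p.Ea / R_GAS * (1.0 / T - 1.0 / p.T_ref))
    return p.eta0 * aT * (1.0 + aT * gammadot / p.gammadot_c) ** (-p.c)


params_strategy = st.builds(
    s.CarreauArrheniusParams,
    eta0=st.floats(1.0, 1e4),
    gammadot_c=st.floats(1.0, 5e3),
    c=st.floats(0.05, 0.95),
    Ea=st.floats(5e4, 3e5),
    T_ref=st.just(473.0),
)


class TestShiftFactor:
    def test_unity_at_reference_temperature(self, pvpva):
        assert s.shift_factor(pvpva.rheology, 473.0) == 1.0

    def test_matches_hand_computed_exponent(self, pvpva):
        # direct scalar evaluation of exp((Ea/R)(1/T - 1/Tref)) at 483 K
        expected = math.exp(198292.0 / 8.314 * (1.0 / 483.0 - 1.0 / 473.0))
        assert s.shift_factor(pvpva.rheology, 483.0) == pytest.approx(
            expected, rel=1e-14)

    def test_below_one_above_reference(self, pvpva):
        assert s.shift_factor(pvpva.rheology, 500.0) < 1.0
        assert s.shift_factor(pvpva.rheology, 450.0) > 1.0

    @settings(deadline=None, derandomize=True)
    @given(params=params_strategy,
           T=st.floats(350.0, 600.0), dT=st.floats(0.5, 50.0))
    def test_strictly_decreasing_in_temperature(self, params, T, dT):
        assert s.shift_factor(params, T + dT) < s.shift_factor(params, T)

    def test_rejects_nonpositive_temperature(self, pvpva):
        with pytest.raises(DomainError):
            s.shift_factor(pvpva.rheology, 0.0)


class TestViscosity:
    @pytest.mark.parametrize("name, eta0", [
        ("PVPVA", 169.7), ("SOL", 147.3), ("bBMA", 25.58)])
    def test_zero_shear_limit_is_eta0_at_reference(self, name, eta0):
        mat = s.REFERENCE_MATERIALS[name]
        assert s.viscosity(mat.rheology, 0.0, 473.0) == eta0

    @pytest.mark.parametrize("gammadot,T", [
        (264.0, 473.0), (10.0, 450.0), (3000.0, 500.0)])
    def test_matches_independent_oracle(self, pvpva, gammadot, T):
        assert s.viscosity(pvpva.rheology, gammadot, T) == pytest.approx(
            oracle_viscosity(pvpva.rheology, gammadot, T), rel=1e-14)

    @settings(deadline=None, derandomize=True)
    @given(params=params_strategy, gammadot=st.floats(0.1, 1e4),
           factor=st.floats(1.1, 10.0), T=st.floats(400.0, 550.0))
    def test_strictly_shear_thinning(self, params, gammadot, factor, T):
        assert s.viscosity(params, gammadot * factor, T) < \
            s.viscosity(params, gammadot, T)

    @settings(deadline=None, derandomize=True)
    @given(params=params_strategy, gammadot=st.floats(0.0, 1e4),
           T=st.floats(400.0, 540.0), dT=st.floats(1.0, 40.0))
    def test_strictly_decreasing_in_temperature(self, params, gammadot, T, dT):
        assert s.viscosity(params, gammadot, T + dT) < \
            s.viscosity(params, gammadot, T)

    def test_rejects_negative_shear_rate(self, pvpva):
        with pytest.raises(DomainError):
            s.viscosity(pvpva.rheology, -1.0, 473.0)


class TestOstwaldIndex:
    @pytest.mark.parametrize("c, expected", [
        (0.0, 1.0), (0.387, 0.613), (0.561, 0.439)])
    def test_one_minus_c(self, c, expected):
        p = s.CarreauArrheniusParams(100.0, 100.0, c, 1e5, 473.0)
        assert s.ostwald_index(p) == pytest.approx(expected)


class TestInvertTemperature:
    def test_round_trip_identity(self, pvpva):
        target = s.viscosity(pvpva.rheology, 100.0, 450.0)
        T = s.invert_temperature(pvpva.rheology, 100.0, target)
        assert T == pytest.approx(450.0, abs=0.01)

    def test_zero_shear_target_at_eta0_returns_reference(self):
        T = s.invert_temperature(s.SOL.rheology, 0.0, 147.3)
        assert T == pytest.approx(473.0, abs=0.01)

    def test_round_trip_over_grid(self, all_materials):
        for mat in all_materials:
            for gdot in (0.0, 50.0, 500.0, 5000.0):
                for T_true in (380.0, 430.0, 470.0, 520.0):
                    target = s.viscosity(mat.rheology, gdot, T_true)
                    assert s.invert_temperature(mat.rheology, gdot, target) \
                        == pytest.approx(T_true, abs=0.01)

    def test_agrees_with_grid_search_oracle(self, all_materials):
        """Brent inversion vs exhaustive 0.01 K grid search."""
        rng = np.random.default_rng(7)
        grid = np.arange(323.0, 623.0 + 0.01, 0.01)
        for _ in range(25):
            mat = all_materials[rng.integers(3)]
            gdot = float(rng.uniform(0.0, 5000.0))
            T_true = float(rng.uniform(360.0, 560.0))
            target = s.viscosity(mat.rheology, gdot, T_true)
            etas = s.viscosity(mat.rheology, gdot, grid)
            T_grid = grid[np.argmin(np.abs(etas - target))]
            T_brent = s.invert_temperature(mat.rheology, gdot, target)
            assert abs(T_brent - T_grid) <= 0.01

    def test_unattainable_target_reports_endpoint_viscosities(self, pvpva):
        with pytest.raises(BracketingError) as excinfo:
            s.invert_temperature(pvpva.rheology, 100.0, 1e12)
        assert "Pa*s" in str(excinfo.value)
        assert excinfo.value.bracket == (323.0, 623.0)


class TestFitCarreauArrhenius:
    @staticmethod
    def synthetic_points(params, n_per_T=10, temps=(453.0, 473.0, 493.0),
                         noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        gdots = np.logspace(0, 4, n_per_T)
        pts = []
        for T in temps:
            etas = s.viscosity(params, gdots, T)
            if noise:
                etas = etas * np.exp(rng.normal(0.0, noise, size=etas.shape))
            pts += [s.FlowCurvePoint(g, T, e) for g, e in zip(gdots, etas)]
        return pts

    def test_noiseless_recovery_to_machine_precision(self, pvpva):
        truth = pvpva.rheology
        fitted = s.fit_carreau_arrhenius(self.synthetic_points(truth), 473.0)
        assert fitted.eta0 == pytest.approx(truth.eta0, rel=1e-6)
        assert fitted.gammadot_c == pytest.approx(truth.gammadot_c, rel=1e-6)
        assert fitted.c == pytest.approx(truth.c, rel=1e-6)
        assert fitted.Ea == pytest.approx(truth.Ea, rel=1e-6)

    def test_noisy_recovery_within_calibrated_tolerance(self, pvpva):
        # 2% multiplicative log-normal noise, ~50 points: repeated-seed
        # simulation puts the eta0 error comfortably inside 10%.
        truth = pvpva.rheology
        for seed in range(5):
            pts = self.synthetic_points(truth, n_per_T=17, noise=0.02,
                                        seed=seed)
            fitted = s.fit_carreau_arrhenius(pts, 473.0)
            assert fitted.eta0 == pytest.approx(truth.eta0, rel=0.10)
            assert fitted.c == pytest.approx(truth.c, rel=0.15)

    def test_single_temperature_is_unidentifiable(self, pvpva):
        pts = self.synthetic_points(pvpva.rheology, temps=(473.0,))
        with pytest.raises(FittingError, match="single temperature"):
            s.fit_carreau_arrhenius(pts, 473.0)

    def test_too_few_points(self, pvpva):
        pts = self.synthetic_points(pvpva.rheology, n_per_T=1,
                                    temps=(453.0, 473.0, 493.0))
        with pytest.raises(FittingError):
            s.fit_carreau_arrhenius(pts, 473.0)
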