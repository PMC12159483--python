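"""Arrhenius, Eyring and Ball temperature-dependence models."""

import math

import numpy as np
import pytest

from mixkin.errors import DomainError, SingularityError, SizeError
from mixkin.temperature import (
    BOLTZMANN,
    PLANCK,
    R_GAS,
    ArrheniusModel,
    BallModel,
    EyringModel,
    RateByTemperature,
    d_value,
    fit_arrhenius,
    fit_ball,
    fit_eyring,
)

TEMPS = (5.0, 15.0, 25.0)


def rates(ks, name="x", temps=TEMPS):
    return RateByTemperature(name, temps, tuple(ks))


def arrhenius_truth(k_ref, Ea, T_ref_c, temps=TEMPS):
    Tref = T_ref_c + 273.15
    return [k_ref * math.exp(-(Ea / R_GAS) * (1 / (T + 273.15) - 1 / Tref))
            for T in temps]


class TestArrhenius:
    def test_identical_rates_give_zero_activation_energy(self):
        fit = fit_arrhenius(rates([0.1, 0.1, 0.1]))
        assert fit.Ea == pytest.approx(0.0, abs=1e-10)
        assert fit.k_ref == pytest.approx(0.1)

    def test_noiseless_parameter_recovery(self):
        ks = arrhenius_truth(0.2011, 1.6e4, 15.0)
        fit = fit_arrhenius(rates(ks))
        assert fit.Ea == pytest.approx(1.6e4, rel=1e-10)
        assert fit.k_ref == pytest.approx(0.2011, rel=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_acceptability_rates_give_published_scale_ea(self):
        fit = fit_arrhenius(rates([0.0694, 0.0815, 0.1279]))
        assert fit.Ea == pytest.approx(2.09e4, rel=0.05)

    def test_default_reference_is_mean_temperature(self):
        fit = fit_arrhenius(rates([0.1, 0.2, 0.4]))
        assert fit.T_ref == pytest.approx(15.0 + 273.15)

    def test_matches_normal_equations_oracle(self):
        ks = [0.0212, 0.0262, 0.0344]
        fit = fit_arrhenius(rates(ks))
        T = np.array(TEMPS) + 273.15
        x = 1 / T - 1 / (288.15)
        X = np.column_stack([np.ones(3), x])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(ks))
        assert fit.k_ref == pytest.approx(math.exp(beta[0]), abs=1e-12)
        assert fit.Ea == pytest.approx(-beta[1] * R_GAS, abs=1e-9)

    def test_predict_k_round_trip(self):
        ks = arrhenius_truth(0.05, 2.0e4, 15.0)
        fit = fit_arrhenius(rates(ks))
        for T, k in zip(TEMPS, ks):
            assert fit.predict_k(T) == pytest.approx(k, rel=1e-10)
        assert fit.predict_k(15.0) == pytest.approx(fit.k_ref)

    def test_predict_monotone_when_ea_positive(self):
        fit = fit_arrhenius(rates([0.1, 0.15, 0.22]))
        assert fit.predict_k(10.0) < fit.predict_k(20.0)

    def test_absolute_zero_rejected(self):
        fit = fit_arrhenius(rates([0.1, 0.15, 0.22]))
        with pytest.raises(DomainError):
            fit.predict_k(-300.0)

    def test_single_temperature_rejected(self):
        with pytest.raises(SizeError):
            RateByTemperature("x", (5.0,), (0.1,))

    def test_zero_spread_rejected(self):
        with pytest.raises(SingularityError):
            RateByTemperature("x", (5.0, 5.0), (0.1, 0.2))


class TestEyring:
    def test_boltzmann_planck_intercept_constant(self):
        assert math.log(BOLTZMANN / PLANCK) == pytest.approx(23.76, abs=5e-3)

    def test_enthalpy_close_to_ea_minus_rt(self):
        ks = [0.0694, 0.0815, 0.1279]
        ea = fit_arrhenius(rates(ks)).Ea
        dh = fit_eyring(rates(ks)).delta_H
        tbar = np.mean(TEMPS) + 273.15
        assert dh == pytest.approx(ea - R_GAS * tbar, rel=0.01)

    def test_published_rates_all_give_negative_entropy(self, fixtures):
        for name, r in fixtures.rates.items():
            assert fit_eyring(r).delta_S < 0, name

    def test_matches_normal_equations_oracle(self):
        ks = np.array([0.0191, 0.0255, 0.0305])
        fit = fit_eyring(rates(ks))
        T = np.array(TEMPS) + 273.15
        X = np.column_stack([np.ones(3), 1 / T])
        y = np.log(ks / 86400.0 / T)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.delta_H == pytest.approx(-beta[1] * R_GAS, abs=1e-8)
        assert fit.delta_S == pytest.approx(
            R_GAS * (beta[0] - math.log(BOLTZMANN / PLANCK)), abs=1e-9
        )


class TestBall:
    def test_d_value_identities(self):
        assert d_value(math.log(10)) == pytest.approx(1.0)
        assert d_value(0.1646) == pytest.approx(13.99, abs=0.01)
        for k in (0.01, 0.5, 3.0):
            assert d_value(k) * k == pytest.approx(math.log(10))
        with pytest.raises(DomainError):
            d_value(0.0)

    def test_two_point_closed_form(self):
        k1, k2 = 0.05, 0.2
        fit = fit_ball(RateByTemperature("x", (5.0, 25.0), (k1, k2)))
        D1, D2 = d_value(k1), d_value(k2)
        assert fit.Z == pytest.approx(20.0 / math.log10(D1 / D2))

    def test_d_halving_every_ten_degrees(self):
        # D halves per +10 C => Z = 10/log10(2)
        Ds = [40.0, 20.0, 10.0]
        ks = [math.log(10) / D for D in Ds]
        fit = fit_ball(rates(ks))
        assert fit.Z == pytest.approx(10 / math.log10(2), rel=1e-12)

    def test_z_positive_when_rates_increase_with_temperature(self, fixtures):
        for name, r in fixtures.rates.items():
            assert fit_ball(r).Z > 0, name

    def test_flat_line_signals_infinite_z(self):
        fit = fit_ball(rates([0.1, 0.1, 0.1]))
        assert math.isinf(fit.Z)

    def test_matches_normal_equations_oracle(self):
        ks = [0.1646, 0.2066, 0.2322]
        fit = fit_ball(rates(ks))
        x = np.array(TEMPS) - 15.0
        y = np.log10([d_value(k) for k in ks])
        X = np.column_stack([np.ones(3), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.D_ref == pytest.approx(10 ** beta[0], rel=1e-12)
        assert fit.Z == pytest.approx(-1 / beta[1], rel=1e-12)

    def test_consistency_with_arrhenius_on_exact_data(self):
        """Both models predict nearly the same D at interior temperatures."""
        ks = arrhenius_truth(0.1, 1.8e4, 15.0)
        arr = fit_arrhenius(rates(ks))
        ball = fit_ball(rates(ks))
        for T in (8.0, 12.0, 18.0, 22.0):
            d_arr = d_value(arr.predict_k(T))
            d_ball = ball.predict_d(T)
            assert d_ball == pytest.approx(d_arr, rel=0.02)


class TestAgainstStudyRates:
    def test_ea_band_and_ordering(self, fixtures):
        """Every index's Ea lies in 9-22 kJ/mol; acceptability is largest."""
        eas = {name: fit_arrhenius(r).Ea for name, r in fixtures.rates.items()}
        for name, ea in eas.items():
            assert 9e3 <= ea <= 22e3, name
        assert max(eas, key=eas.get) == "overall_acceptability"

    def test_parameter_recovery_under_rate_noise(self, rng):
        """Median relative Ea error < 10% at 5% lognormal rate noise."""
        Ea = 20.622e3  # the study's headline activation energy
        ks_true = arrhenius_truth(0.0815, Ea, 15.0)
        errs = []
        for _ in range(500):
            noisy = [k * rng.lognormal(0.0, 0.05) for k in ks_true]
            est = fit_arrhenius(rates(noisy)).Ea
            errs.append(abs(est - Ea) / Ea)
        assert np.median(errs) < 0.10
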