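"""Unit and property tests for the logistic prognosis model."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cipredict as cp
from cipredict.exceptions import FitFailureError, ValidationError

ZERO = cp.CoefficientSet(0.0, 0.0, 0.0, 0.0)


def profile(wm=23.0, age=66.0, ha=0.0):
    return cp.PreopProfile(wrs_max=wm, wrs65_ha=ha, age_years=age)


class TestPredict:
    def test_zero_coefficients_give_logistic_midpoint(self):
        assert cp.predict_wrs_ci(ZERO, profile(80, 30, 40)).point == pytest.approx(50.0)

    @pytest.mark.parametrize(
        "wm, age, ha, expected",
        [
            # frozen from direct high-precision evaluation of the linear
            # predictor 0.84 + 0.012*wm - 0.0094*age + 0.0059*ha
            (23.0, 66.0, 0.0, 62.142476),
            (0.0, 66.0, 0.0, 55.468043),  # intercept + age only
        ],
    )
    def test_published_coefficients_point_values(self, coeffs, wm, age, ha, expected):
        assert cp.predict_wrs_ci(coeffs, profile(wm, age, ha)).point == \
            pytest.approx(expected, abs=1e-4)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValidationError):
            profile(wm=120.0)
        with pytest.raises(ValidationError):
            profile(age=-3.0)
        with pytest.raises(ValidationError):
            cp.PreopProfile(wrs_max=37.0, wrs65_ha=0.0, age_years=60.0, n_items=20)

    @given(wm=st.floats(0, 100), age=st.floats(1, 110), ha=st.floats(0, 100))
    def test_bounds_open(self, coeffs, wm, age, ha):
        p = cp.predict_wrs_ci(coeffs, profile(wm, age, ha)).point
        assert 0.0 < p < 100.0

    @given(wm=st.floats(0, 95), age=st.floats(1, 100), ha=st.floats(0, 95),
           d=st.floats(0.5, 5))
    def test_monotone_in_each_predictor(self, coeffs, wm, age, ha, d):
        base = cp.predict_wrs_ci(coeffs, profile(wm, age, ha)).point
        assert cp.predict_wrs_ci(coeffs, profile(wm + d, age, ha)).point > base
        assert cp.predict_wrs_ci(coeffs, profile(wm, age, ha + d)).point > base
        assert cp.predict_wrs_ci(coeffs, profile(wm, age + d, ha)).point < base

    @given(wm=st.floats(0, 100), age=st.floats(1, 100), ha=st.floats(0, 100))
    def test_linear_predictor_sign_symmetry(self, coeffs, wm, age, ha):
        """eta and -eta map to scores p and 100 - p."""
        r = cp.predict_wrs_ci(coeffs, profile(wm, age, ha))
        mirrored = 100.0 / (1.0 + math.exp(r.linear_predictor))
        assert r.point + mirrored == pytest.approx(100.0, abs=1e-9)


class TestPredictionInterval:
    def test_zero_ses_degenerate(self):
        cs = cp.CoefficientSet(0.84, 0.012, -0.0094, 0.0059)
        r = cp.prediction_interval(cs, profile(), seed=1)
        assert r.interval_low == r.interval_high == pytest.approx(r.point)

    def test_contains_point_and_reproducible(self, coeffs):
        r1 = cp.prediction_interval(coeffs, profile(), level=0.95, seed=7)
        r2 = cp.prediction_interval(coeffs, profile(), level=0.95, seed=7)
        assert (r1.interval_low, r1.interval_high) == (r2.interval_low, r2.interval_high)
        assert r1.interval_low <= r1.point <= r1.interval_high
        assert r1.interval_low < 62.1 < r1.interval_high

    def test_doubling_ses_never_narrows(self, coeffs):
        wide = dataclasses.replace(coeffs, se0=2 * coeffs.se0, se1=2 * coeffs.se1,
                                   se2=2 * coeffs.se2, se3=2 * coeffs.se3)
        a = cp.prediction_interval(coeffs, profile(), n_draws=50_000, seed=3)
        b = cp.prediction_interval(wide, profile(), n_draws=50_000, seed=3)
        assert b.interval_high - b.interval_low >= a.interval_high - a.interval_low

    def test_invalid_arguments(self, coeffs):
        with pytest.raises(ValidationError):
            cp.prediction_interval(coeffs, profile(), level=1.5)
        with pytest.raises(ValidationError):
            cp.prediction_interval(coeffs, profile(), n_draws=10)


def _noise_free_cohort(cs, n=400, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        p = cp.PreopProfile(wrs_max=float(rng.integers(0, 21) * 5),
                            wrs65_ha=float(rng.integers(0, 11) * 5),
                            age_years=float(rng.uniform(25, 86)))
        exact = float(cp.predict_percent(cs, p.wrs_max, p.age_years, p.wrs65_ha))
        rows.append((p, exact, 20))
    return rows


class TestRefit:
    def test_noise_free_roundtrip(self, coeffs):
        fit = cp.refit_coefficients(_noise_free_cohort(coeffs))
        for got, want in zip(fit.betas, coeffs.betas):
            assert abs(got - want) < 1e-4

    def test_binomial_noise_recovery_single_seed(self, coeffs):
        rng = np.random.default_rng(11)
        rows = []
        for p, exact, n in _noise_free_cohort(coeffs, n=5000, seed=11):
            rows.append((p, rng.binomial(n, exact / 100.0) * 100.0 / n, n))
        fit = cp.refit_coefficients(rows)
        assert fit.beta1 == pytest.approx(coeffs.beta1, abs=0.003)
        assert fit.se1 > 0 and fit.se2 > 0

    def test_constant_predictor_fails_loudly(self, coeffs):
        rows = [(cp.PreopProfile(wrs_max=float(5 * i % 100), wrs65_ha=float(5 * i % 50),
                                 age_years=65.0), 50.0, 20)
                for i in range(1, 40)]
        with pytest.raises(FitFailureError, match="age"):
            cp.refit_coefficients(rows)

    def test_too_small_cohort(self):
        with pytest.raises(FitFailureError):
            cp.refit_coefficients([(profile(), 50.0, 20)] * 3)


def test_coefficient_set_json_roundtrip(tmp_path, coeffs):
    path = tmp_path / "coeffs.json"
    coeffs.to_json(path)
    assert cp.CoefficientSet.from_json(path) == coeffs


def test_published_default_values(coeffs):
    assert coeffs.betas == pytest.approx([0.84, 0.012, -0.0094, 0.0059])
    assert coeffs.ses == pytest.approx([0.18, 0.0015, 0.0025, 0.0026])
    with pytest.raises(ValidationError):
        cp.CoefficientSet(0.0, 0.0, 0.0, 0.0, se0=-0.1)
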