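"""Closed-form progress curve, its inverse, sensitivity and equilibrium split."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect, minimize_scalar

from mase import (
    LysateComposition,
    LysateLabel,
    RateConstants,
    equilibrium_split,
    invert_R,
    predict_R,
    sensitivity,
)
from mase.kinetics import peak_sensitivity_kt, peak_sensitivity_time

rates_st = st.floats(min_value=1e-7, max_value=1e-2)
times_st = st.floats(min_value=1.0, max_value=1e6)


class TestPredictR:
    @pytest.mark.parametrize(
        "k_off, t, expected, decimals",
        [
            (1e-5, 28800.0, 0.14, 2),  # slow complex after 8 h
            (1e-3, 7200.0, 1.00, 2),  # fast complex equilibrated within 2 h
        ],
    )
    def test_reference_checkpoints(self, k_off, t, expected, decimals):
        assert round(predict_R(k_off, t), decimals) == expected

    @pytest.mark.parametrize("k_off", [1e-6, 1e-4, 1e-2])
    def test_zero_at_mixing_instant(self, k_off):
        assert predict_R(k_off, 0.0) == 0.0

    def test_ode_frozen_regression_value(self):
        # Frozen from the full 8-species stiff-ODE integration with
        # equivalent lysates (k_on = 1e6) at k_off = 1e-4, t = 4 h.
        assert predict_R(1e-4, 14400.0) == pytest.approx(0.61690930, abs=1e-6)

    def test_vectorized_over_time(self):
        t = np.array([0.0, 100.0, 1e4])
        out = predict_R(1e-4, t)
        assert out.shape == (3,)
        assert out[0] == 0.0

    @pytest.mark.parametrize("bad", [(-1e-5, 10.0), (0.0, 10.0), (np.nan, 10.0),
                                     (1e-5, -1.0), (1e-5, np.inf)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            predict_R(*bad)

    @settings(derandomize=True, max_examples=60)
    @given(k1=rates_st, k2=rates_st, t=times_st)
    def test_strictly_increasing_in_koff(self, k1, k2, t):
        if k1 == k2:
            return
        lo, hi = sorted((k1, k2))
        r_lo, r_hi = predict_R(lo, t), predict_R(hi, t)
        if r_lo < 1.0 - 1e-12:  # away from saturation, strict ordering holds
            assert r_lo < r_hi

    @settings(derandomize=True, max_examples=60)
    @given(k=rates_st, t1=times_st, t2=times_st)
    def test_bounded_and_increasing_in_time(self, k, t1, t2):
        r1, r2 = predict_R(k, t1), predict_R(k, t2)
        for r, t in ((r1, t1), (r2, t2)):
            assert 0.0 <= r <= 1.0
            if k * t < 30.0:  # below double-precision saturation of tanh
                assert r < 1.0
        if t1 < t2 and r1 < 1.0 - 1e-12:
            assert r1 < r2

    def test_approaches_one(self):
        assert predict_R(1e-4, 1e7) == pytest.approx(1.0, abs=1e-12)


class TestInvertR:
    @settings(derandomize=True, max_examples=60)
    @given(k=rates_st, t=times_st)
    def test_round_trip_identity(self, k, t):
        r = predict_R(k, t)
        if 0.0 < r < 1.0:
            assert invert_R(r, t) == pytest.approx(k, rel=1e-10)

    def test_matches_log_space_bisection_oracle(self):
        # independent route: bisection on predict_R over log10 k in [-8, -1]
        r, t = 0.14, 28800.0
        k_bisect = 10.0 ** bisect(
            lambda g: predict_R(10.0 ** g, t) - r, -8.0, -1.0, xtol=1e-13
        )
        k_analytic = invert_R(r, t)
        assert k_analytic == pytest.approx(k_bisect, rel=1e-9)
        assert k_analytic == pytest.approx(1.0e-5, rel=0.05)

    @pytest.mark.parametrize("r, t", [(1.0, 3600.0), (0.0, 3600.0),
                                      (1.2, 3600.0), (0.5, 0.0), (0.5, -1.0)])
    def test_uninformative_points_rejected(self, r, t):
        with pytest.raises(ValueError):
            invert_R(r, t)


class TestSensitivity:
    @pytest.mark.parametrize("k_off", [1e-5, 1e-4, 1e-3])
    def test_zero_at_time_zero(self, k_off):
        assert sensitivity(k_off, 0.0) == 0.0

    @pytest.mark.parametrize("k_off, t", [(1e-4, 3600.0), (1e-5, 28800.0),
                                          (1e-3, 500.0), (1e-2, 50.0)])
    def test_matches_central_finite_difference(self, k_off, t):
        h = 1e-6 * k_off
        fd = (predict_R(k_off + h, t) - predict_R(k_off - h, t)) / (2.0 * h)
        assert sensitivity(k_off, t) == pytest.approx(fd, rel=1e-6)

    def test_positive_for_positive_time(self):
        assert sensitivity(1e-4, 10.0) > 0.0
        # overflow-safe deep into saturation
        assert sensitivity(1e-2, 1e6) == 0.0 or sensitivity(1e-2, 1e6) > 0.0
        assert np.isfinite(sensitivity(1e-2, 1e6))

    @pytest.mark.parametrize("k_off", [1e-5, 1e-4, 1e-3])
    def test_argmax_time_scales_as_constant_over_koff(self, k_off):
        res = minimize_scalar(
            lambda t: -sensitivity(k_off, t),
            bounds=(1.0 / k_off * 0.01, 10.0 / k_off),
            method="bounded",
            options={"xatol": 1e-10 / k_off},
        )
        assert k_off * res.x == pytest.approx(peak_sensitivity_kt(), rel=1e-6)
        assert peak_sensitivity_kt() == pytest.approx(1.5434, abs=1e-3)
        assert peak_sensitivity_time(k_off) == pytest.approx(res.x, rel=1e-6)


class TestEquilibriumSplit:
    def test_no_a_present(self):
        lys = LysateComposition(0.0, 1.0, LysateLabel.UNLABELED_TAGGED)
        state = equilibrium_split(lys, RateConstants(1.0, 1.0))
        assert state.conc["B_U"] == 1.0
        assert state.conc["A_TU"] == 0.0
        assert state.conc["A_TU_B_U"] == 0.0

    def test_symmetric_unit_case_quadratic_root(self):
        # x = (1 - x)^2  ->  x^2 - 3x + 1 = 0, lower root (3 - sqrt(5))/2
        lys = LysateComposition(1.0, 1.0, LysateLabel.UNLABELED_TAGGED)
        state = equilibrium_split(lys, RateConstants(1.0, 1.0))
        expected = (3.0 - math.sqrt(5.0)) / 2.0
        assert state.conc["A_TU_B_U"] == pytest.approx(expected, abs=1e-12)
        # brute-force oracle: bisection on the flux balance
        f = lambda x: 1.0 * (1.0 - x) ** 2 - 1.0 * x
        x_oracle = bisect(f, 0.0, 1.0, xtol=1e-14)
        assert state.conc["A_TU_B_U"] == pytest.approx(x_oracle, abs=1e-12)

    def test_detailed_balance_and_conservation_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a0, b0 = rng.uniform(0.05, 10.0, size=2)
            kon = 10.0 ** rng.uniform(-2, 8)
            koff = 10.0 ** rng.uniform(-6, 0)
            lys = LysateComposition(a0, b0, LysateLabel.LABELED_UNTAGGED)
            state = equilibrium_split(lys, RateConstants(kon, koff))
            x = state.conc["A_L_B_L"]
            fa, fb = state.conc["A_L"], state.conc["B_L"]
            flux_on = kon * fa * fb
            flux_off = koff * x
            assert flux_on == pytest.approx(flux_off, rel=1e-10)
            # mass totals conserved to a rounding ulp
            assert fa + x == pytest.approx(a0, rel=1e-15)
            assert fb + x == pytest.approx(b0, rel=1e-15)
            assert min(fa, fb, x) >= 0.0
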