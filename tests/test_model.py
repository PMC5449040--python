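"""Forward-model tests: quadratic prediction, ensemble, Taylor link, exchange."""

import math
from decimal import Decimal

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coilpress import get_entry
from coilpress.model import (
    GAS_CONSTANT,
    EnsembleModel,
    PressureCoefficients,
    ThermoState,
    check_fast_exchange,
    ensemble_shift,
    predict_shift,
    state_populations,
    taylor_coefficients,
)

from conftest import mild_ensemble, random_ensemble


# -- independent oracles ----------------------------------------------------

def brute_force_shift(model, p):
    """Ensemble shift by direct summation in compensated precision."""
    dp = p - model.p0
    rt = GAS_CONSTANT * model.temperature
    weights = [
        math.exp(-(s.G0 + s.V0 * dp + 0.5 * s.beta0 * dp * dp) / rt)
        for s in model.states
    ]
    z = math.fsum(weights)
    return math.fsum(s.shift * w for s, w in zip(model.states, weights)) / z


def numeric_taylor(model, h=0.8):
    """Richardson-extrapolated central-difference (B1, B2) about p0, per GPa."""

    def derivs(step):
        f = lambda p: ensemble_shift(model, p)
        x = model.p0
        d1 = (f(x - 2 * step) - 8 * f(x - step) + 8 * f(x + step)
              - f(x + 2 * step)) / (12 * step)
        d2 = (-f(x - 2 * step) + 16 * f(x - step) - 30 * f(x)
              + 16 * f(x + step) - f(x + 2 * step)) / (12 * step * step)
        return d1, d2

    a1, a2 = derivs(h)
    b1, b2 = derivs(h / 2)
    d1 = (16 * b1 - a1) / 15
    d2 = (16 * b2 - a2) / 15
    return d1 * 1e3, 0.5 * d2 * 1e6


class TestPredictShift:
    def test_at_reference_pressure_returns_delta0(self):
        entry = get_entry("Ala", "N15")
        assert predict_shift(entry.coefficients, 0.1) == 124.39

    def test_zero_coefficients_give_constant(self):
        c = PressureCoefficients(delta0=7.7, B1=0.0, B2=0.0)
        for p in (0.0, 0.1, 50.0, 200.0, 900.0):
            assert predict_shift(c, p) == 7.7

    def test_gly_nitrogen_at_200_mpa(self):
        # oracle: exact decimal evaluation of the quadratic at dp = 0.1999 GPa
        dp = (Decimal("200") - Decimal("0.1")) / 1000
        expected = (
            Decimal("109.22") + Decimal("3.79") * dp + Decimal("-2.16") * dp * dp
        )
        assert expected == Decimal("109.8913073784")
        value = predict_shift(get_entry("Gly", "N15").coefficients, 200.0)
        assert value == pytest.approx(float(expected), abs=1e-9)
        assert round(value, 4) == 109.8913

    def test_vectorized_matches_scalar(self):
        c = get_entry("Trp", "H1N").coefficients
        grid = np.linspace(0.1, 200, 9)
        vec = predict_shift(c, grid)
        assert vec == pytest.approx([predict_shift(c, p) for p in grid])

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError, match="pressure"):
            predict_shift(PressureCoefficients(1.0, 1.0, -1.0), -5.0)

    @given(
        delta0=st.floats(-200, 200),
        b1=st.floats(-10, 10),
        b2=st.floats(-10, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_exactly_quadratic(self, delta0, b1, b2):
        # constant second finite difference on an equispaced grid
        c = PressureCoefficients(delta0=delta0, B1=b1, B2=b2)
        grid = np.linspace(0.1, 200, 21)
        y = predict_shift(c, grid)
        second = np.diff(y, 2)
        assert np.allclose(second, second[0], atol=1e-9)


class TestPressureCoefficientsValidation:
    def test_negative_p0_rejected(self):
        with pytest.raises(ValueError, match="p0"):
            PressureCoefficients(1.0, 1.0, -1.0, p0=-1.0)

    def test_negative_error_rejected(self):
        with pytest.raises(ValueError, match="B1_err"):
            PressureCoefficients(1.0, 1.0, -1.0, B1_err=-0.1)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            PressureCoefficients(float("nan"), 1.0, -1.0)


class TestStatePopulations:
    def test_symmetric_two_state_is_half_half(self):
        m = EnsembleModel(
            (ThermoState("a", shift=1.0, G0=5.0), ThermoState("b", shift=2.0, G0=5.0))
        )
        for p in (0.1, 50.0, 200.0):
            assert state_populations(m, p) == pytest.approx([0.5, 0.5])

    def test_rt_log9_gap_gives_90_10(self):
        rt = GAS_CONSTANT * 283.0
        m = EnsembleModel(
            (
                ThermoState("major", shift=1.0, G0=0.0),
                ThermoState("minor", shift=2.0, G0=rt * math.log(9.0)),
            )
        )
        assert state_populations(m, 0.1) == pytest.approx([0.9, 0.1], abs=1e-12)

    def test_negative_dV_state_grows_with_pressure(self):
        m = EnsembleModel(
            (
                ThermoState("a", shift=1.0),
                ThermoState("b", shift=2.0, G0=3000.0, V0=-40.0),
            )
        )
        grid = np.linspace(0.1, 200, 40)
        pops = state_populations(m, grid)[1]
        assert np.all(np.diff(pops) > 0)

    def test_sum_to_one_at_high_dimension(self):
        rng = np.random.default_rng(7)
        m = random_ensemble(rng, 6)
        pops = state_populations(m, np.linspace(0.1, 200, 11))
        assert np.allclose(pops.sum(axis=0), 1.0, atol=1e-12)

    @given(offset=st.floats(-1e5, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_gauge_invariance(self, offset):
        rng = np.random.default_rng(11)
        m = random_ensemble(rng, 3)
        shifted = EnsembleModel(
            tuple(
                ThermoState(s.label, s.shift, s.G0 + offset, s.V0, s.beta0)
                for s in m.states
            ),
            temperature=m.temperature,
            p0=m.p0,
        )
        assert state_populations(shifted, 100.0) == pytest.approx(
            state_populations(m, 100.0), abs=1e-12
        )

    def test_overflow_safe_normalization(self):
        # naive exponentiation of -G/RT would overflow at G ~ -1e6 J/mol
        m = EnsembleModel(
            (
                ThermoState("deep", shift=1.0, G0=-1.0e6),
                ThermoState("high", shift=2.0, G0=1.0e6),
            )
        )
        pops = state_populations(m, 0.1)
        assert np.all(np.isfinite(pops))
        assert pops == pytest.approx([1.0, 0.0], abs=1e-300)

    def test_nonfinite_exponent_names_state(self):
        m = EnsembleModel(
            (
                ThermoState("ok", shift=1.0),
                ThermoState("bad", shift=2.0, V0=1e308),
            )
        )
        with pytest.raises(ValueError, match="bad"):
            state_populations(m, 200.0)


class TestEnsembleShift:
    def test_equal_population_average(self):
        m = EnsembleModel(
            (ThermoState("a", shift=8.0), ThermoState("b", shift=9.0))
        )
        assert ensemble_shift(m, 0.1) == pytest.approx(8.5, abs=1e-14)

    def test_dominant_state_limit(self):
        m = EnsembleModel(
            (
                ThermoState("dominant", shift=8.25),
                ThermoState("rare", shift=12.0, G0=50_000.0),
            )
        )
        assert ensemble_shift(m, 0.1) == pytest.approx(8.25, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_ensemble(rng, int(rng.integers(2, 5)))
        for p in (0.1, 37.0, 120.0, 200.0):
            assert ensemble_shift(m, p) == pytest.approx(
                brute_force_shift(m, p), rel=1e-13
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_by_state_shifts(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = random_ensemble(rng, 4)
        shifts = [s.shift for s in m.states]
        vals = ensemble_shift(m, np.linspace(0.1, 200, 25))
        assert np.all(vals >= min(shifts) - 1e-12)
        assert np.all(vals <= max(shifts) + 1e-12)

    def test_monotone_when_single_volume_sign_and_no_beta(self):
        m = EnsembleModel(
            (
                ThermoState("a", shift=7.0),
                ThermoState("b", shift=9.0, G0=1500.0, V0=-35.0),
            )
        )
        vals = ensemble_shift(m, np.linspace(0.1, 200, 50))
        assert np.all(np.diff(vals) > 0)


class TestTaylorCoefficients:
    def test_equal_shifts_give_zero_coefficients(self):
        m = EnsembleModel(
            (
                ThermoState("a", shift=5.0, G0=0.0, V0=-30.0, beta0=0.1),
                ThermoState("b", shift=5.0, G0=2000.0, V0=40.0, beta0=-0.2),
            )
        )
        tc = taylor_coefficients(m)
        assert tc.B1 == pytest.approx(0.0, abs=1e-12)
        assert tc.B2 == pytest.approx(0.0, abs=1e-12)
        assert tc.delta0 == pytest.approx(5.0)

    def test_two_state_equal_population_closed_form(self):
        # B1 = -ddelta * f(1-f) * dV / RT per MPa, f = 1/2
        ddelta, dv, temp = 1.0, -41.4, 283.0
        m = EnsembleModel(
            (
                ThermoState("a", shift=8.0),
                ThermoState("b", shift=8.0 + ddelta, V0=dv),
            ),
            temperature=temp,
        )
        rt = GAS_CONSTANT * temp
        expected_b1 = -ddelta * 0.25 * dv / rt * 1e3
        tc = taylor_coefficients(m)
        assert tc.B1 == pytest.approx(expected_b1, rel=1e-12)
        b1_num, _ = numeric_taylor(m)
        assert tc.B1 == pytest.approx(b1_num, rel=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_numeric_differentiation(self, seed):
        rng = np.random.default_rng(2000 + seed)
        m = random_ensemble(rng, int(rng.integers(2, 4)))
        tc = taylor_coefficients(m)
        b1_num, b2_num = numeric_taylor(m)
        # abs floor covers coefficients passing through zero, where the
        # finite-difference oracle's own roundoff dominates any relative scale
        assert tc.B1 == pytest.approx(b1_num, rel=1e-6, abs=1e-6)
        assert tc.B2 == pytest.approx(b2_num, rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_local_quadratic_tracks_ensemble(self, seed):
        # over [p0, p0 + 10 MPa] the Taylor quadratic is o(dp^2)-close
        rng = np.random.default_rng(3000 + seed)
        m = mild_ensemble(rng, 3)
        tc = taylor_coefficients(m)
        grid = np.linspace(m.p0, m.p0 + 10.0, 30)
        dev = np.abs(predict_shift(tc, grid) - ensemble_shift(m, grid))
        assert dev.max() < 1e-4

    def test_delta0_equals_ensemble_shift_at_p0(self, two_state_model):
        tc = taylor_coefficients(two_state_model)
        assert tc.delta0 == pytest.approx(
            ensemble_shift(two_state_model, two_state_model.p0), rel=1e-14
        )


class TestEnsembleModelValidation:
    def test_single_state_rejected(self):
        with pytest.raises(ValueError, match="two states"):
            EnsembleModel((ThermoState("only", shift=1.0),))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            EnsembleModel(
                (ThermoState("x", shift=1.0), ThermoState("x", shift=2.0))
            )

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            EnsembleModel(
                (ThermoState("a", shift=1.0), ThermoState("b", shift=2.0)),
                temperature=0.0,
            )

    def test_nonfinite_state_field_rejected(self):
        with pytest.raises(ValueError, match="shift"):
            ThermoState("bad", shift=float("inf"))

    def test_json_round_trip(self, two_state_model, tmp_path):
        path = tmp_path / "model.json"
        two_state_model.to_json(path)
        again = EnsembleModel.from_json(path)
        assert again == two_state_model


class TestFastExchange:
    def test_fast_case(self):
        chk = check_fast_exchange(100.0, 1e-5)
        assert chk.product == pytest.approx(1e-3)
        assert chk.fast

    def test_slow_case(self):
        chk = check_fast_exchange(1e4, 1e-3)
        assert chk.product == pytest.approx(10.0)
        assert not chk.fast

    def test_zero_tau_degenerate(self):
        chk = check_fast_exchange(1e6, 0.0)
        assert chk.product == 0.0
        assert chk.fast

    def test_threshold_configurable_and_reported(self):
        chk = check_fast_exchange(100.0, 1e-3, threshold=0.5)
        assert chk.threshold == 0.5
        assert chk.fast  # 0.1 < 0.5

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            check_fast_exchange(1.0, -1.0)

    def test_sign_of_delta_omega_irrelevant(self):
        assert check_fast_exchange(-100.0, 1e-5).product == pytest.approx(1e-3)
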