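"""Thermal performance curves, TSR scaling and Arrhenius loss rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tritherm import (
    ConfigurationError,
    ModelParameters,
    ThermalNiche,
    arrhenius_loss,
    effective_rates,
    rosso_factor,
    scenario_parameterization,
    tsr_length,
)

NICHE = ThermalNiche(5.0, 20.0, 25.0)


class TestRossoFactor:
    @pytest.mark.parametrize(
        "T, expected",
        [
            (20.0, 1.0),  # optimum
            (5.0, 0.0),  # lower boundary
            (25.0, 0.0),  # upper boundary
            (12.5, 0.625),  # interior value, direct arithmetic
            (-40.0, 0.0),
            (60.0, 0.0),
        ],
    )
    def test_reference_values(self, T, expected):
        assert rosso_factor(T, NICHE) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=-20.0, max_value=50.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_maximal_at_optimum(self, T):
        value = rosso_factor(T, NICHE)
        assert 0.0 <= value <= 1.0
        assert value <= rosso_factor(NICHE.topt, NICHE)

    def test_left_skew_of_default_niche(self):
        # the decline above the optimum is steeper than the rise below it
        assert rosso_factor(22.5, NICHE) < rosso_factor(17.5, NICHE)

    def test_shift_moves_the_window(self):
        shifted = NICHE.shifted(-5.0)
        assert rosso_factor(15.0, shifted) == 1.0
        assert rosso_factor(20.0, shifted) == 0.0  # at shifted Tmax

    def test_degenerate_niche_rejected(self):
        with pytest.raises(ConfigurationError):
            ThermalNiche(30.0, 27.0, 25.0)


class TestTsrLength:
    def test_identity_at_reference_and_zero_slope(self):
        assert tsr_length(110.0, 20.0, -0.05) == pytest.approx(110.0)
        assert tsr_length(110.0, 3.0, 0.0) == pytest.approx(110.0)

    def test_five_percent_mass_rule_on_length(self):
        # 300 mm at +5 °C shrinks by the cube-root of the mass reduction
        assert tsr_length(300.0, 25.0, -0.05) == pytest.approx(
            300.0 * math.exp(-0.25 / 3.0), rel=1e-12
        )
        assert tsr_length(300.0, 25.0, -0.05) == pytest.approx(276.0, abs=0.1)

    @given(
        st.floats(min_value=1.0, max_value=500.0),
        st.floats(min_value=-10.0, max_value=40.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_multiplicative_roundtrip(self, l_ref, T):
        scaled = tsr_length(l_ref, T, -0.05)
        # back-transform: scale the result from T to the reference
        back = scaled * math.exp(-(-0.05) * (T - 20.0) / 3.0)
        assert back == pytest.approx(l_ref, rel=1e-12)


class TestArrheniusLoss:
    def test_doubles_mu0_at_optimum_for_any_shift(self):
        for shift in (-8.0, 0.0, 5.0):
            niche = NICHE.shifted(shift)
            assert arrhenius_loss(niche.topt_eff, niche, 5e-3, -0.55) == pytest.approx(
                0.01, rel=1e-12
            )

    def test_strictly_increasing_and_continuous(self):
        ts = np.linspace(-5.0, 40.0, 400)
        vals = [arrhenius_loss(t, NICHE, 5e-3, -0.55) for t in ts]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert max(abs(b - a) for a, b in zip(vals, vals[1:])) < 1e-3

    def test_value_five_degrees_above_optimum(self):
        # mu0*(1+exp(0.55*5/(k*298.15*293.15))), independently evaluated exponent
        k = 8.617e-5
        expected = 5e-3 * (1 + math.exp(0.55 * 5 / (k * 298.15 * 293.15)))
        assert arrhenius_loss(25.0, NICHE, 5e-3, -0.55) == pytest.approx(expected, rel=1e-12)


class TestEffectiveRates:
    def test_baseline_scenario_is_temperature_independent(self, params):
        s1 = scenario_parameterization(1)
        for T in (5.0, 11.3, 20.0, 24.9):
            rb = effective_rates(T, params, s1)
            assert rb.I_T == params.I_topt
            assert rb.G_T == params.G_topt
            assert rb.B_T == params.B_topt
            assert rb.f_T == params.f_topt
            assert rb.mu_C == rb.mu_P == 2 * params.mu0
            assert (rb.lv_T, rb.lmat_T, rb.linf_T) == (params.lv, params.lmat, params.linf)

    @pytest.mark.parametrize("sid", range(1, 11))
    def test_all_scenarios_coincide_at_the_optimum(self, params, sid):
        ref = effective_rates(20.0, params, scenario_parameterization(1))
        rb = effective_rates(20.0, params, scenario_parameterization(sid))
        for fld in ("I_T", "G_T", "B_T", "f_T", "mu_C", "mu_P", "lv_T", "lmat_T", "linf_T"):
            assert getattr(rb, fld) == pytest.approx(getattr(ref, fld), rel=1e-14)

    def test_predator_shift_to_boundary_zeroes_response(self, params):
        s12 = scenario_parameterization(12, predator_shift=-5.0)
        rb = effective_rates(20.0, params, s12)
        assert rb.f_T == 0.0  # environmental T at the shifted Tmax

    def test_scenario_flags_scale_expected_rates(self, params):
        rb = effective_rates(13.0, params, scenario_parameterization(2))
        factor = rosso_factor(13.0, params.consumer_niche)
        assert rb.I_T == pytest.approx(params.I_topt * factor)
        assert rb.f_T == params.f_topt  # predator untouched in scenario 2
        assert rb.mu_P == 2 * params.mu0

    def test_tsr_scenarios_scale_only_their_lengths(self, params):
        rb5 = effective_rates(25.0, params, scenario_parameterization(5))
        shrink = math.exp(-0.05 * 5 / 3)
        assert rb5.lmat_T == pytest.approx(params.lmat * shrink)
        assert rb5.linf_T == pytest.approx(params.linf * shrink)
        assert rb5.lv_T == params.lv
        rb6 = effective_rates(25.0, params, scenario_parameterization(6))
        assert rb6.lv_T == pytest.approx(params.lv * shrink)
        assert rb6.lmat_T == params.lmat

    def test_degenerate_tsr_ordering_is_flagged(self):
        params = ModelParameters(beta=-3.0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            rb = effective_rates(25.0, params, scenario_parameterization(6))
        assert rb.degenerate


class TestScenarioMapping:
    def test_baseline_has_no_temperature_dependence(self):
        spec = scenario_parameterization(1)
        assert not any(
            [
                spec.consumer_rates_thermal,
                spec.predator_rates_thermal,
                spec.tsr_lmat,
                spec.tsr_linf,
                spec.tsr_lv,
            ]
        )
        assert spec.consumer_shift == spec.predator_shift == 0.0

    def test_tsr_only_scenarios(self):
        s5 = scenario_parameterization(5)
        assert (s5.tsr_lmat, s5.tsr_linf, s5.tsr_lv) == (True, True, False)
        assert not s5.consumer_rates_thermal and not s5.predator_rates_thermal
        s9 = scenario_parameterization(9)
        assert s9.predator_rates_thermal and s9.tsr_lv
        assert not s9.consumer_rates_thermal and not s9.tsr_lmat

    def test_shift_only_allowed_for_mismatch_scenarios(self):
        with pytest.raises(ConfigurationError):
            scenario_parameterization(3, predator_shift=-2.0)
        with pytest.raises(ConfigurationError):
            scenario_parameterization(10, consumer_shift=1.0)
        assert scenario_parameterization(11, consumer_shift=-4.0).consumer_shift == -4.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigurationError):
            scenario_parameterization(13)
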