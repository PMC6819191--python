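"""Constitutive model: forward evaluation, fitting, relations, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ivdratchet as ivr
from ivdratchet import URMKParams
from ivdratchet.model import (
    DEFAULT_ALPHA_RELATION,
    DEFAULT_BETA_RELATION,
    ExtrapolationError,
    ParameterDomainError,
    evolution_fraction,
)


class TestSaturatedStrain:
    def test_identity_case(self):
        assert ivr.saturated_strain(0.59, k_r=1.0, e_rth=0.0) == pytest.approx(0.59)

    def test_threshold_and_clamp(self):
        assert ivr.saturated_strain(0.5, 1.0, 0.5) == 0.0
        assert ivr.saturated_strain(0.3, 1.0, 0.5) == 0.0  # clamped below threshold

    def test_invalid_coefficient(self):
        with pytest.raises(ValueError):
            ivr.saturated_strain(1.0, k_r=0.0)


class TestEvolutionParameters:
    def test_alpha_at_highest_stress(self):
        assert ivr.evolution_alpha(1.76) == pytest.approx(72.170, abs=5e-4)

    def test_beta_at_highest_stress(self):
        assert ivr.evolution_beta(1.76) == pytest.approx(0.0684, abs=5e-5)

    def test_zero_slope_gives_constant(self):
        vals = ivr.evolution_alpha(np.array([0.5, 1.5, 2.5]), a0=10.0, a1=0.0)
        np.testing.assert_allclose(vals, 10.0)

    def test_nonpositive_beta_warns(self):
        with pytest.warns(RuntimeWarning):
            ivr.evolution_beta(4.0)


class TestEvaluate:
    def test_first_cycle_hand_oracle(self):
        # K·X_SR·(1 − 1/alpha) at e_r = 1.76, K = 0.01
        params = URMKParams(K=0.01, k_r=1.0, e_rth=0.0)
        assert ivr.evaluate(1, 1.76, params) == pytest.approx(0.017356, abs=1e-6)

    def test_saturation_limit(self):
        params = URMKParams()
        assert ivr.evaluate(1e9, 1.76, params) == pytest.approx(
            0.01 * 1.76, rel=1e-6
        )
        x = ivr.evaluate(np.arange(1, 500), 1.76, params)
        assert np.all(x <= 0.01 * 1.76)

    def test_zero_amplitude_is_identically_zero(self):
        params = URMKParams(K=0.0)
        np.testing.assert_array_equal(ivr.evaluate(np.arange(1, 10), 1.0, params), 0.0)

    def test_cycle_below_one_rejected(self):
        with pytest.raises(ValueError):
            ivr.evaluate(0, 1.0, URMKParams())

    def test_alpha_at_most_one_rejected(self):
        with pytest.raises(ParameterDomainError):
            evolution_fraction(5, alpha=0.9, beta=0.1)

    @given(e_r=st.floats(0.3, 3.0))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_strictly_increasing_with_decreasing_increments(self, e_r):
        """Evolution is strictly increasing in N with strictly positive,
        decreasing per-cycle increments (sharp rise then quasi-steady)."""
        x = ivr.evaluate(np.arange(1, 200), e_r, URMKParams())
        inc = np.diff(x)
        assert np.all(inc > 0)
        assert np.all(np.diff(inc) < 0)

    def test_increasing_in_stress_above_threshold(self):
        params = URMKParams()
        N = np.arange(1, 401)
        lo = ivr.evaluate(N, 0.59, params)
        hi = ivr.evaluate(N, 1.18, params)
        assert np.all(hi > lo)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(K=-0.01),
            dict(k_r=0.0),
            dict(e_rth=-1.0),
            dict(alpha=0.5),
            dict(beta=1.5),
            dict(form_id="nope"),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises((ValueError, KeyError)):
            URMKParams(**kwargs)

    def test_json_round_trip(self, tmp_path):
        params = URMKParams(K=0.0093, alpha=60.0, beta=0.09)
        path = tmp_path / "params.json"
        ivr.params_to_json(params, path)
        assert ivr.params_from_json(path) == params


class TestFormRegistry:
    def test_alternative_form_dispatches(self):
        default = evolution_fraction(10, 60.0, 0.1, "saturating_power")
        alt = evolution_fraction(10, 60.0, 0.1, "exponential_rate")
        assert default != alt
        assert 0 < alt < 1

    def test_unknown_form_rejected(self):
        with pytest.raises(KeyError):
            evolution_fraction(10, 60.0, 0.1, "unknown")


class TestFitSingleCurve:
    @pytest.mark.parametrize("e_r", [0.59, 1.18, 1.76])
    def test_noise_free_round_trip(self, e_r, cycle_grid):
        params = URMKParams()
        y = ivr.evaluate(cycle_grid, e_r, params)
        fit = ivr.fit_single_curve((cycle_grid, y))
        assert fit.amplitude == pytest.approx(0.01 * e_r, rel=1e-3)
        assert fit.alpha == pytest.approx(ivr.evolution_alpha(e_r), rel=1e-3)
        assert fit.beta == pytest.approx(ivr.evolution_beta(e_r), rel=1e-3)
        assert fit.pearson_r > 0.999999

    def test_constant_curve_degenerate(self, cycle_grid):
        fit = ivr.fit_single_curve((cycle_grid, np.full(cycle_grid.size, 0.017)))
        assert fit.degenerate
        assert fit.amplitude == pytest.approx(0.017)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            ivr.fit_single_curve((np.arange(1, 6), np.linspace(0, 1, 5)))

    def test_metadata_carried_from_curve(self, cycle_grid):
        y = ivr.evaluate(cycle_grid, 1.18, URMKParams())
        curve = ivr.RatchetingCurve(
            cycle_grid, y, ivr.ratcheting_rate(y, cycle_grid),
            stress_variation=1.18, stress_rate=0.59, segment="L5-6",
        )
        fit = ivr.fit_single_curve(curve)
        assert fit.stress_variation == 1.18
        assert fit.segment == "L5-6"


class TestFitK:
    def test_exact_amplitudes_recover_K(self):
        e_r = [0.59, 1.18, 1.76]
        amps = [0.0093 * e for e in e_r]
        assert ivr.fit_K(amps, e_r) == pytest.approx(0.0093, rel=1e-12)

    def test_generated_with_default_K(self, cycle_grid):
        params = URMKParams()
        fits = [
            ivr.fit_single_curve((cycle_grid, ivr.evaluate(cycle_grid, e, params)))
            for e in (0.59, 1.18, 1.76)
        ]
        K = ivr.fit_K([f.amplitude for f in fits], [0.59, 1.18, 1.76])
        assert K == pytest.approx(0.01, abs=1e-4)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            ivr.fit_K([0.01], [1.0])

    def test_all_subthreshold_rejected(self):
        with pytest.raises(ValueError):
            ivr.fit_K([0.0, 0.0], [0.1, 0.2], k_r=1.0, e_rth=0.5)


class TestParameterRelations:
    def test_recovery_from_exact_relations(self):
        records = [
            (e, ivr.evolution_alpha(e), ivr.evolution_beta(e))
            for e in (0.59, 1.18, 1.76)
        ]
        rel = ivr.fit_parameter_relations(records)
        assert rel.alpha_intercept == pytest.approx(DEFAULT_ALPHA_RELATION[0], rel=1e-6)
        assert rel.alpha_slope == pytest.approx(DEFAULT_ALPHA_RELATION[1], rel=1e-6)
        assert rel.beta_intercept == pytest.approx(DEFAULT_BETA_RELATION[0], rel=1e-6)
        assert rel.beta_slope == pytest.approx(DEFAULT_BETA_RELATION[1], rel=1e-6)
        assert rel.alpha_r_squared == pytest.approx(1.0)

    def test_duplicate_stresses_rejected(self):
        with pytest.raises(ValueError):
            ivr.fit_parameter_relations([(1.0, 60.0, 0.1), (1.0, 61.0, 0.09)])


class TestPredict:
    def test_training_stress_matches_forward_model(self, cycle_grid):
        params = URMKParams()
        curve = ivr.predict(1.18, cycle_grid)
        np.testing.assert_allclose(
            curve.ratcheting_strain, ivr.evaluate(cycle_grid, 1.18, params), rtol=1e-12
        )

    def test_interpolated_stress_lies_between_neighbours(self, cycle_grid):
        lo = ivr.predict(0.59, cycle_grid).ratcheting_strain
        mid = ivr.predict(0.88, cycle_grid).ratcheting_strain
        hi = ivr.predict(1.18, cycle_grid).ratcheting_strain
        assert np.all(lo < mid) and np.all(mid < hi)
        assert np.all(np.diff(mid) > 0)  # monotone increasing output

    def test_beta_extrapolation_rejected(self, cycle_grid):
        # 0.13 - 0.035·e_r <= 0 for e_r >= ~3.714 MPa
        with pytest.raises(ExtrapolationError):
            ivr.predict(3.8, cycle_grid)

    def test_outside_training_band_warns(self, cycle_grid):
        rel = ivr.ParameterRelations(training_stresses=(0.59, 1.18, 1.76))
        with pytest.warns(RuntimeWarning):
            ivr.predict(3.0, cycle_grid, rel)


class TestFitConditions:
    def _curves(self, cycle_grid, stresses=(0.59, 1.18, 1.76)):
        params = URMKParams()
        out = []
        for e in stresses:
            y = ivr.evaluate(cycle_grid, e, params)
            out.append(
                ivr.RatchetingCurve(
                    cycle_grid, y, ivr.ratcheting_rate(y, cycle_grid),
                    stress_variation=e, stress_rate=0.59,
                )
            )
        return out

    def test_full_recovery(self, cycle_grid):
        result = ivr.fit_conditions(self._curves(cycle_grid))
        assert result.K_overall == pytest.approx(0.01, abs=1e-4)
        assert result.relations.alpha_intercept == pytest.approx(
            DEFAULT_ALPHA_RELATION[0], rel=1e-3
        )
        fitted = result.params()
        assert fitted.K == pytest.approx(0.01, abs=1e-4)
        assert 0.59 in result.K_by_rate

    def test_single_stress_warns_and_skips_regressions(self, cycle_grid):
        with pytest.warns(RuntimeWarning):
            result = ivr.fit_conditions(self._curves(cycle_grid, stresses=(1.18,)))
        assert result.K_overall is None
        assert result.relations is None
        with pytest.raises(ValueError):
            result.params()
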