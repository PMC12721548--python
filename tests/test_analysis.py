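"""ICER arithmetic, price simulation, tornado, PSA, and acceptability curves."""

import numpy as np
import pandas as pd
import pytest
import yaml

from pscea import (
    CEResult,
    base_case,
    ceac,
    ceac_crossing,
    load_parameters,
    owsa,
    price_discount_analysis,
    psa,
    threshold_price,
)
from pscea.analysis import PSADraws, _moment_matched_sampler
from pscea.params import ParameterValue


def reported_base(params) -> CEResult:
    r = params.reported
    return CEResult(r.cost_treatment, r.cost_control, r.qaly_treatment, r.qaly_control)


class TestICER:
    def test_published_decomposition_identity(self, params):
        res = CEResult.from_increments(74616.56, 0.21)
        assert res.icer == pytest.approx(355316.95, abs=0.01)
        assert reported_base(params).icer == pytest.approx(355316.95, abs=0.01)

    def test_identical_arms_flagged(self):
        res = CEResult(100.0, 100.0, 1.0, 1.0)
        assert res.delta_cost == 0.0
        assert res.delta_qaly == 0.0
        assert res.dominance == "tie"
        assert np.isnan(res.icer)

    def test_dominant_flag(self):
        res = CEResult(90.0, 100.0, 1.2, 1.0)
        assert res.dominance == "dominant"
        assert res.icer < 0

    def test_dominated_flag(self):
        res = CEResult(110.0, 100.0, 0.9, 1.0)
        assert res.dominance == "dominated"


class TestPriceSimulation:
    FRACTIONS = (0.9, 0.8, 0.7, 0.68, 0.67, 0.6)
    PUBLISHED = (334729.95, 314142.90, 293555.90, 289438.52, 287379.81, 272968.90)

    def test_full_price_reproduces_base(self, params):
        base = reported_base(params)
        table = price_discount_analysis(base, params.soca_calibrated_total(), [1.0])
        assert table["icer"].iloc[0] == pytest.approx(base.icer, rel=1e-12)

    def test_published_discount_rows(self, params):
        base = reported_base(params)
        table = price_discount_analysis(
            base, params.soca_calibrated_total(), self.FRACTIONS
        )
        for got, want in zip(table["icer"], self.PUBLISHED):
            assert got == pytest.approx(want, rel=1e-3)

    def test_seventy_percent_reduction(self, params):
        base = reported_base(params)
        table = price_discount_analysis(base, params.soca_calibrated_total(), [0.3])
        assert table["icer"].iloc[0] == pytest.approx(211207.90, rel=1e-3)

    def test_icer_affine_in_fraction(self, params):
        base = reported_base(params)
        f = np.linspace(0.2, 1.0, 9)
        table = price_discount_analysis(base, params.soca_calibrated_total(), f)
        slopes = np.diff(table["icer"]) / np.diff(table["fraction"])
        assert np.allclose(slopes, slopes[0], rtol=1e-9)

    def test_out_of_range_fraction_rejected(self, params):
        base = reported_base(params)
        with pytest.raises(ValueError):
            price_discount_analysis(base, 1000.0, [1.2])
        with pytest.raises(ValueError):
            price_discount_analysis(base, 1000.0, [0.0])


class TestThresholdPrice:
    def test_three_gdp_threshold_near_77(self, params):
        res = threshold_price(
            reported_base(params),
            params.soca_calibrated_total(),
            unit_price=115.0,
            wtp=params.wtp,
        )
        assert res.feasible
        assert res.price_per_mg == pytest.approx(77.0, abs=1.0)
        assert res.fraction == pytest.approx(0.670, abs=0.01)

    def test_wtp_at_base_icer_needs_no_discount(self, params):
        base = reported_base(params)
        res = threshold_price(
            base, params.soca_calibrated_total(), 115.0, wtp=base.icer
        )
        assert res.feasible
        assert res.fraction == pytest.approx(1.0, abs=1e-9)

    def test_tiny_wtp_is_infeasible(self, params):
        res = threshold_price(
            reported_base(params), params.soca_calibrated_total(), 115.0, wtp=1.0
        )
        assert not res.feasible
        assert res.price_per_mg is None


def _zero_width(params, tmp_path):
    doc = params.to_dict()
    for row in doc["parameters"].values():
        row["low"] = row["high"] = row["base"]
    path = tmp_path / "frozen.yaml"
    path.write_text(yaml.safe_dump(doc))
    return load_parameters(path)


class TestOWSA:
    def test_zero_width_bounds_give_zero_span(self, params, tmp_path):
        frozen = _zero_width(params, tmp_path)
        table = owsa(frozen)
        assert np.allclose(table["span"], 0.0, atol=1e-9)
        base = base_case(frozen).icer
        assert np.allclose(table["icer_at_low"], base, rtol=1e-12)

    def test_soca_price_span_follows_linearity(self, params):
        table = owsa(params, parameters=["cost_socazolimab_per_mg"])
        base = base_case(params)
        soca_total = params.soca_calibrated_total()
        expected = (138.0 - 92.0) / 115.0 * soca_total / base.delta_qaly
        assert table["span"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_sorted_by_span(self, params):
        table = owsa(params)
        assert list(table["span"]) == sorted(table["span"], reverse=True)

    def test_discount_rate_varied_zero_to_eight_percent(self, params):
        table = owsa(params, parameters=["discount_rate"])
        assert table["low"].iloc[0] == 0.0
        assert table["high"].iloc[0] == 0.08
        assert table["span"].iloc[0] > 0


class TestPSA:
    def test_reproducible_with_seed(self, params):
        d1 = psa(params, n=50, seed=123)
        d2 = psa(params, n=50, seed=123)
        pd.testing.assert_frame_equal(d1.draws, d2.draws)

    def test_degenerate_distributions_reproduce_base_case(self, params, tmp_path):
        frozen = _zero_width(params, tmp_path)
        draws = psa(frozen, n=5, seed=1)
        base = base_case(frozen)
        assert np.allclose(draws.draws["cost_treatment"], base.cost_treatment)
        assert np.allclose(draws.draws["qaly_control"], base.qaly_control)

    def test_gamma_moment_matching(self):
        pv = ParameterValue(115.0, 92.0, 138.0, "gamma", "cost")
        rng = np.random.default_rng(0)
        draws = _moment_matched_sampler("x", pv, rng)(200_000)
        assert draws.mean() == pytest.approx(115.0, rel=0.005)
        assert draws.std() == pytest.approx((138.0 - 92.0) / 3.92, rel=0.02)
        assert np.all(draws > 0)

    def test_beta_support_violation_names_parameter(self):
        pv = ParameterValue(1.5, 1.2, 1.8, "beta", "utility")
        with pytest.raises(ValueError, match="bad_param"):
            _moment_matched_sampler("bad_param", pv, np.random.default_rng(0))

    def test_mean_preserving_sampling_recovers_base_case(self, params):
        """PSA means converge to the base case under mean-preserving draws."""
        draws = psa(params, n=50_000, seed=31)
        base = base_case(params)
        assert draws.draws["cost_treatment"].mean() == pytest.approx(
            base.cost_treatment, rel=0.02
        )
        assert draws.draws["cost_control"].mean() == pytest.approx(
            base.cost_control, rel=0.02
        )
        assert draws.draws["qaly_treatment"].mean() == pytest.approx(
            base.qaly_treatment, rel=0.02
        )
        assert draws.draws["qaly_control"].mean() == pytest.approx(
            base.qaly_control, rel=0.02
        )


def _draws_from(dc, dq):
    frame = pd.DataFrame(
        {
            "cost_treatment": dc,
            "cost_control": np.zeros_like(dc),
            "qaly_treatment": dq,
            "qaly_control": np.zeros_like(dq),
        }
    )
    return PSADraws(draws=frame, seed=0, n=len(frame))


class TestCEAC:
    def test_dominant_draws_always_accepted(self):
        draws = _draws_from(np.array([-10.0, -5.0]), np.array([0.1, 0.2]))
        curves = ceac(draws, [0.0, 1e5, 6e5])
        assert np.all(curves["p_treatment"] == 1.0)

    def test_zero_wtp_reduces_to_cost_comparison(self):
        dc = np.array([-1.0, 2.0, -3.0, 4.0])
        draws = _draws_from(dc, np.ones(4))
        curves = ceac(draws, [0.0])
        assert curves["p_treatment"].iloc[0] == pytest.approx(np.mean(dc < 0))

    def test_curves_sum_to_one_and_monotone(self, params):
        draws = psa(params, n=400, seed=17)
        assert np.all(draws.delta_qaly > 0)
        curves = ceac(draws)
        assert np.allclose(curves["p_treatment"] + curves["p_control"], 1.0)
        assert np.all(np.diff(curves["p_treatment"]) >= -1e-12)

    def test_tie_goes_to_control(self):
        draws = _draws_from(np.array([0.0]), np.array([0.0]))
        curves = ceac(draws, [1e5])
        assert curves["p_treatment"].iloc[0] == 0.0

    def test_crossing_linear_interpolation(self):
        curves = pd.DataFrame(
            {"wtp": [300_000.0, 500_000.0], "p_treatment": [0.4, 0.6]}
        )
        assert ceac_crossing(curves) == pytest.approx(400_000.0)

    def test_no_crossing_flagged(self):
        curves = pd.DataFrame({"wtp": [0.0, 1e5], "p_treatment": [0.1, 0.2]})
        assert ceac_crossing(curves) is None
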