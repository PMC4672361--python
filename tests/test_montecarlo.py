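"""Monte Carlo propagation, distribution fitting and sensitivity."""

import math

import numpy as np
import pytest

from pahrisk import (DistributionSpec, ExposureParameterSet, fit_cw_distribution,
                     merge_results, sample_parameters, sensitivity,
                     simulate_risk, total_risk)

POINT_SPECS = [DistributionSpec("Cw", "point", {"value": 10.0})]


class TestDistributionSpec:
    def test_lognormal_log_params_roundtrip(self):
        spec = DistributionSpec("Cw", "lognormal", {"mean": 10.0, "cv": 2.0})
        mu, sigma = spec.log_params()
        assert math.exp(mu + sigma ** 2 / 2) == pytest.approx(10.0)
        assert math.sqrt(math.expm1(sigma ** 2)) == pytest.approx(2.0)

    @pytest.mark.parametrize("family,params", [
        ("lognormal", {"mean": -1.0, "cv": 0.2}),
        ("lognormal", {"mean": 10.0, "cv": 0.0}),
        ("uniform", {"low": 5.0, "high": 5.0}),
        ("point", {}),
    ])
    def test_invalid_specs_rejected(self, family, params):
        with pytest.raises(ValueError):
            DistributionSpec("Cw", family, params)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            DistributionSpec("Kp", "point", {"value": 1.2})


class TestSampling:
    def test_point_specs_draw_constants(self):
        draws = sample_parameters([DistributionSpec("BW", "point", {"value": 62.1})],
                                  n=100, seed=0)
        assert (draws["BW"] == 62.1).all()

    def test_uniform_mean_within_three_se(self):
        spec = DistributionSpec("ED", "uniform", {"low": 0.0, "high": 70.0})
        draws = sample_parameters([spec], n=10_000, seed=1)["ED"]
        se = 70.0 / math.sqrt(12) / math.sqrt(10_000)
        assert abs(draws.mean() - 35.0) < 3 * se
        assert draws.min() >= 0.0 and draws.max() <= 70.0

    def test_same_seed_reproduces_table(self):
        specs = [DistributionSpec("Cw", "lognormal", {"mean": 10.0, "cv": 1.0}),
                 DistributionSpec("ED", "uniform", {"low": 0.0, "high": 70.0})]
        a = sample_parameters(specs, n=500, seed=7)
        b = sample_parameters(specs, n=500, seed=7)
        assert a.equals(b)

    def test_undrawn_parameters_held_at_defaults(self):
        draws = sample_parameters([], n=10, seed=0)
        defaults = ExposureParameterSet()
        assert (draws["IR"] == defaults.ir).all()
        assert (draws["SA"] == defaults.sa).all()


class TestFitting:
    def test_lognormal_recovery_from_its_own_draws(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(math.log(10.0), math.log(2.0), 10_000)
        spec = fit_cw_distribution(x)
        assert spec.family == "lognormal"
        assert spec.geometric_mean == pytest.approx(10.0, rel=0.05)

    def test_single_candidate_is_returned_regardless(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1.0, 5.0, 200)   # not lognormal at all
        spec = fit_cw_distribution(x, candidates=("lognormal",))
        assert spec.family == "lognormal"

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cw_distribution([5.0] * 50)

    def test_too_few_or_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_cw_distribution([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="positive"):
            fit_cw_distribution([1.0] * 9 + [-1.0])


class TestSimulation:
    def test_degenerate_run_reproduces_deterministic_risk(self):
        result = simulate_risk(POINT_SPECS, n=1000, seed=0)
        det = total_risk(ExposureParameterSet(cw_ng_l=10.0)).cr_total
        assert result.mean == pytest.approx(det, rel=1e-12)
        assert result.se == 0.0
        assert result.p5 == result.p50 == result.p95 == pytest.approx(det, rel=1e-12)

    def test_mean_risk_matches_linearity_in_cw(self):
        # risk is linear in Cw, so E[risk] = risk at E[Cw]
        specs = [DistributionSpec("Cw", "lognormal", {"mean": 10.0, "cv": 1.0})]
        result = simulate_risk(specs, n=200_000, seed=5)
        det = total_risk(ExposureParameterSet(cw_ng_l=10.0)).cr_total
        assert result.mean == pytest.approx(det, rel=0.02)

    def test_single_draw_summaries_collapse(self):
        result = simulate_risk(POINT_SPECS, n=1, seed=0)
        assert result.mean == result.p5 == result.p50 == result.p95
        assert result.se == 0.0

    def test_probabilistic_mean_exceeds_median_parameter_risk(self):
        # lognormal Cw and uniform ED: the mean of the risk distribution
        # sits above the risk evaluated at median parameters
        specs = [DistributionSpec("Cw", "lognormal", {"mean": 10.0, "cv": 1.5}),
                 DistributionSpec("ED", "uniform", {"low": 0.0, "high": 70.0})]
        result = simulate_risk(specs, n=10_000, seed=9)
        median_cw = DistributionSpec("Cw", "lognormal",
                                     {"mean": 10.0, "cv": 1.5}).geometric_mean
        det = total_risk(ExposureParameterSet(cw_ng_l=median_cw, ed=35.0)).cr_total
        assert result.mean > det

    def test_se_shrinks_as_root_n(self):
        specs = [DistributionSpec("Cw", "lognormal", {"mean": 10.0, "cv": 1.0})]
        ses = [simulate_risk(specs, n=n, seed=13).se for n in (100, 1000, 10_000)]
        for se_small, se_big, factor in zip(ses, ses[1:], (math.sqrt(10),) * 2):
            assert se_small / se_big == pytest.approx(factor, rel=0.5)

    def test_merge_preserves_pooled_mean(self):
        a = simulate_risk([DistributionSpec("Cw", "point", {"value": 5.0})], n=10, seed=0)
        b = simulate_risk([DistributionSpec("Cw", "point", {"value": 15.0})], n=10, seed=0)
        merged = merge_results(a, b)
        assert merged.mean == pytest.approx((a.mean + b.mean) / 2)
        assert merged.n == 20


class TestSensitivity:
    def test_only_cw_varied_is_perfectly_rank_correlated(self):
        specs = [DistributionSpec("Cw", "lognormal", {"mean": 10.0, "cv": 1.0})]
        result = simulate_risk(specs, n=500, seed=2)
        assert result.sensitivity["Cw"] == pytest.approx(1.0)
        assert math.isnan(result.sensitivity["BW"])

    def test_only_bw_varied_is_perfectly_anticorrelated(self):
        specs = [DistributionSpec("BW", "lognormal", {"mean": 62.1, "cv": 0.2})]
        result = simulate_risk(specs, ExposureParameterSet(cw_ng_l=10.0),
                               n=500, seed=2)
        assert result.sensitivity["BW"] == pytest.approx(-1.0)

    def test_larger_relative_spread_dominates_ranking(self):
        specs = [DistributionSpec("Cw", "lognormal", {"mean": 10.0, "cv": 1.5}),
                 DistributionSpec("ED", "uniform", {"low": 0.0, "high": 70.0})]
        result = simulate_risk(specs, n=10_000, seed=3)
        assert abs(result.sensitivity["Cw"]) > abs(result.sensitivity["ED"])

    def test_absent_parameter_has_negligible_correlation(self):
        # a parameter that varies but is excluded from the risk formula
        # has rank correlation around zero; here every *constant* one is NaN
        # and the varied irrelevant analogue is emulated by shuffling
        rng = np.random.default_rng(8)
        specs = [DistributionSpec("Cw", "lognormal", {"mean": 10.0, "cv": 1.0})]
        result = simulate_risk(specs, n=10_000, seed=4)
        decoy = rng.normal(size=result.n)
        import pandas as pd
        draws = pd.DataFrame({"decoy": decoy, "Cw": result.risks})
        rho = sensitivity(draws, result.risks)["decoy"]
        assert abs(rho) < 3 / math.sqrt(result.n)

    def test_all_constant_inputs_rejected(self):
        import pandas as pd
        draws = pd.DataFrame({"A": np.ones(10), "B": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            sensitivity(draws, np.arange(10.0))


def test_median_of_linear_ramp_uses_type7_interpolation():
    from pahrisk.montecarlo import _summarize
    risks = np.arange(1.0, 101.0) * 1e-6
    summary = _summarize(risks, {})
    assert summary.p50 == pytest.approx(50.5e-6)
    assert summary.p5 <= summary.p50 <= summary.p95
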