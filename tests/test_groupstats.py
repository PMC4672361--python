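"""Geometric means, Box-Cox, normality, comparisons, exceedance, correlation."""

import math

import numpy as np
import pytest

from pahrisk import (CHINA_STANDARD, VillageRecord, boxcox_lambda, compare,
                     comparison_table, exceedance_rates, geometric_mean_ci,
                     incidence_mortality_correlation, normality_tests)
from pahrisk.groupstats import AGGREGATE_ROWS
from conftest import make_sample


class TestGeometricMean:
    def test_exp_of_mean_logs(self):
        assert geometric_mean_ci([10.0, 1000.0]).gm == pytest.approx(100.0)

    def test_constant_sample_zero_width_interval(self):
        s = geometric_mean_ci([7.0, 7.0, 7.0])
        assert s.gm == pytest.approx(7.0)
        assert s.ci_low == pytest.approx(7.0)
        assert s.ci_high == pytest.approx(7.0)

    def test_lognormal_simulation_recovers_gm_and_covers(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(math.log(10.0), 1.0, 10_000)
        s = geometric_mean_ci(x)
        assert s.gm == pytest.approx(10.0, rel=0.02)
        assert s.ci_low <= 10.0 <= s.ci_high

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            geometric_mean_ci([1.0, 0.0])

    def test_gm_never_exceeds_arithmetic_mean(self, small_campaign):
        _, samples = small_campaign
        values = [s.conc["Nap"] for s in samples if "Nap" in s.conc]
        assert geometric_mean_ci(values).gm <= np.mean(values)


class TestBoxCox:
    def test_lognormal_data_lambda_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(2.0, 1.0, 5000)
        lam, _ = boxcox_lambda(x)
        assert abs(lam) < 0.15

    def test_normal_data_lambda_near_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(100.0, 5.0, 5000)
        lam, _ = boxcox_lambda(x)
        assert abs(lam - 1.0) < 0.5

    def test_zero_lambda_branch_is_natural_log(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(0.0, 1.0, 200)
        lam, transformed = boxcox_lambda(x)
        if lam == 0.0:
            assert np.allclose(transformed, np.log(x))
        # the limit definition holds regardless of the fitted value
        from scipy import stats
        assert np.allclose(stats.boxcox(x, lmbda=0.0), np.log(x))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            boxcox_lambda([1.0] * 20 + [-2.0])


class TestNormality:
    def test_level_on_normal_samples(self):
        rng = np.random.default_rng(5)
        passes = 0
        for _ in range(20):
            p = normality_tests(rng.normal(size=1000))
            passes += (p["anderson_darling_p"] > 0.05
                       and p["kolmogorov_smirnov_p"] > 0.05)
        assert passes >= 18   # ~level 0.05 per test

    def test_power_on_exponential_samples(self):
        rng = np.random.default_rng(6)
        rejections = 0
        for _ in range(20):
            p = normality_tests(rng.exponential(size=1000))
            rejections += (p["anderson_darling_p"] < 0.05
                           and p["kolmogorov_smirnov_p"] < 0.05)
        assert rejections == 20

    def test_constant_input_gives_nan(self):
        p = normality_tests([3.0] * 20)
        assert math.isnan(p["anderson_darling_p"])


class TestCompare:
    def test_identical_groups_not_significant(self):
        r = compare({"a": range(1, 11), "b": range(1, 11)}, "wilcoxon")
        assert r.p_value == pytest.approx(1.0)
        assert r.marker == ""

    def test_huge_shift_detected(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(10.0, 1.0, 20)
        r = compare({"a": a, "b": b}, "wilcoxon")
        assert r.p_value < 0.01
        assert r.marker == "**"

    def test_kruskal_type_i_error_rate(self):
        rng = np.random.default_rng(8)
        base = rng.lognormal(1.0, 0.5, 30)
        not_significant = 0
        reps = 50
        for _ in range(reps):
            groups = {k: rng.permutation(base)[:10] for k in "abc"}
            r = compare(groups, "kruskal_wallis")
            not_significant += r.p_value >= 0.05
        assert not_significant >= int(0.94 * reps) - 3

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=15), rng.normal(1.0, 1.0, 15)
        p1 = compare({"x": a, "y": b}, "wilcoxon").p_value
        p2 = compare({"x": b, "y": a}, "wilcoxon").p_value
        assert p1 == pytest.approx(p2)

    def test_arity_mismatch_rejected(self):
        three = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        with pytest.raises(ValueError, match="exactly 2"):
            compare(three, "wilcoxon")
        with pytest.raises(ValueError, match="3 or more"):
            compare({"a": [1, 2], "b": [3, 4]}, "kruskal_wallis")


class TestExceedance:
    @pytest.mark.parametrize("count,total,expected", [
        (60, 232, 25.9), (98, 232, 42.2), (63, 232, 27.2), (0, 50, 0.0),
    ])
    def test_fraction_rounding_to_one_decimal_percent(self, count, total, expected):
        samples = ([make_sample({"BaP": 20.0})] * count
                   + [make_sample({"BaP": 1.0})] * (total - count))
        rates = exceedance_rates(samples, CHINA_STANDARD)
        assert rates["BaP"]["count"] == count
        assert rates["BaP"]["total"] == total
        assert rates["BaP"]["percent"] == expected

    def test_fraction_equals_mean_of_flag_column(self, small_campaign, pefs):
        from pahrisk import screen_sample
        _, samples = small_campaign
        rates = exceedance_rates(samples, CHINA_STANDARD, pefs)
        flags = [screen_sample(s, CHINA_STANDARD, pefs) for s in samples]
        for key in ("BaP", "total", "bapeq"):
            assert rates[key]["count"] == sum(f[key] for f in flags)


class TestIncidenceMortality:
    def test_perfect_linearity_gives_r_one(self):
        villages = [VillageRecord(f"V{i}", "risk", 2000, inc, 0.8 * inc)
                    for i, inc in enumerate([100.0, 200.0, 300.0, 400.0])]
        result = incidence_mortality_correlation(villages)
        assert result["r"] == pytest.approx(1.0)

    def test_independent_rates_near_zero(self):
        rng = np.random.default_rng(10)
        villages = [VillageRecord(f"V{i}", "control", 2000,
                                  float(rng.lognormal(5, 0.3)),
                                  float(rng.lognormal(5, 0.3)))
                    for i in range(1000)]
        assert abs(incidence_mortality_correlation(villages)["r"]) < 0.1

    def test_zero_variance_rejected(self):
        villages = [VillageRecord(f"V{i}", "risk", 2000, 100.0, float(m))
                    for i, m in enumerate([80, 90, 100])]
        with pytest.raises(ValueError, match="variance"):
            incidence_mortality_correlation(villages)


class TestComparisonTable:
    def test_table_has_campaign_layout(self, small_campaign, pefs):
        from pahrisk.synthetic import DEFAULT_DETECTION_LIMITS
        _, samples = small_campaign
        table = comparison_table(samples, "season", "water_type", pefs,
                                 "half_dl", DEFAULT_DETECTION_LIMITS)
        # 15 detected analytes (DahA never detected) + 3 aggregate rows
        assert len(table) == 18
        assert list(table["analyte"][-3:]) == list(AGGREGATE_ROWS)
        for level in ("winter", "summer"):
            for wt in ("SW", "SG", "DG"):
                assert f"{level}_{wt}_gm" in table.columns
            assert f"{level}_P" in table.columns
        assert {"P_SW", "P_SG", "P_DG", "P_all"} <= set(table.columns)

    def test_group_stratification_variant(self, small_campaign, pefs):
        from pahrisk.synthetic import DEFAULT_DETECTION_LIMITS
        _, samples = small_campaign
        table = comparison_table(samples, "group", "water_type", pefs,
                                 "half_dl", DEFAULT_DETECTION_LIMITS)
        assert {"control_SW_gm", "risk_SW_gm", "P_all"} <= set(table.columns)
        p_values = table["P_all"].dropna()
        assert ((p_values >= 0) & (p_values <= 1)).all()
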