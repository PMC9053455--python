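"""Cluster profiling battery: means tables, normality screen, variance and
mean-equality tests, and pairwise post hoc comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paregions.profiling import (
    anova_battery,
    bonferroni_adjust,
    brown_forsythe_robust,
    cluster_means_table,
    levene_test,
    normality_screen,
    oneway_anova,
    posthoc_pairwise,
    sidak_adjust,
    standardized_means_matrix,
)
from paregions.synthetic import COVARIATE_NAMES

from conftest import make_solution


def covariates_from(values: dict, indicator="gdp_pc"):
    """Covariate frame with one meaningful indicator, rest constant-ish."""
    rows = []
    for rid, v in values.items():
        row = {"region_id": rid, indicator: v}
        for c in COVARIATE_NAMES:
            row.setdefault(c, 50.0)
        rows.append(row)
    return pd.DataFrame(rows)


class TestClusterMeans:
    def test_hand_computed_means_and_flags(self):
        cov = covariates_from({"a": 10.0, "b": 20.0, "c": 100.0, "d": 200.0})
        sol = make_solution({"a": 0, "b": 0, "c": 1, "d": 1})
        table = cluster_means_table(cov, sol, indicators=["gdp_pc"])
        assert table.loc["gdp_pc", "C1"] == 15.0
        assert table.loc["gdp_pc", "C2"] == 150.0
        assert table.loc["gdp_pc", "largest"] == "C2"
        assert table.loc["gdp_pc", "smallest"] == "C1"

    def test_single_region_clusters(self):
        cov = covariates_from({"a": 7.0, "b": 13.0})
        table = cluster_means_table(cov, make_solution({"a": 0, "b": 1}),
                                    indicators=["gdp_pc"])
        assert table.loc["gdp_pc", "C1"] == 7.0 and table.loc["gdp_pc", "C2"] == 13.0

    def test_missing_covariates_fail_loudly(self):
        cov = covariates_from({"a": 1.0})
        with pytest.raises(ValueError, match="missing"):
            cluster_means_table(cov, make_solution({"a": 0, "zz": 1}))

    def test_zero_noise_cluster_means_equal_archetype_means(self, archetypes):
        from paregions.synthetic import SimulationConfig, generate_covariates, ArchetypeSpec

        zero_sd = [
            ArchetypeSpec(a.name, a.class_mix, a.covariate_means,
                          {k: 0.0 for k in a.covariate_sds})
            for a in archetypes
        ]
        cov = generate_covariates(SimulationConfig(n_regions_per_archetype=3, rng_seed=0),
                                  zero_sd)
        sol = make_solution(
            {r: i // 3 for i, r in enumerate(cov["region_id"])})
        table = cluster_means_table(cov, sol, indicators=["unemployment", "tertiary"])
        for j, a in enumerate(zero_sd):
            assert table.loc["unemployment", f"C{j + 1}"] == pytest.approx(
                a.covariate_means["unemployment"])
            assert table.loc["tertiary", f"C{j + 1}"] == pytest.approx(
                a.covariate_means["tertiary"])


class TestNormalityScreen:
    def _screen_one_group(self, values):
        cov = covariates_from({f"r{i}": v for i, v in enumerate(values)})
        sol = make_solution({f"r{i}": 0 for i in range(len(values))})
        return normality_screen(cov, sol, indicators=["gdp_pc"]).iloc[0]

    def test_normal_data_mostly_included(self):
        """Gaussian data passes the Shapiro screen in >= 90% of 100 seeds
        (single group, n=50: inclusion probability is 1 - alpha = 0.95)."""
        included = 0
        for seed in range(100):
            vals = np.random.default_rng(seed).normal(size=50)
            included += bool(self._screen_one_group(vals)["included"])
        assert included >= 90

    def test_lognormal_data_mostly_excluded(self):
        excluded = 0
        for seed in range(100):
            vals = np.exp(np.random.default_rng(seed).normal(size=50))
            excluded += not self._screen_one_group(vals)["included"]
        assert excluded >= 90

    def test_constant_indicator_untestable_but_included(self):
        row = self._screen_one_group([5.0] * 10)
        assert row["included"] and row["untestable"]

    def test_small_cluster_untestable(self):
        cov = covariates_from({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0})
        sol = make_solution({"a": 0, "b": 0, "c": 1, "d": 1, "e": 1})
        row = normality_screen(cov, sol, indicators=["gdp_pc"]).iloc[0]
        assert row["untestable"]


class TestLevene:
    def test_symmetric_equal_spread_groups(self):
        stat, p = levene_test([np.array([-1.0, 1.0]), np.array([-1.0, 1.0])])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_power_against_ninefold_variance(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, p = levene_test([rng.normal(0, 1, 100), rng.normal(0, 3, 100)])
            rejections += p < 0.05
        assert rejections >= 90

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            levene_test([np.array([1.0]), np.array([1.0, 2.0])])


class TestOnewayAnova:
    def test_no_between_group_variance(self):
        g = np.array([0.0, 2.0])
        f, df1, df2, p = oneway_anova([g, g, g])
        assert f == 0.0 and (df1, df2) == (2, 3)
        assert p == pytest.approx(1.0)

    def test_separation_limit(self):
        rng = np.random.default_rng(0)
        f, _, _, p = oneway_anova(
            [rng.normal(0, 1e-9, 3), 1.0 + rng.normal(0, 1e-9, 3)]
        )
        assert f > 1e10 and p < 1e-12

    def test_zero_within_variance_unequal_means(self):
        f, _, _, p = oneway_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert np.isinf(f) and p == 0.0

    def test_hand_worked_three_by_three(self):
        # groups {1,2,3},{2,3,4},{4,5,6}: SSB=14, SSW=6, F=(14/2)/(6/6)=7
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([4.0, 5, 6])]
        f, df1, df2, p = oneway_anova(groups)
        assert f == pytest.approx(7.0)
        assert (df1, df2) == (2, 6)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestBrownForsythe:
    def test_two_groups_match_welch(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 3, 80)
        f, df1, df2, p = brown_forsythe_robust([a, b])
        t = stats.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t.statistic**2, rel=1e-9)
        assert p == pytest.approx(t.pvalue, abs=1e-6)

    def test_close_to_classical_f_when_homoscedastic(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(g * 0.1, 1, 200) for g in range(3)]
        f_star, *_ = brown_forsythe_robust(groups)
        f_classic, *_ = oneway_anova(groups)
        assert abs(f_star - f_classic) / f_classic < 0.05

    def test_zero_variance_paths(self):
        f, _, _, p = brown_forsythe_robust([np.array([1.0, 1.0]), np.array([1.0, 1.0])])
        assert f == 0.0 and p == 1.0


class TestPosthoc:
    def test_equal_groups_all_null(self):
        g = np.array([0.0, 2.0, 4.0])
        comps = posthoc_pairwise({"A": g, "B": g.copy(), "C": g.copy()},
                                 homoscedastic=True)
        assert all(c.adjusted_p == 1.0 and not c.significant for c in comps)
        assert all(c.procedure == "bonferroni" for c in comps)

    def test_outlier_group_drives_differences(self):
        rng = np.random.default_rng(3)
        groups = {f"C{i}": rng.normal(0, 1, 30) for i in range(1, 4)}
        groups["C4"] = rng.normal(10.0, 1, 30)  # +10 SD shift
        comps = posthoc_pairwise(groups, homoscedastic=True)
        sig = {c.pair for c in comps if c.significant}
        assert sig == {("C1", "C4"), ("C2", "C4"), ("C3", "C4")}

    def test_bonferroni_formula_m6(self):
        rng = np.random.default_rng(4)
        groups = {f"G{i}": rng.normal(i * 0.3, 1, 25) for i in range(4)}
        comps = posthoc_pairwise(groups, homoscedastic=True)
        assert len(comps) == 6
        for c in comps:
            assert c.adjusted_p == pytest.approx(min(1.0, 6 * c.raw_p))
            assert c.adjusted_p >= c.raw_p

    def test_tamhane_uses_sidak_bound(self):
        rng = np.random.default_rng(5)
        groups = {f"G{i}": rng.normal(0, 1 + i, 20) for i in range(4)}
        comps = posthoc_pairwise(groups, homoscedastic=False)
        for c in comps:
            assert c.procedure == "tamhane_t2"
            assert c.adjusted_p == pytest.approx(min(1.0, 1 - (1 - c.raw_p) ** 6))

    @pytest.mark.parametrize("p_raw", [0.001, 0.01, 0.05, 0.2, 0.9])
    def test_sidak_never_exceeds_bonferroni(self, p_raw):
        for m in (3, 6, 10):
            assert sidak_adjust(p_raw, m) <= bonferroni_adjust(p_raw, m)
            assert 0.0 <= sidak_adjust(p_raw, m) <= 1.0


class TestFullBattery:
    def test_unhealthy_cluster_dominates_pairwise_differences(self, default_run):
        """On archetype data generated with the unhealthy profile as the
        outlier, the significant post hoc pairs predominantly involve the
        unhealthy cluster."""
        results = anova_battery(default_run["covariates"], default_run["solution"])
        with_u = without_u = 0
        any_sig_indicators = 0
        for r in results:
            if not r.included:
                continue
            sig = [c for c in r.pairwise if c.significant]
            if sig:
                any_sig_indicators += 1
                assert any("unhealthy" in c.pair for c in sig), r.indicator
            with_u += sum("unhealthy" in c.pair for c in sig)
            without_u += sum("unhealthy" not in c.pair for c in sig)
        assert any_sig_indicators >= 5
        assert with_u > without_u

    def test_robust_branch_taken_when_levene_rejects(self):
        rng = np.random.default_rng(6)
        n = 40
        cov = covariates_from(
            {f"r{i}": v for i, v in enumerate(
                np.r_[rng.normal(0, 1, n), rng.normal(0.5, 6, n)])}
        )
        sol = make_solution({f"r{i}": int(i >= n) for i in range(2 * n)})
        res = [r for r in anova_battery(cov, sol, indicators=["gdp_pc"])][0]
        if res.included:  # heavy-tailed draw may fail the screen
            assert res.levene_p < 0.05
            assert res.robust_used
            assert all(c.procedure == "tamhane_t2" for c in res.pairwise)

    def test_standardized_means_shape(self, default_run):
        z = standardized_means_matrix(default_run["covariates"], default_run["solution"])
        assert z.shape == (len(COVARIATE_NAMES), 4)
        # each row is a contrast of cluster means of a z-scored variable
        assert z.abs().max().max() < 5
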