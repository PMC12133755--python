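"""Cultivar screen: aggregation, exact 1-D clustering, Welch test, OLS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from berrybruise.cultivar_analysis import (
    DegenerateClusteringError,
    aggregate,
    fit_linear,
    screen_report,
    two_means_cluster,
    welch_t_test,
)
from berrybruise.synthgen import CultivarSimSpec, simulate_cultivars


def brute_force_two_cluster(values):
    """Global 2-partition optimum by enumerating every binary assignment."""
    values = np.asarray(values, float)
    n = len(values)
    best = (np.inf, None)
    for bits in itertools.product([0, 1], repeat=n):
        bits = np.array(bits)
        if bits.sum() in (0, n):
            continue
        wcss = sum(
            ((values[bits == g] - values[bits == g].mean()) ** 2).sum()
            for g in (0, 1)
        )
        if wcss < best[0] - 1e-12:
            best = (wcss, bits)
    return best


class TestAggregate:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["cultivar", "year", "ratio"])

    def test_mean_per_cultivar_year(self):
        df = self._df([("a", 1, 0.1), ("a", 1, 0.2), ("a", 1, 0.3)])
        out = aggregate(df)
        assert out.loc[0, "mean_ratio"] == pytest.approx(0.2)

    def test_all_null_cultivar_dropped_with_warning(self):
        df = self._df([("a", 1, 0.1), ("b", 1, None), ("b", 1, None)])
        with pytest.warns(UserWarning, match="no valid ratio"):
            out = aggregate(df)
        assert list(out["cultivar"]) == ["a"]

    def test_two_years_give_two_records(self):
        df = self._df([("a", 2021, 0.1), ("a", 2022, 0.3)])
        out = aggregate(df)
        assert len(out) == 2

    def test_null_count_reported(self):
        df = self._df([("a", 1, 0.1), ("a", 1, None)])
        out = aggregate(df)
        assert out.loc[0, "n_null"] == 1 and out.loc[0, "n_samples"] == 1


class TestTwoMeansCluster:
    def test_hand_worked_four_points(self):
        res = two_means_cluster([0.10, 0.12, 0.30, 0.32])
        assert res.centroids == (pytest.approx(0.11), pytest.approx(0.31))
        assert res.threshold == pytest.approx(0.21)
        assert list(res.labels) == ["resistant", "resistant", "susceptible", "susceptible"]
        assert res.boundary_midpoint == pytest.approx(0.21)

    def test_two_point_degenerate_geometry(self):
        res = two_means_cluster([0.0, 1.0])
        assert res.centroids == (0.0, 1.0)
        assert res.threshold == 0.5

    def test_identical_values_raise(self):
        with pytest.raises(DegenerateClusteringError):
            two_means_cluster([0.2, 0.2, 0.2])

    @pytest.mark.parametrize("seed", range(15))
    def test_equals_exhaustive_partition_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        values = np.round(rng.random(n), 4)
        if np.ptp(values) == 0:
            values[0] += 0.5
        res = two_means_cluster(values)
        wcss, _ = brute_force_two_cluster(values)
        assert res.inertia == pytest.approx(wcss, abs=1e-10)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        values = rng.random(9)
        res1 = two_means_cluster(values)
        perm = rng.permutation(9)
        res2 = two_means_cluster(values[perm])
        assert res1.threshold == pytest.approx(res2.threshold)
        assert list(np.asarray(res1.labels)[perm]) == list(res2.labels)

    def test_threshold_sits_between_centroids(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            values = rng.random(7)
            res = two_means_cluster(values)
            lo, hi = res.centroids
            assert lo < res.threshold < hi


class TestWelch:
    def test_hand_derived_example(self):
        res = welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.t == pytest.approx(-1.0, abs=1e-3)
        assert res.df == pytest.approx(8.0, abs=1e-3)
        assert res.p_value == pytest.approx(0.3466, abs=1e-3)

    def test_identical_samples_give_t_zero_p_one(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p_value == pytest.approx(1.0)

    def test_antisymmetric_in_sample_order(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 9.0, 3.0]
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p_value == pytest.approx(r2.p_value)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_reference(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, int(rng.integers(3, 20)))
        b = rng.normal(0.4, 2, int(rng.integers(3, 20)))
        res = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_reduces_to_pooled_t_under_equal_variance_and_size(self):
        # With equal n and equal sample variances the Welch df collapses to
        # the classical n_a + n_b - 2.
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 10.0  # same variance, shifted
        res = welch_t_test(a, b)
        assert res.df == pytest.approx(len(a) + len(b) - 2, abs=1e-9)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestFitLinear:
    def test_exact_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = -0.05 * x + 0.4
        fit = fit_linear(x, y)
        assert fit.slope == pytest.approx(-0.05)
        assert fit.intercept == pytest.approx(0.4)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_defines_r2_zero(self):
        fit = fit_linear([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_noisy_line_slope_within_analytic_interval(self):
        rng = np.random.default_rng(17)
        n, sd, slope = 40, 0.05, -0.08
        x = rng.uniform(1, 6, n)
        y = slope * x + 0.5 + rng.normal(0, sd, n)
        fit = fit_linear(x, y)
        ref = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope)
        assert fit.r_squared == pytest.approx(ref.rvalue**2)
        # 95% CI from the closed-form OLS sampling distribution
        half = 1.96 * sd / np.sqrt(((x - x.mean()) ** 2).sum())
        assert abs(fit.slope - slope) <= 2 * half


class TestScreenReport:
    def test_recovers_generating_labels_and_validates_firmness(self):
        df = simulate_cultivars(CultivarSimSpec(seed=3))
        screens = screen_report(df)
        sc = screens["2021"]
        truth = df.groupby("cultivar")["true_group"].first()
        got = sc.table.set_index("cultivar")["label"]
        assert (got == truth.loc[got.index]).all()
        assert sc.firmness_test is not None
        # resistant cultivars must be firmer, significantly so
        assert sc.firmness_test.t > 0
        assert sc.firmness_test.p_value < 0.01
        assert sc.firmness_fit.slope < 0

    def test_threshold_lands_between_group_levels(self):
        df = simulate_cultivars(CultivarSimSpec(seed=12))
        sc = screen_report(df)["2021"]
        assert 0.18 < sc.clusters.threshold < 0.26

    def test_single_group_data_propagates_degenerate_error(self):
        df = pd.DataFrame({
            "cultivar": list("abcd"), "year": [1] * 4,
            "ratio": [0.2] * 4,
        })
        with pytest.raises(DegenerateClusteringError):
            screen_report(df)

    def test_small_year_skipped_with_warning(self):
        df = pd.DataFrame({
            "cultivar": ["a", "b", "c"], "year": [1, 1, 1],
            "ratio": [0.1, 0.2, 0.3],
        })
        with pytest.warns(UserWarning, match="skipped"):
            screens = screen_report(df)
        assert screens == {}

    def test_pooled_mode_merges_years(self):
        df1 = simulate_cultivars(CultivarSimSpec(seed=1, year="2021"))
        df2 = simulate_cultivars(CultivarSimSpec(seed=2, year="2022"))
        screens = screen_report(pd.concat([df1, df2]), pooled=True)
        assert list(screens) == ["pooled"]
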