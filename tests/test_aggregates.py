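"""Geometric cluster-size model: estimators, goodness of fit, lambda link."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrostress.aggregates import (
    ClusterCounts,
    DEFAULT_LINK,
    GeometricModel,
    chain_length,
    close_packed_diameter_3,
    fit_lambda_link,
    geometric_pmf,
    gof_chi2,
    gof_g_test,
    mle_p,
    predict_distribution,
    predict_p,
    singles_fraction,
)
from hydrostress.synthetic import gen_clusters


def exact_geometric_counts(p: float, n_clusters: int, n_max: int) -> ClusterCounts:
    """Counts exactly proportional to the pmf, tail lumped at n_max."""
    sizes = np.arange(1, n_max + 1)
    probs = geometric_pmf(p, sizes)
    probs[-1] = (1 - p) ** (n_max - 1)  # open tail
    return ClusterCounts(sizes=sizes, counts=n_clusters * probs)


class TestGeometricPmf:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(p=st.floats(0.01, 1.0))
    def test_size_one_probability_is_p(self, p):
        assert geometric_pmf(p, 1) == pytest.approx(p)

    def test_baffled_flask_two_cell_probability(self):
        assert geometric_pmf(0.655, 2) == pytest.approx(0.2260, abs=5e-5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(p=st.floats(0.01, 0.99), n_max=st.integers(1, 200))
    def test_partial_sums_geometric_series(self, p, n_max):
        total = geometric_pmf(p, np.arange(1, n_max + 1)).sum()
        assert total == pytest.approx(1 - (1 - p) ** n_max, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            geometric_pmf(0.5, 0)
        with pytest.raises(ValueError):
            geometric_pmf(1.5, 1)
        with pytest.raises(ValueError):
            geometric_pmf(0.5, 1.5)


class TestEstimators:
    def test_all_singles(self):
        c = ClusterCounts.from_dict({1: 10})
        assert singles_fraction(c, "per_cell") == 1.0
        assert singles_fraction(c, "per_cluster") == 1.0
        assert mle_p(c) == 1.0

    def test_hand_counts(self):
        c = ClusterCounts.from_dict({1: 4, 2: 3})
        assert singles_fraction(c, "per_cell") == pytest.approx(0.4)
        assert singles_fraction(c, "per_cluster") == pytest.approx(4 / 7)

    def test_mle_is_reciprocal_mean_size(self):
        c = ClusterCounts.from_dict({1: 2, 2: 1})
        assert mle_p(c) == pytest.approx(3 / 4)

    def test_per_cluster_singles_on_exact_proportions_is_p(self):
        c = exact_geometric_counts(0.61, 1e5, 40)
        assert singles_fraction(c, "per_cluster") == pytest.approx(0.61, rel=1e-12)

    @pytest.mark.parametrize("p", [0.433, 0.655])
    def test_monte_carlo_consistency(self, p):
        """Both estimators converge to the generating p at N = 1e5."""
        c = gen_clusters(100_000, p, seed=42)
        assert abs(mle_p(c) - p) < 0.005
        assert abs(singles_fraction(c, "per_cluster") - p) < 0.005


class TestGoodnessOfFit:
    def test_perfect_fit_gives_zero(self):
        c = exact_geometric_counts(0.5, 1024, 12)
        assert gof_chi2(c, GeometricModel(0.5)).statistic == pytest.approx(0, abs=1e-9)
        assert gof_g_test(c, GeometricModel(0.5)).statistic == pytest.approx(
            0, abs=1e-9
        )

    def test_g_close_to_chi2_on_populated_bins(self):
        # asymptotic equivalence holds once every class is well populated,
        # so pool the tail at 50 expected counts rather than the default 5
        c = gen_clusters(10_000, 0.5, seed=7)
        model = GeometricModel(mle_p(c))
        chi2 = gof_chi2(c, model, min_expected=50).statistic
        g = gof_g_test(c, model, min_expected=50).statistic
        assert abs(g - chi2) / max(chi2, 1e-12) < 0.05

    def test_df_accounts_for_estimated_parameter(self):
        c = gen_clusters(1000, 0.5, seed=3)
        fitted = gof_chi2(c, GeometricModel(mle_p(c)), p_estimated=True)
        fixed = gof_chi2(c, GeometricModel(0.5), p_estimated=False)
        assert fixed.df == fitted.df + 1

    def test_pooling_keeps_expected_above_floor(self):
        c = gen_clusters(500, 0.7, seed=11)
        res = gof_chi2(c, GeometricModel(0.7), p_estimated=False)
        assert np.all(res.expected >= 5.0)
        assert res.expected.sum() == pytest.approx(c.total_clusters)

    def test_power_against_mixture(self):
        """Half p=0.2 / half p=0.9 mixtures are rejected nearly always."""
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 200
        for _ in range(reps):
            sizes = np.concatenate(
                [rng.geometric(0.2, 250), rng.geometric(0.9, 250)]
            )
            c = ClusterCounts.from_samples(sizes)
            res = gof_chi2(c, GeometricModel(mle_p(c)), p_estimated=True)
            rejections += res.p_value < 0.05
        assert rejections / reps > 0.9

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            gof_chi2(ClusterCounts.from_dict({1: 3}), GeometricModel(0.5))


class TestLambdaLink:
    def test_noiseless_recovery(self):
        lam = np.linspace(4e-5, 1.4e-4, 5)
        p = 0.92 - 4589.0 * lam
        link = fit_lambda_link(lam, p)
        assert link.intercept == pytest.approx(0.92, abs=1e-10)
        assert link.slope == pytest.approx(-4589.0, abs=1e-6)
        assert link.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_two_flask_points(self):
        # hand-computed two-point line through the flask measurements
        link = fit_lambda_link([1.025e-4, 6.123e-5], [0.433, 0.655])
        assert link.slope == pytest.approx(-5379.2, abs=0.5)
        assert link.intercept == pytest.approx(0.9844, abs=1e-4)

    def test_noisy_recovery_within_15_percent(self):
        rng = np.random.default_rng(8)
        lam = np.linspace(4e-5, 1.4e-4, 5)
        p = 0.92 - 4589.0 * lam + rng.normal(0, 0.02, 5)
        link = fit_lambda_link(lam, p)
        assert abs(link.slope - (-4589.0)) / 4589.0 < 0.15

    def test_degenerate_abscissae_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_lambda_link([1e-4, 1e-4], [0.4, 0.6])


class TestPrediction:
    def test_zero_lambda_gives_intercept(self):
        assert predict_p(0.0) == pytest.approx(DEFAULT_LINK.intercept)

    def test_baffled_flask_lambda(self):
        assert predict_p(6.123e-5) == pytest.approx(0.639, abs=5e-4)

    def test_clamped_above_physical_range(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert predict_p(2.5e-4) == 0.0

    def test_composition_identity(self):
        lam = 8e-5
        pmf = predict_distribution(lam, n_max=6)
        p = predict_p(lam)
        assert pmf == pytest.approx(
            [geometric_pmf(p, n) for n in range(1, 7)], rel=1e-12
        )

    def test_unbaffled_flask_single_cell_probability(self):
        assert predict_distribution(1.025e-4, n_max=3)[0] == pytest.approx(
            0.4496, abs=5e-4
        )

    def test_pmf_strictly_decreasing(self):
        pmf = predict_distribution(6.123e-5, n_max=10)
        assert np.all(np.diff(pmf) < 0)


class TestClusterGeometry:
    def test_three_cell_chain(self):
        assert chain_length(3, 15.5e-6) == pytest.approx(46.5e-6)

    def test_single_cell_chain_is_cell(self):
        assert chain_length(1, 12e-6) == 12e-6

    def test_five_cell_chain(self):
        assert chain_length(5, 15.5e-6) == pytest.approx(77.5e-6)

    def test_close_packed_three_cell_diameter(self):
        assert close_packed_diameter_3(15.5e-6) * 1e6 == pytest.approx(33.4, abs=0.05)
        assert close_packed_diameter_3(0.0) == 0.0
        assert close_packed_diameter_3(1.0) == pytest.approx(2.1547, abs=1e-4)
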