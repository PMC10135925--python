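"""Volume-weighted turbulence statistics of finite-volume field exports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrostress import hydro
from hydrostress.hydro import (
    FlowField,
    FluidProperties,
    WATER_310K,
    epsilon_from_k_omega,
    fill_epsilon,
    heterogeneity,
    kolmogorov_length,
    lambda_volume_distribution,
    power_per_volume_from_dissipation,
    power_per_volume_from_torque,
    q_criterion,
    volume_fraction_below,
    volume_weighted_mean,
)


class TestFluidProperties:
    def test_dynamic_viscosity_derived(self):
        f = FluidProperties(density=1000.0, kinematic_viscosity=1e-6)
        assert f.dynamic_viscosity == pytest.approx(1e-3, rel=1e-12)

    def test_inconsistent_dynamic_viscosity_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            FluidProperties(1000.0, 1e-6, dynamic_viscosity=1.1e-3)

    def test_reference_water_values(self):
        assert WATER_310K.density == 993.37
        assert WATER_310K.dynamic_viscosity == pytest.approx(
            993.37 * 0.6959e-6, rel=1e-12
        )


class TestFlowFieldValidation:
    def test_negative_k_names_record(self):
        with pytest.raises(ValueError, match="record 1"):
            FlowField(volume=[1.0, 1.0], k=[0.1, -0.2], omega=[1.0, 1.0])

    def test_large_volume_mismatch_rejected(self):
        with pytest.raises(ValueError, match="total_volume"):
            FlowField(volume=[1.0], k=[0.1], omega=[1.0], total_volume=2.0)

    def test_moderate_volume_mismatch_warns(self):
        with pytest.warns(UserWarning, match="normalise"):
            FlowField(volume=[1.0], k=[0.1], omega=[1.0], total_volume=1.005)


class TestEpsilonFromKOmega:
    @pytest.mark.parametrize(
        "k, omega, expected",
        [(1.0, 1.0, 0.09), (0.0, 5.0, 0.0), (2.5, 4.0, 0.9)],
    )
    def test_scalar_values(self, k, omega, expected):
        assert epsilon_from_k_omega(k, omega) == pytest.approx(expected, rel=1e-12)

    def test_negative_input_names_record(self):
        with pytest.raises(ValueError, match="record 2"):
            epsilon_from_k_omega(np.array([1.0, 1.0, -0.5]), np.ones(3))

    def test_fill_preserves_provided_epsilon(self):
        f = FlowField(
            volume=[1.0, 1.0], k=[1.0, 1.0], omega=[1.0, 1.0],
            epsilon=[0.5, 0.5],
        )
        assert np.array_equal(fill_epsilon(f).epsilon, [0.5, 0.5])
        forced = fill_epsilon(f, force=True)
        assert np.allclose(forced.epsilon, 0.09)


class TestKolmogorovLength:
    def test_identity_case(self):
        assert kolmogorov_length(1.0, 1.0) == pytest.approx(1.0)

    def test_water_value(self):
        # (nu^3/eps)^(1/4) evaluated directly
        assert kolmogorov_length(6.959e-7, 1e-3) == pytest.approx(
            1.3549e-4, rel=1e-4
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        eps1=st.floats(1e-8, 1e3),
        factor=st.floats(1.0001, 1e4),
    )
    def test_strictly_decreasing_in_epsilon(self, eps1, factor):
        assert kolmogorov_length(1e-6, eps1 * factor) < kolmogorov_length(1e-6, eps1)

    def test_zero_epsilon_warns_and_returns_inf(self):
        with pytest.warns(UserWarning, match="quiescent"):
            assert kolmogorov_length(1e-6, 0.0) == np.inf
        with pytest.raises(ValueError):
            kolmogorov_length(1e-6, 0.0, on_zero="error")


class TestVolumeWeightedReductions:
    def test_uniform_value_is_identity(self, random_field):
        assert volume_weighted_mean(
            np.full(random_field.n_cells, 3.7), random_field
        ) == pytest.approx(3.7, rel=1e-12)

    def test_hand_sum(self):
        f = FlowField(volume=[1.0, 3.0], k=[0, 0], omega=[0, 0])
        assert volume_weighted_mean([0.0, 4.0], f) == pytest.approx(3.0)

    def test_matches_loop_oracle(self, random_field, rng):
        q = rng.lognormal(0.0, 1.0, random_field.n_cells)
        acc = vol = 0.0
        for qi, vi in zip(q, random_field.volume):
            acc += qi * vi
            vol += vi
        assert volume_weighted_mean(q, random_field) == pytest.approx(
            acc / vol, rel=1e-12
        )

    def test_length_mismatch_rejected(self, random_field):
        with pytest.raises(ValueError, match="aligned"):
            volume_weighted_mean(np.ones(3), random_field)


class TestPowerPerVolume:
    @pytest.mark.parametrize(
        "n, torque, volume, expected",
        [
            (1.0, 1.0, 2 * np.pi, 1.0),
            (3.0, 0.0, 0.004, 0.0),
            (130 / 60, 5.44e-4, 1.6e-4, 46.28),
        ],
    )
    def test_torque_route(self, n, torque, volume, expected):
        assert power_per_volume_from_torque(n, torque, volume) == pytest.approx(
            expected, rel=1e-3
        )

    def test_torque_route_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            power_per_volume_from_torque(1.0, 1.0, 0.0)

    def test_uniform_dissipation(self):
        f = FlowField(volume=np.full(10, 0.1), k=np.ones(10), omega=np.ones(10),
                      epsilon=np.ones(10))
        fluid = FluidProperties(1000.0, 1e-6)
        assert power_per_volume_from_dissipation(f, fluid) == pytest.approx(1000.0)

    def test_equals_density_times_mean(self, random_field, water):
        eps = random_field.dissipation()
        assert power_per_volume_from_dissipation(
            random_field, water
        ) == pytest.approx(
            water.density * volume_weighted_mean(eps, random_field), rel=1e-12
        )

    def test_torque_and_dissipation_routes_consistent(self, random_field, water):
        """A torque chosen as M = (P/V)*V/(2*pi*n) closes the energy balance."""
        pv = power_per_volume_from_dissipation(random_field, water)
        n = 2.1667
        torque = pv * random_field.total_volume / (2 * np.pi * n)
        assert power_per_volume_from_torque(
            n, torque, random_field.total_volume
        ) == pytest.approx(pv, rel=1e-9)


class TestHeterogeneity:
    def test_uniform_field_is_one(self):
        f = FlowField(volume=np.ones(5), k=np.ones(5), omega=np.ones(5))
        assert heterogeneity(f) == pytest.approx(1.0)

    def test_small_hot_spot(self):
        # one cell at 10x dissipation with negligible volume barely moves the mean
        eps = np.array([1.0] * 1000 + [10.0])
        vol = np.array([1.0] * 1000 + [1e-9])
        f = FlowField(volume=vol, k=np.ones(1001), omega=np.ones(1001), epsilon=eps)
        assert heterogeneity(f) == pytest.approx(10.0, rel=1e-6)

    def test_scale_invariance(self, random_field, water):
        eps = random_field.dissipation()
        scaled = FlowField(
            volume=random_field.volume, k=random_field.k,
            omega=random_field.omega, epsilon=1e3 * eps,
        )
        assert heterogeneity(scaled) == pytest.approx(
            heterogeneity(random_field), rel=1e-12
        )

    def test_percentile_variant_not_above_max(self, random_field):
        assert heterogeneity(random_field, percentile=99.9) <= heterogeneity(
            random_field
        )

    def test_all_zero_dissipation_rejected(self):
        f = FlowField(volume=np.ones(3), k=np.zeros(3), omega=np.zeros(3))
        with pytest.raises(ValueError, match="undefined"):
            heterogeneity(f)


class TestLambdaDistribution:
    def test_uniform_field_point_mass(self, water):
        f = FlowField(volume=np.ones(50), k=np.full(50, 0.01), omega=np.full(50, 2.0))
        dist = lambda_volume_distribution(f, water)
        assert np.count_nonzero(dist.volume_fraction) == 1
        assert dist.volume_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_value_field_fractions(self, water):
        eps = np.array([1e-3, 1e-1])
        f = FlowField(volume=np.array([0.25, 0.75]), k=np.ones(2), omega=np.ones(2),
                      epsilon=eps)
        lam = kolmogorov_length(water.kinematic_viscosity, eps)
        edges = [lam[1] * 0.9, np.sqrt(lam[0] * lam[1]), lam[0] * 1.1]
        dist = lambda_volume_distribution(f, water, bin_edges=edges)
        # higher dissipation -> smaller lambda -> first bin
        assert dist.volume_fraction == pytest.approx([0.75, 0.25])

    def test_mean_is_volume_weighted_mean(self, random_field, water):
        dist = lambda_volume_distribution(random_field, water)
        lam = kolmogorov_length(
            water.kinematic_viscosity, random_field.dissipation()
        )
        assert dist.mean == pytest.approx(
            volume_weighted_mean(lam, random_field), rel=1e-12
        )

    def test_fractions_sum_to_one(self, random_field, water):
        dist = lambda_volume_distribution(random_field, water)
        assert dist.volume_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_quiescent_cells_clamped_to_top_bin(self, water):
        k = np.array([0.01, 0.01, 0.0])
        f = FlowField(volume=np.array([0.4, 0.4, 0.2]), k=k, omega=np.full(3, 2.0))
        with pytest.warns(UserWarning):
            dist = lambda_volume_distribution(f, water)
        assert dist.quiescent_volume == pytest.approx(0.2)
        assert dist.volume_fraction[-1] == pytest.approx(0.2)
        assert dist.volume_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_monotone_edges_rejected(self, random_field, water):
        with pytest.raises(ValueError, match="increasing"):
            lambda_volume_distribution(
                random_field, water, bin_edges=[1e-4, 5e-5, 2e-4]
            )


class TestVolumeFractionBelow:
    def test_extremes(self, random_field, water):
        lam = kolmogorov_length(
            water.kinematic_viscosity, random_field.dissipation()
        )
        below = volume_fraction_below(random_field, water, lam.min() * 0.5)
        above = volume_fraction_below(random_field, water, lam.max() * 2.0)
        assert below.fraction == 0.0
        assert above.fraction == 1.0
        assert above.absolute_volume == pytest.approx(random_field.total_volume)

    def test_absolute_volume_of_known_fraction(self, water):
        """A 2.077 % fraction of a 4 L vessel is 83 mL."""
        vol = np.array([0.02077, 1 - 0.02077]) * 4e-3
        eps = np.array([1.0, 1e-4])  # first cell: tiny lambda
        f = FlowField(volume=vol, k=np.ones(2), omega=np.ones(2), epsilon=eps)
        lam = kolmogorov_length(water.kinematic_viscosity, eps)
        res = volume_fraction_below(f, water, np.sqrt(lam[0] * lam[1]))
        assert res.fraction == pytest.approx(0.02077)
        assert res.absolute_volume * 1e6 == pytest.approx(83.08, abs=0.01)  # mL

    def test_is_a_cdf(self, random_field, water):
        thresholds = np.geomspace(1e-6, 1e-2, 25)
        fracs = [
            volume_fraction_below(random_field, water, t).fraction
            for t in thresholds
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert all(0 <= x <= 1 for x in fracs)


class TestQCriterion:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(w=st.floats(1e-3, 1e3))
    def test_solid_body_rotation(self, w):
        g = np.array([[0.0, -w, 0.0], [w, 0.0, 0.0], [0.0, 0.0, 0.0]])
        assert q_criterion(g) == pytest.approx(w**2, rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(gamma=st.floats(1e-3, 1e3))
    def test_pure_shear_is_zero(self, gamma):
        g = np.zeros((3, 3))
        g[0, 1] = gamma
        assert q_criterion(g) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(a=st.floats(1e-3, 1e3))
    def test_incompressible_plane_strain(self, a):
        assert q_criterion(np.diag([a, -a, 0.0])) == pytest.approx(
            -(a**2), rel=1e-12
        )

    def test_stack_input(self, rng):
        stack = rng.normal(size=(7, 3, 3))
        out = q_criterion(stack)
        assert out.shape == (7,)
        assert out[3] == pytest.approx(q_criterion(stack[3]))

    def test_nonfinite_rejected(self):
        g = np.zeros((3, 3))
        g[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            q_criterion(g)
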