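"""Persistence length, helical symmetry and block averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actinmech.core import (
    ChainTrace,
    DegenerateGeometryError,
    FilamentModel,
    Trajectory,
)
from actinmech.mechanics import (
    block_average,
    crossover_length,
    estimate_helical_parameters,
    estimate_persistence_length,
    tangent_correlation,
)
from actinmech.simulate import (
    HelixEnsembleParams,
    WLCParams,
    generate_helix_ensemble,
    generate_wlc_trajectory,
    ideal_helix_points,
)


def _ar1(rng, n, rho):
    x = np.empty(n)
    x[0] = rng.standard_normal() / np.sqrt(1 - rho**2)
    eps = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    return x


class TestBlockAverage:
    def test_iid_plateau_matches_analytic_se(self):
        rng = np.random.default_rng(12)
        n = 2**14
        ratios = [
            block_average(rng.standard_normal(n)).plateau_se / (1 / np.sqrt(n))
            for _ in range(10)
        ]
        assert abs(np.median(ratios) - 1) < 0.10

    def test_ar1_plateau_matches_correlated_se(self):
        rho, n = 0.9, 2**14
        rng = np.random.default_rng(21)
        analytic = (
            1 / np.sqrt(1 - rho**2)
            * np.sqrt((1 + rho) / (1 - rho)) / np.sqrt(n)
        )
        ratios = [
            block_average(_ar1(rng, n, rho)).plateau_se / analytic
            for _ in range(15)
        ]
        assert abs(np.median(ratios) - 1) < 0.15

    def test_constant_series_gives_zero_se(self):
        res = block_average(np.full(64, 3.14))
        assert res.plateau_se == 0.0
        assert np.all(res.se == 0.0)

    def test_block_sizes_are_powers_of_two(self):
        res = block_average(np.random.default_rng(0).standard_normal(100))
        assert list(res.block_sizes) == [2**i for i in range(len(res.block_sizes))]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            block_average(np.arange(5.0))


class TestTangentCorrelation:
    def test_straight_chain_is_fully_correlated(self):
        nodes = np.column_stack([np.zeros(20), np.zeros(20), np.arange(20.0)])
        table = tangent_correlation(Trajectory([ChainTrace(nodes)]), k_max=5)
        np.testing.assert_allclose(table["mean_cos"], 1.0, atol=1e-12)

    def test_planar_zigzag_alternating_tangents(self):
        # segments alternate between two directions separated by angle alpha
        alpha = np.deg2rad(40.0)
        u = np.array([np.sin(alpha / 2), 0, np.cos(alpha / 2)])
        v = np.array([-np.sin(alpha / 2), 0, np.cos(alpha / 2)])
        nodes = [np.zeros(3)]
        for i in range(12):
            nodes.append(nodes[-1] + (u if i % 2 == 0 else v))
        table = tangent_correlation(
            Trajectory([ChainTrace(np.vstack(nodes))]), k_max=2
        )
        assert table.loc[0, "mean_cos"] == pytest.approx(np.cos(alpha), abs=1e-12)
        assert table.loc[1, "mean_cos"] == pytest.approx(1.0, abs=1e-12)

    def test_k_max_bound_enforced(self):
        traj = Trajectory(
            [ChainTrace(np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)]))]
        )
        with pytest.raises(ValueError):
            tangent_correlation(traj, k_max=5)


class TestPersistenceLength:
    @pytest.mark.parametrize("lp_um", [9.8, 12.21])
    def test_parameter_recovery(self, lp_um):
        traj = generate_wlc_trajectory(
            WLCParams(n_nodes=2000, b=55.0, lp=lp_um * 1e4, n_frames=500,
                      seed=int(lp_um * 100))
        )
        fit = estimate_persistence_length(traj)
        assert abs(fit.lp_um - lp_um) / lp_um < 0.10
        assert fit.sd_um >= 0
        assert fit.n_frames_used == 500

    def test_stiff_limit_flagged_beyond_resolvable(self):
        # perfectly straight chains: the correlation decay has zero slope
        nodes = np.column_stack(
            [np.zeros(100), np.zeros(100), 55.0 * np.arange(100.0)]
        )
        traj = Trajectory([ChainTrace(nodes)] * 10)
        fit = estimate_persistence_length(traj)
        assert fit.beyond_resolvable
        assert np.isinf(fit.lp_um)

    def test_nonpositive_correlations_advise_smaller_range(self):
        rng = np.random.default_rng(0)
        frames = [
            ChainTrace(np.cumsum(rng.standard_normal((30, 3)), axis=0))
            for _ in range(3)
        ]
        with pytest.raises(ValueError, match="k_star"):
            estimate_persistence_length(Trajectory(frames), k_star=25)


class TestHelicalParameters:
    @pytest.mark.parametrize("rise", [25.0, 27.5, 30.0])
    @pytest.mark.parametrize("twist", [-165.0, -166.15, -167.0])
    @pytest.mark.parametrize("radius", [10.0, 25.0])
    def test_noise_free_identity(self, rise, twist, radius):
        pts = ideal_helix_points(13, rise, twist, radius)
        res = estimate_helical_parameters(
            Trajectory([FilamentModel.from_points(pts)])
        )
        assert abs(res.rise - rise) < 1e-6
        assert abs(res.twist - twist) < 1e-6
        assert abs(res.crossover - crossover_length(rise, twist)) < 1e-6

    @pytest.mark.parametrize("n", [4, 5, 13, 26])
    def test_identity_for_any_subunit_count(self, n):
        pts = ideal_helix_points(n, 27.5, -166.15, 25.0)
        res = estimate_helical_parameters(
            Trajectory([FilamentModel.from_points(pts)])
        )
        assert abs(res.rise - 27.5) < 1e-6
        assert abs(res.twist + 166.15) < 1e-6

    def test_noisy_ensemble_recovery_within_3_se(self):
        p = HelixEnsembleParams(sigma_xyz=0.5, n_frames=500, seed=3)
        res = estimate_helical_parameters(generate_helix_ensemble(p))
        assert abs(res.rise - 27.5) < 3 * res.rise_sd / np.sqrt(500)
        assert abs(res.twist + 166.15) < 3 * res.twist_sd / np.sqrt(500)

    def test_zero_radius_is_degenerate(self):
        pts = np.column_stack([np.zeros(13), np.zeros(13), 27.5 * np.arange(13)])
        with pytest.raises(DegenerateGeometryError):
            estimate_helical_parameters(
                Trajectory([FilamentModel.from_points(pts)])
            )


class TestCrossoverLength:
    def test_reference_values(self):
        # 180 * 27.5 / (180 - 166.15) = 4950 / 13.85
        assert crossover_length(27.5, -166.15) == pytest.approx(
            4950.0 / 13.85, abs=1e-9
        )
        assert crossover_length(27.5, -166.6) == pytest.approx(
            4950.0 / 13.4, abs=1e-9
        )

    def test_linear_in_rise(self):
        assert crossover_length(55.0, -166.15) == pytest.approx(
            2 * crossover_length(27.5, -166.15)
        )

    @given(
        st.floats(1.0, 100.0),
        st.floats(1.0, 179.0),
        st.floats(0.01, 0.5),
    )
    def test_monotone_increasing_in_abs_twist(self, rise, twist, dt):
        if twist + dt >= 180:
            return
        assert crossover_length(rise, -(twist + dt)) > crossover_length(
            rise, -twist
        )

    @pytest.mark.parametrize("twist", [0.0, 180.0, -185.0])
    def test_invalid_twist_rejected(self, twist):
        with pytest.raises(ValueError):
            crossover_length(27.5, twist)
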