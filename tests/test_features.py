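"""Closed-form and oracle tests for the 17 trajectory descriptors."""

import math

import numpy as np
import pytest

from trajkit import (
    DegenerateTrajectoryError,
    MsdCurve,
    SimulationSpec,
    SpacingError,
    Trajectory,
    simulate,
)
from trajkit import features as F

from conftest import random_walk


def brute_force_msd(positions: np.ndarray, dt: float, n_max: int):
    """O(N^2) double-loop time-averaged MSD, the independent oracle."""
    N = positions.shape[0]
    vals = []
    for n in range(1, n_max + 1):
        acc = 0.0
        for i in range(N - n):
            diff = positions[i + n] - positions[i]
            acc += float(diff @ diff)
        vals.append(acc / (N - n))
    return np.array(vals)


class TestMsd:
    def test_ballistic_line_closed_form(self, line_1d):
        msd = F.msd_time_averaged(line_1d)
        np.testing.assert_allclose(msd.values, msd.lags**2, rtol=1e-12)

    def test_constant_trajectory_is_zero(self):
        tr = Trajectory(times=np.arange(10.0), positions=np.ones((10, 2)))
        msd = F.msd_time_averaged(tr)
        assert np.all(msd.values == 0)

    def test_oscillating_positions_enumerated(self):
        tr = Trajectory(times=np.arange(4.0), positions=[0.0, 1.0, 0.0, 1.0])
        msd = F.msd_time_averaged(tr, n_max=3)
        np.testing.assert_allclose(msd.values, [1.0, 0.0, 1.0], atol=1e-15)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 51))
            dim = int(rng.integers(1, 4))
            pos = rng.standard_normal((n, dim))
            tr = Trajectory(times=np.arange(float(n)), positions=pos)
            n_max = n - 1
            got = F.msd_time_averaged(tr, n_max=n_max).values
            want = brute_force_msd(pos, 1.0, n_max)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_irregular_times_rejected(self):
        tr = Trajectory(times=[0.0, 1.0, 3.0, 4.0], positions=np.zeros((4, 1)))
        with pytest.raises(SpacingError):
            F.msd_time_averaged(tr)

    def test_ensemble_of_identical_lines(self, line_1d):
        msd = F.msd_ensemble([line_1d, line_1d])
        np.testing.assert_allclose(msd.values, msd.lags**2, rtol=1e-12)

    def test_ensemble_mirror_symmetry(self):
        t = np.arange(10.0)
        up = Trajectory(times=t, positions=t.copy())
        down = Trajectory(times=t, positions=-t)
        msd = F.msd_ensemble([up, down])
        np.testing.assert_allclose(msd.values, msd.lags**2, rtol=1e-12)

    def test_ensemble_brownian_matches_2dDt(self):
        # 2000 walks, D=1, d=2 -> MSD(n) = 4n within 3 standard errors
        specs = [
            SimulationSpec(mode="normal", n_points=20, dim=2, seed=s)
            for s in range(2000)
        ]
        trajs = [simulate(s) for s in specs]
        msd = F.msd_ensemble(trajs)
        expected = 4.0 * msd.lags
        # relative SE of a chi^2_2 mean over M samples is 1/sqrt(M)
        se = expected / np.sqrt(len(trajs))
        assert np.all(np.abs(msd.values - expected) < 3 * se)

    def test_ensemble_empty_list_rejected(self):
        with pytest.raises(DegenerateTrajectoryError):
            F.msd_ensemble([])


class TestAnomalousExponent:
    def test_ballistic_exact(self):
        lags = np.arange(1.0, 11.0)
        assert F.anomalous_exponent(MsdCurve(lags, lags**2)) == pytest.approx(2.0)

    def test_linear_any_prefactor(self):
        lags = np.arange(1.0, 11.0)
        for c in (0.01, 1.0, 37.5):
            assert F.anomalous_exponent(MsdCurve(lags, c * lags)) == pytest.approx(1.0)

    def test_ensemble_brownian_near_one(self):
        trajs = [
            simulate(SimulationSpec(mode="normal", n_points=1000, dim=2, seed=s))
            for s in range(100)
        ]
        alpha = F.anomalous_exponent(F.msd_ensemble(trajs))
        assert alpha == pytest.approx(1.0, abs=0.1)

    def test_zero_msd_rejected(self):
        with pytest.raises(DegenerateTrajectoryError):
            F.anomalous_exponent(MsdCurve([1.0, 2.0, 3.0], [1.0, 0.0, 1.0]))


class TestMsdRatio:
    def test_linear_is_zero(self):
        lags = np.arange(1.0, 9.0)
        assert F.msd_ratio(MsdCurve(lags, 3.0 * lags), 1, 4) == pytest.approx(0.0)

    def test_ballistic_hand_value(self):
        lags = np.arange(1.0, 9.0)
        assert F.msd_ratio(MsdCurve(lags, lags**2), 1, 2) == pytest.approx(-0.25)

    def test_plateau_is_positive(self):
        lags = np.arange(1.0, 9.0)
        assert F.msd_ratio(MsdCurve(lags, np.full(8, 5.0)), 1, 4) > 0


class TestGyrationShape:
    def test_repeated_point_zero_tensor(self):
        tr = Trajectory(times=[0, 1, 2], positions=np.ones((3, 2)))
        spec = F.gyration_tensor(tr)
        np.testing.assert_allclose(spec.tensor, 0.0, atol=1e-15)
        np.testing.assert_allclose(spec.eigenvalues, 0.0, atol=1e-15)

    def test_two_point_segment(self):
        tr = Trajectory(times=[0, 1], positions=[[0.0, 0.0], [2.0, 0.0]])
        spec = F.gyration_tensor(tr)
        np.testing.assert_allclose(spec.tensor, [[1.0, 0.0], [0.0, 0.0]], atol=1e-14)
        np.testing.assert_allclose(spec.eigenvalues, [1.0, 0.0], atol=1e-14)
        assert F.gyration_radius(spec) == pytest.approx(1.0)
        assert F.asymmetry(spec) == pytest.approx(-math.log(0.5), abs=1e-12)
        assert F.anisotropy(spec) == pytest.approx(1.0)

    def test_unit_square_corners(self):
        tr = Trajectory(
            times=[0, 1, 2, 3],
            positions=[[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]],
        )
        spec = F.gyration_tensor(tr)
        np.testing.assert_allclose(spec.tensor, 0.25 * np.eye(2), atol=1e-14)
        assert F.gyration_radius(spec) == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert F.asymmetry(spec) == pytest.approx(0.0, abs=1e-12)
        assert F.anisotropy(spec) == pytest.approx(0.0, abs=1e-12)

    def test_asymmetry_hand_value_3_1(self):
        spec = make_spectrum([3.0, 1.0])
        assert F.asymmetry(spec) == pytest.approx(-math.log(1 - 4 / 32), abs=1e-12)
        assert F.anisotropy(spec) == pytest.approx(0.25, abs=1e-12)

    def test_anisotropy_3d_isotropic(self):
        spec = make_spectrum([2.0, 2.0, 2.0])
        assert F.anisotropy(spec) == pytest.approx(0.0, abs=1e-12)

    def test_anisotropy_3d_collinear(self):
        spec = make_spectrum([2.0, 0.0, 0.0])
        assert F.anisotropy(spec) == pytest.approx(1.0)

    def test_zero_spectrum_rejected(self):
        spec = make_spectrum([0.0, 0.0])
        with pytest.raises(DegenerateTrajectoryError):
            F.asymmetry(spec)
        with pytest.raises(DegenerateTrajectoryError):
            F.anisotropy(spec)


def make_spectrum(eigenvalues):
    from trajkit import GyrationSpectrum

    return GyrationSpectrum(tensor=np.diag(sorted(eigenvalues, reverse=True)))


class TestKurtosis:
    def test_alternating_two_values(self):
        pos = np.tile([[0.0, 0.0], [1.0, 0.0]], (10, 1))
        tr = Trajectory(times=np.arange(20.0), positions=pos)
        assert F.kurtosis(tr) == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_projections_near_three(self):
        rng = np.random.default_rng(11)
        pos = np.column_stack(
            [rng.standard_normal(10_000), 0.01 * rng.standard_normal(10_000)]
        )
        tr = Trajectory(times=np.arange(10_000.0), positions=pos)
        assert F.kurtosis(tr) == pytest.approx(3.0, abs=0.2)

    def test_constant_trajectory_rejected(self):
        tr = Trajectory(times=np.arange(5.0), positions=np.ones((5, 2)))
        with pytest.raises(DegenerateTrajectoryError):
            F.kurtosis(tr)


class TestPathGeometry:
    def test_straight_line_closed_forms(self, line_1d):
        assert F.straightness(line_1d) == pytest.approx(1.0)
        assert F.efficiency(line_1d) == pytest.approx(1.0)
        assert F.fractal_dimension_katz(line_1d) == pytest.approx(1.0)

    def test_closed_loop_zero(self):
        tr = Trajectory(times=[0, 1, 2], positions=[0.0, 1.0, 0.0])
        assert F.straightness(tr) == pytest.approx(0.0)
        assert F.efficiency(tr) == pytest.approx(0.0)

    def test_l_path_hand_values(self, l_path):
        assert F.straightness(l_path) == pytest.approx(math.sqrt(2) / 2, abs=1e-12)
        assert F.efficiency(l_path) == pytest.approx(0.5, abs=1e-12)

    def test_katz_u_path_hand_value(self):
        tr = Trajectory(
            times=[0, 1, 2, 3],
            positions=[[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]],
        )
        expected = math.log(3) / (math.log(3) + math.log(math.sqrt(2) / 3))
        assert F.fractal_dimension_katz(tr) == pytest.approx(expected, abs=1e-12)

    def test_katz_degenerate_zigzag_returns_inf(self):
        # [0,1,0]: n=2, L=2, e=1 -> log(n) + log(e/L) = 0
        tr = Trajectory(times=[0, 1, 2], positions=[0.0, 1.0, 0.0])
        assert F.fractal_dimension_katz(tr) == math.inf

    def test_zero_path_length_rejected(self):
        tr = Trajectory(times=[0, 1], positions=np.zeros((2, 2)))
        for fn in (F.straightness, F.efficiency, F.fractal_dimension_katz):
            with pytest.raises(DegenerateTrajectoryError):
                fn(tr)


class TestTrappedness:
    def test_clamp_boundary_exact_zero(self):
        # When the exponent argument is >= 0 the raw value is <= 0 and
        # clamps to exactly 0: a fast-escaping straight line does this.
        tr = Trajectory(times=np.arange(4.0), positions=0.01 * np.arange(4.0))
        assert F.trappedness(tr) == 0.0

    def test_limit_approaches_one(self):
        # Huge short-time diffusivity inside a tiny extent -> P -> 1
        pos = np.tile([[0.0, 0.0], [100.0, 0.0]], (50, 1))
        tr = Trajectory(times=np.arange(100.0), positions=pos)
        assert F.trappedness(tr) > 0.99

    def test_confined_exceeds_directed(self):
        conf = simulate(
            SimulationSpec(mode="confined", n_points=500, radius=2.0, diffusivity=5.0, seed=5)
        )
        dire = simulate(
            SimulationSpec(mode="directed", n_points=500, velocity=(2.0, 0.0), seed=5)
        )
        assert F.trappedness(conf) > F.trappedness(dire)

    def test_in_unit_interval_on_random_walks(self):
        for seed in range(10):
            tr = random_walk(seed, n=200)
            assert 0.0 <= F.trappedness(tr) <= 1.0


class TestGaussianity:
    def test_constant_modulus_displacements_2d(self):
        # steps around a circle: all displacement magnitudes equal -> -0.5
        theta = np.linspace(0, 4 * np.pi, 41)
        pos = np.column_stack([np.cos(theta), np.sin(theta)])
        tr = Trajectory(times=np.arange(41.0), positions=pos)
        assert F.gaussianity(tr) == pytest.approx(-0.5, abs=1e-12)

    def test_brownian_near_zero(self, brownian_2d):
        assert F.gaussianity(brownian_2d) == pytest.approx(0.0, abs=0.1)

    def test_zero_displacement_rejected(self):
        tr = Trajectory(times=np.arange(5.0), positions=np.ones((5, 2)))
        with pytest.raises(DegenerateTrajectoryError):
            F.gaussianity(tr)


class TestVelocityVacf:
    def test_unit_line_velocities(self, line_1d):
        v, speed = F.velocity_series(line_1d)
        np.testing.assert_allclose(v, 1.0)
        assert speed == pytest.approx(1.0)

    def test_constant_trajectory_zero_speed(self):
        tr = Trajectory(times=np.arange(5.0), positions=np.ones((5, 1)))
        _, speed = F.velocity_series(tr)
        assert speed == 0.0

    def test_zigzag_speeds(self):
        tr = Trajectory(times=[0, 1, 2], positions=[0.0, 1.0, 0.0])
        v, speed = F.velocity_series(tr)
        np.testing.assert_allclose(np.abs(v), 1.0)
        assert speed == pytest.approx(1.0)

    def test_vacf_constant_velocity(self, line_1d):
        c = F.vacf(line_1d)
        np.testing.assert_allclose(c.values, 1.0, atol=1e-12)

    def test_vacf_alternating_velocity(self):
        pos = np.array([0.0, 1.0] * 8)[:16]
        tr = Trajectory(times=np.arange(16.0), positions=pos)
        c = F.vacf(tr, n_max=3)
        np.testing.assert_allclose(c.values, [1.0, -1.0, 1.0, -1.0], atol=1e-12)

    def test_vacf_brownian_whiteness(self, brownian_2d):
        c = F.vacf(brownian_2d)
        assert np.all(np.abs(c.values[1:]) <= 0.05)

    def test_vacf_constant_trajectory_rejected(self):
        tr = Trajectory(times=np.arange(5.0), positions=np.ones((5, 2)))
        with pytest.raises(DegenerateTrajectoryError):
            F.vacf(tr)


class TestGreenKubo:
    def test_recovers_brownian_diffusivity(self, brownian_2d):
        # white-noise VACF integral: (1/d) * C(0) dt / 2 = D
        d_gk = F.green_kubo_diffusivity(brownian_2d)
        assert d_gk == pytest.approx(1.0, rel=0.15)

    def test_constant_trajectory_is_zero(self):
        tr = Trajectory(times=np.arange(5.0), positions=np.ones((5, 2)))
        assert F.green_kubo_diffusivity(tr) == 0.0

    def test_agrees_with_msd_slope(self, brownian_2d):
        d_gk = F.green_kubo_diffusivity(brownian_2d)
        msd = F.msd_time_averaged(brownian_2d)
        d_msd = msd.values[0] / (2 * brownian_2d.ndim * msd.lags[0])
        assert abs(d_gk - d_msd) / d_msd < 0.2


class TestFourier:
    def test_single_sine_frequency(self):
        t = np.arange(1000.0)
        tr = Trajectory(times=t, positions=np.sin(2 * np.pi * 0.1 * t))
        bin_width = 1.0 / 1000
        assert abs(F.fourier_dominant_frequency(tr) - 0.1) <= bin_width

    def test_constant_trajectory_zero(self):
        tr = Trajectory(times=np.arange(8.0), positions=np.full((8, 1), 3.0))
        assert F.fourier_dominant_frequency(tr) == 0.0

    def test_two_tone_picks_dominant(self):
        t = np.arange(1000.0)
        x = 2 * np.sin(2 * np.pi * 0.1 * t) + np.sin(2 * np.pi * 0.3 * t)
        tr = Trajectory(times=t, positions=x)
        bin_width = 1.0 / 1000
        assert abs(F.fourier_dominant_frequency(tr) - 0.1) <= bin_width


class TestExtractAllFeatures:
    def test_returns_17_named_features_in_order(self, brownian_2d):
        fv = F.extract_all_features(brownian_2d)
        assert list(fv) == list(F.FEATURE_NAMES)
        assert len(fv) == 17
        assert all(isinstance(v, float) for v in fv.values())

    def test_straight_line_composition(self):
        t = np.arange(40.0)
        tr = Trajectory(times=t, positions=t.copy())
        fv = F.extract_all_features(tr)
        assert fv["straightness"] == pytest.approx(1.0)
        assert fv["efficiency"] == pytest.approx(1.0)
        assert fv["alpha"] == pytest.approx(2.0, abs=1e-9)
        assert fv["fractal_dim"] == pytest.approx(1.0, abs=1e-9)
        assert fv["vacf_first_lag"] == pytest.approx(1.0)
        assert fv["mean_speed"] == pytest.approx(1.0)

    def test_deterministic(self, brownian_2d):
        a = F.extract_all_features(brownian_2d)
        b = F.extract_all_features(brownian_2d)
        assert a == b

    def test_error_carries_feature_name(self):
        tr = Trajectory(times=np.arange(20.0), positions=np.ones((20, 2)))
        with pytest.raises(DegenerateTrajectoryError, match="alpha"):
            F.extract_all_features(tr)

    def test_bounded_features_in_range(self):
        for seed in range(5):
            fv = F.extract_all_features(random_walk(seed, n=200))
            for name in ("straightness", "efficiency", "trappedness", "anisotropy"):
                assert 0.0 <= fv[name] <= 1.0, name
            assert fv["asymmetry"] >= 0.0
            assert fv["gyration_radius"] >= 0.0
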