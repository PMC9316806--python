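"""Kabsch superposition and RMSD series/distributions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tetrastab.distributions import histogram_distribution
from tetrastab.errors import DegenerateGeometryError, DimensionError, SelectionError
from tetrastab.superpose import (
    CA_SELECTION,
    AtomSelection,
    kabsch_superpose,
    rmsd_distribution,
    rmsd_series,
)
from tetrastab.synthetic import TrajectorySimConfig, simulate_trajectory

from .oracles import grid_rmsd_oracle


def raw_rmsd(a, b):
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(0, 3, (8, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_pure_translation(self, rng):
        pts = rng.normal(0, 3, (8, 3))
        _, _, rmsd = kabsch_superpose(pts + np.array([5.0, 0.0, 0.0]), pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        """Applying any proper rotation+translation to mobile leaves the
        minimized RMSD unchanged."""
        ref = rng.normal(0, 3, (10, 3))
        mob = ref + rng.normal(0, 0.5, ref.shape)
        _, _, base = kabsch_superpose(mob, ref)
        for seed in range(5):
            g = np.random.default_rng(seed)
            r = Rotation.from_euler("zyz", g.uniform(0, 360, 3), degrees=True).as_matrix()
            t = g.uniform(-10, 10, 3)
            _, _, moved = kabsch_superpose(mob @ r.T + t, ref)
            assert moved == pytest.approx(base, abs=1e-9)

    def test_symmetry(self, rng):
        a = rng.normal(0, 3, (7, 3))
        b = a + rng.normal(0, 1, a.shape)
        assert kabsch_superpose(a, b)[2] == pytest.approx(kabsch_superpose(b, a)[2], abs=1e-9)

    def test_minimality_vs_raw(self, rng):
        for _ in range(20):
            a = rng.normal(0, 4, (6, 3))
            b = rng.normal(0, 4, (6, 3))
            assert kabsch_superpose(a, b)[2] <= raw_rmsd(a, b) + 1e-12

    def test_rotation_always_proper(self, rng):
        for _ in range(20):
            a = rng.normal(0, 4, (5, 3))
            b = rng.normal(0, 4, (5, 3))
            rot, _, _ = kabsch_superpose(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-9)

    def test_square_with_out_of_plane_displacement_matches_oracle(self):
        """Planar unit square vs. rotated copy with one corner lifted 1 Å."""
        ref = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mob = ref @ rot90.T
        mob[0, 2] += 1.0
        _, _, rmsd = kabsch_superpose(mob, ref)
        oracle, step = grid_rmsd_oracle(mob, ref)
        bound = np.sqrt(2.0) * np.deg2rad(step)  # max point radius ~ sqrt(2)/2 per point pair
        assert rmsd <= oracle + 1e-9
        assert oracle - rmsd <= bound

    def test_oracle_equivalence_random_configs(self, rng):
        from .conftest import random_points

        for _ in range(8):
            n = int(rng.integers(5, 11))
            ref = random_points(rng, n)
            mob = random_points(rng, n)
            _, _, rmsd = kabsch_superpose(mob, ref)
            oracle, step = grid_rmsd_oracle(mob, ref, coarse_deg=12.0, refinements=2)
            radius = max(np.linalg.norm(mob - mob.mean(axis=0), axis=1).max(), 1.0)
            assert rmsd <= oracle + 1e-9
            assert oracle - rmsd <= 2.0 * radius * np.deg2rad(step)

    def test_count_mismatch(self, rng):
        with pytest.raises(DimensionError):
            kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))

    def test_too_few_points(self):
        with pytest.raises(DimensionError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degenerate(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_mass_weights_shift_optimum(self, rng):
        """With one dominant weight the fit centers on that atom."""
        ref = rng.normal(0, 3, (6, 3))
        mob = ref.copy()
        mob[0] += 2.0
        w = np.array([100.0, 1, 1, 1, 1, 1])
        _, _, weighted = kabsch_superpose(mob, ref, weights=w)
        _, _, uniform = kabsch_superpose(mob, ref)
        assert weighted != pytest.approx(uniform, abs=1e-6)


class TestRMSDSeries:
    def test_zero_fluctuation_all_zero(self, tetramer, toy_spec):
        traj, _ = simulate_trajectory(tetramer, TrajectorySimConfig(n_frames=5, sigma=0.0, seed=1), toy_spec)
        series = rmsd_series(traj)
        assert np.allclose(series.values, 0.0, atol=1e-9)
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotations_give_zero(self, tetramer):
        from tetrastab.core import Trajectory

        frames = []
        for angle in (0, 30, 125, 260):
            r = Rotation.from_euler("xyz", [angle, angle / 2, 10], degrees=True).as_matrix()
            frames.append(tetramer.coords @ r.T + angle * 0.1)
        traj = Trajectory(tetramer, np.stack(frames))
        series = rmsd_series(traj)
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_gaussian_noise_mean_matches_sqrt3_sigma(self, tetramer, toy_spec):
        """iid sigma-noise around the clean reference concentrates the
        minimized RMSD at sqrt(3)*sigma."""
        sigma = 1.0
        traj, truth = simulate_trajectory(
            tetramer, TrajectorySimConfig(n_frames=200, sigma=sigma, seed=5), toy_spec
        )
        series = rmsd_series(traj, reference=tetramer)
        expect = np.sqrt(3.0) * sigma
        assert truth.expected_mean_rmsd == pytest.approx(expect)
        assert abs(series.values.mean() - expect) / expect < 0.05

    def test_empty_selection_raises(self, tetramer, stable_traj):
        traj, _ = stable_traj
        with pytest.raises(SelectionError):
            rmsd_series(traj, selection=AtomSelection(atom_names=frozenset({"ZZ"})))

    def test_reference_frame_value_is_zero(self, stable_traj):
        traj, _ = stable_traj
        series = rmsd_series(traj, reference=3)
        assert series.values[3] == pytest.approx(0.0, abs=1e-9)


class TestDistribution:
    def test_constant_series_single_bin(self):
        d = histogram_distribution(np.full(10, 2.5), n_bins=5)
        assert d.densities.size == 1
        assert d.mean == d.median == pytest.approx(2.5)
        assert d.mode_bin_center == pytest.approx(2.5)

    def test_hand_counted_two_bins(self):
        d = histogram_distribution(np.array([1.0, 1.0, 3.0, 3.0]), n_bins=2, hist_range=(1.0, 3.0))
        assert d.densities[0] == pytest.approx(d.densities[1])
        widths = np.diff(d.bin_edges)
        assert float(np.sum(d.densities * widths)) == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance_of_mean(self, rng, tetramer, toy_spec):
        traj, _ = simulate_trajectory(tetramer, TrajectorySimConfig(n_frames=30, sigma=0.5, seed=2), toy_spec)
        series = rmsd_series(traj, reference=tetramer)
        d1 = rmsd_distribution(series, n_bins=10)
        doubled = type(series)(
            values=series.values * 2, times=series.times, reference_tag=series.reference_tag,
            selection=series.selection,
        )
        d2 = rmsd_distribution(doubled, n_bins=10)
        assert d2.mean == pytest.approx(2 * d1.mean)

    def test_density_integrates_to_one(self, rng):
        d = histogram_distribution(rng.normal(5, 2, 500), n_bins=37)
        widths = np.diff(d.bin_edges)
        assert float(np.sum(d.densities * widths)) == pytest.approx(1.0, abs=1e-9)
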